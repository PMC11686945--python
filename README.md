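# phenoshift

Phenological-shift detection and climate-tracking analysis for estuarine
monitoring series.

Long-term monitoring programs sample fish, zooplankton and phytoplankton
monthly for decades.  As temperature and salinity trend, the *timing* of
each taxon's seasonal abundance peak can drift — and when predators and
prey drift at different rates, food webs can decouple (the match–mismatch
problem).  `phenoshift` turns long-format monthly abundance and
water-quality tables into quantitative answers to three questions: which
taxa are shifting their phenology, whether those shifts track the local
climate trend, and how diverse the trends are within and between trophic
groups.

## The model

For each taxon × station stratum the yearly date of peak abundance
(mid-month convention, circularly unwrapped across the calendar boundary)
gives three Pearson correlations on a common set of n years:

* **PT** — peak day-of-year vs. year (the phenological trend),
* **CT** — climate covariate vs. year (the local climate trend),
* **PC** — peak day-of-year vs. covariate (climate sensitivity),

each Fisher-transformed, z = arctanh(r), with var(z) = 1/(n−3).  Because
every pair of effect sizes shares a variable, the stratum carries a full
3×3 sampling covariance block (the overlapping-correlations formula).  The
stacked triplets enter a trivariate mixed-effects meta-regression

    z = Wβ + ε + u,   Var(z) = V + Σ_g Z_g (I ⊗ T_g) Z_gᵀ

fitted by maximum likelihood (β profiled out by GLS), with random effects
for series start/end year and station-within-region.  Its output is a
triplet of linearized slopes per group with 95% Wald CIs.  A stratum
*tracks* its climate when the three slopes are congruent — a significant
advance (PT < 0) in a warming system (CT > 0) must come with a significant
negative PC — or when both phenology and climate are stationary.
Trend diversity per trophic group is summarized by Bayesian 95% confidence
ellipses in (PT, CT) space, their areas and pairwise overlaps.

A synthetic-data generator with known ground truth (drifting
Gaussian-on-the-circle seasonal peaks forced by trending, noisy climate)
makes the whole chain testable end to end; see `docs/methods.md` for the
full model description and conventions.

## Worked example

```python
from phenoshift import synthetic, pipeline

cfg = synthetic.preset("chesapeake-like", taxa_per_group=1,
                       regions_per_estuary=1, stations_per_region=1,
                       b_PT=-1.5, seed=7)          # a -1.5 d/yr advance
monitoring, climate, truth = synthetic.simulate(cfg)
res = pipeline.run_pipeline(monitoring, climate, covariate="temperature")
for s, v in zip(res.slopes, res.verdicts):
    print(f"{s.group['taxon']:>16}  PT={s.PT.estimate:+.3f} "
          f"[{s.PT.ci_low:+.3f}, {s.PT.ci_high:+.3f}]  "
          f"CT={s.CT.estimate:+.3f}  PC={s.PC.estimate:+.3f}  "
          f"-> {v.status} ({v.direction})")
```

prints

```
          fish_1  PT=-0.401 [-0.779, -0.024]  CT=+1.553  PC=-0.414  -> tracking_shift (advancing)
 phytoplankton_1  PT=-0.918 [-1.296, -0.541]  CT=+1.553  PC=-0.976  -> tracking_shift (advancing)
   zooplankton_1  PT=-0.849 [-1.226, -0.472]  CT=+1.553  PC=-0.759  -> tracking_shift (advancing)
```

Read: in this simulated warming estuary (CT ≈ +1.55 on the Fisher-z scale,
i.e. a near-deterministic warming trend), all three taxa show significant
negative PT slopes — peaks arriving earlier — and significantly negative
climate sensitivities consistent with the warming, so each is classified as
tracking its environment with an advancing phenology, exactly the
configuration the generator was told to produce.

The numbered scripts under `analysis/` run the same stages over three
simulated estuaries (San Francisco-, Chesapeake- and Massachusetts
Bay-like conditions, differing in whether salinity or temperature trends
dominate) and write slope tables, tracking rates, ellipse summaries and
comparison statistics under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_extract_phenology.py
...
python analysis/07_summaries.py
```

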