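import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from phenoshift import meta_model as mm
from phenoshift import synthetic
from phenoshift.effect_sizes import EffectSizeTriplet, CorrelationTriplet
from helpers import dense_gls


def _manual_effect(z, Sigma, n=23, **stratum):
    trip = CorrelationTriplet(p_PT=np.tanh(z[0]), p_CT=np.tanh(z[1]),
                              p_PC=np.tanh(z[2]), n=n)
    return EffectSizeTriplet(z=np.asarray(z, dtype=float),
                             Sigma=np.asarray(Sigma, dtype=float), n=n,
                             triplet=trip, stratum=stratum)


class TestBuildDesign:
    def test_no_moderators_three_indicator_columns(self):
        effects = [_manual_effect([0.1, 0.2, 0.3], 0.05 * np.eye(3), taxon="a"),
                   _manual_effect([0.0, 0.1, 0.2], 0.05 * np.eye(3), taxon="b")]
        d = mm.build_design(effects)
        assert d.W.shape == (6, 3)
        assert (d.W.sum(axis=1) == 1).all()

    def test_two_level_moderator_doubles_columns(self):
        effects = [
            _manual_effect([0.1, 0.2, 0.3], 0.05 * np.eye(3), group="x"),
            _manual_effect([0.0, 0.1, 0.2], 0.05 * np.eye(3), group="y"),
        ]
        d = mm.build_design(effects, moderators=("group",))
        assert d.W.shape == (6, 6)

    def test_duplicate_moderator_rejected(self):
        effects = [_manual_effect([0.1, 0.2, 0.3], 0.05 * np.eye(3), g="x")]
        with pytest.raises(mm.DesignError, match="duplicate"):
            mm.build_design(effects, moderators=("g", "g"))

    def test_unresolvable_moderator_level_rejected(self):
        effects = [_manual_effect([0.1, 0.2, 0.3], 0.05 * np.eye(3))]
        with pytest.raises(mm.DesignError, match="unresolvable"):
            mm.build_design(effects, moderators=("missing_factor",))


class TestFitML:
    def test_single_stratum_saturated_returns_its_effect_sizes(self):
        z = np.array([-0.3, 0.5, -0.4])
        effects = [_manual_effect(z, 0.05 * np.eye(3), taxon="a")]
        fit = mm.fit_ml(mm.build_design(effects))
        assert np.allclose(fit.beta, z, atol=1e-10)
        assert np.allclose(fit.se, np.sqrt(0.05), atol=1e-10)

    def test_identical_diagonal_blocks_give_arithmetic_means(self, rng):
        zs = rng.normal(0, 0.5, (7, 3))
        effects = [_manual_effect(z, 0.04 * np.eye(3), taxon=f"t{i}")
                   for i, z in enumerate(zs)]
        fit = mm.fit_ml(mm.build_design(effects))
        assert np.allclose(fit.beta, zs.mean(axis=0), atol=1e-10)

    def test_gls_closed_form_with_fixed_variance(self, rng):
        """With variance components fixed (none estimated), the fit equals
        the dense GLS closed form on random designs to 1e-8."""
        for _ in range(20):
            m = int(rng.integers(2, 12))
            effects = []
            for i in range(m):
                A = rng.normal(0, 0.2, (3, 3))
                Sigma = A @ A.T + 0.05 * np.eye(3)
                effects.append(_manual_effect(rng.normal(0, 0.5, 3), Sigma,
                                              taxon=f"t{i}",
                                              group=f"g{i % 2}"))
            design = mm.build_design(effects, moderators=("group",))
            fit = mm.fit_ml(design)
            Omega = np.zeros((3 * m, 3 * m))
            for i, e in enumerate(effects):
                Omega[3 * i:3 * i + 3, 3 * i:3 * i + 3] = e.Sigma
            beta, cov = dense_gls(design.z, design.W, Omega)
            assert np.allclose(fit.beta, beta, atol=1e-8)
            assert np.allclose(fit.cov_beta, cov, atol=1e-8)

    def test_stratum_order_invariance(self, rng):
        effects, _ = synthetic.simulate_effect_sets(
            25, [-0.3, 0.4, -0.35], [0.04, 0.02, 0.03], seed=3)
        fit1 = mm.fit_ml(mm.build_design(effects, random=("stratum",)),
                         restarts=1)
        perm = rng.permutation(len(effects))
        fit2 = mm.fit_ml(mm.build_design([effects[i] for i in perm],
                                         random=("stratum",)), restarts=1)
        assert np.allclose(fit1.beta, fit2.beta, atol=1e-9)
        assert np.allclose(fit1.loglik, fit2.loglik, atol=1e-7)

    def test_ml_is_local_optimum(self, rng):
        effects, _ = synthetic.simulate_effect_sets(
            30, [-0.3, 0.4, -0.35], [0.04, 0.02, 0.03], seed=7)
        design = mm.build_design(effects, random=("stratum",))
        fit = mm.fit_ml(design, restarts=2)
        from phenoshift.meta_model import _profile_gls
        best = fit.loglik
        T_hat = fit.tau2["stratum"]
        sd = np.sqrt(np.diag(T_hat))
        for _ in range(50):
            pert = sd * np.exp(rng.normal(0, 0.3, 3))
            ll, _, _ = _profile_gls(design, {"stratum": np.diag(pert ** 2)},
                                    reml=False)
            assert ll <= best + 1e-6

    def test_nonconvergence_is_reported_not_raised(self):
        # 2 strata, full 3x3 random covariance: wildly over-parameterized
        effects, _ = synthetic.simulate_effect_sets(
            2, [0.0, 0.0, 0.0], [0.01, 0.01, 0.01], seed=1)
        fit = mm.fit_ml(mm.build_design(effects, random=("stratum",)),
                        diagonal_random=False, restarts=1)
        assert isinstance(fit.converged, bool)  # flag, never an exception

    def test_reml_differs_from_ml_but_close(self):
        effects, _ = synthetic.simulate_effect_sets(
            40, [-0.3, 0.4, -0.35], [0.04, 0.02, 0.03], seed=9)
        design = mm.build_design(effects, random=("stratum",))
        ml = mm.fit_ml(design, method="ML", restarts=1)
        reml = mm.fit_ml(design, method="REML", restarts=1)
        assert not np.allclose(ml.loglik, reml.loglik)
        assert np.allclose(ml.beta, reml.beta, atol=0.05)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestAgainstMetafor:
    """Independent oracle: metafor::rma.mv on the identical design."""

    def test_diagonal_random_effects_match(self, tmp_path):
        effects, _ = synthetic.simulate_effect_sets(
            40, [-0.3, 0.4, -0.35], [0.04, 0.02, 0.03], n_range=(10, 40),
            seed=5)
        design = mm.build_design(effects, random=("stratum",))
        fit = mm.fit_ml(design, restarts=2)

        rows = []
        for i, e in enumerate(effects):
            for t, etype in enumerate(("PT", "CT", "PC")):
                rows.append({"stratum": i, "type": etype, "z": e.z[t]})
        pd.DataFrame(rows).to_csv(tmp_path / "z.csv", index=False)
        V = np.zeros((len(effects) * 3, len(effects) * 3))
        for i, e in enumerate(effects):
            V[3 * i:3 * i + 3, 3 * i:3 * i + 3] = e.Sigma
        np.savetxt(tmp_path / "V.csv", V, delimiter=",")
        script = tmp_path / "fit.R"
        script.write_text("""
            suppressMessages(library(metafor))
            d <- read.csv("z.csv")
            V <- as.matrix(read.csv("V.csv", header=FALSE))
            d$type <- factor(d$type, levels=c("PT","CT","PC"))
            fit <- rma.mv(z ~ type - 1, V=V, random = ~ type | stratum,
                          struct="DIAG", data=d, method="ML")
            cat(jsonlite::toJSON(list(beta=as.numeric(fit$beta), se=fit$se,
                tau2=fit$tau2, ll=as.numeric(logLik(fit))), digits=12))
        """)
        res = subprocess.run(["Rscript", "fit.R"], cwd=tmp_path,
                             capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout[res.stdout.index("{"):])
        assert np.allclose(fit.beta, ref["beta"], atol=1e-5)
        assert np.allclose(fit.se, ref["se"], atol=1e-5)
        assert np.allclose(np.diag(fit.tau2["stratum"]), ref["tau2"],
                           atol=1e-4)
        assert np.allclose(fit.loglik, ref["ll"][0], atol=1e-5)


class TestWaldCI:
    def test_closed_form_interval(self):
        effects = [_manual_effect([0.5, 0.05, 0.0],
                                  np.diag([0.01, 0.01, 0.01]))]
        fit = mm.fit_ml(mm.build_design(effects))
        ci = mm.wald_ci(fit, 0.95)
        pt = ci[ci["effect_type"] == "PT"].iloc[0]
        assert pt["ci_low"] == pytest.approx(0.304, abs=1e-3)
        assert pt["ci_high"] == pytest.approx(0.696, abs=1e-3)
        assert pt["significant"]
        ct = ci[ci["effect_type"] == "CT"].iloc[0]
        assert not ct["significant"]

    def test_invalid_level_rejected(self):
        effects = [_manual_effect([0.1, 0.1, 0.1], 0.05 * np.eye(3))]
        fit = mm.fit_ml(mm.build_design(effects))
        with pytest.raises(ValueError):
            mm.wald_ci(fit, 1.1)


class TestExtractSlopes:
    def test_identity_without_back_transform(self):
        z = np.array([-0.3, 0.5, -0.4])
        fit = mm.fit_ml(mm.build_design(
            [_manual_effect(z, 0.05 * np.eye(3))]))
        (triplet,) = mm.extract_slopes(fit)
        assert triplet.PT.estimate == pytest.approx(z[0])
        assert triplet.scale_of_estimate == "fisher_z"

    def test_back_transform_maps_through_tanh_preserving_order(self):
        z = np.array([-0.3, 0.5, 0.0])
        fit = mm.fit_ml(mm.build_design(
            [_manual_effect(z, 0.05 * np.eye(3))]))
        (raw,) = mm.extract_slopes(fit)
        (bt,) = mm.extract_slopes(fit, back_transform=True)
        assert bt.PC.estimate == pytest.approx(0.0)
        for etype in ("PT", "CT", "PC"):
            c_raw, c_bt = raw.component(etype), bt.component(etype)
            assert c_bt.estimate == pytest.approx(np.tanh(c_raw.estimate))
            assert c_bt.ci_low < c_bt.estimate < c_bt.ci_high
            assert c_bt.significant == c_raw.significant
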