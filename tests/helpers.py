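"""Shared test oracles, independent of the implementation paths they check."""

from __future__ import annotations

import numpy as np


def mc_fisher_cov(R: np.ndarray, n: int, reps: int, seed: int = 0,
                  chunks: int = 40) -> dict[tuple[str, str], tuple[float, float]]:
    """Monte-Carlo covariance of Fisher-z pairs from a trivariate normal.

    Variables are ordered (phenology, time, climate); the sample
    correlations r(P,T), r(P,C), r(T,C) of each replicate are Fisher
    transformed and the empirical covariance of each effect-size pair is
    returned with a chunk-based standard error.

    Keys are effect-size pairs: ("PT","PC"), ("PT","CT"), ("PC","CT").
    """
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R)
    per = max(reps // chunks, 1)
    acc: dict[tuple[str, str], list[float]] = {
        ("PT", "PC"): [], ("PT", "CT"): [], ("PC", "CT"): []}
    for _ in range(chunks):
        X = rng.standard_normal((per, n, 3)) @ L.T
        Xc = X - X.mean(axis=1, keepdims=True)
        S = np.einsum("cni,cnj->cij", Xc, Xc)
        d = np.sqrt(np.einsum("cii->ci", S))
        r = S / (d[:, :, None] * d[:, None, :])
        clip = lambda a: np.arctanh(np.clip(a, -1 + 1e-12, 1 - 1e-12))
        z_PT = clip(r[:, 0, 1])
        z_PC = clip(r[:, 0, 2])
        z_CT = clip(r[:, 1, 2])
        pairz = {("PT", "PC"): (z_PT, z_PC), ("PT", "CT"): (z_PT, z_CT),
                 ("PC", "CT"): (z_PC, z_CT)}
        for p, (za, zb) in pairz.items():
            acc[p].append(float(np.mean(za * zb) - za.mean() * zb.mean()))
    return {p: (float(np.mean(v)), float(np.std(v, ddof=1) / np.sqrt(len(v))))
            for p, v in acc.items()}


def correlation_matrix_from_triplet(r_PT: float, r_CT: float,
                                    r_PC: float) -> np.ndarray:
    """3×3 correlation matrix of (phenology, time, climate)."""
    return np.array([[1.0, r_PT, r_PC],
                     [r_PT, 1.0, r_CT],
                     [r_PC, r_CT, 1.0]])


def random_valid_triplets(k: int, seed: int, max_abs: float = 0.85
                          ) -> list[tuple[float, float, float]]:
    """Random (r_PT, r_CT, r_PC) triplets whose correlation matrix is PD."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < k:
        r = rng.uniform(-max_abs, max_abs, 3)
        R = correlation_matrix_from_triplet(*r)
        if np.linalg.eigvalsh(R)[0] > 0.05:
            out.append(tuple(float(x) for x in r))
    return out


def dense_gls(z: np.ndarray, W: np.ndarray, Omega: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form GLS via explicit dense inversion (linear-algebra oracle)."""
    Oi = np.linalg.inv(Omega)
    cov = np.linalg.inv(W.T @ Oi @ W)
    beta = cov @ W.T @ Oi @ z
    return beta, cov
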