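"""PERMDISP: actual communities vs null simulations in Raup-Crick space.

The stratum's samples are pooled with one equal-sized batch of
null-simulated communities, beta_RC distances are computed over the pool,
the pool is embedded by principal coordinates, and a one-way F statistic on
per-point distances to the own-group centroid is referred to a permutation
distribution.  A significant result (P < .05) reads as deterministic-driven
assembly for the stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import derive_seed
from .io_core import BinaryMatrix, FeatureTable
from .raup_crick import _draw_null_stack, beta_rc, presence_and_weights

__all__ = ["PermdispResult", "permdisp_vs_null", "centroid_distances", "anova_f"]


@dataclass
class PermdispResult:
    f_stat: float
    p_value: float
    centroid_dist_actual: float
    centroid_dist_null: float
    n_perm: int
    seed: int


def _pcoa_embedding(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding of a distance matrix.

    Returns coordinates over all axes with |eigenvalue| above tolerance and
    the eigenvalue signs.  Negative eigenvalues are retained as
    absolute-value-scaled "imaginary" axes whose squared contributions are
    subtracted when measuring distances (the classical PERMDISP correction).
    """
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2.0)
    tol = 1e-8 * max(1.0, float(np.abs(evals).max()))
    keep = np.abs(evals) > tol
    evals = evals[keep]
    evecs = evecs[:, keep]
    coords = evecs * np.sqrt(np.abs(evals))
    return coords, np.sign(evals)


def centroid_distances(dist: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-point distance to its own group's spatial centroid in PCoA space."""
    coords, signs = _pcoa_embedding(dist)
    out = np.empty(dist.shape[0])
    for g in np.unique(groups):
        idx = groups == g
        centroid = coords[idx].mean(axis=0)
        delta2 = (coords[idx] - centroid) ** 2
        d2 = (delta2 * signs).sum(axis=1)  # negative axes subtract
        out[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return out


def anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA F on a vector of values with integer group labels."""
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    k = 0
    for g in np.unique(groups):
        idx = groups == g
        mu = values[idx].mean()
        ss_b += idx.sum() * (mu - grand) ** 2
        ss_w += ((values[idx] - mu) ** 2).sum()
        k += 1
    n = values.size
    if ss_w <= 0 or n <= k:
        return float("nan") if ss_b <= 0 else float("inf")
    return float((ss_b / (k - 1)) / (ss_w / (n - k)))


def permdisp_vs_null(
    m: BinaryMatrix | FeatureTable,
    n_null_sets: int = 1,
    n_reps_rc: int = 999,
    n_perm: int = 999,
    seed: int = 0,
    pool_weights: np.ndarray | None = None,
) -> PermdispResult:
    """Dispersion test of actual vs null-simulated communities.

    One batch of simulated communities per null set is appended to the
    actual samples; beta_RC over the pool provides the distances, using the
    same sampling weights (stratum occupancy, or ``pool_weights`` for a
    regional pool) for both the simulated group and the beta_RC null.
    P-values come from permuting group labels of the centroid distances.
    """
    presence, _, taxon_ids, w = presence_and_weights(m, pool_weights)
    n_actual = presence.shape[0]
    if n_actual < 3:
        raise ValueError("permdisp requires at least 3 actual samples")
    rng_sim = np.random.default_rng(derive_seed(seed, "nullsets"))
    richness = presence.sum(axis=1).astype(np.int64)
    sim_stack = _draw_null_stack(
        np.log(w), np.tile(richness, n_null_sets), 1, rng_sim
    )[0]
    pooled = np.vstack([presence, sim_stack])
    ids = [f"a{i}" for i in range(n_actual)] + [
        f"n{i}" for i in range(sim_stack.shape[0])
    ]
    pooled_ft = FeatureTable(pooled.astype(np.int64), ids, taxon_ids)
    rc = beta_rc(
        pooled_ft,
        n_reps=n_reps_rc,
        seed=derive_seed(seed, "rc"),
        pool_weights=w,
    )
    dist = rc.values.copy()
    np.fill_diagonal(dist, 0.0)
    # beta_RC lives in [-1, 1]; shift to a non-negative dissimilarity scale
    dist = (dist + 1.0) / 2.0
    np.fill_diagonal(dist, 0.0)

    groups = np.array([0] * n_actual + [1] * sim_stack.shape[0])
    z = centroid_distances(dist, groups)
    if not np.isfinite(z).all() or np.allclose(z, 0):
        warnings.warn("degenerate embedding in permdisp; F undefined")
        return PermdispResult(
            float("nan"), float("nan"), float(z[groups == 0].mean()),
            float(z[groups == 1].mean()), n_perm, seed,
        )
    f_obs = anova_f(z, groups)
    rng = np.random.default_rng(derive_seed(seed, "perm"))
    count = 0
    for _ in range(n_perm):
        f_p = anova_f(z, rng.permutation(groups))
        if f_p >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermdispResult(
        float(f_obs),
        float(p),
        float(z[groups == 0].mean()),
        float(z[groups == 1].mean()),
        n_perm,
        seed,
    )
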