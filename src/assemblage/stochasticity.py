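"""Modified stochasticity ratio (MST).

MST compares each observed pairwise dissimilarity D to its expectation E
under the occupancy-weighted, richness-preserving null:

    MST = D / E            if D <= E
    MST = (1 - D) / (1 - E) otherwise   (D_max = 1)

so MST = 1 when the pair looks exactly like a stochastic draw and tends to
0 under strong determinism in either direction (convergence or divergence).
Stratum means above 0.5 are read as stochastic-dominated, below 0.5 as
deterministic-dominated.

Determinism that acts identically on every sample collapses into the
stratum-local occupancy profile and is invisible to a stratum-local null;
pass ``pool_weights`` (e.g. cohort-wide occupancy) to test against a
regional stochastic pool instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .io_core import BinaryMatrix, FeatureTable
from .raup_crick import _draw_null_stack, presence_and_weights

__all__ = ["MSTResult", "mst", "mst_per_sample", "mst_from_components"]


@dataclass
class MSTResult:
    pairwise: np.ndarray  # (n_samples, n_samples), diagonal NaN
    sample_ids: list[str]
    group_mean: float
    dissimilarity_metric: Literal["jaccard", "bray_curtis"]
    null_mean_dissim: np.ndarray
    n_reps: int
    seed: int


def _jaccard_matrix(presence_sx_t: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard dissimilarity on a samples x taxa 0/1 matrix."""
    b = presence_sx_t.astype(np.int64)
    shared = b @ b.T
    sizes = b.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        return 1.0 - shared / union


def _bray_matrix(counts_sx_t: np.ndarray) -> np.ndarray:
    c = counts_sx_t.astype(float)
    mins = np.minimum(c[:, None, :], c[None, :, :]).sum(axis=2)
    totals = c.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        return 1.0 - 2.0 * mins / denom


def mst_from_components(d_obs: float, e_null: float, d_max: float = 1.0) -> float:
    """Scalar MST from an observed and a null-expected dissimilarity."""
    if not (0 <= e_null <= d_max):
        raise ValueError("null expectation outside [0, d_max]")
    if e_null in (0.0, d_max):
        return float("nan")
    if d_obs <= e_null:
        return d_obs / e_null
    return (d_max - d_obs) / (d_max - e_null)


def mst(
    data: BinaryMatrix | FeatureTable,
    n_reps: int = 1000,
    metric: Literal["jaccard", "bray_curtis"] = "jaccard",
    seed: int = 0,
    pool_weights: np.ndarray | None = None,
) -> MSTResult:
    """Pairwise MST over the samples of a stratum.

    Null communities are the weighted richness-preserving draws shared with
    the Raup-Crick module.  For ``bray_curtis`` each null community receives
    the observed sample's non-zero abundances permuted onto its drawn taxa.
    """
    if metric not in ("jaccard", "bray_curtis"):
        raise ValueError(f"unknown metric: {metric!r}")
    if metric == "bray_curtis" and not isinstance(data, FeatureTable):
        raise ValueError("bray_curtis requires a FeatureTable of counts")
    presence, sample_ids, taxon_ids, w = presence_and_weights(data, pool_weights)
    n_s = presence.shape[0]
    if n_s < 2:
        raise ValueError("mst requires at least 2 samples")
    counts = None
    if metric == "bray_curtis":
        frame = data.to_frame()
        counts = frame.loc[sample_ids, taxon_ids].to_numpy()
    richness = presence.sum(axis=1).astype(np.int64)
    rng = np.random.default_rng(int(seed) % (2**32))

    if metric == "jaccard":
        d_obs = _jaccard_matrix(presence)
    else:
        d_obs = _bray_matrix(counts)

    acc = np.zeros((n_s, n_s), dtype=float)
    chunk = max(1, int(2e7 // max(1, n_s * presence.shape[1])))
    done = 0
    log_w = np.log(w)
    while done < n_reps:
        k = min(chunk, n_reps - done)
        stack = _draw_null_stack(log_w, richness, k, rng, chunk=k)
        if metric == "jaccard":
            s64 = stack.astype(np.int64)
            shared = np.matmul(s64, s64.transpose(0, 2, 1))
            union = richness[:, None] + richness[None, :] - shared
            with np.errstate(invalid="ignore", divide="ignore"):
                acc += (1.0 - shared / union).sum(axis=0)
        else:
            for b in range(k):
                null_counts = np.zeros_like(counts, dtype=float)
                for i in range(n_s):
                    vals = counts[i][counts[i] > 0].astype(float)
                    rng.shuffle(vals)
                    idx = np.nonzero(stack[b, i])[0]
                    null_counts[i, idx] = vals[: idx.size]
                acc += _bray_matrix(null_counts)
        done += k
    e_null = acc / n_reps

    degenerate = (e_null <= 0) | (e_null >= 1)
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        warnings.warn("pairs with null expectation 0 or 1 are masked in MST")

    vals = np.where(
        d_obs <= e_null,
        np.divide(d_obs, e_null, out=np.full_like(e_null, np.nan), where=e_null > 0),
        np.divide(
            1.0 - d_obs,
            1.0 - e_null,
            out=np.full_like(e_null, np.nan),
            where=e_null < 1,
        ),
    )
    vals[degenerate] = np.nan
    np.fill_diagonal(vals, np.nan)
    iu = np.triu_indices(n_s, k=1)
    off = vals[iu]
    group_mean = float(np.nanmean(off)) if np.isfinite(off).any() else float("nan")
    return MSTResult(vals, sample_ids, group_mean, metric, e_null, n_reps, seed)


def mst_per_sample(result: MSTResult) -> pd.Series:
    """Mean MST of each sample against its same-stratum partners."""
    if len(result.sample_ids) < 2:
        warnings.warn("singleton stratum: per-sample MST undefined")
        return pd.Series(
            [np.nan] * len(result.sample_ids), index=result.sample_ids, name="mst"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmean(result.pairwise, axis=1)
    return pd.Series(vals, index=result.sample_ids, name="mst")
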