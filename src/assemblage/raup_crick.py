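"""Modified Raup-Crick dissimilarity from an occupancy-weighted,
richness-preserving probabilistic null.

Each null replicate rebuilds every community by drawing its observed
richness from the taxon pool without replacement, with selection
probability proportional to pool-wide occupancy.  The scaled statistic

    beta_RC = 2 * (P[null shares more] + 0.5 * P[tie]) - 1

approaches +1 when observed pairs share fewer taxa than the null
(deterministically dissimilar) and -1 when they share more
(deterministically similar).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import BinaryMatrix

__all__ = ["RCMatrix", "beta_rc", "simulate_null_communities", "presence_and_weights"]


@dataclass
class RCMatrix:
    values: np.ndarray  # (n_samples, n_samples), diagonal NaN
    sample_ids: list[str]
    n_reps: int
    seed: int


def _occupancy_weights(e: np.ndarray) -> np.ndarray:
    w = e.sum(axis=1).astype(float)
    if (w <= 0).any():
        raise ValueError("taxa with zero occupancy in pool")
    return w


def presence_and_weights(data, pool_weights=None):
    """Presence matrix (samples x taxa, bool) plus null sampling weights.

    ``pool_weights`` switches the null pool from stratum-local occupancy to
    externally supplied (e.g. cohort-wide) weights; taxa with zero weight and
    zero occupancy are dropped, while a present taxon with zero weight is an
    error.  Accepts a :class:`FeatureTable` (keeps locally absent taxa so a
    regional pool can draw them) or a :class:`BinaryMatrix`.
    """
    from .io_core import FeatureTable  # local import avoids cycle at module load

    if isinstance(data, FeatureTable):
        presence = data.counts >= 1
        sample_ids = list(data.sample_ids)
        taxon_ids = list(data.taxon_ids)
    elif isinstance(data, BinaryMatrix):
        presence = data.entries.T.astype(bool)
        sample_ids = list(data.sample_ids)
        taxon_ids = list(data.taxon_ids)
    else:
        raise TypeError("expected FeatureTable or BinaryMatrix")
    empty = ~presence.any(axis=1)
    if empty.any():
        warnings.warn("dropping samples with zero richness")
        presence = presence[~empty]
        sample_ids = [s for s, e in zip(sample_ids, empty) if not e]
    occupancy = presence.sum(axis=0).astype(float)
    if pool_weights is None:
        w = occupancy
    else:
        w = np.asarray(pool_weights, dtype=float).copy()
        if w.size != presence.shape[1]:
            raise ValueError("pool_weights length does not match taxon count")
        orphan = (w <= 0) & (occupancy > 0)
        if orphan.any():
            # locally present taxa missing from the regional pool: floor their
            # weight so the null can still draw them
            if not (w > 0).any():
                raise ValueError("pool_weights must contain positive entries")
            warnings.warn(
                f"{int(orphan.sum())} present taxa have zero pool weight; "
                "flooring to the smallest positive weight"
            )
            w[orphan] = w[w > 0].min()
    keep = w > 0
    presence = presence[:, keep]
    w = w[keep]
    taxon_ids = [t for t, k in zip(taxon_ids, keep) if k]
    return presence, sample_ids, taxon_ids, w


def _draw_null_stack(
    log_w: np.ndarray,
    richness: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """(n_reps, n_samples, n_taxa) boolean stack of null communities.

    Gumbel top-k keys realize sequential weighted sampling without
    replacement with probability proportional to occupancy.
    """
    n_s = richness.size
    n_t = log_w.size
    out = np.empty((n_reps, n_s, n_t), dtype=bool)
    cols = np.arange(n_t)
    for lo in range(0, n_reps, chunk):
        hi = min(lo + chunk, n_reps)
        g = rng.gumbel(size=(hi - lo, n_s, n_t))
        keys = g + log_w
        order = np.argsort(-keys, axis=2)
        rank = np.empty_like(order)
        np.put_along_axis(rank, order, np.broadcast_to(cols, order.shape), axis=2)
        out[lo:hi] = rank < richness[None, :, None]
    return out


def simulate_null_communities(
    m, n_sets: int, seed: int = 0, pool_weights: np.ndarray | None = None
) -> list[BinaryMatrix]:
    """Replicate stochastic-assembly communities matching per-sample richness.

    Each set replaces every sample with a weighted random draw of equal
    richness (weights = stratum occupancy, or ``pool_weights`` for a regional
    pool); used as the null group for dispersion testing.
    """
    presence, sample_ids, taxon_ids, w = presence_and_weights(m, pool_weights)
    richness = presence.sum(axis=1).astype(np.int64)
    rng = np.random.default_rng(int(seed) % (2**32))
    stack = _draw_null_stack(np.log(w), richness, n_sets, rng)
    return [
        BinaryMatrix(stack[b].T.astype(np.uint8), list(taxon_ids), list(sample_ids))
        for b in range(n_sets)
    ]


def beta_rc(
    m,
    n_reps: int = 999,
    seed: int = 0,
    pool_weights: np.ndarray | None = None,
) -> RCMatrix:
    """Pairwise modified Raup-Crick matrix over the samples of ``m``.

    ``m`` is a :class:`BinaryMatrix` or :class:`FeatureTable`;
    ``pool_weights`` overrides the stratum-local occupancy weighting with a
    regional pool (aligned to ``m``'s taxa).
    """
    presence, sample_ids, _, w = presence_and_weights(m, pool_weights)
    n_s = presence.shape[0]
    if n_s < 2:
        raise ValueError("beta_rc requires at least 2 samples")
    richness = presence.sum(axis=1).astype(np.int64)
    rng = np.random.default_rng(int(seed) % (2**32))

    obs = presence.astype(np.int64)
    obs_shared = obs @ obs.T  # (n_s, n_s)

    gt = np.zeros((n_s, n_s), dtype=np.int64)
    ties = np.zeros((n_s, n_s), dtype=np.int64)
    chunk = max(1, int(2e7 // max(1, n_s * presence.shape[1])))
    done = 0
    log_w = np.log(w)
    while done < n_reps:
        k = min(chunk, n_reps - done)
        stack = _draw_null_stack(log_w, richness, k, rng, chunk=k)
        s64 = stack.astype(np.int64)
        null_shared = np.matmul(s64, s64.transpose(0, 2, 1))
        gt += (null_shared > obs_shared).sum(axis=0)
        ties += (null_shared == obs_shared).sum(axis=0)
        done += k

    frac = (gt + 0.5 * ties) / n_reps
    vals = 2.0 * frac - 1.0
    np.fill_diagonal(vals, np.nan)
    vals = np.clip(vals, -1.0, 1.0)
    return RCMatrix(vals, list(sample_ids), n_reps, seed)
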