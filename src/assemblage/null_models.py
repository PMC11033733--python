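"""Fixed-fixed binary matrix null models and the C-score / SES statistic."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

from ._kernels import quasiswap_repair, sequential_swap_chain
from .io_core import BinaryMatrix

__all__ = [
    "NullEnsemble",
    "SESResult",
    "c_score",
    "sequential_swap",
    "quasiswap",
    "quasiswap_counts",
    "ses",
]


@dataclass
class NullEnsemble:
    """Stack of randomized matrices sharing the source matrix's marginals."""

    matrices: np.ndarray  # (n_sim, n_taxa, n_samples) uint8
    algorithm: Literal["sequential_swap", "quasiswap"]
    n_sim: int
    seed: int
    burn_in: int = 0
    thin: int = 1

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.matrices)

    def __len__(self) -> int:
        return self.n_sim


@dataclass
class SESResult:
    c_obs: float
    null_mean: float
    null_sd: float
    ses: float
    n_sim: int
    classification: Literal["overdispersed", "underdispersed", "indeterminate"]


def c_score(m: BinaryMatrix | np.ndarray) -> float:
    """Mean checkerboard units per taxon pair.

    For taxa i, j with row totals R_i, R_j sharing S_ij samples the pair
    contributes CU_ij = (R_i - S_ij)(R_j - S_ij); the score averages CU over
    all unordered pairs (zero-CU pairs included).
    """
    e = m.entries if isinstance(m, BinaryMatrix) else np.asarray(m, dtype=np.uint8)
    n_taxa = e.shape[0]
    if n_taxa < 2:
        raise ValueError("C-score requires at least 2 taxa")
    r = e.sum(axis=1).astype(np.int64)
    s = (e.astype(np.int64) @ e.T.astype(np.int64))
    cu = (r[:, None] - s) * (r[None, :] - s)
    iu = np.triu_indices(n_taxa, k=1)
    return float(cu[iu].mean())


def _c_scores_stack(stack: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Vectorized C-score over an (n_sim, taxa, samples) uint8 stack."""
    n_taxa = stack.shape[1]
    iu = np.triu_indices(n_taxa, k=1)
    parts = []
    for lo in range(0, stack.shape[0], chunk):
        s64 = stack[lo : lo + chunk].astype(np.int64)
        r = s64.sum(axis=2)  # (chunk, taxa)
        s = np.matmul(s64, s64.transpose(0, 2, 1))  # (chunk, taxa, taxa)
        cu = (r[:, :, None] - s) * (r[:, None, :] - s)
        parts.append(cu[:, iu[0], iu[1]].mean(axis=1))
    return np.concatenate(parts)


def _has_checkerboard(e: np.ndarray) -> bool:
    r = e.sum(axis=1).astype(np.int64)
    s = e.astype(np.int64) @ e.T.astype(np.int64)
    cu = (r[:, None] - s) * (r[None, :] - s)
    np.fill_diagonal(cu, 0)
    return bool((cu > 0).any())


def sequential_swap(
    m: BinaryMatrix,
    n_sim: int = 10_000,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int = 0,
) -> NullEnsemble:
    """Sequential-swap randomization: a Markov chain of checkerboard flips.

    Defaults follow a standard mixing heuristic: ``burn_in`` = 10x the
    number of presences, ``thin`` = the number of presences.
    """
    e = m.entries.copy()
    fill = int(e.sum())
    if burn_in is None:
        burn_in = 10 * fill
    if thin is None:
        thin = max(fill, 1)
    if not _has_checkerboard(e):
        warnings.warn(
            "matrix has no swappable 2x2 checkerboard submatrix; "
            "returning identical copies (SES undefined downstream)"
        )
        stack = np.repeat(e[None, :, :], n_sim, axis=0)
        return NullEnsemble(stack, "sequential_swap", n_sim, seed, burn_in, thin)
    stack = sequential_swap_chain(e, n_sim, burn_in, thin, int(seed) % (2**32))
    return NullEnsemble(stack, "sequential_swap", n_sim, seed, burn_in, thin)


def _fixed_marginal_fill(
    row_sums: np.ndarray, col_sums: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random non-negative integer matrix with exact marginals.

    Sequential multivariate-hypergeometric rows (Patefield-style), i.e. a
    draw from the independence null over contingency tables.
    """
    remaining = col_sums.astype(np.int64).copy()
    out = np.zeros((row_sums.size, col_sums.size), dtype=np.int64)
    for i, rs in enumerate(row_sums):
        if rs > 0:
            out[i] = rng.multivariate_hypergeometric(remaining, int(rs))
            remaining -= out[i]
    return out


def quasiswap(m: BinaryMatrix, n_sim: int = 1000, seed: int = 0) -> NullEnsemble:
    """Independent fixed-fixed binary matrices via fill-and-repair quasiswap.

    Each member starts from a random integer matrix with the source
    marginals and is repaired to 0/1 by excess-reducing 2x2 moves.
    """
    e = m.entries
    row_sums = e.sum(axis=1).astype(np.int64)
    col_sums = e.sum(axis=0).astype(np.int64)
    if not _has_checkerboard(e):
        warnings.warn(
            "matrix has no swappable 2x2 checkerboard submatrix; "
            "returning identical copies (SES undefined downstream)"
        )
        stack = np.repeat(e[None, :, :], n_sim, axis=0)
        return NullEnsemble(stack, "quasiswap", n_sim, seed, 0, 1)
    ss = np.random.SeedSequence(int(seed) % (2**32))
    child_seeds = ss.generate_state(2 * n_sim, dtype=np.uint32)
    stack = np.empty((n_sim, e.shape[0], e.shape[1]), dtype=np.uint8)
    for b in range(n_sim):
        rng = np.random.default_rng(int(child_seeds[2 * b]))
        filled = _fixed_marginal_fill(row_sums, col_sums, rng)
        repaired = quasiswap_repair(filled, int(child_seeds[2 * b + 1]))
        stack[b] = repaired.astype(np.uint8)
    return NullEnsemble(stack, "quasiswap", n_sim, seed, 0, 1)


def quasiswap_counts(
    counts: np.ndarray, n_sim: int = 1000, seed: int = 0
) -> np.ndarray:
    """Abundance null: integer tables preserving row and column totals.

    Returns an ``(n_sim,) + counts.shape`` stack of independent draws from
    the fixed-marginal independence null (the abundance analogue of
    quasiswap used for niche-breadth nulls).
    """
    counts = np.asarray(counts, dtype=np.int64)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    ss = np.random.SeedSequence(int(seed) % (2**32))
    child_seeds = ss.generate_state(n_sim, dtype=np.uint32)
    out = np.empty((n_sim,) + counts.shape, dtype=np.int64)
    for b in range(n_sim):
        rng = np.random.default_rng(int(child_seeds[b]))
        out[b] = _fixed_marginal_fill(row_sums, col_sums, rng)
    return out


def ses(m: BinaryMatrix, ensemble: NullEnsemble) -> SESResult:
    """Standardized effect size of the C-score against a null ensemble.

    SES = (C_obs - mean(C_null)) / sd(C_null); SES > 2 is classified as
    overdispersed, SES < -2 as underdispersed, otherwise indeterminate.
    A zero null SD yields NaN SES (flagged, not raised).
    """
    c_obs = c_score(m)
    null_scores = _c_scores_stack(ensemble.matrices)
    null_mean = float(null_scores.mean())
    null_sd = float(null_scores.std(ddof=1)) if len(null_scores) > 1 else 0.0
    if null_sd > 0:
        val = (c_obs - null_mean) / null_sd
    else:
        warnings.warn("null C-score SD is zero; SES undefined")
        val = float("nan")
    if np.isnan(val):
        cls = "indeterminate"
    elif val > 2:
        cls = "overdispersed"
    elif val < -2:
        cls = "underdispersed"
    else:
        cls = "indeterminate"
    return SESResult(c_obs, null_mean, null_sd, float(val), ensemble.n_sim, cls)
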