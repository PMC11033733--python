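"""Levins niche breadth and generalist/specialist/neutralist classification.

A taxon's breadth B_j = 1 / sum_i P_ij^2, where P_ij is the fraction of
taxon j's total found in sample i; B ranges from 1 (all abundance in one
sample) to N (even spread over N samples).  Labels come from comparing the
empirical B_j with the 2.5th/97.5th percentiles of its null distribution
under an abundance quasiswap (marginal-fixed integer shuffle) of the count
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .io_core import FeatureTable
from .null_models import quasiswap_counts

__all__ = ["EcotypeCall", "niche_breadth", "classify_ecotypes"]


@dataclass
class EcotypeCall:
    taxon_id: str
    breadth: float
    null_lo: float
    null_hi: float
    label: Literal["generalist", "specialist", "neutralist"]
    n_reps: int
    seed: int


def _breadth_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorized B over columns of a (samples x taxa) count matrix.

    Zero-total columns yield NaN.
    """
    c = counts.astype(float)
    totals = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = c / totals
        return 1.0 / (p**2).sum(axis=0)


def niche_breadth(table: FeatureTable) -> pd.Series:
    """Per-taxon Levins breadth; zero-total taxa are dropped with a warning."""
    b = _breadth_from_counts(table.counts)
    keep = np.isfinite(b)
    if not keep.all():
        dropped = [t for t, k in zip(table.taxon_ids, keep) if not k]
        warnings.warn(f"dropping zero-total taxa from niche breadth: {dropped}")
    return pd.Series(
        b[keep],
        index=[t for t, k in zip(table.taxon_ids, keep) if k],
        name="niche_breadth",
    )


def classify_ecotypes(
    table: FeatureTable, n_reps: int = 1000, seed: int = 0
) -> list[EcotypeCall]:
    """Label each taxon against its quasiswap null breadth distribution.

    generalist: B above the null 97.5th percentile; specialist: below the
    2.5th; neutralist: within the interval (boundaries inclusive).
    """
    keep = table.counts.sum(axis=0) > 0
    # canonical sample order makes labels exactly invariant to row shuffles
    order = np.argsort(np.asarray(table.sample_ids))
    counts = table.counts[order][:, keep]
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    obs = _breadth_from_counts(counts)
    null_stack = quasiswap_counts(counts, n_sim=n_reps, seed=seed)
    # (n_reps, n_taxa) null breadths
    null_b = np.empty((n_reps, counts.shape[1]))
    for r in range(n_reps):
        null_b[r] = _breadth_from_counts(null_stack[r])
    lo = np.nanpercentile(null_b, 2.5, axis=0)
    hi = np.nanpercentile(null_b, 97.5, axis=0)
    calls = []
    for j, t in enumerate(taxa):
        if obs[j] > hi[j]:
            label = "generalist"
        elif obs[j] < lo[j]:
            label = "specialist"
        else:
            label = "neutralist"
        calls.append(
            EcotypeCall(t, float(obs[j]), float(lo[j]), float(hi[j]), label, n_reps, seed)
        )
    return calls
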