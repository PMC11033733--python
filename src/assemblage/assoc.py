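"""Partial Spearman correlation (rank, then Pearson on residuals)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PartialCorrResult", "partial_spearman"]


@dataclass
class PartialCorrResult:
    x_name: str
    y_name: str
    controls: list[str]
    rho: float
    p_value: float
    n: int
    zero_order_rho: float


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), z])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    controls: np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
    control_names: list[str] | None = None,
) -> PartialCorrResult:
    """Spearman correlation of x and y partialling out control variables.

    All variables are rank-transformed, then the Pearson correlation of the
    residuals after linear projection onto the controls is taken; p from a
    t statistic with n - k - 2 degrees of freedom.  The unconditional
    (zero-order) Spearman correlation is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None:
        z = np.zeros((len(x), 0))
    else:
        z = np.asarray(controls, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    if len(x) != len(y) or len(x) != len(z):
        raise ValueError("x, y and controls must have equal lengths")
    names = list(control_names or [f"c{i}" for i in range(z.shape[1])])
    keep = []
    for j in range(z.shape[1]):
        if np.unique(z[:, j]).size > 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping constant control {names[j]!r}")
    z = z[:, keep]
    names = [names[j] for j in keep]
    k = z.shape[1]
    n = len(x)
    if n <= k + 2:
        raise ValueError("need n > number of controls + 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("x and y must be non-constant")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = np.column_stack([stats.rankdata(z[:, j]) for j in range(k)]) if k else z
    if k:
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), rz])) < k + 1:
            raise ValueError("singular control matrix")
        ex = _residualize(rx, rz)
        ey = _residualize(ry, rz)
    else:
        ex, ey = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    rho = float((ex * ey).sum() / denom) if denom > 0 else float("nan")
    df = n - k - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    zero = float(stats.spearmanr(x, y).statistic)
    return PartialCorrResult(x_name, y_name, names, rho, p, n, zero)
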