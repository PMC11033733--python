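"""Two-state continuous-time Markov model for per-calf assembly dynamics.

States: 1 = stochastic, 2 = deterministic.  Transition intensities follow a
proportional-hazards form q_rs(x) = q_rs0 * exp(beta_rs . x) with the
covariate taken at the start of each observation interval.  "Forward"
transitions are stochastic -> deterministic; "backward" the reverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MarkovFit",
    "assign_states",
    "transition_matrix",
    "fit_two_state",
    "hazard_ratios",
]

STATE_STOCHASTIC = 1
STATE_DETERMINISTIC = 2


@dataclass
class MarkovFit:
    q12_0: float
    q21_0: float
    beta12: dict[str, float]
    beta21: dict[str, float]
    se12: dict[str, float]
    se21: dict[str, float]
    loglik: float
    converged: bool
    vcov: np.ndarray
    covariates: list[str]
    n_intervals: int
    message: str = ""


def assign_states(
    mst_per_sample: pd.Series,
    metadata: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Build an assembly panel from per-sample MST and metadata.

    State is deterministic (2) iff MST < threshold, else stochastic (1);
    ties at the threshold go stochastic.  NaN MST records are dropped with a
    warning.  Output columns: calf_id, time, state plus metadata covariates.
    """
    md = metadata.set_index("sample_id")
    common = [s for s in mst_per_sample.index if s in md.index]
    vals = mst_per_sample.loc[common]
    nan_mask = vals.isna()
    if nan_mask.any():
        warnings.warn(f"dropping {int(nan_mask.sum())} records with NaN MST")
        vals = vals[~nan_mask]
    rows = []
    for sid, v in vals.items():
        rec = md.loc[sid]
        state = STATE_DETERMINISTIC if v < threshold else STATE_STOCHASTIC
        row = {
            "calf_id": rec["calf_id"],
            "time": float(rec["week"]),
            "state": state,
            "mst": float(v),
        }
        for col in ("treatment", "health"):
            if col in md.columns:
                row[col] = rec[col]
        rows.append(row)
    panel = pd.DataFrame(rows)
    panel = panel.drop_duplicates(["calf_id", "time"]).sort_values(
        ["calf_id", "time"], kind="stable"
    )
    return panel.reset_index(drop=True)


def transition_matrix(q12: float, q21: float, t: float) -> np.ndarray:
    """Closed-form 2x2 CTMC transition probability matrix over time t."""
    if q12 < 0 or q21 < 0 or t < 0:
        raise ValueError("rates and time must be non-negative")
    s = q12 + q21
    if s == 0:
        return np.eye(2)
    e = np.exp(-s * t)
    p11 = (q21 + q12 * e) / s
    p22 = (q12 + q21 * e) / s
    return np.array([[p11, 1.0 - p11], [1.0 - p22, p22]])


def _intervals(panel: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, ...]:
    """Per-interval arrays: dt, from-state, to-state, covariate row (at the
    interval start)."""
    sub = panel.sort_values(["calf_id", "time"], kind="stable")
    calf = sub["calf_id"].to_numpy()
    t = sub["time"].to_numpy(dtype=float)
    s = sub["state"].to_numpy(dtype=int)
    x = sub[covariates].to_numpy(dtype=float) if covariates else np.zeros((len(sub), 0))
    same = calf[1:] == calf[:-1]
    dt = t[1:] - t[:-1]
    if (dt[same] <= 0).any():
        raise ValueError("observation times must be strictly increasing per calf")
    return dt[same], s[:-1][same], s[1:][same], x[:-1][same]


def _nll(theta: np.ndarray, dt, s0, s1, x, k: int) -> float:
    lq12, lq21 = theta[0], theta[1]
    b12 = theta[2 : 2 + k]
    b21 = theta[2 + k : 2 + 2 * k]
    q12 = np.exp(np.clip(lq12 + x @ b12, -30, 10))
    q21 = np.exp(np.clip(lq21 + x @ b21, -30, 10))
    s = q12 + q21
    e = np.exp(-s * dt)
    p11 = (q21 + q12 * e) / s
    p22 = (q12 + q21 * e) / s
    probs = np.where(
        s0 == 1,
        np.where(s1 == 1, p11, 1.0 - p11),
        np.where(s1 == 2, p22, 1.0 - p22),
    )
    return -float(np.log(np.clip(probs, 1e-300, None)).sum())


def _numerical_hessian(fn, theta: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = theta.size
    h = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            f_pp = fn(theta + ei + ej)
            f_pm = fn(theta + ei - ej)
            f_mp = fn(theta - ei + ej)
            f_mm = fn(theta - ei - ej)
            h[i, j] = h[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * eps * eps)
    return h


def fit_two_state(panel: pd.DataFrame, covariates: list[str] | None = None) -> MarkovFit:
    """Maximum-likelihood fit of the two-state panel model.

    Parameters are log baseline intensities (positivity by construction)
    plus per-covariate log-hazard effects on each transition direction.
    Initial intensities come from crude transition counts over person-time.
    Standard errors come from the inverse observed information (numerical
    Hessian at the optimum).
    """
    covariates = list(covariates or [])
    work = panel.copy()
    for c in covariates:
        if work[c].dtype == object:
            # binary-encode two-level string covariates (e.g. health H/UH)
            levels = sorted(work[c].unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {c} has more than 2 levels")
            work[c] = (work[c] == levels[-1]).astype(float)
    dt, s0, s1, x = _intervals(work, covariates)
    if dt.size == 0:
        raise ValueError("panel contains no observation intervals")
    n12 = int(((s0 == 1) & (s1 == 2)).sum())
    n21 = int(((s0 == 2) & (s1 == 1)).sum())
    t1 = float(dt[s0 == 1].sum())
    t2 = float(dt[s0 == 2].sum())
    if n12 == 0 or n21 == 0:
        warnings.warn(
            "no observed transitions in at least one direction; "
            "intensity estimate will sit near the boundary"
        )
    q12_init = max(n12, 0.5) / max(t1, 1e-9)
    q21_init = max(n21, 0.5) / max(t2, 1e-9)
    k = len(covariates)
    theta0 = np.concatenate(
        [[np.log(q12_init), np.log(q21_init)], np.zeros(2 * k)]
    )
    obj = lambda th: _nll(th, dt, s0, s1, x, k)
    bounds = [(-12.0, 6.0)] * 2 + [(-8.0, 8.0)] * (2 * k)
    res = optimize.minimize(obj, theta0, method="L-BFGS-B", bounds=bounds)
    theta = res.x
    hess = _numerical_hessian(obj, theta)
    try:
        vcov = np.linalg.inv(hess)
        ses_all = np.sqrt(np.clip(np.diag(vcov), 0, None))
    except np.linalg.LinAlgError:
        vcov = np.full((theta.size, theta.size), np.nan)
        ses_all = np.full(theta.size, np.nan)
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"two-state Markov fit did not converge: {res.message}")
    beta12 = {c: float(theta[2 + i]) for i, c in enumerate(covariates)}
    beta21 = {c: float(theta[2 + k + i]) for i, c in enumerate(covariates)}
    se12 = {c: float(ses_all[2 + i]) for i, c in enumerate(covariates)}
    se21 = {c: float(ses_all[2 + k + i]) for i, c in enumerate(covariates)}
    return MarkovFit(
        q12_0=float(np.exp(theta[0])),
        q21_0=float(np.exp(theta[1])),
        beta12=beta12,
        beta21=beta21,
        se12=se12,
        se21=se21,
        loglik=-float(res.fun),
        converged=converged,
        vcov=vcov,
        covariates=covariates,
        n_intervals=int(dt.size),
        message=str(res.message),
    )


def hazard_ratios(fit: MarkovFit, z: float = 1.959963984540054) -> pd.DataFrame:
    """Wald hazard-ratio table per transition direction and covariate.

    forward = stochastic -> deterministic; backward = the reverse.
    """
    rows = []
    for direction, betas, ses_ in (
        ("forward", fit.beta12, fit.se12),
        ("backward", fit.beta21, fit.se21),
    ):
        for cov in fit.covariates:
            b, se = betas[cov], ses_[cov]
            with np.errstate(over="ignore"):  # huge SE -> inf bound, not an error
                rows.append(
                    {
                        "transition": direction,
                        "covariate": cov,
                        "hr": float(np.exp(b)),
                        "ci_lo": float(np.exp(b - z * se)),
                        "ci_hi": float(np.exp(b + z * se)),
                    }
                )
    return pd.DataFrame(rows, columns=["transition", "covariate", "hr", "ci_lo", "ci_hi"])
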