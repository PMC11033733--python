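"""Synthetic longitudinal cohorts with known assembly regimes.

The generator emulates a two-arm calf trial (CON/SCB, healthy/unhealthy
subgroups, sampling weeks 1, 2, 3, 6, 8 with attrition) and plants ground
truth for every pipeline stage: stochastic (neutral multinomial) vs
deterministic (Gaussian niche-filtered) assembly per calf-week, optional
generalist/specialist taxa, and a two-state continuous-time Markov chain
with a health-dependent hazard driving per-calf regime dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .io_core import FeatureTable
from .markov import STATE_STOCHASTIC, transition_matrix

__all__ = [
    "CohortConfig",
    "simulate_metacommunity",
    "simulate_neutral_sample",
    "simulate_filtered_sample",
    "plant_ecotypes",
    "simulate_stratum",
    "simulate_cohort",
]

Regime = Literal["neutral", "filtered_convergent", "filtered_divergent"]


@dataclass
class CohortConfig:
    """Knobs for :func:`simulate_cohort`; defaults mirror the emulated design
    (42 calves per arm, subgroups 14/28 and 21/21, ~21 missing samples)."""

    n_calves_per_arm: int = 42
    weeks: tuple[int, ...] = (1, 2, 3, 6, 8)
    n_taxa: int = 120
    lognormal_mean: float = 0.0
    lognormal_sd: float = 1.5
    depth: int = 5000
    regime_schedule: dict[tuple[str, str, int], Regime] | None = None
    filter_strength: float = 5.0
    n_generalists: int = 0
    n_specialists: int = 0
    q12: float = 0.3
    q21: float = 0.2
    beta_health_forward: float = 0.0
    beta_health_backward: float = 0.0
    attrition: int = 21
    con_h: int | None = None
    scb_h: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 10:
            raise ValueError("need at least 10 taxa")
        if list(self.weeks) != sorted(set(self.weeks)):
            raise ValueError("weeks must be strictly increasing")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be >= 0")
        n = self.n_calves_per_arm
        if self.con_h is None:
            self.con_h = int(round(14 / 42 * n))
        if self.scb_h is None:
            self.scb_h = int(round(21 / 42 * n))
        if not (0 <= self.con_h <= n and 0 <= self.scb_h <= n):
            raise ValueError("subgroup sizes exceed arm size")


def simulate_metacommunity(
    n_taxa: int, mean: float = 0.0, sd: float = 1.5, seed: int = 0
) -> np.ndarray:
    """Lognormal metacommunity relative abundances (descending, sum to 1)."""
    if n_taxa < 10:
        raise ValueError("need at least 10 taxa")
    rng = np.random.default_rng(int(seed) % (2**32))
    ab = rng.lognormal(mean, sd, size=n_taxa)
    ab = np.sort(ab)[::-1]
    return ab / ab.sum()


def simulate_neutral_sample(
    pool: np.ndarray, depth: int, seed: int = 0
) -> np.ndarray:
    """Pure drift: a multinomial draw of ``depth`` reads from the pool."""
    rng = np.random.default_rng(int(seed) % (2**32))
    return rng.multinomial(depth, pool / pool.sum())


def filtered_weights(
    pool: np.ndarray, environment: float, optima: np.ndarray, filter_strength: float
) -> np.ndarray:
    """Selection-reweighted pool under Gaussian niche filtering."""
    w = pool * np.exp(-filter_strength * (optima - environment) ** 2)
    if (w > 1e-12).sum() < 5:
        warnings.warn("filter so strong that fewer than 5 taxa remain viable")
    total = w.sum()
    if total <= 0:
        raise ValueError("all taxa filtered out")
    return w / total


def simulate_filtered_sample(
    pool: np.ndarray,
    environment: float,
    optima: np.ndarray,
    filter_strength: float,
    depth: int,
    seed: int = 0,
) -> np.ndarray:
    """Deterministic selection: multinomial draw from the filtered pool.

    ``filter_strength = 0`` reduces exactly to :func:`simulate_neutral_sample`.
    """
    rng = np.random.default_rng(int(seed) % (2**32))
    return rng.multinomial(depth, filtered_weights(pool, environment, optima, filter_strength))


def plant_ecotypes(
    table: FeatureTable,
    n_generalists: int,
    n_specialists: int,
    k_specialist: int = 2,
    seed: int = 0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Overwrite selected taxa with known generalist/specialist profiles.

    Generalists receive a near-even split of their total across all samples;
    specialists concentrate their total in ``k_specialist`` samples.  Returns
    the modified table and a truth frame (taxon_id, planted label).
    """
    n_plant = n_generalists + n_specialists
    if n_plant > table.n_taxa:
        raise ValueError("ecotype plan exceeds taxon count")
    rng = np.random.default_rng(int(seed) % (2**32))
    counts = table.counts.copy()
    n_s = table.n_samples
    totals = counts.sum(axis=0)
    # plant into the most abundant taxa so integer splits stay meaningful
    order = np.argsort(totals)[::-1]
    chosen = order[:n_plant]
    truth = []
    for rank, j in enumerate(chosen):
        total = max(int(totals[j]), n_s * 10)
        if rank < n_generalists:
            base, rem = divmod(total, n_s)
            col = np.full(n_s, base, dtype=np.int64)
            col[:rem] += 1
            counts[:, j] = col
            truth.append({"taxon_id": table.taxon_ids[j], "label": "generalist"})
        else:
            col = np.zeros(n_s, dtype=np.int64)
            hosts = rng.choice(n_s, size=min(k_specialist, n_s), replace=False)
            base, rem = divmod(total, hosts.size)
            col[hosts] = base
            col[hosts[:rem]] += 1
            counts[:, j] = col
            truth.append({"taxon_id": table.taxon_ids[j], "label": "specialist"})
    out = FeatureTable(
        counts,
        list(table.sample_ids),
        list(table.taxon_ids),
        None if table.taxonomy is None else list(table.taxonomy),
    )
    return out, pd.DataFrame(truth, columns=["taxon_id", "label"])


def simulate_stratum(
    regime: Regime,
    n_samples: int,
    pool: np.ndarray,
    optima: np.ndarray,
    environment: float = 0.5,
    filter_strength: float = 5.0,
    depth: int = 1000,
    seed: int = 0,
) -> FeatureTable:
    """Single stratum of samples under one assembly regime (test helper)."""
    rows = []
    for i in range(n_samples):
        s = derive_seed(seed, "stratum", regime, i)
        if regime == "neutral":
            rows.append(simulate_neutral_sample(pool, depth, seed=s))
        elif regime == "filtered_convergent":
            rows.append(
                simulate_filtered_sample(pool, environment, optima, filter_strength, depth, seed=s)
            )
        elif regime == "filtered_divergent":
            env = 0.1 if i % 2 == 0 else 0.9
            rows.append(
                simulate_filtered_sample(pool, env, optima, filter_strength, depth, seed=s)
            )
        else:
            raise ValueError(f"unknown regime: {regime!r}")
    return FeatureTable(
        np.vstack(rows),
        [f"s{i}" for i in range(n_samples)],
        [f"t{j}" for j in range(pool.size)],
    )


def _simulate_states(
    weeks: tuple[int, ...],
    q12: float,
    q21: float,
    health_x: float,
    bf: float,
    bb: float,
    rng: np.random.Generator,
) -> list[int]:
    """Latent CTMC state at each observation week (initial state stochastic)."""
    r12 = q12 * np.exp(bf * health_x)
    r21 = q21 * np.exp(bb * health_x)
    states = [STATE_STOCHASTIC]
    for i in range(1, len(weeks)):
        dt = weeks[i] - weeks[i - 1]
        p = transition_matrix(r12, r21, dt)
        cur = states[-1] - 1
        nxt = rng.choice(2, p=p[cur]) + 1
        states.append(int(nxt))
    return states


def _placeholder_lineage(j: int) -> str:
    phylum = f"Phylum{j % 5}"
    return (
        f"k__Bacteria; p__{phylum}; c__Class{j % 7}; o__Order{j % 9}; "
        f"f__Family{j % 11}; g__Genus{j}"
    )


def simulate_cohort(config: CohortConfig) -> tuple[FeatureTable, pd.DataFrame, dict]:
    """Full cohort: counts, metadata and a ground-truth bundle.

    Per calf the latent assembly state evolves by the two-state CTMC with a
    health hazard multiplier; the state (or a regime-schedule override)
    selects the neutral vs filtered generator for each sampled week.
    Attrition removes ``config.attrition`` random samples.
    """
    seed = config.seed
    pool = simulate_metacommunity(
        config.n_taxa, config.lognormal_mean, config.lognormal_sd,
        seed=derive_seed(seed, "metacommunity"),
    )
    rng_opt = np.random.default_rng(derive_seed(seed, "optima"))
    # optima range deliberately wider than the [0, 1] environment range so
    # moderate filter_strength produces a hard selective filter
    optima = rng_opt.uniform(-1.0, 2.0, size=config.n_taxa)

    calves = []
    n = config.n_calves_per_arm
    for i in range(n):
        calves.append(("CON", "H" if i < config.con_h else "UH", f"C{i + 1:03d}"))
    for i in range(n):
        calves.append(("SCB", "H" if i < config.scb_h else "UH", f"C{n + i + 1:03d}"))

    env_rng = np.random.default_rng(derive_seed(seed, "environments"))
    stratum_env: dict[tuple[str, str, int], float] = {}
    for treatment in ("CON", "SCB"):
        for health in ("H", "UH"):
            for week in config.weeks:
                stratum_env[(treatment, health, week)] = float(env_rng.uniform(0.3, 0.7))

    rows = []
    meta_rows = []
    truth_states: dict[str, dict[int, int]] = {}
    regime_used: dict[str, str] = {}
    for treatment, health, calf_id in calves:
        health_x = 1.0 if health == "UH" else 0.0
        srng = np.random.default_rng(derive_seed(seed, "states", calf_id))
        states = _simulate_states(
            config.weeks, config.q12, config.q21, health_x,
            config.beta_health_forward, config.beta_health_backward, srng,
        )
        truth_states[calf_id] = dict(zip(config.weeks, states))
        for wi, week in enumerate(config.weeks):
            key = (treatment, health, week)
            override = (config.regime_schedule or {}).get(key)
            if override is not None:
                regime = override
            else:
                regime = (
                    "neutral"
                    if states[wi] == STATE_STOCHASTIC
                    else "filtered_convergent"
                )
            sid = f"{calf_id}w{week}"
            draw_seed = derive_seed(seed, "sample", calf_id, week)
            if regime == "neutral":
                vec = simulate_neutral_sample(pool, config.depth, seed=draw_seed)
            elif regime == "filtered_convergent":
                vec = simulate_filtered_sample(
                    pool, stratum_env[key], optima, config.filter_strength,
                    config.depth, seed=draw_seed,
                )
            elif regime == "filtered_divergent":
                # alternate opposed environments within the stratum
                env = 0.1 if derive_seed("divergent", calf_id) % 2 == 0 else 0.9
                vec = simulate_filtered_sample(
                    pool, env, optima, config.filter_strength,
                    config.depth, seed=draw_seed,
                )
            else:
                raise ValueError(f"unknown regime: {regime!r}")
            regime_used[sid] = regime
            rows.append(vec)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "calf_id": calf_id,
                    "week": week,
                    "treatment": treatment,
                    "health": health,
                }
            )

    counts = np.vstack(rows)
    metadata = pd.DataFrame(meta_rows)

    removed: list[str] = []
    if config.attrition > 0:
        arng = np.random.default_rng(derive_seed(seed, "attrition"))
        n_total = len(metadata)
        n_drop = min(config.attrition, n_total - 2)
        drop_idx = arng.choice(n_total, size=n_drop, replace=False)
        removed = metadata.iloc[drop_idx]["sample_id"].tolist()
        keep = np.setdiff1d(np.arange(n_total), drop_idx)
        counts = counts[keep]
        metadata = metadata.iloc[keep].reset_index(drop=True)

    taxon_ids = [f"g{j:03d}" for j in range(config.n_taxa)]
    taxonomy = [_placeholder_lineage(j) for j in range(config.n_taxa)]
    table = FeatureTable(counts, metadata["sample_id"].tolist(), taxon_ids, taxonomy)

    ecotype_truth = pd.DataFrame(columns=["taxon_id", "label"])
    if config.n_generalists or config.n_specialists:
        table, ecotype_truth = plant_ecotypes(
            table, config.n_generalists, config.n_specialists,
            seed=derive_seed(seed, "ecotypes"),
        )

    truth = {
        "markov": {
            "q12": config.q12,
            "q21": config.q21,
            "beta_health_forward": config.beta_health_forward,
            "beta_health_backward": config.beta_health_backward,
        },
        "states": truth_states,
        "regimes": regime_used,
        "ecotypes": ecotype_truth.to_dict(orient="records"),
        "attrition_removed": removed,
        "stratum_environment": {
            "|".join(map(str, k)): v for k, v in stratum_env.items()
        },
    }
    return table, metadata, truth
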