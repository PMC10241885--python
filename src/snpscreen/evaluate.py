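"""Replicated simulation-times-screening experiments and their criteria.

For each replication a fresh study is simulated, screened, and the
membership of every active SNP in the selected set is recorded.  Two
criteria summarize a cell: the per-SNP selection proportion ``P_s^k`` and
the proportion ``P_a`` of replications in which *all* active SNPs are
selected simultaneously.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .screening import (
    METHODS,
    ScreeningConfig,
    default_d,
    method_statistics,
    normalize_method,
    rank_statistics,
)
from .simulate import SimulationConfig, simulate_counts

__all__ = [
    "EvaluationSummary",
    "mc_standard_error",
    "evaluate_method",
    "evaluate_methods",
    "run_grid",
]


def mc_standard_error(p: float, reps: int) -> float:
    """Monte-Carlo standard error of a proportion over ``reps`` replications."""
    return math.sqrt(max(p * (1.0 - p), 0.0) / reps)


@dataclass(frozen=True)
class EvaluationSummary:
    """Selection-proportion criteria for one simulation cell and method.

    ``per_snp_proportion`` maps each active SNP index to the fraction of
    replications selecting it; ``all_selected_proportion`` is the fraction
    selecting every active SNP at once (1.0 for an empty active set, by
    vacuous-truth convention).
    """

    config: SimulationConfig
    method: str
    d: int
    reps: int
    per_snp_proportion: Dict[int, float]
    all_selected_proportion: float

    def __post_init__(self) -> None:
        pa = self.all_selected_proportion
        if self.per_snp_proportion and pa > min(self.per_snp_proportion.values()) + 1e-12:
            raise ValueError("P_a cannot exceed the smallest per-SNP proportion")

    @property
    def all_selected_se(self) -> float:
        return mc_standard_error(self.all_selected_proportion, self.reps)


def _replicate_selections(config, methods, d, reps):
    """Per-method boolean (reps, n_active) selection-membership arrays.

    All methods are evaluated on the same replication draws, which is
    valid (each summary is marginally correct) and halves the runtime of
    method comparisons.
    """
    active = np.array(config.active, dtype=np.int64)
    hits = {meth: np.zeros((reps, active.size), dtype=bool) for meth in methods}
    children = np.random.SeedSequence(config.seed).spawn(reps)
    for rep, child in enumerate(children):
        data = simulate_counts(config, rng=child)
        for meth in methods:
            stats = method_statistics(data.case_counts, data.control_counts, meth)
            top = rank_statistics(stats)[:d]
            hits[meth][rep] = np.isin(active, top)
    return active, hits


def _summarize(config, method, d, reps, active, hits) -> EvaluationSummary:
    per_snp = {int(k): float(hits[:, j].mean()) for j, k in enumerate(active)}
    pa = 1.0 if active.size == 0 else float(hits.all(axis=1).mean())
    return EvaluationSummary(config, method, d, reps, per_snp, pa)


def evaluate_method(
    config: SimulationConfig,
    screening: Optional[ScreeningConfig] = None,
    reps: int = 100,
) -> EvaluationSummary:
    """Replicated simulate-and-screen evaluation of one method.

    ``screening`` defaults to MAX-SIS with the top-d rule at
    ``d = default_d(config.n)``; only the top-d rule is meaningful for the
    selection-proportion criteria.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if screening is None:
        screening = ScreeningConfig("max", d=default_d(config.n))
    if screening.rule != "top_d":
        raise ValueError("evaluate_method supports the top_d rule only")
    d = min(screening.d, config.m)
    active, hits = _replicate_selections(config, [screening.method], d, reps)
    return _summarize(config, screening.method, d, reps, active, hits[screening.method])


def evaluate_methods(
    config: SimulationConfig,
    methods: Sequence[str],
    reps: int = 100,
    d: Optional[int] = None,
) -> Dict[str, EvaluationSummary]:
    """Evaluate several methods on shared replication draws."""
    methods = [normalize_method(meth) for meth in methods]
    if d is None:
        d = default_d(config.n)
    d = min(d, config.m)
    active, hits = _replicate_selections(config, methods, d, reps)
    return {
        meth: _summarize(config, meth, d, reps, active, hits[meth]) for meth in methods
    }


def run_grid(
    models: Sequence[str],
    ns: Sequence[int],
    ws: Sequence[float],
    alphas: Sequence[float],
    methods: Sequence[str] = ("rec", "add", "dom", "max", "pc"),
    m: int = 10_000,
    reps: int = 100,
    seed: int = 0,
    d: Optional[int] = None,
) -> pd.DataFrame:
    """Evaluate a parameter grid; one row per cell, method and criterion.

    Per-cell seeds are derived deterministically from the master seed and
    the cell parameters, so results do not depend on evaluation order.
    The long-format table has columns model, n, w, alpha, method, d,
    reps, snp_index ("all" for P_a), proportion and mc_se.
    """
    rows = []
    for model, n, w, alpha in itertools.product(models, ns, ws, alphas):
        cell_seed = np.random.SeedSequence(
            [seed, ("I", "II", "III", "IV").index(model), n,
             int(round(w * 10**6)), int(round(alpha * 10**6))]
        ).generate_state(1)[0]
        config = SimulationConfig(
            model=model, m=m, n=n, w=w, alpha=alpha, seed=int(cell_seed)
        )
        summaries = evaluate_methods(config, methods, reps=reps, d=d)
        for meth, summ in summaries.items():
            base = dict(
                model=model, n=n, w=w, alpha=alpha,
                method=METHODS[meth], d=summ.d, reps=reps,
            )
            for k, prop in summ.per_snp_proportion.items():
                rows.append(dict(base, snp_index=str(k), proportion=prop,
                                 mc_se=mc_standard_error(prop, reps)))
            rows.append(dict(base, snp_index="all",
                             proportion=summ.all_selected_proportion,
                             mc_se=summ.all_selected_se))
    return pd.DataFrame(rows)
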