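"""Trinomial genotype-count simulation under four genetic models.

Controls follow Hardy-Weinberg genotype proportions at minor allele
frequency ``alpha``.  Active SNPs tilt the case genotype distribution by a
model-specific weight vector applied to the control distribution:

* Model I   (recessive): weights ``(1, 1, lambda)``, default lambda 1.8
* Model II  (additive):  weights ``(1, lambda, 2*lambda - 1)``, default 1.4
* Model III (dominant):  weights ``(1, lambda, lambda)``, default 1.6
* Model IV  (mixture):   active SNPs split into thirds following
  Models I, II and III with their default effect sizes.

Irrelevant SNPs use the control distribution for cases too, so their
genotype is independent of the phenotype.  Count tables are drawn as
independent trinomials: case triples with ``r`` trials, control triples
with ``s`` trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .stats import GenotypeCounts, PopulationSnpModel

__all__ = [
    "MODEL_LAMBDA",
    "SimulationConfig",
    "SimulatedDataset",
    "control_genotype_probs",
    "case_genotype_probs",
    "simulate_counts",
    "simulate_genotype_matrix",
]

#: default effect size per single-model label
MODEL_LAMBDA = {"I": 1.8, "II": 1.4, "III": 1.6}

_MODEL_WEIGHTS = {
    "I": lambda lam: np.array([1.0, 1.0, lam]),
    "II": lambda lam: np.array([1.0, lam, 2.0 * lam - 1.0]),
    "III": lambda lam: np.array([1.0, lam, lam]),
}

_MATRIX_ENTRY_GUARD = 10**8


def control_genotype_probs(alpha: float) -> np.ndarray:
    """Hardy-Weinberg genotype distribution ((1-a)^2, 2a(1-a), a^2)."""
    if not 0 < alpha <= 0.5:
        raise ValueError(f"minor allele frequency must lie in (0, 0.5], got {alpha!r}")
    return np.array([(1 - alpha) ** 2, 2 * alpha * (1 - alpha), alpha**2])


def case_genotype_probs(model: str, lam: float, control_probs) -> np.ndarray:
    """Case conditional genotype distribution under one single-SNP model.

    Applies the model's weight vector to the control distribution and
    renormalizes; ``lam = 1`` reproduces the control distribution (null).
    """
    if model not in _MODEL_WEIGHTS:
        raise ValueError(f"unknown genetic model {model!r}; expected I, II or III")
    if lam < 1:
        raise ValueError(f"effect size lambda must be >= 1, got {lam!r}")
    q = np.asarray(control_probs, dtype=np.float64)
    if q.shape != (3,) or np.any(q < 0) or not math.isclose(q.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("control_probs must be a genotype distribution of length 3")
    weighted = _MODEL_WEIGHTS[model](lam) * q
    return weighted / weighted.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation cell.

    ``w`` is the case:control ratio p:q, so the case count is
    ``r = round(n * w / (1 + w))`` and the control count ``s = n - r``.
    ``active`` lists 0-based indices of associated SNPs (default: the
    first six, or fewer when ``m < 6``).
    """

    model: str
    m: int
    n: int
    w: float = 1.0
    alpha: float = 0.3
    lam: Optional[float] = None
    active: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("I", "II", "III", "IV"):
            raise ValueError(f"model must be one of I, II, III, IV; got {self.model!r}")
        if self.m < 1:
            raise ValueError(f"m must be positive, got {self.m}")
        if not 0 < self.alpha <= 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5], got {self.alpha}")
        if self.w <= 0:
            raise ValueError(f"case:control ratio w must be positive, got {self.w}")
        r, s = self.case_control_sizes()
        if r < 1 or s < 1:
            raise ValueError(f"n={self.n}, w={self.w} gives empty group (r={r}, s={s})")
        if self.active is None:
            object.__setattr__(self, "active", tuple(range(min(6, self.m))))
        else:
            active = tuple(int(k) for k in self.active)
            if any(k < 0 or k >= self.m for k in active) or len(set(active)) != len(active):
                raise ValueError(f"active indices must be distinct and within 0..{self.m - 1}")
            object.__setattr__(self, "active", active)
        if self.lam is not None and self.lam < 1:
            raise ValueError(f"lambda must be >= 1, got {self.lam}")

    def case_control_sizes(self) -> tuple:
        r = int(round(self.n * self.w / (1.0 + self.w)))
        return r, self.n - r

    @property
    def case_fraction(self) -> float:
        r, s = self.case_control_sizes()
        return r / (r + s)

    def active_groups(self):
        """(indices, single-model label, lambda) per homogeneous block."""
        if not self.active:
            return []
        if self.model in MODEL_LAMBDA:
            lam = self.lam if self.lam is not None else MODEL_LAMBDA[self.model]
            return [(np.array(self.active), self.model, lam)]
        # mixture: thirds follow Models I, II, III with their default lambdas
        parts = np.array_split(np.array(self.active), 3)
        return [
            (idx, mdl, MODEL_LAMBDA[mdl])
            for idx, mdl in zip(parts, ("I", "II", "III"))
            if idx.size
        ]

    def population_models(self):
        """Per-SNP-group population models plus the null-SNP model."""
        qc = control_genotype_probs(self.alpha)
        p = self.case_fraction
        null = PopulationSnpModel.from_conditionals(p, qc, qc)
        groups = [
            (idx, PopulationSnpModel.from_conditionals(p, case_genotype_probs(mdl, lam, qc), qc))
            for idx, mdl, lam in self.active_groups()
        ]
        return groups, null


@dataclass(frozen=True)
class SimulatedDataset:
    """Count tables for one simulated study.

    ``case_counts`` and ``control_counts`` are (m, 3) integer arrays;
    every row sums to the study's case/control sizes.
    """

    case_counts: np.ndarray
    control_counts: np.ndarray
    active: np.ndarray
    config: SimulationConfig

    @property
    def m(self) -> int:
        return self.case_counts.shape[0]

    def tables(self) -> Iterator[GenotypeCounts]:
        for case, ctrl in zip(self.case_counts, self.control_counts):
            yield GenotypeCounts(*map(int, case), *map(int, ctrl))

    def table(self, k: int) -> GenotypeCounts:
        return GenotypeCounts(
            *map(int, self.case_counts[k]), *map(int, self.control_counts[k])
        )


def _seed_sequence(config: SimulationConfig, rng) -> np.random.SeedSequence:
    if rng is None:
        return np.random.SeedSequence(config.seed)
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, (int, np.integer)):
        return np.random.SeedSequence(int(rng))
    raise TypeError("rng must be None, an int, or a numpy SeedSequence")


def simulate_counts(config: SimulationConfig, rng=None) -> SimulatedDataset:
    """Draw per-SNP 2x3 count tables for one study.

    Null and active SNP blocks use independent RNG substreams spawned
    from the master seed, so the draw is reproducible and block-wise
    order-independent.
    """
    ss = _seed_sequence(config, rng)
    groups = config.active_groups()
    null_ss, active_ss = ss.spawn(2)
    rng_null = np.random.default_rng(null_ss)
    r, s = config.case_control_sizes()
    qc = control_genotype_probs(config.alpha)

    control = rng_null.multinomial(s, qc, size=config.m)
    case = rng_null.multinomial(r, qc, size=config.m)
    if groups:
        rng_active = np.random.default_rng(active_ss)
        for idx, mdl, lam in groups:
            pc = case_genotype_probs(mdl, lam, qc)
            case[idx] = rng_active.multinomial(r, pc, size=idx.size)
    return SimulatedDataset(
        case.astype(np.int64),
        control.astype(np.int64),
        np.array(config.active, dtype=np.int64),
        config,
    )


def simulate_genotype_matrix(config: SimulationConfig, rng=None):
    """Expand the generative law to a per-sample genotype matrix.

    Returns ``(genotypes, phenotypes)`` where genotypes is an (n, m)
    int8 matrix (rows: r cases then s controls) and phenotypes the
    matching 0/1 vector.  Tabulating the matrix per SNP reproduces the
    count-level distribution of :func:`simulate_counts`.
    """
    if config.n * config.m > _MATRIX_ENTRY_GUARD:
        raise ValueError(
            f"genotype matrix would have {config.n * config.m} entries; "
            f"guard is {_MATRIX_ENTRY_GUARD}"
        )
    ss = _seed_sequence(config, rng)
    null_ss, active_ss = ss.spawn(2)
    rng_null = np.random.default_rng(null_ss)
    r, s = config.case_control_sizes()
    qc = control_genotype_probs(config.alpha)

    geno = np.empty((config.n, config.m), dtype=np.int8)
    cum_null = np.cumsum(qc)[:2]
    geno[:r, :] = _draw_genotypes(rng_null, (r, config.m), cum_null)
    geno[r:, :] = _draw_genotypes(rng_null, (s, config.m), cum_null)
    groups = config.active_groups()
    if groups:
        rng_active = np.random.default_rng(active_ss)
        for idx, mdl, lam in groups:
            pc = case_genotype_probs(mdl, lam, qc)
            geno[:r, idx] = _draw_genotypes(rng_active, (r, idx.size), np.cumsum(pc)[:2])
    pheno = np.concatenate([np.ones(r, dtype=np.int8), np.zeros(s, dtype=np.int8)])
    return geno, pheno


def _draw_genotypes(rng, shape, cum2):
    u = rng.random(shape)
    return (u[..., None] > cum2).sum(axis=-1).astype(np.int8)
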