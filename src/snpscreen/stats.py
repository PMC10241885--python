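"""Association statistics for 2x3 case-control genotype count tables.

The central quantities are the score-based trend statistic ``Z``, its
sample-size-free rescaling ``omega = Z / sqrt(n)`` (algebraically a Pearson
correlation between the score-coded genotype and the 0/1 phenotype), and
the model-robust maximum ``nu``, the largest ``|omega|`` over the
recessive, additive and dominant score vectors.  Population counterparts
of ``omega`` and ``nu`` are provided for probability models, together with
a normalized Pearson chi-square comparator index.

All statistics are computed in double precision.  Degenerate tables (a
score with zero variance, e.g. a monomorphic SNP under the recessive
score) yield an *undefined* :class:`StatValue` with value 0 instead of
raising, so that screening over many SNPs never aborts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "ScoreVector",
    "StatValue",
    "GenotypeCounts",
    "PopulationSnpModel",
    "RECESSIVE",
    "ADDITIVE",
    "DOMINANT",
    "CANONICAL_SCORES",
    "catt_z",
    "adjusted_catt",
    "amax",
    "population_omega",
    "population_nu",
    "pc_index",
    "counts_from_genotypes",
    "counts_matrix_from_genotypes",
    "omega_matrix",
    "nu_vector",
    "phi2_vector",
]

_CANONICAL_TRIPLES = {
    "recessive": (0.0, 0.0, 1.0),
    "additive": (0.0, 0.5, 1.0),
    "dominant": (0.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class ScoreVector:
    """A genotype score triple ``(x0, x1, x2)`` for the trend statistic.

    The three canonical vectors — recessive ``(0, 0, 1)``, additive
    ``(0, 1/2, 1)`` and dominant ``(0, 1, 1)`` — are available as module
    constants and via :meth:`canonical`.
    """

    label: str
    x0: float
    x1: float
    x2: float

    def __post_init__(self) -> None:
        if self.x0 == self.x1 == self.x2:
            raise ValueError("score vector must not be constant")

    @classmethod
    def canonical(cls, label: str) -> "ScoreVector":
        try:
            x0, x1, x2 = _CANONICAL_TRIPLES[label]
        except KeyError:
            raise ValueError(
                f"unknown score label {label!r}; expected one of "
                f"{sorted(_CANONICAL_TRIPLES)}"
            ) from None
        return cls(label, x0, x1, x2)

    def as_array(self) -> np.ndarray:
        return np.array([self.x0, self.x1, self.x2], dtype=np.float64)


RECESSIVE = ScoreVector.canonical("recessive")
ADDITIVE = ScoreVector.canonical("additive")
DOMINANT = ScoreVector.canonical("dominant")
CANONICAL_SCORES = (RECESSIVE, ADDITIVE, DOMINANT)


@dataclass(frozen=True)
class StatValue:
    """A statistic value plus a definedness flag.

    ``defined`` is ``False`` when the variance term in the denominator is
    zero (or the maximum is over an empty set of defined components); by
    convention the value is then 0.
    """

    value: float
    defined: bool = True

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class GenotypeCounts:
    """Case/control genotype counts (aa, Aa, AA coded 0, 1, 2) for one SNP."""

    r0: int
    r1: int
    r2: int
    s0: int
    s1: int
    s2: int

    def __post_init__(self) -> None:
        for name in ("r0", "r1", "r2", "s0", "s1", "s2"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(
                    f"invalid genotype count table {self}: {name}={v!r} "
                    "must be a nonnegative integer"
                )

    @property
    def r(self) -> int:
        return self.r0 + self.r1 + self.r2

    @property
    def s(self) -> int:
        return self.s0 + self.s1 + self.s2

    @property
    def n(self) -> int:
        return self.r + self.s

    def case(self) -> np.ndarray:
        return np.array([self.r0, self.r1, self.r2], dtype=np.int64)

    def control(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2], dtype=np.int64)

    def totals(self) -> np.ndarray:
        return self.case() + self.control()

    def flipped(self) -> "GenotypeCounts":
        """Counts under reversed allele coding (genotype i -> 2 - i)."""
        return GenotypeCounts(self.r2, self.r1, self.r0, self.s2, self.s1, self.s0)


@dataclass(frozen=True)
class PopulationSnpModel:
    """Joint genotype/phenotype probabilities for one SNP.

    ``p`` is the case proportion P(Y=1); ``p0, p1, p2`` are the joint
    probabilities P(G=i, Y=1) and ``q0, q1, q2`` the P(G=i, Y=0).
    """

    p: float
    p0: float
    p1: float
    p2: float
    q0: float
    q1: float
    q2: float

    def __post_init__(self) -> None:
        vals = (self.p, self.p0, self.p1, self.p2, self.q0, self.q1, self.q2)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError(f"probabilities must lie in [0, 1]: {self}")
        if not (0 < self.p < 1):
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if not math.isclose(self.p0 + self.p1 + self.p2, self.p, abs_tol=1e-9):
            raise ValueError("case joint probabilities must sum to p")
        if not math.isclose(self.q0 + self.q1 + self.q2, self.q, abs_tol=1e-9):
            raise ValueError("control joint probabilities must sum to 1 - p")

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def f(self) -> np.ndarray:
        """Marginal genotype distribution f_i = p_i + q_i."""
        return self.case_joint() + self.control_joint()

    def case_joint(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2], dtype=np.float64)

    def control_joint(self) -> np.ndarray:
        return np.array([self.q0, self.q1, self.q2], dtype=np.float64)

    def case_conditional(self) -> np.ndarray:
        return self.case_joint() / self.p

    def control_conditional(self) -> np.ndarray:
        return self.control_joint() / self.q

    @classmethod
    def from_conditionals(
        cls,
        p: float,
        case_probs: Sequence[float],
        control_probs: Sequence[float],
    ) -> "PopulationSnpModel":
        """Build from P(Y=1) and the two conditional genotype distributions."""
        cp = np.asarray(case_probs, dtype=np.float64)
        qp = np.asarray(control_probs, dtype=np.float64)
        if cp.shape != (3,) or qp.shape != (3,):
            raise ValueError("conditional distributions must have length 3")
        for probs, who in ((cp, "case"), (qp, "control")):
            if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{who} conditional probabilities must be a distribution")
        j_case = p * cp
        j_ctrl = (1.0 - p) * qp
        return cls(p, *j_case, *j_ctrl)


# ---------------------------------------------------------------------------
# vectorized kernels
# ---------------------------------------------------------------------------

def _as_count_matrices(case_counts, control_counts):
    case = np.asarray(case_counts, dtype=np.float64)
    control = np.asarray(control_counts, dtype=np.float64)
    if case.ndim == 1:
        case = case[None, :]
    if control.ndim == 1:
        control = control[None, :]
    if case.shape != control.shape or case.shape[1] != 3:
        raise ValueError(
            f"count matrices must both be (m, 3); got {case.shape} and {control.shape}"
        )
    if np.any(case < 0) or np.any(control < 0):
        bad = int(np.argmax(np.any((case < 0) | (control < 0), axis=1)))
        raise ValueError(f"negative genotype counts in table {bad}")
    r = case.sum(axis=1)
    s = control.sum(axis=1)
    if np.any(r == 0) or np.any(s == 0):
        bad = int(np.argmax((r == 0) | (s == 0)))
        raise ValueError(
            f"table {bad} has an empty case or control margin (r={r[bad]:.0f}, "
            f"s={s[bad]:.0f}); both groups must be present"
        )
    return case, control, r, s


def _omega_kernel(case, control, r, s, x):
    """omega for one score vector over an (m, 3) pair of count matrices."""
    n = r + s
    ni = case + control
    num = (s[:, None] * case - r[:, None] * control) @ x
    bracket = n * (ni @ (x * x)) - (ni @ x) ** 2
    denom_sq = r * s * bracket
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = num / np.sqrt(denom_sq)
    omega[bracket <= 0] = np.nan
    return omega


def omega_matrix(case_counts, control_counts) -> np.ndarray:
    """Adjusted trend statistics for many SNPs at once.

    Parameters are (m, 3) case and control count matrices; returns an
    (m, 3) array with columns for the recessive, additive and dominant
    score vectors.  Undefined entries (zero score variance) are NaN.
    """
    case, control, r, s = _as_count_matrices(case_counts, control_counts)
    cols = [
        _omega_kernel(case, control, r, s, sv.as_array())
        for sv in CANONICAL_SCORES
    ]
    return np.stack(cols, axis=1)


def nu_vector(case_counts, control_counts) -> np.ndarray:
    """Max of |omega| over the three canonical scores, per SNP.

    NaN where all three components are undefined.
    """
    om = omega_matrix(case_counts, control_counts)
    with np.errstate(all="ignore"):
        nu = np.nanmax(np.abs(om), axis=1)
    return nu


def phi2_vector(case_counts, control_counts) -> np.ndarray:
    """Pearson chi-square of the 2x3 table divided by n, per SNP.

    Genotype columns with zero total drop out (their expected and observed
    counts are both zero).
    """
    case, control, r, s = _as_count_matrices(case_counts, control_counts)
    n = r + s
    ni = case + control
    e_case = r[:, None] * ni / n[:, None]
    e_ctrl = s[:, None] * ni / n[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ni > 0, (case - e_case) ** 2 / e_case, 0.0) + np.where(
            ni > 0, (control - e_ctrl) ** 2 / e_ctrl, 0.0
        )
    return terms.sum(axis=1) / n


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def _validate_table(counts: GenotypeCounts) -> None:
    if not isinstance(counts, GenotypeCounts):
        raise TypeError(f"expected GenotypeCounts, got {type(counts).__name__}")
    if counts.r == 0 or counts.s == 0:
        raise ValueError(
            f"invalid genotype count table {counts}: both case (r={counts.r}) "
            f"and control (s={counts.s}) groups must be nonempty"
        )


def catt_z(counts: GenotypeCounts, score: ScoreVector) -> StatValue:
    """Trend statistic Z for a 2x3 count table and a score vector.

    Z = sqrt(n) * sum_i X_i (s r_i - r s_i)
        / sqrt( r s [ n sum_i X_i^2 n_i - (sum_i X_i n_i)^2 ] ).

    Asymptotically N(0, 1) under no association.  Returns an undefined
    :class:`StatValue` when the bracketed variance term is <= 0.
    """
    _validate_table(counts)
    x = score.as_array()
    case, control = counts.case().astype(float), counts.control().astype(float)
    r, s, n = float(counts.r), float(counts.s), float(counts.n)
    ni = case + control
    num = math.sqrt(n) * float(x @ (s * case - r * control))
    bracket = n * float((x * x) @ ni) - float(x @ ni) ** 2
    if bracket <= 0:
        return StatValue(0.0, defined=False)
    return StatValue(num / math.sqrt(r * s * bracket))


def adjusted_catt(counts: GenotypeCounts, score: ScoreVector) -> StatValue:
    """Sample-size-free trend statistic omega = Z / sqrt(n), in [-1, 1].

    Equals the Pearson correlation between the score-coded genotype and
    the 0/1 phenotype over the n samples of the table.
    """
    _validate_table(counts)
    x = score.as_array()
    case, control = counts.case().astype(float), counts.control().astype(float)
    r, s, n = float(counts.r), float(counts.s), float(counts.n)
    ni = case + control
    num = float(x @ (s * case - r * control))
    bracket = n * float((x * x) @ ni) - float(x @ ni) ** 2
    if bracket <= 0:
        return StatValue(0.0, defined=False)
    return StatValue(num / math.sqrt(r * s * bracket))


def amax(counts: GenotypeCounts) -> StatValue:
    """Max of |omega| over the recessive, additive and dominant scores.

    Components with zero score variance are excluded; if all three are
    undefined the result is an undefined StatValue with value 0.
    """
    _validate_table(counts)
    parts = [adjusted_catt(counts, sv) for sv in CANONICAL_SCORES]
    defined = [abs(sv.value) for sv in parts if sv.defined]
    if not defined:
        return StatValue(0.0, defined=False)
    return StatValue(max(defined))


def population_omega(model: PopulationSnpModel, score: ScoreVector) -> StatValue:
    """Population association measure for one score vector.

    omega = sum_i X_i (q p_i - p q_i)
            / sqrt( p q [ sum_i X_i^2 f_i - (sum_i X_i f_i)^2 ] ),

    zero exactly when genotype and phenotype are independent.
    """
    x = score.as_array()
    pj, qj, f = model.case_joint(), model.control_joint(), model.f
    num = float(x @ (model.q * pj - model.p * qj))
    bracket = float((x * x) @ f) - float(x @ f) ** 2
    if bracket <= 1e-15:
        return StatValue(0.0, defined=False)
    return StatValue(num / math.sqrt(model.p * model.q * bracket))


def population_nu(model: PopulationSnpModel) -> StatValue:
    """Max of |population omega| over the three canonical scores."""
    parts = [population_omega(model, sv) for sv in CANONICAL_SCORES]
    defined = [abs(sv.value) for sv in parts if sv.defined]
    if not defined:
        return StatValue(0.0, defined=False)
    return StatValue(max(defined))


def pc_index(counts: GenotypeCounts) -> StatValue:
    """Pearson chi-square of the 2x3 table divided by n (phi^2).

    A comparator screening index: nonnegative, and 0 iff case and control
    genotype proportions are identical.  Genotype columns that are empty
    in both groups are dropped before the chi-square computation.
    """
    _validate_table(counts)
    table = np.stack([counts.case(), counts.control()])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return StatValue(0.0)
    chi2 = sp_stats.chi2_contingency(table, correction=False).statistic
    return StatValue(float(chi2) / counts.n)


def counts_from_genotypes(genotypes, phenotypes) -> GenotypeCounts:
    """Tabulate a 2x3 count table from per-sample genotypes and phenotypes.

    ``genotypes`` holds values in {0, 1, 2} with missing entries encoded
    as NaN or None; samples with a missing genotype are dropped
    (complete-case per SNP).  ``phenotypes`` holds 1 for cases, 0 for
    controls.
    """
    g = np.array(genotypes, dtype=np.float64)
    y = np.asarray(phenotypes)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError(
            f"genotype and phenotype vectors must be equal-length 1-d arrays; "
            f"got shapes {g.shape} and {y.shape}"
        )
    if not np.isin(y, (0, 1)).all():
        bad = y[~np.isin(y, (0, 1))][0]
        raise ValueError(f"phenotype values must be 0 or 1, found {bad!r}")
    mask = np.isfinite(g)
    if not np.isin(g[mask], (0, 1, 2)).all():
        bad = g[mask][~np.isin(g[mask], (0, 1, 2))][0]
        raise ValueError(f"genotype values must be 0, 1, 2 or missing, found {bad!r}")
    g, y = g[mask], np.asarray(y, dtype=np.int64)[mask]
    case = [int(np.sum((g == i) & (y == 1))) for i in range(3)]
    ctrl = [int(np.sum((g == i) & (y == 0))) for i in range(3)]
    return GenotypeCounts(*case, *ctrl)


def counts_matrix_from_genotypes(genotype_matrix, phenotypes):
    """Vectorized per-SNP tabulation for a samples-by-SNPs matrix.

    Missing genotypes are NaN.  Returns (case_counts, control_counts) as
    (m, 3) integer arrays with per-SNP complete-case handling.
    """
    g = np.asarray(genotype_matrix, dtype=np.float64)
    y = np.asarray(phenotypes, dtype=np.int64)
    if g.ndim != 2 or g.shape[0] != y.shape[0]:
        raise ValueError("genotype matrix rows must match phenotype length")
    is_case = (y == 1)[:, None]
    case = np.stack([((g == i) & is_case).sum(axis=0) for i in range(3)], axis=1)
    ctrl = np.stack([((g == i) & ~is_case).sum(axis=0) for i in range(3)], axis=1)
    return case.astype(np.int64), ctrl.astype(np.int64)
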