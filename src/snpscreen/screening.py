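"""Ranking and active-set selection from per-SNP screening statistics.

Two selection rules are supported: keep the SNPs with the ``d`` largest
statistics (top-d, default size ``d = floor(n / log n)``), or keep every
SNP whose statistic reaches the threshold ``c0 * n**(-tau)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .stats import GenotypeCounts, nu_vector, omega_matrix, phi2_vector

__all__ = [
    "METHODS",
    "ScreeningConfig",
    "ScreeningResult",
    "normalize_method",
    "default_d",
    "rank_statistics",
    "threshold_select",
    "method_statistics",
    "screen_counts",
]

#: canonical method keys -> human-readable names
METHODS = {
    "rec": "REC-SIS",
    "add": "ADD-SIS",
    "dom": "DOM-SIS",
    "max": "MAX-SIS",
    "pc": "PC-SIS-comparator",
}

_ALIASES = {
    "rec": "rec", "rec-sis": "rec", "recessive": "rec",
    "add": "add", "add-sis": "add", "additive": "add",
    "dom": "dom", "dom-sis": "dom", "dominant": "dom",
    "max": "max", "max-sis": "max",
    "pc": "pc", "pc-sis": "pc", "pc-sis-comparator": "pc",
}


def normalize_method(method: str) -> str:
    key = _ALIASES.get(method.strip().lower())
    if key is None:
        raise ValueError(
            f"unknown screening method {method!r}; expected one of {sorted(METHODS)}"
        )
    return key


def default_d(n: int) -> int:
    """Default selection size: the integer part of n / log(n) (natural log)."""
    if n != int(n) or n < 2:
        raise ValueError(f"sample size must be an integer >= 2, got {n!r}")
    return int(math.floor(n / math.log(n)))


def rank_statistics(stats) -> np.ndarray:
    """Indices that sort ``stats`` in decreasing order.

    Ties are broken by smaller index; NaN entries (undefined statistics)
    rank last, after every defined value, themselves in index order.
    Returned indices are 0-based.
    """
    arr = np.asarray(stats, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("statistics must form a 1-d vector")
    # ascending stable sort of the negated values puts NaN last in index order
    return np.argsort(-arr, kind="stable")


def threshold_select(stats, n: int, c0: float, tau: float) -> np.ndarray:
    """Indices whose statistic reaches the threshold ``c0 * n**(-tau)``."""
    if not c0 > 0:
        raise ValueError(f"c0 must be positive, got {c0!r}")
    if not 0 <= tau < 0.5:
        raise ValueError(f"tau must lie in [0, 1/2), got {tau!r}")
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    arr = np.asarray(stats, dtype=np.float64)
    cutoff = c0 * float(n) ** (-tau)
    with np.errstate(invalid="ignore"):
        keep = arr >= cutoff  # NaN compares False: undefined never selected
    return np.flatnonzero(keep)


@dataclass(frozen=True)
class ScreeningConfig:
    """Selection rule parameters.

    ``rule`` is ``"top_d"`` (requires ``d``) or ``"threshold"`` (requires
    ``c0`` and ``tau``).
    """

    method: str
    rule: str = "top_d"
    d: Optional[int] = None
    c0: Optional[float] = None
    tau: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", normalize_method(self.method))
        if self.rule == "top_d":
            if self.d is None or self.d < 1:
                raise ValueError("top_d rule requires a positive integer d")
            if self.c0 is not None or self.tau is not None:
                raise ValueError("c0/tau are threshold-rule parameters, not top_d")
        elif self.rule == "threshold":
            if self.c0 is None or self.tau is None:
                raise ValueError("threshold rule requires c0 and tau")
            if self.d is not None:
                raise ValueError("d is a top_d-rule parameter, not threshold")
            if not self.c0 > 0:
                raise ValueError(f"c0 must be positive, got {self.c0!r}")
            if not 0 <= self.tau < 0.5:
                raise ValueError(f"tau must lie in [0, 1/2), got {self.tau!r}")
        else:
            raise ValueError(f"unknown rule {self.rule!r}; expected top_d or threshold")


@dataclass(frozen=True)
class ScreeningResult:
    """Per-SNP statistics with their decreasing ranking and selected set.

    ``statistics`` may contain NaN for undefined entries; ``ranking`` is a
    0-based permutation; ``selected`` is sorted ascending.
    """

    statistics: np.ndarray
    ranking: np.ndarray
    selected: np.ndarray
    config: ScreeningConfig
    n: int


def _coerce_tables(tables):
    """Accept (case, control) arrays, a dataset object, or GenotypeCounts."""
    if isinstance(tables, tuple) and len(tables) == 2:
        case = np.asarray(tables[0], dtype=np.int64)
        control = np.asarray(tables[1], dtype=np.int64)
        return case, control
    if hasattr(tables, "case_counts") and hasattr(tables, "control_counts"):
        return np.asarray(tables.case_counts), np.asarray(tables.control_counts)
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one count table")
    if not all(isinstance(t, GenotypeCounts) for t in tables):
        raise TypeError("expected GenotypeCounts tables or a (case, control) array pair")
    case = np.stack([t.case() for t in tables])
    control = np.stack([t.control() for t in tables])
    return case, control


def method_statistics(case_counts, control_counts, method: str) -> np.ndarray:
    """The per-SNP screening statistic vector for one method."""
    method = normalize_method(method)
    if method == "max":
        return nu_vector(case_counts, control_counts)
    if method == "pc":
        return phi2_vector(case_counts, control_counts)
    col = {"rec": 0, "add": 1, "dom": 2}[method]
    return np.abs(omega_matrix(case_counts, control_counts)[:, col])


def screen_counts(
    tables, config: ScreeningConfig, *, require_common_margins: bool = True
) -> ScreeningResult:
    """Screen a collection of 2x3 count tables from one study.

    By default all tables must share the same case and control margins.
    With ``require_common_margins=False`` (real data with per-SNP
    missingness) margins may differ and the study-level ``n`` used by the
    threshold rule is the maximum per-SNP total.  Statistics are ranked
    decreasingly and the config's rule is applied.
    """
    case, control = _coerce_tables(tables)
    r = case.sum(axis=1)
    s = control.sum(axis=1)
    if require_common_margins and (np.unique(r).size != 1 or np.unique(s).size != 1):
        raise ValueError(
            "tables have inconsistent case/control margins; "
            "screen_counts expects tables from a single study"
        )
    m = case.shape[0]
    n = int((r + s).max())
    stats = method_statistics(case, control, config.method)
    ranking = rank_statistics(stats)
    if config.rule == "top_d":
        if config.d > m:
            raise ValueError(f"d={config.d} exceeds the number of SNPs m={m}")
        selected = np.sort(ranking[: config.d])
    else:
        selected = threshold_select(stats, n, config.c0, config.tau)
    return ScreeningResult(stats, ranking, selected, config, n)
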