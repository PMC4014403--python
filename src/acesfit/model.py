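"""Domain types for the two-state (telegraph) model of gene expression.

The model tracks a promoter that switches between an inactive (OFF) and an
active (ON) state, transcribes RNA only while ON, translates protein from
RNA, and degrades both species by first-order decay.  Six central dogma rate
constants (CDRCs) parameterize it:

========  =====================================================  ==========
field     meaning                                                units
========  =====================================================  ==========
k_on      OFF -> ON promoter activation                          time^-1
k_off     ON -> OFF promoter inactivation (0 = always ON)        time^-1
k_r       transcription rate from the ON state                   RNA/time
k_p       translation rate per RNA                               protein/(RNA*time)
g_r       RNA degradation                                        time^-1
g_p       protein degradation (often dilution-dominated)         time^-1
========  =====================================================  ==========

All rates share one user-chosen time unit (minutes by default).  Stationary
count distributions are invariant to a uniform rescaling of all six rates,
so the unit choice never changes fitted moments — only rate-dimensioned
ratios (RNA synthesis rate, burst frequency) carry the unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

__all__ = [
    "CDRC_FIELDS",
    "CDRCSet",
    "CDRCRanges",
    "MomentVector",
    "RatioSet",
    "RATIO_FIELDS",
    "ValidationError",
    "compute_ratios",
    "default_ranges",
]

CDRC_FIELDS = ("k_on", "k_off", "k_r", "k_p", "g_r", "g_p")


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


def _require_positive(name: str, value: float, allow_zero: bool = False) -> None:
    ok = math.isfinite(value) and (value >= 0.0 if allow_zero else value > 0.0)
    if not ok:
        bound = "non-negative" if allow_zero else "strictly positive"
        raise ValidationError(f"{name} must be finite and {bound}, got {value!r}")


@dataclass(frozen=True)
class CDRCSet:
    """One complete set of the six central dogma rate constants.

    ``k_off = 0`` is allowed and encodes a constitutive, always-ON gene;
    every other rate must be strictly positive and finite.
    """

    k_on: float
    k_off: float
    k_r: float
    k_p: float
    g_r: float
    g_p: float

    def __post_init__(self) -> None:
        for f in CDRC_FIELDS:
            _require_positive(f, getattr(self, f), allow_zero=(f == "k_off"))

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in CDRC_FIELDS)

    def replace(self, **kwargs: float) -> "CDRCSet":
        values = {f: getattr(self, f) for f in CDRC_FIELDS}
        values.update(kwargs)
        return CDRCSet(**values)

    def scaled(self, factor: float) -> "CDRCSet":
        """All six rates multiplied by ``factor`` (a change of time unit)."""
        _require_positive("factor", factor)
        return CDRCSet(*(v * factor for v in self.as_tuple()))


@dataclass(frozen=True)
class CDRCRanges:
    """Physiological (min, max) interval for each CDRC, shared time unit.

    Ranges bound the ACES search and the test-library grid; they are user
    configuration, typically drawn from genome-wide rate measurements for
    the organism at hand.
    """

    k_on: tuple[float, float]
    k_off: tuple[float, float]
    k_r: tuple[float, float]
    k_p: tuple[float, float]
    g_r: tuple[float, float]
    g_p: tuple[float, float]

    def __post_init__(self) -> None:
        for f in CDRC_FIELDS:
            lo, hi = getattr(self, f)
            _require_positive(f + "_min", lo)
            _require_positive(f + "_max", hi)
            if not lo < hi:
                raise ValidationError(f"range for {f} must have min < max, got ({lo}, {hi})")

    def __getitem__(self, field: str) -> tuple[float, float]:
        if field not in CDRC_FIELDS:
            raise KeyError(field)
        return getattr(self, field)

    def replace(self, **kwargs: tuple[float, float]) -> "CDRCRanges":
        values = {f: getattr(self, f) for f in CDRC_FIELDS}
        values.update(kwargs)
        return CDRCRanges(**values)

    def log_width(self, field: str) -> float:
        lo, hi = self[field]
        return math.log10(hi) - math.log10(lo)

    def contains(self, cdrc: CDRCSet, rtol: float = 1e-9) -> bool:
        for f in CDRC_FIELDS:
            lo, hi = self[f]
            v = getattr(cdrc, f)
            if not (lo * (1.0 - rtol) <= v <= hi * (1.0 + rtol)):
                return False
        return True


def default_ranges() -> CDRCRanges:
    """Fallback ranges when no configuration is supplied.

    Each CDRC spans four decades centred on budding-yeast-scale magnitudes
    (rates in min^-1): switching around minutes-to-hours timescales, mRNA
    decay around typical ~20 min half-lives, protein decay around
    dilution-dominated ~90 min doubling.  These are deliberately generic
    placeholders; quantitative studies should supply measured ranges.
    """
    return CDRCRanges(
        k_on=(1e-3, 1e1),
        k_off=(1e-3, 1e1),
        k_r=(1e-2, 1e2),
        k_p=(1e-2, 1e2),
        g_r=(1e-3, 1e1),
        g_p=(1e-5, 1e-1),
    )


@dataclass(frozen=True)
class MomentVector:
    """First four central moments of a protein count distribution.

    M is the mean, V the variance, S the third central moment (mu3) and K
    the fourth central moment (mu4).  These four numbers are the fitting
    target: they capture protein distribution shape for this model.
    """

    M: float
    V: float
    S: float
    K: float

    def __post_init__(self) -> None:
        _require_positive("M", self.M)
        _require_positive("V", self.V)
        _require_positive("K", self.K)
        if not math.isfinite(self.S):
            raise ValidationError(f"S must be finite, got {self.S!r}")
        # mu4 >= mu2^2 for every distribution (Cauchy-Schwarz); small slack
        # for moments produced by floating-point solves.
        if self.K < self.V**2 * (1.0 - 1e-9):
            raise ValidationError(f"K must satisfy K >= V^2, got K={self.K}, V^2={self.V ** 2}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.M, self.V, self.S, self.K)

    @property
    def skewness(self) -> float:
        """Standardized skewness mu3 / V^1.5 (reporting only)."""
        return self.S / self.V**1.5

    @property
    def kurtosis(self) -> float:
        """Standardized kurtosis mu4 / V^2, no excess subtracted (reporting only)."""
        return self.K / self.V**2


RATIO_FIELDS = (
    "p_on",
    "rna_synth",
    "burst_size",
    "burst_freq",
    "mean_rna",
    "protein_per_rna",
    "friedman_b",
    "friedman_a",
)


@dataclass(frozen=True)
class RatioSet:
    """Eight mechanistically meaningful combinations of the CDRCs.

    p_on            probability the promoter is ON, k_on/(k_on+k_off)
    rna_synth       effective RNA synthesis rate, k_r * p_on
    burst_size      RNAs made per ON period, k_r/k_off (inf when k_off = 0)
    burst_freq      completed OFF->ON cycles per time, k_on*k_off/(k_on+k_off)
    mean_rna        average RNA count, (k_r/g_r) * p_on
    protein_per_rna mean protein per mean RNA, k_p/g_p
    friedman_b      translational burst size, k_p/g_r
    friedman_a      RNAs made per protein lifetime, k_r/g_p
    """

    p_on: float
    rna_synth: float
    burst_size: float
    burst_freq: float
    mean_rna: float
    protein_per_rna: float
    friedman_b: float
    friedman_a: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in RATIO_FIELDS)

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in RATIO_FIELDS}


def compute_ratios(cdrc: CDRCSet) -> RatioSet:
    """Derive the eight mechanistic ratios from a rate-constant set.

    For a constitutive gene (``k_off = 0``) the burst picture degenerates:
    burst_size is reported as ``inf`` and burst_freq as ``0``.
    """
    k_on, k_off, k_r, k_p, g_r, g_p = cdrc.as_tuple()
    p_on = k_on / (k_on + k_off)
    if k_off > 0.0:
        burst_size = k_r / k_off
        burst_freq = k_on * k_off / (k_on + k_off)
    else:
        burst_size = math.inf
        burst_freq = 0.0
    return RatioSet(
        p_on=p_on,
        rna_synth=k_r * p_on,
        burst_size=burst_size,
        burst_freq=burst_freq,
        mean_rna=(k_r / g_r) * p_on,
        protein_per_rna=k_p / g_p,
        friedman_b=k_p / g_r,
        friedman_a=k_r / g_p,
    )


# keep dataclasses' field order in sync with the canonical tuples
assert tuple(f.name for f in fields(CDRCSet)) == CDRC_FIELDS
assert tuple(f.name for f in fields(RatioSet)) == RATIO_FIELDS
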