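"""Coarse-grained rate-constant libraries spanning every parameter regime.

A library is the full Cartesian product of a few log-spaced values per rate
(five by default), filtered to the window of experimentally usable protein
means: below ~17 proteins fluorescence is not measurable, and the default
upper bound of 100,000 captures essentially all budding-yeast genes.  Such
a library exercises an inference method in every regime — bursty,
constitutive, translation- or transcription-dominated — without favouring
the regimes where simpler analytical methods happen to work.
"""

from __future__ import annotations

import logging
import math
from itertools import product

import numpy as np

from .model import CDRC_FIELDS, CDRCRanges, CDRCSet, ValidationError
from .moments import mean_protein

__all__ = ["build_grid", "filter_by_mean", "MEAN_FILTER_LO", "MEAN_FILTER_HI"]

logger = logging.getLogger(__name__)

#: default detectability window for the mean-protein filter
MEAN_FILTER_LO = 17.0
MEAN_FILTER_HI = 100_000.0


def build_grid(ranges: CDRCRanges, n_values: int = 5) -> list[CDRCSet]:
    """Full Cartesian product of ``n_values`` log-spaced values per rate.

    Values include both range endpoints (a single value degenerates to the
    geometric midpoint); the ordering is deterministic — the last rate in
    canonical field order varies fastest — so rebuilt libraries are
    byte-identical.
    """
    if n_values < 1:
        raise ValidationError("n_values must be >= 1")
    axes = []
    for f in CDRC_FIELDS:
        lo, hi = ranges[f]
        if n_values == 1:
            axes.append(np.array([math.sqrt(lo * hi)]))
        else:
            axis = np.logspace(math.log10(lo), math.log10(hi), n_values)
            axis[0], axis[-1] = lo, hi  # endpoints exact, not log/exp round-trips
            axes.append(axis)
    return [CDRCSet(*values) for values in product(*axes)]


def filter_by_mean(
    sets: list[CDRCSet],
    lo: float = MEAN_FILTER_LO,
    hi: float = MEAN_FILTER_HI,
    return_report: bool = False,
):
    """Keep rate sets whose closed-form protein mean lies in [lo, hi].

    Bounds are inclusive (sets are removed only when strictly below ``lo``
    or strictly above ``hi``).  The counts removed at each bound are logged
    and, with ``return_report=True``, returned alongside the surviving list.
    """
    if not lo < hi:
        raise ValidationError("mean filter needs lo < hi")
    kept: list[CDRCSet] = []
    n_below = 0
    n_above = 0
    for s in sets:
        m = mean_protein(s)
        if m < lo:
            n_below += 1
        elif m > hi:
            n_above += 1
        else:
            kept.append(s)
    logger.info(
        "mean filter [%g, %g]: kept %d of %d (%d below, %d above)",
        lo, hi, len(kept), len(sets), n_below, n_above,
    )
    if return_report:
        return kept, {"n_below": n_below, "n_above": n_above, "n_kept": len(kept)}
    return kept
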