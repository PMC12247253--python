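"""Mating-to-first-litter and inter-litter delivery intervals.

Breeding frequency is the proposed compensation mechanism for inbreeding
depression: if more-related pairs shorten the interval between litters,
they produce more litters and offset the pups lost to weaning.  Two
quantities capture it per mating cage:

- first-litter interval: days from the recorded mating date to the first
  birth (missing, not zero, when no mating date was recorded);
- delivery intervals: day gaps between consecutive births, summarised by
  their arithmetic mean per pair (the per-pair mean is the correlation
  unit; a per-gap variant is available from ``delivery_intervals``).

Same-day repeat births are biologically impossible and are treated as data
errors: excluded from the gap list and tallied, never counted as zero
intervals.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .ibd_stats import CorrResult, pearson
from .records_io import LitterRecord
from .trend_scan import TrendSeries, cumulative_scan


@dataclass
class IntervalRecord:
    """Breeding-frequency summary of one mating cage."""

    mating_id: str
    relatedness_pct: Optional[float]
    first_litter_interval: Optional[float]  # days, mating -> first birth
    delivery_intervals: list[float]  # day gaps between consecutive births
    mean_delivery_interval: Optional[float]

    @property
    def n_gaps(self) -> int:
        return len(self.delivery_intervals)


def compute_intervals(
    litters: Sequence[LitterRecord],
    relatedness: Optional[Mapping[str, float]] = None,
) -> tuple[list[IntervalRecord], dict]:
    """Per-pair interval records from date-sorted litters.

    Returns the records plus a tally of excluded nonpositive gaps.  Pairs
    with a single litter yield an empty gap list and an undefined mean.
    """
    groups: "OrderedDict[str, list[LitterRecord]]" = OrderedDict()
    for rec in litters:
        if rec.mating_id is None or rec.birth_date is None:
            continue
        groups.setdefault(rec.mating_id, []).append(rec)

    out: list[IntervalRecord] = []
    n_nonpositive = 0
    for mating_id, recs in groups.items():
        recs = sorted(recs, key=lambda r: r.birth_date)
        gaps: list[float] = []
        for a, b in zip(recs, recs[1:]):
            gap = (b.birth_date - a.birth_date).days
            if gap <= 0:
                n_nonpositive += 1
            else:
                gaps.append(float(gap))
        mating_date = recs[0].mating_date
        if mating_date is not None:
            first = float((recs[0].birth_date - mating_date).days)
            if first <= 0:
                first = None
                n_nonpositive += 1
        else:
            first = None
        rel = relatedness.get(mating_id) if relatedness else None
        out.append(
            IntervalRecord(
                mating_id=mating_id,
                relatedness_pct=rel,
                first_litter_interval=first,
                delivery_intervals=gaps,
                mean_delivery_interval=float(np.mean(gaps)) if gaps else None,
            )
        )
    return out, {"n_nonpositive_gaps_excluded": n_nonpositive}


def interval_relatedness_association(
    records: Sequence[IntervalRecord],
    mode: str = "delivery",
    scope: str = "pooled",
    litters: Optional[Sequence[LitterRecord]] = None,
    relatedness: Optional[Mapping[str, float]] = None,
    **scan_kwargs,
):
    """Association between relatedness and breeding intervals.

    ``mode='first'`` uses the mating-to-first-litter interval,
    ``mode='delivery'`` the per-pair mean delivery interval.  ``scope=
    'pooled'`` returns a single Pearson :class:`CorrResult` over all pairs;
    ``scope='cumulative_scan'`` (delivery mode only) delegates to the
    trend-scan machinery and needs the underlying ``litters`` and
    ``relatedness``.
    """
    if mode not in ("first", "delivery"):
        raise ParameterError(f"unknown mode {mode!r}")
    if scope == "cumulative_scan":
        if mode != "delivery":
            raise ParameterError("cumulative scan is defined for delivery intervals")
        if litters is None or relatedness is None:
            raise ParameterError("cumulative scan needs litters and relatedness")
        return cumulative_scan(
            litters, relatedness, outcome="delivery_interval", **scan_kwargs
        )
    if scope != "pooled":
        raise ParameterError(f"unknown scope {scope!r}")

    xs, ys = [], []
    for rec in records:
        val = (
            rec.first_litter_interval
            if mode == "first"
            else rec.mean_delivery_interval
        )
        if rec.relatedness_pct is None or val is None:
            continue
        xs.append(rec.relatedness_pct)
        ys.append(val)
    return pearson(xs, ys)  # raises UndefinedStatisticError below minimum n


def intervals_to_frame(records: Sequence[IntervalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mating_id": [r.mating_id for r in records],
            "relatedness_pct": [r.relatedness_pct for r in records],
            "first_litter_interval": [r.first_litter_interval for r in records],
            "mean_delivery_interval": [r.mean_delivery_interval for r in records],
            "n_gaps": [r.n_gaps for r in records],
        }
    )
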