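"""Cumulative-window trend scan of relatedness-outcome associations.

The colony's breeding dynamics are probed longitudinally by recomputing the
association between parental relatedness and a reproductive outcome on
every cumulative window: for each cutoff year Y the statistics use all
litters born up to and including Y, so the point at Y uses exactly the data
of Y-1 plus the year-Y litters.  Plotted over Y this traces how the
association built up and decayed across the colony's history, which the
narrative divides into three phases (no effect / inbreeding depression
with compensatory breeding / decoupling), with descriptive boundaries at
1985 and 2015.

Outcomes:

- ``loss_by_mice`` / ``loss_by_litter``: per-pair loss ratios, with both a
  Pearson correlation and the weighted binomial GLM;
- ``born`` / ``weaned``: per-pair totals (Pearson only);
- ``male_loss`` / ``female_loss``: sex-specific losses under the 1:1
  sex-ratio-at-birth assumption (expected males = expected females =
  born/2, losses floored at zero by default);
- ``delivery_interval``: per-pair mean day gap between consecutive litters
  (Pearson only).

:func:`detect_changepoints` makes the by-eye phase segmentation
reproducible: it exhaustively fits a piecewise-constant model to the
Pearson-r sequence and returns the least-squares breakpoint years.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, ParameterError, UndefinedStatisticError
from .ibd_stats import CorrResult, GlmFit, fit_binomial_glm, pearson
from .records_io import LitterRecord

OUTCOMES = (
    "loss_by_mice",
    "loss_by_litter",
    "born",
    "weaned",
    "male_loss",
    "female_loss",
    "delivery_interval",
)

#: descriptive phase boundaries (a boundary year belongs to the later phase)
DEFAULT_PHASE_BOUNDARIES = (1985, 2015)

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass
class SexLossRecord:
    """Per-litter sex-specific loss under the 1:1 birth-ratio assumption."""

    mating_id: str
    birth_year: int
    born: int
    expected_males: float
    expected_females: float
    male_loss: float
    female_loss: float
    floored: bool


@dataclass
class TrendPoint:
    cutoff_year: int
    n_pairs: int
    pearson: Optional[CorrResult]
    glm: Optional[GlmFit]
    outcome: str


@dataclass
class TrendSeries:
    points: list[TrendPoint]
    outcome: str
    boundaries: tuple[int, ...] = DEFAULT_PHASE_BOUNDARIES

    @property
    def phases(self) -> list[str]:
        return [
            _ROMAN[bisect_right(self.boundaries, p.cutoff_year)] for p in self.points
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long-format, plot-ready table.  p-values are floored at 1e-300
        before the -log10 transform to avoid infinities."""
        rows = []
        for point, phase in zip(self.points, self.phases):
            r = point.pearson
            g = point.glm
            rows.append(
                {
                    "cutoff_year": point.cutoff_year,
                    "outcome": point.outcome,
                    "n_pairs": point.n_pairs,
                    "r": r.r if r else np.nan,
                    "r_p": r.p if r else np.nan,
                    "neglog10_r_p": -np.log10(max(r.p, 1e-300)) if r else np.nan,
                    "beta1": g.beta1 if g else np.nan,
                    "mcfadden_r2": g.mcfadden_r2 if g else np.nan,
                    "lrt_p": g.lrt_p if g else np.nan,
                    "neglog10_lrt_p": -np.log10(max(g.lrt_p, 1e-300)) if g else np.nan,
                    "phase": phase,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ChangepointResult:
    years: list[int]
    indices: list[int]
    sse: float
    tied: bool


def sex_specific_losses(
    litters: Sequence[LitterRecord], floor: bool = True
) -> tuple[list[SexLossRecord], dict]:
    """Impute per-sex pre-weaning losses from weaned sex counts.

    With no sex recorded at birth, expected males = expected females =
    born/2 (fractional for odd litters).  A pair weaning more of one sex
    than its expectation contributes zero loss for that sex when
    ``floor=True`` (negative deaths are uninterpretable); flooring events
    are tallied.  Litters without both sex counts are skipped and tallied.
    """
    out: list[SexLossRecord] = []
    n_skipped = n_floored = 0
    for rec in litters:
        if (
            rec.males_weaned is None
            or rec.females_weaned is None
            or rec.born is None
            or rec.birth_date is None
            or rec.mating_id is None
        ):
            n_skipped += 1
            continue
        expected = rec.born / 2.0
        male_loss = expected - rec.males_weaned
        female_loss = expected - rec.females_weaned
        floored = False
        if floor and (male_loss < 0 or female_loss < 0):
            floored = True
            n_floored += 1
            male_loss = max(0.0, male_loss)
            female_loss = max(0.0, female_loss)
        out.append(
            SexLossRecord(
                mating_id=rec.mating_id,
                birth_year=rec.birth_date.year,
                born=rec.born,
                expected_males=expected,
                expected_females=expected,
                male_loss=male_loss,
                female_loss=female_loss,
                floored=floored,
            )
        )
    return out, {"n_skipped": n_skipped, "n_floored": n_floored}


def _litter_frame(
    litters: Sequence[LitterRecord],
    relatedness: Mapping[str, float],
    outcome: str,
    floor_sex: bool,
) -> pd.DataFrame:
    """One row per usable litter with the columns the outcome needs."""
    if outcome in ("male_loss", "female_loss"):
        sexrecs, _ = sex_specific_losses(litters, floor=floor_sex)
        rows = [
            {
                "pair": s.mating_id,
                "year": s.birth_year,
                "loss": s.male_loss if outcome == "male_loss" else s.female_loss,
                "expected": s.expected_males,
            }
            for s in sexrecs
        ]
    else:
        rows = []
        for rec in litters:
            if rec.mating_id is None or rec.birth_date is None:
                continue
            rows.append(
                {
                    "pair": rec.mating_id,
                    "year": rec.birth_date.year,
                    "born": rec.born or 0,
                    "weaned": rec.weaned or 0,
                    "dead": rec.dead if rec.dead is not None else 0,
                    "litters": 1,
                    "loss_litters": 1 if (rec.dead or 0) >= 1 else 0,
                    "date": rec.birth_date.toordinal(),
                }
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    rel = {k: v for k, v in relatedness.items() if v is not None}
    frame["rel"] = frame["pair"].map(rel)
    return frame[frame["rel"].notna()].reset_index(drop=True)


def _cumulative_by_year(frame, col, years, how="sum"):
    """pairs x years matrix of cumulative per-pair aggregates."""
    pivot = frame.pivot_table(
        index="pair", columns="year", values=col, aggfunc=how
    ).reindex(columns=years)
    if how == "sum":
        values = pivot.fillna(0.0).to_numpy(dtype=float).cumsum(axis=1)
        return values, pivot.index.to_numpy()
    # running maximum with missing years carried forward (used for dates)
    return (
        np.fmax.accumulate(pivot.to_numpy(dtype=float), axis=1),
        pivot.index.to_numpy(),
    )


def cumulative_scan(
    litters: Sequence[LitterRecord],
    relatedness: Mapping[str, float],
    outcome: str = "loss_by_mice",
    start_year: int = 1963,
    end_year: int = 2024,
    min_pairs: int = 10,
    with_glm: bool = True,
    boundaries: Sequence[int] = DEFAULT_PHASE_BOUNDARIES,
    floor_sex_losses: bool = True,
) -> TrendSeries:
    """Recompute the relatedness-outcome association on every cumulative
    window ``[.., Y]`` for Y in ``start_year..end_year``.

    ``relatedness`` maps mating IDs to relatedness percent; pairs without a
    value are excluded.  Cutoffs with fewer than ``min_pairs`` eligible
    pairs (or degenerate inputs) yield missing statistics, never errors and
    never zeros.  ``min_pairs=1`` mimics plotting from the very first year
    of records.
    """
    if outcome not in OUTCOMES:
        raise ParameterError(f"unknown outcome {outcome!r}; choose from {OUTCOMES}")
    if start_year > end_year:
        raise ParameterError(f"start_year {start_year} > end_year {end_year}")
    if min_pairs < 1:
        raise ParameterError("min_pairs must be >= 1")

    frame = _litter_frame(litters, relatedness, outcome, floor_sex_losses)
    cutoffs = list(range(start_year, end_year + 1))
    series = TrendSeries(points=[], outcome=outcome, boundaries=tuple(boundaries))
    if frame.empty:
        series.points = [TrendPoint(y, 0, None, None, outcome) for y in cutoffs]
        return series

    ymin, ymax = int(frame["year"].min()), int(frame["year"].max())
    years = np.arange(ymin, ymax + 1)

    if outcome in ("male_loss", "female_loss"):
        cum_loss, pairs_idx = _cumulative_by_year(frame, "loss", years)
        cum_exp, _ = _cumulative_by_year(frame, "expected", years)
    else:
        cum = {
            col: _cumulative_by_year(frame, col, years)[0]
            for col in ("born", "weaned", "dead", "litters", "loss_litters")
        }
        pairs_idx = _cumulative_by_year(frame, "born", years)[1]
        if outcome == "delivery_interval":
            cum_maxdate, _ = _cumulative_by_year(frame, "date", years, how="max")
            first_date = frame.groupby("pair")["date"].min().reindex(pairs_idx).to_numpy()
    rel_vec = frame.groupby("pair")["rel"].first().reindex(pairs_idx).to_numpy()

    for year in cutoffs:
        if year < ymin:
            series.points.append(TrendPoint(year, 0, None, None, outcome))
            continue
        col = min(year, ymax) - ymin

        glm_args = None
        if outcome == "loss_by_mice":
            denom = cum["born"][:, col]
            num = cum["dead"][:, col]
            mask = denom > 0
            y_vals = np.divide(num, denom, out=np.zeros_like(denom), where=mask)
            glm_args = (num, denom)
        elif outcome == "loss_by_litter":
            denom = cum["litters"][:, col]
            num = cum["loss_litters"][:, col]
            mask = denom > 0
            y_vals = np.divide(num, denom, out=np.zeros_like(denom), where=mask)
            glm_args = (num, denom)
        elif outcome in ("born", "weaned"):
            totals = cum[outcome][:, col]
            mask = cum["litters"][:, col] > 0
            y_vals = totals
        elif outcome in ("male_loss", "female_loss"):
            denom = cum_exp[:, col]
            num = cum_loss[:, col]
            mask = denom > 0
            y_vals = np.divide(num, denom, out=np.zeros_like(denom), where=mask)
            glm_args = (num, denom)
        else:  # delivery_interval
            counts = cum["litters"][:, col]
            mask = counts >= 2
            span = cum_maxdate[:, col] - first_date
            with np.errstate(invalid="ignore"):
                y_vals = np.where(mask, span / np.maximum(counts - 1, 1), np.nan)

        n_pairs = int(mask.sum())
        corr = fit = None
        if n_pairs >= min_pairs:
            x = rel_vec[mask]
            y = np.asarray(y_vals, dtype=float)[mask]
            try:
                corr = pearson(x, y)
            except UndefinedStatisticError:
                corr = None
            if with_glm and glm_args is not None:
                try:
                    fit = fit_binomial_glm(x, glm_args[0][mask], glm_args[1][mask])
                except DegenerateDesignError:
                    fit = None
        series.points.append(TrendPoint(year, n_pairs, corr, fit, outcome))
    return series


def annotate_phases(series: TrendSeries, boundaries: Sequence[int]) -> TrendSeries:
    """Relabel the series' phases.  A cutoff equal to a boundary year is
    assigned to the later phase.  Empty boundaries give a single phase."""
    bounds = list(boundaries)
    if bounds != sorted(bounds):
        raise ParameterError(f"phase boundaries must be sorted, got {boundaries}")
    series.boundaries = tuple(bounds)
    return series


def _segment_cost(s1: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    """Squared error of the best constant on values[i:j] via prefix sums."""
    n = j - i
    tot = s1[j] - s1[i]
    return float(s2[j] - s2[i] - tot * tot / n)


def detect_changepoints(
    series: Union[TrendSeries, Sequence[float]],
    k: int,
    years: Optional[Sequence[int]] = None,
) -> ChangepointResult:
    """Least-squares piecewise-constant segmentation of the Pearson-r
    sequence by exhaustive search (k breakpoints, k <= 2).

    Returns the cutoff years at which each new segment begins (matching the
    phase convention that a boundary year opens the later phase).  Exact
    ties are broken toward the earliest breakpoints and flagged.
    """
    if k not in (1, 2):
        raise ParameterError(f"k must be 1 or 2, got {k}")
    if isinstance(series, TrendSeries):
        pts = [(p.cutoff_year, p.pearson.r) for p in series.points if p.pearson]
        yrs = [y for y, _ in pts]
        vals = np.array([v for _, v in pts], dtype=float)
    else:
        vals = np.asarray(series, dtype=float)
        yrs = list(years) if years is not None else list(range(len(vals)))
    n = vals.size
    if n < 2 * k + 2:
        raise ParameterError(
            f"need >= {2 * k + 2} non-missing points for k={k}, got {n}"
        )
    s1 = np.concatenate([[0.0], np.cumsum(vals)])
    s2 = np.concatenate([[0.0], np.cumsum(vals**2)])

    best: Optional[tuple[float, tuple[int, ...]]] = None
    tied = False
    if k == 1:
        candidates = ((s,) for s in range(1, n))
    else:
        candidates = ((s1_, s2_) for s1_ in range(1, n - 1) for s2_ in range(s1_ + 1, n))
    for splits in candidates:
        edges = (0, *splits, n)
        sse = sum(_segment_cost(s1, s2, i, j) for i, j in zip(edges, edges[1:]))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, splits)
            tied = False
        elif abs(sse - best[0]) <= 1e-12 and splits != best[1]:
            tied = True
    assert best is not None
    return ChangepointResult(
        years=[yrs[s] for s in best[1]],
        indices=list(best[1]),
        sse=best[0],
        tied=tied,
    )
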