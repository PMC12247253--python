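"""Reading, validation, cleaning and per-pair aggregation of breeding records.

A breeding-record table has one row per litter (one reproductive event of a
mating cage): the cage identifier, the dam and sire identifiers, the mating
and birth dates, the number of pups at birth and at weaning, and the weaned
counts by sex.  Sixty years of mixed record keeping means rows can be
duplicated, incomplete or internally inconsistent, so every downstream
analysis starts from :func:`clean_records`, which applies a fixed, fully
tallied sequence of quality-control rules:

1. remove rows identical on all mapped fields;
2. remove rows with missing/invalid stock, cage ID, birth date or counts,
   or with sex counts that do not sum to the weaned count;
3. cap ``weaned`` at ``born`` (weaned > born can only be a data-entry error);
4. derive ``dead = born - weaned``.

Pre-weaning loss of a litter is always this derived ``dead`` count: the fate
of animals after weaning was not recorded.
"""

from __future__ import annotations

import datetime as dt
import json
from collections import Counter, OrderedDict
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import EmptyInputError, ParameterError, SchemaError

#: canonical field -> default column name in input files
DEFAULT_SCHEMA: dict[str, str] = {
    "mating_id": "mating_id",
    "dam_id": "dam_id",
    "sire_id": "sire_id",
    "mating_date": "mating_date",
    "birth_date": "birth_date",
    "born": "born",
    "weaned": "weaned",
    "males_weaned": "males_weaned",
    "females_weaned": "females_weaned",
    "stock": "stock",
}

#: columns that must exist in the input file
MANDATORY_FIELDS = ("mating_id", "dam_id", "sire_id", "birth_date", "born", "weaned")

_DATE_FORMATS = {"iso": "%Y-%m-%d", "us": "%m/%d/%Y"}


@dataclass(frozen=True)
class LitterRecord:
    """One reproductive event of a mating cage.

    ``dead`` is derived (born - weaned) and is ``None`` until
    :func:`clean_records` has run.  ``parse_errors`` names fields that failed
    to parse; such rows are retained at read time (so they can be tallied)
    and removed during cleaning.
    """

    mating_id: Optional[str]
    dam_id: Optional[str]
    sire_id: Optional[str]
    birth_date: Optional[dt.date]
    mating_date: Optional[dt.date] = None
    born: Optional[int] = None
    weaned: Optional[int] = None
    males_weaned: Optional[int] = None
    females_weaned: Optional[int] = None
    dead: Optional[int] = None
    stock: Optional[str] = None
    parse_errors: tuple[str, ...] = ()

    @property
    def birth_year(self) -> Optional[int]:
        return self.birth_date.year if self.birth_date is not None else None


@dataclass
class PairSummary:
    """Aggregate reproductive outcome of one mating cage."""

    mating_id: str
    dam_id: Optional[str]
    sire_id: Optional[str]
    n_litters: int
    total_born: int
    total_weaned: int
    total_dead: int
    n_litters_with_loss: int
    first_birth_date: Optional[dt.date]
    mean_delivery_interval: Optional[float]  # days; defined when n_litters >= 2
    relatedness_pct: Optional[float] = None  # filled by the pedigree module


@dataclass
class CleaningReport:
    """Tally of every quality-control action taken by :func:`clean_records`."""

    n_rows_in: int = 0
    n_duplicates_removed: int = 0
    n_incomplete_removed: int = 0
    n_capped: int = 0
    n_pairs_in: int = 0
    n_pairs_retained: int = 0
    n_pairs_removed: int = 0
    details: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _parse_date(value, fmt: str) -> tuple[Optional[dt.date], bool]:
    """Return (date, ok).  Empty values are valid-and-missing."""
    if value is None:
        return None, True
    if isinstance(value, dt.datetime):
        return value.date(), True
    if isinstance(value, dt.date):
        return value, True
    s = str(value).strip()
    if not s:
        return None, True
    try:
        return dt.datetime.strptime(s, _DATE_FORMATS[fmt]).date(), True
    except ValueError:
        return None, False


def _parse_count(value) -> tuple[Optional[int], bool]:
    if value is None:
        return None, True
    s = str(value).strip()
    if not s:
        return None, True
    try:
        f = float(s)
    except ValueError:
        return None, False
    if f != int(f):
        return None, False
    return int(f), True


def _opt_str(value) -> Optional[str]:
    if value is None:
        return None
    s = str(value).strip()
    return s or None


def read_records(
    path,
    schema: Optional[Mapping[str, str]] = None,
    date_format: str = "iso",
    delimiter: Optional[str] = None,
) -> list[LitterRecord]:
    """Read a delimited breeding-record table into :class:`LitterRecord` rows.

    Parameters
    ----------
    path
        CSV or TSV file.  The delimiter is taken from the extension
        (``.tsv`` -> tab, otherwise comma) unless ``delimiter`` is given.
    schema
        Mapping from canonical field names (keys of :data:`DEFAULT_SCHEMA`)
        to the column names actually used in the file.
    date_format
        ``"iso"`` (YYYY-MM-DD) or ``"us"`` (MM/DD/YYYY).  The dialect is an
        explicit choice, never guessed per row.

    Unparseable dates or counts are flagged on the record (``parse_errors``)
    rather than silently dropped; :func:`clean_records` removes and tallies
    them.  Row order is preserved.
    """
    if date_format not in _DATE_FORMATS:
        raise ParameterError(f"unknown date_format {date_format!r}; use 'iso' or 'us'")
    path = Path(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    sep = delimiter or ("\t" if path.suffix.lower() == ".tsv" else ",")
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if frame.shape[0] == 0:
        raise EmptyInputError(f"{path} contains no data rows")
    for fld in MANDATORY_FIELDS:
        if colmap[fld] not in frame.columns:
            raise SchemaError(
                f"mandatory column {colmap[fld]!r} (field {fld!r}) missing from {path}"
            )

    def cell(row, fld):
        col = colmap[fld]
        return row[col] if col in frame.columns else None

    records: list[LitterRecord] = []
    for _, row in frame.iterrows():
        errors: list[str] = []
        birth_date, ok = _parse_date(cell(row, "birth_date"), date_format)
        if not ok:
            errors.append("birth_date")
        mating_date, ok = _parse_date(cell(row, "mating_date"), date_format)
        if not ok:
            errors.append("mating_date")
        counts = {}
        for fld in ("born", "weaned", "males_weaned", "females_weaned"):
            counts[fld], ok = _parse_count(cell(row, fld))
            if not ok:
                errors.append(fld)
        records.append(
            LitterRecord(
                mating_id=_opt_str(cell(row, "mating_id")),
                dam_id=_opt_str(cell(row, "dam_id")),
                sire_id=_opt_str(cell(row, "sire_id")),
                birth_date=birth_date,
                mating_date=mating_date,
                born=counts["born"],
                weaned=counts["weaned"],
                males_weaned=counts["males_weaned"],
                females_weaned=counts["females_weaned"],
                stock=_opt_str(cell(row, "stock")),
                parse_errors=tuple(errors),
            )
        )
    return records


def _row_valid(rec: LitterRecord) -> bool:
    """Completeness/consistency rules for a single record."""
    if rec.parse_errors:
        return False
    if rec.mating_id is None or rec.stock is None:
        return False
    if rec.birth_date is None:
        return False
    if rec.born is None or rec.weaned is None:
        return False
    for v in (rec.born, rec.weaned, rec.males_weaned, rec.females_weaned):
        if v is not None and v < 0:
            return False
    if rec.males_weaned is not None and rec.females_weaned is not None:
        if rec.males_weaned + rec.females_weaned != rec.weaned:
            return False
    return True


def clean_records(
    records: Sequence[LitterRecord], pair_level: bool = False
) -> tuple[list[LitterRecord], CleaningReport]:
    """Apply the quality-control pipeline and return retained records + tally.

    ``pair_level=True`` removes every litter of a mating cage when any of its
    rows fails the completeness/consistency filter (whole-pair exclusion);
    the default removes only the offending rows.

    All failures become report entries; the function never raises on bad
    data.  The operation is idempotent: cleaning already-clean records
    changes nothing.
    """
    report = CleaningReport(n_rows_in=len(records))

    # 1. duplicates: identical on every mapped field (dead excluded; it is
    #    derived below and None on raw reads).
    seen: "OrderedDict[tuple, None]" = OrderedDict()
    deduped: list[LitterRecord] = []
    for rec in records:
        key = replace(rec, dead=None)
        if key in seen:
            report.n_duplicates_removed += 1
        else:
            seen[key] = None
            deduped.append(rec)

    report.n_pairs_in = len({r.mating_id for r in deduped if r.mating_id is not None})

    # 2. completeness / consistency
    invalid_dates = sum(1 for r in deduped if "birth_date" in r.parse_errors)
    if pair_level:
        bad_pairs = {r.mating_id for r in deduped if not _row_valid(r)}
        kept = [
            r
            for r in deduped
            if _row_valid(r) and r.mating_id not in bad_pairs
        ]
    else:
        kept = [r for r in deduped if _row_valid(r)]
    report.n_incomplete_removed = len(deduped) - len(kept)
    report.details["n_invalid_birth_dates"] = invalid_dates

    # 3. capping + 4. derived dead count
    out: list[LitterRecord] = []
    sex_cleared = 0
    for rec in kept:
        weaned = rec.weaned
        males, females = rec.males_weaned, rec.females_weaned
        capped = False
        if weaned > rec.born:
            weaned = rec.born
            capped = True
            report.n_capped += 1
            if males is not None and females is not None and males + females != weaned:
                # sex counts referred to the pre-cap weaned figure and can no
                # longer be reconciled; drop them rather than invent a split
                males = females = None
                sex_cleared += 1
        dead = rec.born - weaned
        if capped or dead != rec.dead or weaned != rec.weaned:
            rec = replace(
                rec, weaned=weaned, males_weaned=males, females_weaned=females, dead=dead
            )
        out.append(rec)
    report.details["n_sex_counts_cleared"] = sex_cleared

    # capping can make previously distinct rows identical; a final dedup
    # pass keeps the output duplicate-free (and cleaning idempotent)
    final_seen: "OrderedDict[LitterRecord, None]" = OrderedDict()
    for rec in out:
        if rec in final_seen:
            report.n_duplicates_removed += 1
        else:
            final_seen[rec] = None
    out = list(final_seen)

    report.n_pairs_retained = len({r.mating_id for r in out})
    report.n_pairs_removed = report.n_pairs_in - report.n_pairs_retained
    return out, report


def summarize_pairs(
    records: Sequence[LitterRecord], min_litters: int = 1
) -> list[PairSummary]:
    """Aggregate cleaned litters into one :class:`PairSummary` per mating cage.

    Only pairs with at least ``min_litters`` litters are returned (the
    analyses are run at thresholds 1-4 to probe sensitivity to breeding
    experience).  Delivery intervals are day gaps between consecutive
    birth dates after sorting.
    """
    if min_litters < 1:
        raise ParameterError(f"min_litters must be >= 1, got {min_litters}")
    groups: "OrderedDict[str, list[LitterRecord]]" = OrderedDict()
    for rec in records:
        if rec.mating_id is None:
            continue
        groups.setdefault(rec.mating_id, []).append(rec)

    out: list[PairSummary] = []
    for mating_id, litters in groups.items():
        if len(litters) < min_litters:
            continue
        dates = sorted(r.birth_date for r in litters if r.birth_date is not None)
        if len(dates) >= 2:
            gaps = [(b - a).days for a, b in zip(dates, dates[1:])]
            mean_int = sum(gaps) / len(gaps)
        else:
            mean_int = None
        total_born = sum(r.born for r in litters)
        total_weaned = sum(r.weaned for r in litters)
        out.append(
            PairSummary(
                mating_id=mating_id,
                dam_id=litters[0].dam_id,
                sire_id=litters[0].sire_id,
                n_litters=len(litters),
                total_born=total_born,
                total_weaned=total_weaned,
                total_dead=total_born - total_weaned,
                n_litters_with_loss=sum(1 for r in litters if (r.dead or 0) >= 1),
                first_birth_date=dates[0] if dates else None,
                mean_delivery_interval=mean_int,
            )
        )
    return out


def records_to_frame(records: Iterable[LitterRecord]) -> pd.DataFrame:
    """Tabular view of litter records (one row per litter)."""
    return pd.DataFrame([asdict(r) for r in records]).drop(columns=["parse_errors"])


def pairs_to_frame(pairs: Iterable[PairSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in pairs])


def write_records_csv(records: Iterable[LitterRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_pairs_csv(pairs: Iterable[PairSummary], path) -> None:
    pairs_to_frame(pairs).to_csv(path, index=False)
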