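import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonykin import (
    EmptyInputError,
    LitterRecord,
    ParameterError,
    SchemaError,
    clean_records,
    read_records,
    summarize_pairs,
)

COLUMNS = (
    "mating_id,dam_id,sire_id,mating_date,birth_date,born,weaned,"
    "males_weaned,females_weaned,stock"
)


def _write(tmp_path, rows, name="r.csv"):
    path = tmp_path / name
    path.write_text(COLUMNS + "\n" + "\n".join(rows) + "\n")
    return path


def test_read_identity_roundtrip(tmp_path):
    path = _write(
        tmp_path,
        [
            "M1,D1,S1,2010-01-01,2010-02-01,6,6,3,3,BW",
            "M1,D1,S1,,2010-03-05,5,3,1,2,BW",
            "M2,D2,S2,,2011-06-10,4,4,2,2,BW",
        ],
    )
    recs = read_records(path)
    assert len(recs) == 3
    assert recs[0].mating_id == "M1"
    assert recs[0].birth_date == dt.date(2010, 2, 1)
    assert recs[0].mating_date == dt.date(2010, 1, 1)
    assert (recs[1].born, recs[1].weaned) == (5, 3)
    assert recs[2].mating_id == "M2" and recs[2].stock == "BW"


def test_blank_dam_retained_as_unknown(tmp_path):
    path = _write(tmp_path, ["M1,,S1,,2010-02-01,6,6,3,3,BW"])
    recs = read_records(path)
    assert recs[0].dam_id is None
    cleaned, _ = clean_records(recs)
    assert len(cleaned) == 1  # unknown parentage is not a QC failure


def test_invalid_date_flagged_then_tallied(tmp_path):
    path = _write(
        tmp_path,
        [
            "M1,D1,S1,,2015-13-40,6,6,3,3,BW",
            "M1,D1,S1,,2015-03-01,4,4,2,2,BW",
        ],
    )
    recs = read_records(path)
    assert "birth_date" in recs[0].parse_errors  # flagged, not dropped
    cleaned, report = clean_records(recs)
    assert len(cleaned) == 1
    assert report.details["n_invalid_birth_dates"] == 1


def test_missing_mandatory_column_names_it(tmp_path):
    path = tmp_path / "r.csv"
    path.write_text("mating_id,dam_id,sire_id,birth_date,born\nM1,D1,S1,2010-02-01,6\n")
    with pytest.raises(SchemaError, match="weaned"):
        read_records(path)


def test_empty_file_raises(tmp_path):
    path = tmp_path / "r.csv"
    path.write_text(COLUMNS + "\n")
    with pytest.raises(EmptyInputError):
        read_records(path)


def test_us_date_dialect(tmp_path):
    path = _write(tmp_path, ["M1,D1,S1,,02/01/2010,6,6,3,3,BW"])
    recs = read_records(path, date_format="us")
    assert recs[0].birth_date == dt.date(2010, 2, 1)
    # the dialect is explicit, never guessed: iso parse of the same file fails
    recs_iso = read_records(path, date_format="iso")
    assert "birth_date" in recs_iso[0].parse_errors


def _rec(**kw):
    base = dict(
        mating_id="M1",
        dam_id="D1",
        sire_id="S1",
        birth_date=dt.date(2020, 1, 1),
        born=5,
        weaned=3,
        stock="BW",
    )
    base.update(kw)
    return LitterRecord(**base)


def test_dead_is_born_minus_weaned():
    cleaned, _ = clean_records([_rec(born=5, weaned=3)])
    assert cleaned[0].dead == 2


def test_capping_weaned_to_born():
    cleaned, report = clean_records([_rec(born=5, weaned=6)])
    assert cleaned[0].weaned == 5 and cleaned[0].dead == 0
    assert report.n_capped == 1


def test_duplicate_rows_collapse():
    rec = _rec()
    cleaned, report = clean_records([rec, rec])
    assert len(cleaned) == 1
    assert report.n_duplicates_removed == 1


def test_inconsistent_sex_counts_removed():
    bad = _rec(weaned=4, males_weaned=2, females_weaned=1)
    cleaned, report = clean_records([bad])
    assert cleaned == []
    assert report.n_incomplete_removed == 1


def test_pair_level_cleaning_drops_whole_pair():
    good = _rec(birth_date=dt.date(2020, 2, 1))
    bad = _rec(stock=None)
    row_level, _ = clean_records([good, bad])
    assert len(row_level) == 1
    pair_level, report = clean_records([good, bad], pair_level=True)
    assert pair_level == []
    assert report.n_pairs_removed == 1


def test_cleaning_is_idempotent(toy_csv):
    once, _ = clean_records(read_records(toy_csv))
    twice, report2 = clean_records(once)
    assert twice == once
    assert report2.n_duplicates_removed == 0
    assert report2.n_incomplete_removed == 0
    assert report2.n_capped == 0


def test_dead_conservation(toy_csv):
    cleaned, _ = clean_records(read_records(toy_csv))
    assert sum(r.dead for r in cleaned) == sum(r.born for r in cleaned) - sum(
        r.weaned for r in cleaned
    )


def test_summarize_totals_and_loss_litters():
    recs = [
        _rec(born=4, weaned=4, birth_date=dt.date(2020, 1, 1)),
        _rec(born=5, weaned=3, birth_date=dt.date(2020, 3, 1)),
        _rec(born=6, weaned=6, birth_date=dt.date(2020, 5, 1)),
    ]
    cleaned, _ = clean_records(recs)
    (pair,) = summarize_pairs(cleaned)
    assert pair.total_born == 15
    assert pair.total_dead == 2
    assert pair.n_litters_with_loss == 1


def test_summarize_min_litters_filter_and_interval():
    d0 = dt.date(2020, 1, 1)
    recs = [
        _rec(birth_date=d0),
        _rec(birth_date=d0 + dt.timedelta(days=30)),
        _rec(birth_date=d0 + dt.timedelta(days=62)),
        _rec(mating_id="M2", birth_date=d0),
        _rec(mating_id="M2", birth_date=d0 + dt.timedelta(days=40)),
    ]
    cleaned, _ = clean_records(recs)
    pairs = summarize_pairs(cleaned, min_litters=3)
    assert [p.mating_id for p in pairs] == ["M1"]
    assert pairs[0].mean_delivery_interval == pytest.approx(31.0)
    with pytest.raises(ParameterError):
        summarize_pairs(cleaned, min_litters=0)


def test_summary_partitions_litters(toy_csv):
    """With min_litters=1 every retained litter lands in exactly one pair."""
    cleaned, _ = clean_records(read_records(toy_csv))
    pairs = summarize_pairs(cleaned, min_litters=1)
    assert sum(p.n_litters for p in pairs) == len(cleaned)
    assert sum(p.total_born for p in pairs) == sum(r.born for r in cleaned)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    rows=st.lists(
        st.tuples(
            st.sampled_from(["M1", "M2", "M3", None]),  # mating_id
            st.integers(0, 12),  # born
            st.integers(0, 15),  # weaned (may exceed born)
            st.booleans(),  # valid date?
            st.sampled_from(["BW", None]),  # stock
        ),
        max_size=30,
    )
)
def test_cleaning_invariants_hold_on_arbitrary_rows(rows):
    recs = [
        LitterRecord(
            mating_id=mid,
            dam_id="D",
            sire_id="S",
            birth_date=dt.date(2020, 1, 1) if ok_date else None,
            born=born,
            weaned=weaned,
            stock=stock,
        )
        for mid, born, weaned, ok_date, stock in rows
    ]
    cleaned, report = clean_records(recs)
    for rec in cleaned:
        assert rec.weaned <= rec.born
        assert rec.dead == rec.born - rec.weaned
    assert report.n_pairs_in == report.n_pairs_retained + report.n_pairs_removed
    again, _ = clean_records(cleaned)
    assert again == cleaned
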