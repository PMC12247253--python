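import datetime as dt

import numpy as np
import pytest

from colonykin import (
    LitterRecord,
    ParameterError,
    annotate_phases,
    cumulative_scan,
    detect_changepoints,
    fit_binomial_glm,
    pearson,
    sex_specific_losses,
    summarize_pairs,
)


def _litter(mid, year, born, weaned, males=None, females=None, month=6):
    return LitterRecord(
        mating_id=mid, dam_id=f"D{mid}", sire_id=f"S{mid}",
        birth_date=dt.date(year, month, 15), born=born, weaned=weaned,
        males_weaned=males, females_weaned=females,
        dead=born - weaned, stock="BW",
    )


def _toy_scan_data():
    rng = np.random.default_rng(3)
    litters, rel = [], {}
    for k in range(30):
        mid = f"M{k}"
        rel[mid] = float(rng.uniform(0, 50))
        for j in range(3):
            born = int(rng.integers(3, 9))
            dead = int(rng.binomial(born, 0.15 + 0.004 * rel[mid]))
            litters.append(_litter(mid, 2000 + j, born, born - dead))
    return litters, rel


def test_single_year_data_gives_single_live_point():
    litters = [_litter(f"M{k}", 2005, 6, 6 - k % 3) for k in range(12)]
    rel = {f"M{k}": float(k) for k in range(12)}
    series = cumulative_scan(
        litters, rel, start_year=2000, end_year=2010, min_pairs=10, with_glm=False
    )
    live = [p for p in series.points if p.pearson is not None]
    assert {p.cutoff_year for p in live} == set(range(2005, 2011))
    assert all(p.n_pairs == 0 for p in series.points if p.cutoff_year < 2005)


def test_npairs_nondecreasing_and_nested():
    litters, rel = _toy_scan_data()
    series = cumulative_scan(
        litters, rel, start_year=1999, end_year=2004, min_pairs=5, with_glm=False
    )
    ns = [p.n_pairs for p in series.points]
    assert ns == sorted(ns)
    assert ns[-1] == 30


def test_final_cutoff_equals_pooled_stats():
    """End-to-end consistency: the last scan point reproduces the direct
    pooled computation on the full dataset."""
    litters, rel = _toy_scan_data()
    series = cumulative_scan(
        litters, rel, start_year=2000, end_year=2002, min_pairs=5
    )
    pairs = summarize_pairs(litters, 1)
    x = [rel[p.mating_id] for p in pairs]
    corr = pearson(x, [p.total_dead / p.total_born for p in pairs])
    fit = fit_binomial_glm(
        x, [p.total_dead for p in pairs], [p.total_born for p in pairs]
    )
    last = series.points[-1]
    assert last.pearson.r == pytest.approx(corr.r, abs=1e-12)
    assert last.glm.beta1 == pytest.approx(fit.beta1, abs=1e-10)
    assert last.glm.mcfadden_r2 == pytest.approx(fit.mcfadden_r2, abs=1e-10)


def test_delivery_interval_outcome_matches_pair_means():
    d0 = dt.date(2000, 1, 1)
    litters = []
    rel = {}
    for k in range(12):
        mid = f"M{k}"
        rel[mid] = float(k * 4)
        gap = 30 + k  # deterministic spacing per pair
        for j in range(3):
            litters.append(
                LitterRecord(
                    mating_id=mid, dam_id="D", sire_id="S",
                    birth_date=d0 + dt.timedelta(days=j * gap + 365 * 0),
                    born=5, weaned=5, dead=0, stock="BW",
                )
            )
    series = cumulative_scan(
        litters, rel, outcome="delivery_interval",
        start_year=2000, end_year=2000, min_pairs=5, with_glm=False,
    )
    point = series.points[-1]
    corr = pearson(list(rel.values()), [30.0 + k for k in range(12)])
    assert point.pearson.r == pytest.approx(corr.r, abs=1e-12)


def test_sex_loss_arithmetic():
    recs, report = sex_specific_losses(
        [
            _litter("M1", 2000, 6, 5, males=2, females=3),
            _litter("M2", 2000, 5, 3, males=3, females=0),
            _litter("M3", 2000, 4, 4, males=2, females=2),
            _litter("M4", 2000, 4, 3),  # missing sex counts
        ]
    )
    assert len(recs) == 3
    assert report["n_skipped"] == 1
    assert (recs[0].male_loss, recs[0].female_loss) == (1.0, 0.0)
    # born=5 -> expected 2.5 of each; 3 males weaned floors male loss at 0
    assert recs[1].male_loss == 0.0 and recs[1].floored
    assert recs[1].female_loss == 2.5
    assert (recs[2].male_loss, recs[2].female_loss) == (0.0, 0.0)
    assert report["n_floored"] == 1


def test_sex_loss_unfloored_variant():
    recs, _ = sex_specific_losses(
        [_litter("M1", 2000, 5, 5, males=3, females=2)], floor=False
    )
    assert recs[0].male_loss == -0.5
    # without flooring, per-sex losses add up to the total loss exactly
    assert recs[0].male_loss + recs[0].female_loss == pytest.approx(5 - 5)


def test_phase_annotation_defaults_and_convention():
    litters, rel = _toy_scan_data()
    series = cumulative_scan(
        litters, rel, start_year=1970, end_year=2020, min_pairs=5, with_glm=False
    )
    by_year = dict(zip((p.cutoff_year for p in series.points), series.phases))
    assert by_year[1970] == "I"
    assert by_year[1990] == "II"
    assert by_year[2020] == "III"
    assert by_year[1985] == "II"  # boundary year opens the later phase
    annotate_phases(series, [])
    assert set(series.phases) == {"I"}
    with pytest.raises(ParameterError):
        annotate_phases(series, [2015, 1985])


def test_changepoint_exact_step():
    res = detect_changepoints([0, 0, 0, 0.3, 0.3, 0.3], k=1)
    assert res.indices == [3]
    assert res.sse == pytest.approx(0.0, abs=1e-15)
    assert not res.tied


def test_changepoint_constant_series_ties_earliest():
    res = detect_changepoints([0.2] * 8, k=1)
    assert res.indices == [1]
    assert res.tied


def test_changepoint_guards():
    with pytest.raises(ParameterError):
        detect_changepoints([0, 1, 0, 1], k=3)
    with pytest.raises(ParameterError):
        detect_changepoints([0, 1, 0], k=1)


def test_changepoint_recovery_on_noisy_two_step_series():
    """Two-step series at signal/noise 3: both breakpoints recovered within
    +/-2 positions in >= 90% of replicates."""
    rng = np.random.default_rng(11)
    n, b1, b2 = 40, 14, 28
    signal = np.zeros(n)
    signal[b1:b2] = 0.3
    sigma = 0.1  # step size / noise = 3
    hits = 0
    reps = 200
    for _ in range(reps):
        series = signal + rng.normal(0, sigma, n)
        res = detect_changepoints(series, k=2)
        if abs(res.indices[0] - b1) <= 2 and abs(res.indices[1] - b2) <= 2:
            hits += 1
    assert hits / reps >= 0.90


def test_scan_parameter_guards():
    litters, rel = _toy_scan_data()
    with pytest.raises(ParameterError):
        cumulative_scan(litters, rel, start_year=2010, end_year=2000)
    with pytest.raises(ParameterError):
        cumulative_scan(litters, rel, outcome="nope")
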