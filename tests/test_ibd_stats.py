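import numpy as np
import pytest
from scipy import stats as sps

from colonykin import (
    DegenerateDesignError,
    PairSummary,
    UndefinedStatisticError,
    bin_and_anova,
    fit_binomial_glm,
    loss_ratio_by_litter,
    loss_ratio_by_mice,
    pearson,
)
from colonykin.ibd_stats import assign_bin
from colonykin.validation import binomial_loglik, grid_fit_binomial


def _pair(**kw):
    base = dict(
        mating_id="M1", dam_id="D", sire_id="S", n_litters=3, total_born=20,
        total_weaned=15, total_dead=5, n_litters_with_loss=1,
        first_birth_date=None, mean_delivery_interval=None, relatedness_pct=10.0,
    )
    base.update(kw)
    return PairSummary(**base)


def test_loss_ratio_by_mice():
    assert loss_ratio_by_mice(_pair()) == pytest.approx(0.25)
    assert loss_ratio_by_mice(_pair(total_dead=0)) == 0.0
    with pytest.raises(UndefinedStatisticError):
        loss_ratio_by_mice(_pair(total_born=0))


def test_loss_ratio_by_litter():
    assert loss_ratio_by_litter(_pair()) == pytest.approx(1 / 3)
    assert loss_ratio_by_litter(_pair(n_litters_with_loss=0)) == 0.0
    assert loss_ratio_by_litter(_pair(n_litters=4, n_litters_with_loss=4)) == 1.0
    with pytest.raises(UndefinedStatisticError):
        loss_ratio_by_litter(_pair(n_litters=0))


def test_glm_no_association_is_null():
    fit = fit_binomial_glm([0.0, 50.0], [5, 5], [10, 10])
    assert fit.beta1 == pytest.approx(0.0, abs=1e-8)
    assert fit.mcfadden_r2 == pytest.approx(0.0, abs=1e-10)
    assert fit.lrt_p == pytest.approx(1.0)


def test_glm_constant_covariate_rejected():
    with pytest.raises(DegenerateDesignError):
        fit_binomial_glm([10.0, 10.0, 10.0], [1, 2, 3], [5, 5, 5])


def test_glm_matches_grid_oracle_on_toy_data():
    x = np.array([0.0, 10.0, 20.0, 35.0, 50.0])
    s = np.array([1, 2, 3, 5, 7])
    t = np.array([10, 10, 10, 10, 10])
    fit = fit_binomial_glm(x, s, t)
    g0, g1, gll = grid_fit_binomial(x, s, t)
    assert fit.beta0 == pytest.approx(g0, abs=1e-4)
    assert fit.beta1 == pytest.approx(g1, abs=1e-4)
    assert fit.loglik_model == pytest.approx(
        binomial_loglik(fit.beta0, fit.beta1, x, s, t)
    )
    # null log-likelihood at the pooled proportion, evaluated directly
    p0 = s.sum() / t.sum()
    assert fit.loglik_null == pytest.approx(
        float(np.sum(s * np.log(p0) + (t - s) * np.log(1 - p0)))
    )


def test_glm_sufficiency_of_pair_totals():
    """Per-litter rows and per-pair totals give the same weighted fit."""
    rng = np.random.default_rng(7)
    x_pairs = rng.uniform(0, 40, 15)
    litters = []
    for xp in x_pairs:
        for _ in range(int(rng.integers(1, 5))):
            t = int(rng.integers(2, 9))
            s = int(rng.binomial(t, 0.2 + 0.004 * xp))
            litters.append((xp, s, t))
    lx, ls, lt = map(np.array, zip(*litters))
    fit_rows = fit_binomial_glm(lx, ls, lt)
    # aggregate to totals per distinct covariate value (= per pair)
    agg = {}
    for xp, s, t in litters:
        a = agg.setdefault(xp, [0, 0])
        a[0] += s
        a[1] += t
    ax = np.array(list(agg))
    asucc = np.array([agg[k][0] for k in agg])
    atri = np.array([agg[k][1] for k in agg])
    fit_tot = fit_binomial_glm(ax, asucc, atri)
    assert fit_rows.beta0 == pytest.approx(fit_tot.beta0, abs=1e-8)
    assert fit_rows.beta1 == pytest.approx(fit_tot.beta1, abs=1e-8)
    assert fit_rows.loglik_model == pytest.approx(fit_tot.loglik_model, abs=1e-8)


def test_mcfadden_invariant_to_covariate_scale():
    x_pct = np.array([0.0, 10.0, 25.0, 40.0, 50.0])
    s = np.array([1, 2, 2, 4, 6])
    t = np.array([10, 10, 10, 10, 10])
    fit_pct = fit_binomial_glm(x_pct, s, t)
    fit_prop = fit_binomial_glm(x_pct / 100.0, s, t)
    assert fit_prop.beta1 == pytest.approx(100.0 * fit_pct.beta1, rel=1e-6)
    assert fit_prop.mcfadden_r2 == pytest.approx(fit_pct.mcfadden_r2, rel=1e-8)
    assert fit_prop.lrt_p == pytest.approx(fit_pct.lrt_p, rel=1e-8)


def test_glm_flags_complete_separation():
    fit = fit_binomial_glm([0.0, 5.0, 40.0, 45.0], [0, 0, 8, 8], [8, 8, 8, 8])
    assert not fit.converged


def test_glm_lrt_p_matches_chi2_closed_form():
    fit = fit_binomial_glm([0.0, 20.0, 40.0], [1, 3, 6], [10, 10, 10])
    assert fit.lrt_stat == pytest.approx(
        2 * (fit.loglik_model - fit.loglik_null), abs=1e-10
    )
    assert fit.lrt_p == pytest.approx(sps.chi2.sf(fit.lrt_stat, 1))
    assert 0.0 <= fit.mcfadden_r2 < 1.0


def test_glm_slope_sign_matches_weighted_proportion_difference():
    """On two-group designs the slope sign follows the proportion contrast."""
    up = fit_binomial_glm([0.0, 50.0], [2, 8], [10, 10])
    down = fit_binomial_glm([0.0, 50.0], [8, 2], [10, 10])
    assert up.beta1 > 0 > down.beta1


def test_pearson_examples_and_guards():
    assert pearson([1, 2, 3, 4, 5], [3, 5, 7, 9, 11]).r == pytest.approx(1.0)
    with pytest.raises(UndefinedStatisticError):
        pearson([1, 2, 3], [4, 4, 4])
    with pytest.raises(UndefinedStatisticError):
        pearson([1, 2], [3, 4])


def test_pearson_matches_closed_form():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 5.0])
    res = pearson(x, y)
    r_direct = float(
        np.sum((x - x.mean()) * (y - y.mean()))
        / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    )
    assert res.r == pytest.approx(r_direct)
    tstat = r_direct * np.sqrt((len(x) - 2) / (1 - r_direct**2))
    assert res.p == pytest.approx(2 * sps.t.sf(abs(tstat), len(x) - 2))


def test_bin_assignment_half_open_edges():
    assert assign_bin(24.95) == "<25"
    assert assign_bin(25.0) == "25-29.9"
    assert assign_bin(30.0) == "30-34.9"
    assert assign_bin(39.99) == "35-39.9"
    assert assign_bin(40.0) == ">=40"
    assert assign_bin(0.0) == "<25"
    assert assign_bin(100.0) == ">=40"


def _pairs_with(rel_and_ratio):
    out = []
    for k, (rel, ratio) in enumerate(rel_and_ratio):
        dead = int(round(ratio * 20))
        out.append(
            _pair(
                mating_id=f"M{k}", relatedness_pct=rel, total_born=20,
                total_dead=dead, total_weaned=20 - dead,
            )
        )
    return out


def test_anova_equal_group_means_gives_f_zero():
    pairs = _pairs_with(
        [(10, 0.1), (10, 0.2), (10, 0.3), (27, 0.1), (27, 0.2), (27, 0.3)]
    )
    comp = bin_and_anova(pairs, metric="by_mice")
    assert comp.anova_f == pytest.approx(0.0, abs=1e-12)
    assert comp.anova_p == pytest.approx(1.0)


def test_anova_matches_hand_computed_f():
    groups = {10.0: [0.1, 0.2], 27.0: [0.3, 0.4], 42.0: [0.5, 0.8]}
    pairs = _pairs_with([(rel, v) for rel, vals in groups.items() for v in vals])
    comp = bin_and_anova(pairs, metric="by_mice")
    data = [np.array(v) for v in groups.values()]
    grand = np.mean(np.concatenate(data))
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
    f_hand = (ss_between / 2) / (ss_within / 3)
    assert comp.anova_f == pytest.approx(f_hand, rel=1e-4)
    assert comp.n == (2, 2, 0, 0, 2)


def test_anova_needs_two_bins():
    pairs = _pairs_with([(5, 0.1), (7, 0.2), (9, 0.3)])
    with pytest.raises(UndefinedStatisticError):
        bin_and_anova(pairs, metric="by_mice")
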