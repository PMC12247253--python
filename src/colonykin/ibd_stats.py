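"""Inbreeding-depression statistics.

Two loss metrics summarise how much of a pair's reproductive output dies
before weaning:

- loss ratio by mice:    total dead / total born;
- loss ratio by litter:  fraction of the pair's litters in which at least
  one pup was lost.

Their association with parental relatedness r (percent, 0-100) is
quantified three ways, mirroring standard practice for proportion
outcomes:

- a binomial GLM with logit link, weighted by the number of events (mice
  born or litters) through the (successes, trials) formulation, summarised
  by McFadden's pseudo-R^2 = 1 - ll_model/ll_null and a 1-df likelihood
  ratio test;
- Pearson's product-moment correlation on the per-pair (r, loss ratio)
  values;
- a one-way ANOVA across five relatedness categories
  (<25, 25-29.9, 30-34.9, 35-39.9, >=40 percent).

Log-likelihoods are the binomial kernel sum(s log p + (t-s) log(1-p));
the combinatorial constant is omitted as it cancels from the score,
the LRT and the maximiser.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .errors import DegenerateDesignError, UndefinedStatisticError
from .records_io import PairSummary

#: half-open relatedness bins [0,25), [25,30), [30,35), [35,40), [40,100]
BIN_EDGES = (0.0, 25.0, 30.0, 35.0, 40.0)
BIN_LABELS = ("<25", "25-29.9", "30-34.9", "35-39.9", ">=40")


@dataclass
class GlmFit:
    """A fitted weighted binomial-logit model of loss on relatedness."""

    beta0: float
    beta1: float
    loglik_model: float
    loglik_null: float
    mcfadden_r2: float
    lrt_stat: float
    lrt_p: float
    n_obs: int
    total_weight: float
    converged: bool


@dataclass
class CorrResult:
    r: float
    p: float
    n: int


@dataclass
class BinnedComparison:
    """Per-relatedness-bin loss summaries and the across-bin ANOVA."""

    labels: tuple[str, ...]
    n: tuple[int, ...]
    mean: tuple[float, ...]
    se: tuple[float, ...]
    anova_f: float
    anova_p: float


def loss_ratio_by_mice(pair: PairSummary) -> float:
    """Dead pups / pups born over all of the pair's litters."""
    if pair.total_born <= 0:
        raise UndefinedStatisticError(
            f"pair {pair.mating_id}: loss ratio undefined with total_born=0"
        )
    return pair.total_dead / pair.total_born


def loss_ratio_by_litter(pair: PairSummary) -> float:
    """Fraction of the pair's litters with at least one pup lost."""
    if pair.n_litters <= 0:
        raise UndefinedStatisticError(
            f"pair {pair.mating_id}: loss ratio undefined with n_litters=0"
        )
    return pair.n_litters_with_loss / pair.n_litters


def _kernel_loglik(s: np.ndarray, t: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(s * np.log(p) + (t - s) * np.log(1.0 - p)))


def fit_binomial_glm(x, successes, trials) -> GlmFit:
    """Weighted binomial-logit fit of loss counts on relatedness.

    ``successes[i]`` of ``trials[i]`` events are losses at covariate
    ``x[i]``; per-litter rows and per-pair totals give the identical fit
    (the totals are sufficient under the model).  The null model refit has
    the closed form p0 = sum(s)/sum(t).

    Raises :class:`DegenerateDesignError` when the covariate is constant.
    On complete separation the convergence flag is honest (``False``);
    coefficients are never silently trusted.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(successes, dtype=float)
    t = np.asarray(trials, dtype=float)
    if not (x.shape == s.shape == t.shape):
        raise DegenerateDesignError("x, successes, trials must have equal length")
    if np.any(s < 0) or np.any(t < s):
        raise DegenerateDesignError("need 0 <= successes <= trials elementwise")
    use = t > 0
    x, s, t = x[use], s[use], t[use]
    if x.size == 0:
        raise DegenerateDesignError("no observations with trials > 0")
    if np.unique(x).size < 2:
        raise DegenerateDesignError("constant covariate: slope inestimable")

    exog = np.column_stack([np.ones_like(x), x])
    endog = np.column_stack([s, t - s])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 scale on tiny n
        res = model.fit(maxiter=200)
    separated = any(
        issubclass(w.category, PerfectSeparationWarning) for w in caught
    )
    beta0, beta1 = (float(v) for v in res.params)

    eta = beta0 + beta1 * x
    ll_model = _kernel_loglik(s, t, expit(eta))
    p0 = s.sum() / t.sum()
    ll_null = _kernel_loglik(s, t, np.full_like(x, p0))

    lrt = max(0.0, 2.0 * (ll_model - ll_null))
    lrt_p = float(sps.chi2.sf(lrt, df=1))
    mcfadden = max(0.0, 1.0 - ll_model / ll_null) if ll_null < 0 else 0.0

    converged = bool(
        getattr(res, "converged", True)
        and not separated
        and np.all(np.isfinite(res.params))
        and np.max(np.abs(eta)) < 30.0  # fitted probabilities pinned at 0/1
    )
    return GlmFit(
        beta0=beta0,
        beta1=beta1,
        loglik_model=ll_model,
        loglik_null=ll_null,
        mcfadden_r2=mcfadden,
        lrt_stat=lrt,
        lrt_p=lrt_p,
        n_obs=int(x.size),
        total_weight=float(t.sum()),
        converged=converged,
    )


def pearson(x, y) -> CorrResult:
    """Pearson product-moment correlation with the two-sided t-test p-value.

    Constant input or n < 3 raises :class:`UndefinedStatisticError`; scans
    propagate that as a missing point, never as r = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UndefinedStatisticError("x and y must have equal length")
    if x.size < 3:
        raise UndefinedStatisticError(f"need n >= 3, got n={x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return CorrResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def assign_bin(relatedness_pct: float) -> str:
    """Relatedness category label under the half-open bin convention."""
    idx = int(np.searchsorted(BIN_EDGES, relatedness_pct, side="right")) - 1
    idx = max(idx, 0)
    return BIN_LABELS[idx]


def bin_and_anova(
    pairs: Sequence[PairSummary],
    metric: str = "by_mice",
) -> BinnedComparison:
    """Group pairs into the five relatedness categories and compare the
    chosen loss metric across the non-empty ones by one-way ANOVA.

    Pairs without relatedness or with an undefined metric are excluded.
    Per-bin mean and standard error are reported for bar-plot reproduction.
    """
    if metric not in ("by_mice", "by_litter"):
        raise UndefinedStatisticError(f"unknown metric {metric!r}")
    ratio = loss_ratio_by_mice if metric == "by_mice" else loss_ratio_by_litter
    values: dict[str, list[float]] = {lab: [] for lab in BIN_LABELS}
    for pair in pairs:
        if pair.relatedness_pct is None:
            continue
        try:
            v = ratio(pair)
        except UndefinedStatisticError:
            continue
        values[assign_bin(pair.relatedness_pct)].append(v)

    groups = [np.asarray(values[lab]) for lab in BIN_LABELS if values[lab]]
    if len(groups) < 2:
        raise UndefinedStatisticError(
            f"ANOVA needs >= 2 non-empty relatedness bins, got {len(groups)}"
        )
    f, p = sps.f_oneway(*groups)
    if not np.isfinite(f):  # all values identical: no variance anywhere
        f, p = 0.0, 1.0
    n = tuple(len(values[lab]) for lab in BIN_LABELS)
    mean = tuple(
        float(np.mean(values[lab])) if values[lab] else float("nan")
        for lab in BIN_LABELS
    )
    se = tuple(
        float(np.std(values[lab], ddof=1) / np.sqrt(len(values[lab])))
        if len(values[lab]) > 1
        else float("nan")
        for lab in BIN_LABELS
    )
    return BinnedComparison(
        labels=BIN_LABELS, n=n, mean=mean, se=se, anova_f=float(f), anova_p=float(p)
    )
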