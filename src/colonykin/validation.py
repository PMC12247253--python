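"""Independent reference implementations used to cross-validate the package.

Each function here computes a quantity the main modules also compute, but by
a structurally different route, so the two can be checked against each
other:

- :func:`kinship_path_counting` evaluates Wright's path-counting formula
  (sum over common ancestors and node-disjoint ancestral path pairs, with
  the ancestor's inbreeding correction) instead of the tabular recursion;
- :func:`gene_drop_kinship` estimates identity-by-descent by Monte-Carlo
  transmission of founder alleles down the pedigree;
- :func:`grid_fit_binomial` maximises the weighted binomial log-likelihood
  by an exhaustive grid search with iterative refinement instead of IRLS;
- :func:`random_pedigree` draws small random pedigrees for property tests.

These stay deliberately naive: clarity and independence over speed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .pedigree import Pedigree


# -- path-counting kinship --------------------------------------------------

def _ancestral_paths(ped: Pedigree, start: str) -> list[tuple[str, int, frozenset]]:
    """All upward paths from ``start``: (ancestor, length, nodes-excluding-
    ancestor).  The zero-length path (start itself) is included."""
    out: list[tuple[str, int, frozenset]] = []
    stack: list[tuple[str, tuple[str, ...]]] = [(start, (start,))]
    while stack:
        node, path = stack.pop()
        out.append((node, len(path) - 1, frozenset(path[:-1])))
        for parent in ped.parents[node]:
            if parent is not None:
                stack.append((parent, path + (parent,)))
    return out


def inbreeding_path_counting(ped: Pedigree, individual: str) -> float:
    """F(x) = phi(father, mother) by path counting."""
    sire, dam = ped.parents[individual]
    if sire is None or dam is None:
        return 0.0
    return kinship_path_counting(ped, sire, dam)


def kinship_path_counting(ped: Pedigree, a: str, b: str) -> float:
    """Kinship by summing 0.5^(La+Lb+1) * (1 + F(ancestor)) over all common
    ancestors and pairs of ancestral paths that share no node except the
    ancestor.  Exponentially slow on deep pedigrees; fine below ~30
    individuals."""
    if a == b:
        return 0.5 * (1.0 + inbreeding_path_counting(ped, a))
    paths_a = _ancestral_paths(ped, a)
    paths_b = _ancestral_paths(ped, b)
    by_anc: dict[str, list[tuple[int, frozenset]]] = {}
    for anc, length, nodes in paths_b:
        by_anc.setdefault(anc, []).append((length, nodes))
    f_cache: dict[str, float] = {}
    total = 0.0
    for anc, la, nodes_a in paths_a:
        for lb, nodes_b in by_anc.get(anc, ()):
            if nodes_a & nodes_b:
                continue
            if anc not in f_cache:
                f_cache[anc] = inbreeding_path_counting(ped, anc)
            total += 0.5 ** (la + lb + 1) * (1.0 + f_cache[anc])
    return total


# -- gene dropping ----------------------------------------------------------

def gene_drop_kinship(
    ped: Pedigree,
    a: str,
    b: str,
    n_drops: int = 200_000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Monte-Carlo kinship estimate and its standard error.

    Founder alleles get unique labels; every individual inherits one allele
    from each parent, chosen uniformly per drop.  The per-drop estimator is
    the fraction of the four cross-individual allele comparisons that are
    identical by descent (a Rao-Blackwellised version of drawing one allele
    from each individual).
    """
    if rng is None:
        rng = np.random.default_rng()
    order = sorted(ped.parents, key=ped.rank().__getitem__)
    next_code = 0
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for node in order:
        pair = []
        for parent in ped.parents[node]:
            if parent is None:
                pair.append(np.full(n_drops, next_code, dtype=np.int32))
                next_code += 1
            else:
                p1, p2 = alleles[parent]
                pick = rng.integers(0, 2, n_drops).astype(bool)
                pair.append(np.where(pick, p2, p1))
        alleles[node] = (pair[0], pair[1])
    a1, a2 = alleles[a]
    b1, b2 = alleles[b]
    per_drop = 0.25 * (
        (a1 == b1).astype(np.float64)
        + (a1 == b2)
        + (a2 == b1)
        + (a2 == b2)
    )
    est = float(per_drop.mean())
    se = float(per_drop.std(ddof=1) / np.sqrt(n_drops))
    return est, se


# -- random pedigrees -------------------------------------------------------

def random_pedigree(
    rng: np.random.Generator,
    n_individuals: int = 25,
    n_founders: int = 6,
    p_unknown: float = 0.1,
) -> Pedigree:
    """A random pedigree built by adding individuals whose parents are drawn
    from earlier individuals (so it is acyclic by construction).  Some
    parents are left unknown with probability ``p_unknown``."""
    ids = [f"I{k:03d}" for k in range(n_individuals)]
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    for k, ind in enumerate(ids):
        if k < n_founders:
            parents[ind] = (None, None)
            continue
        chosen: list[Optional[str]] = []
        for _ in range(2):
            if rng.random() < p_unknown:
                chosen.append(None)
            else:
                chosen.append(ids[int(rng.integers(0, k))])
        if chosen[0] is not None and chosen[0] == chosen[1]:
            chosen[1] = None  # one animal cannot be both parents
        parents[ind] = (chosen[0], chosen[1])
    return Pedigree(parents)


# -- brute-force binomial GLM -----------------------------------------------

def binomial_loglik(
    beta0: float,
    beta1: float,
    x: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
) -> float:
    """Weighted binomial log-likelihood kernel
    sum s*log(p) + (t - s)*log(1 - p), logit(p) = beta0 + beta1*x."""
    eta = beta0 + beta1 * np.asarray(x, dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    s = np.asarray(successes, dtype=float)
    t = np.asarray(trials, dtype=float)
    return float(np.sum(s * np.log(p) + (t - s) * np.log(1.0 - p)))


def grid_fit_binomial(
    x,
    successes,
    trials,
    b0_range: tuple[float, float] = (-8.0, 8.0),
    b1_range: tuple[float, float] = (-2.0, 2.0),
    n_grid: int = 41,
    n_rounds: int = 60,
) -> tuple[float, float, float]:
    """(beta0, beta1, loglik) by grid search with iterative refinement.

    Each round evaluates the likelihood on an ``n_grid`` x ``n_grid`` lattice
    centred on the best point so far, then halves the window.  The shrink is
    deliberately slow so the search can track the diagonal ridge that the
    intercept/slope correlation creates; on an edge hit the window is
    recentred without shrinking, so the maximiser cannot be locked out.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(successes, dtype=float)
    t = np.asarray(trials, dtype=float)
    c0 = 0.5 * (b0_range[0] + b0_range[1])
    c1 = 0.5 * (b1_range[0] + b1_range[1])
    w0 = 0.5 * (b0_range[1] - b0_range[0])
    w1 = 0.5 * (b1_range[1] - b1_range[0])
    best = (c0, c1, binomial_loglik(c0, c1, x, s, t))
    for _ in range(n_rounds):
        g0 = np.linspace(c0 - w0, c0 + w0, n_grid)
        g1 = np.linspace(c1 - w1, c1 + w1, n_grid)
        eta = g0[:, None, None] + g1[None, :, None] * x[None, None, :]
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1.0 - 1e-12)
        ll = np.sum(s * np.log(p) + (t - s) * np.log(1.0 - p), axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c0, c1 = float(g0[i]), float(g1[j])
        if ll[i, j] > best[2]:
            best = (c0, c1, float(ll[i, j]))
        c0, c1 = best[0], best[1]
        on_edge = i in (0, n_grid - 1) or j in (0, n_grid - 1)
        if not on_edge:
            w0 *= 0.5
            w1 *= 0.5
    return best
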