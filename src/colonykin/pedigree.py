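"""Pedigree construction and kinship/relatedness computation.

The kinship coefficient phi(a, b) is the probability that one allele drawn
at random from individual *a* and one from *b* are identical by descent.
It satisfies the classical recursion over a pedigree in which founders
(individuals with no recorded parents) are mutually unrelated and
non-inbred:

    phi(x, x) = 1/2 * (1 + phi(father(x), mother(x)))
    phi(a, b) = 1/2 * (phi(father(a), b) + phi(mother(a), b))   (a != b,
                a not an ancestor of b)

with phi taken as 0 whenever a parent is unknown.  The recursion is
evaluated in topological order so the "not an ancestor of" condition is
always satisfied, and results are memoised per pedigree.

The relatedness of a mating pair is reported as r = 2 * phi, expressed as a
percentage: 0 means no shared ancestry within the traced depth and 100
means genetic identity.  Parent-offspring and full-sibling pairs of
unrelated, non-inbred parents both have r = 50.

Because very old records can contain ambiguous entries, ancestor tracing
is truncated at a configurable number of generations (default five) before
kinship is computed: ancestors at exactly the cutoff depth are treated as
founders, which can only remove shared paths, never add them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .errors import CycleError, ParameterError, PedigreeLookupError
from .records_io import LitterRecord, PairSummary

ParentPair = tuple[Optional[str], Optional[str]]  # (sire, dam)


class Pedigree:
    """Directed acyclic parent map over individual IDs.

    ``parents`` maps each individual to a ``(sire, dam)`` tuple; ``None``
    codes an unknown parent.  Parents referenced but never given their own
    entry become implicit founders.  Construction validates acyclicity.
    """

    def __init__(self, parents: Mapping[str, ParentPair]):
        full: dict[str, ParentPair] = {}
        for child, (sire, dam) in parents.items():
            full[child] = (sire, dam)
        for child, (sire, dam) in parents.items():
            for p in (sire, dam):
                if p is not None and p not in full:
                    full[p] = (None, None)
        self.parents: dict[str, ParentPair] = full
        self._check_acyclic()
        self._rank: Optional[dict[str, int]] = None
        self._phi_cache: dict[tuple[str, str], float] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, (sire, dam) in self.parents.items():
            for p in (sire, dam):
                if p is not None:
                    g.add_edge(p, child)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise CycleError([e[0] for e in cycle] + [cycle[-1][1]])

    def __contains__(self, individual: str) -> bool:
        return individual in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    @property
    def founders(self) -> set[str]:
        return {i for i, (s, d) in self.parents.items() if s is None and d is None}

    def rank(self) -> dict[str, int]:
        """Topological rank: every ancestor ranks strictly before its
        descendants, so the individual with the larger rank can never be an
        ancestor of the other."""
        if self._rank is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.parents)
            for child, (sire, dam) in self.parents.items():
                for p in (sire, dam):
                    if p is not None:
                        g.add_edge(p, child)
            self._rank = {n: i for i, n in enumerate(nx.topological_sort(g))}
        return self._rank

    def ancestor_depths(self, focal: str) -> dict[str, int]:
        """Minimum number of parent edges from ``focal`` to each ancestor
        (focal itself at depth 0)."""
        if focal not in self.parents:
            raise PedigreeLookupError(focal)
        depths = {focal: 0}
        frontier = [focal]
        while frontier:
            nxt = []
            for node in frontier:
                for p in self.parents[node]:
                    if p is not None and p not in depths:
                        depths[p] = depths[node] + 1
                        nxt.append(p)
            frontier = nxt
        return depths


@dataclass
class KinshipResult:
    """Kinship phi and relatedness percentage for one dam x sire pair.

    ``phi``/``relatedness_pct`` are ``None`` when either parent is unknown
    or absent from the pedigree.  ``truncated`` records whether ancestor
    tracing severed any lineage at the generation cutoff.
    """

    dam_id: Optional[str]
    sire_id: Optional[str]
    phi: Optional[float]
    relatedness_pct: Optional[float]
    generations_used: int
    truncated: bool


def build_pedigree(
    records: Sequence[LitterRecord],
    registry: Optional[Mapping[str, ParentPair]] = None,
) -> Pedigree:
    """Build the colony pedigree from breeding records.

    Every dam and sire named in the records becomes a node.  ``registry``
    optionally supplies individual-level parentage (individual ->
    (sire, dam)), e.g. from a studbook file or the simulator's truth
    sidecar; individuals with no registry entry are founders.
    """
    parents: dict[str, ParentPair] = {}
    if registry:
        parents.update({k: tuple(v) for k, v in registry.items()})  # type: ignore[misc]
    for rec in records:
        for ind in (rec.dam_id, rec.sire_id):
            if ind is not None and ind not in parents:
                parents[ind] = (None, None)
    return Pedigree(parents)


def truncate_ancestry(
    ped: Pedigree,
    focal: tuple[str, str],
    max_generations: int = 5,
) -> tuple[Pedigree, bool]:
    """Restrict a pedigree to ancestors of either focal individual within
    ``max_generations`` parent edges.

    Ancestors at exactly the cutoff depth have their parents severed and
    become founders of the sub-pedigree.  Returns ``(sub_pedigree,
    truncated)`` where ``truncated`` reports whether any severing occurred.
    """
    if max_generations < 1:
        raise ParameterError(f"max_generations must be >= 1, got {max_generations}")
    a, b = focal
    depths_a = ped.ancestor_depths(a)
    depths_b = ped.ancestor_depths(b)
    depth = dict(depths_b)
    for node, d in depths_a.items():
        if node not in depth or d < depth[node]:
            depth[node] = d

    keep = {n for n, d in depth.items() if d <= max_generations}
    truncated = False
    sub: dict[str, ParentPair] = {}
    for node in keep:
        sire, dam = ped.parents[node]
        if depth[node] == max_generations:
            if sire is not None or dam is not None:
                truncated = True
            sub[node] = (None, None)
        else:
            # parents of a kept node at depth < cutoff are themselves kept
            sub[node] = (sire, dam)
    return Pedigree(sub), truncated


def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Kinship coefficient phi(a, b) by the memoised tabular recursion."""
    for ind in (a, b):
        if ind not in ped.parents:
            raise PedigreeLookupError(ind)
    rank = ped.rank()
    cache = ped._phi_cache

    def phi(x: Optional[str], y: Optional[str]) -> float:
        if x is None or y is None:
            return 0.0
        key = (x, y) if x <= y else (y, x)
        got = cache.get(key)
        if got is not None:
            return got
        if x == y:
            sire, dam = ped.parents[x]
            val = 0.5 * (1.0 + phi(sire, dam))
        else:
            # recurse on the individual appearing later in topological
            # order: it cannot be an ancestor of the other
            if rank[x] < rank[y] or (rank[x] == rank[y] and x != y):
                x, y = y, x
            sire, dam = ped.parents[x]
            val = 0.5 * (phi(sire, y) + phi(dam, y))
        cache[key] = val
        return val

    return phi(a, b)


def inbreeding(ped: Pedigree, individual: str) -> float:
    """Inbreeding coefficient F = kinship of the individual's parents."""
    if individual not in ped.parents:
        raise PedigreeLookupError(individual)
    sire, dam = ped.parents[individual]
    if sire is None or dam is None:
        return 0.0
    return kinship(ped, sire, dam)


def pair_relatedness(
    ped: Pedigree,
    pairs: Iterable[tuple[Optional[str], Optional[str]]],
    max_generations: int = 5,
) -> list[KinshipResult]:
    """Relatedness r = 200 * phi for each (dam, sire) pair, with ancestor
    tracing truncated at ``max_generations``.

    Pairs with an unknown dam or sire, or one absent from the pedigree,
    yield a missing (``None``) relatedness rather than an error.
    """
    out: list[KinshipResult] = []
    for dam, sire in pairs:
        if dam is None or sire is None or dam not in ped or sire not in ped:
            out.append(
                KinshipResult(dam, sire, None, None, max_generations, False)
            )
            continue
        sub, truncated = truncate_ancestry(ped, (dam, sire), max_generations)
        phi = kinship(sub, dam, sire)
        out.append(
            KinshipResult(dam, sire, phi, 200.0 * phi, max_generations, truncated)
        )
    return out


def attach_relatedness(
    pairs: Sequence[PairSummary],
    ped: Pedigree,
    max_generations: int = 5,
) -> list[KinshipResult]:
    """Fill ``relatedness_pct`` on pair summaries in place and return the
    per-pair :class:`KinshipResult` list (same order)."""
    results = pair_relatedness(
        ped, [(p.dam_id, p.sire_id) for p in pairs], max_generations
    )
    for summary, res in zip(pairs, results):
        summary.relatedness_pct = res.relatedness_pct
    return results


# -- studbook interchange ---------------------------------------------------
# 4-column whitespace text: id sire dam sex, unknown coded "0" (the common
# pedigree-file convention).


def write_studbook(ped: Pedigree, path, sexes: Optional[Mapping[str, str]] = None) -> None:
    lines = []
    for ind, (sire, dam) in ped.parents.items():
        sex = (sexes or {}).get(ind, "0")
        lines.append(f"{ind}\t{sire or '0'}\t{dam or '0'}\t{sex}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_studbook(path) -> tuple[Pedigree, dict[str, str]]:
    parents: dict[str, ParentPair] = {}
    sexes: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ParameterError(f"studbook line needs >= 3 columns: {line!r}")
        ind, sire, dam = fields[:3]
        parents[ind] = (None if sire == "0" else sire, None if dam == "0" else dam)
        if len(fields) > 3 and fields[3] != "0":
            sexes[ind] = fields[3]
    return Pedigree(parents), sexes
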