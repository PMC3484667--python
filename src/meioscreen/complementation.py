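"""Complementation-group inference from pairwise transheterozygote assays.

Two recessive meiotic mutations are placed in the same gene when the
transheterozygote still shows the mutant phenotype — here, elevated X
chromosome nondisjunction — i.e. the alleles *fail to complement*.  Each
pairwise test is classified as fail / complement / inconclusive from its
adjusted X-ND percentage and sample size, and complementation groups are the
connected components of the fail-to-complement graph (failure is not
guaranteed transitive experimentally, so a consistency report flags
intransitive triangles and homozygote/group conflicts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "FAIL",
    "COMPLEMENT",
    "INCONCLUSIVE",
    "DEFAULT_FAIL_THRESHOLD",
    "DEFAULT_MIN_N",
    "ComplementationTest",
    "ComplementationGraph",
    "classify_test",
    "group_alleles",
    "consistency_report",
]

FAIL = "fail"
COMPLEMENT = "complement"
INCONCLUSIVE = "inconclusive"

# Default decision rule: the control baseline sits well below 1% X ND while
# even the weakest named mutant class runs ~2.4-24%; 5% splits the two ranges
# with margin.  Pairs scored on fewer than 50 adjusted progeny are too noisy
# to classify.
DEFAULT_FAIL_THRESHOLD = 5.0
DEFAULT_MIN_N = 50


@dataclass(frozen=True)
class ComplementationTest:
    """One transheterozygote nondisjunction assay between two alleles."""

    allele_a: str
    allele_b: str
    x_ndj_pct: float
    n_progeny: int

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"a complementation test needs two distinct alleles, got {self.allele_a!r} twice")
        if not 0.0 <= self.x_ndj_pct <= 100.0:
            raise ValueError(f"x_ndj_pct must be in [0, 100], got {self.x_ndj_pct}")
        if self.n_progeny < 0:
            raise ValueError(f"n_progeny must be nonnegative, got {self.n_progeny}")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.allele_a, self.allele_b))


def classify_test(
    test: ComplementationTest,
    fail_threshold: float = DEFAULT_FAIL_THRESHOLD,
    min_n: int = DEFAULT_MIN_N,
) -> str:
    """Classify one test as ``fail``, ``complement`` or ``inconclusive``.

    A pair fails to complement when the transheterozygote's X-ND percentage is
    at or above ``fail_threshold`` and the assay scored at least ``min_n``
    adjusted progeny; with enough progeny but low nondisjunction the alleles
    complement; with too few progeny the test is inconclusive.
    """
    if fail_threshold < 0:
        raise ValueError(f"fail_threshold must be nonnegative, got {fail_threshold}")
    if test.n_progeny < min_n:
        return INCONCLUSIVE
    return FAIL if test.x_ndj_pct >= fail_threshold else COMPLEMENT


@dataclass
class ComplementationGraph:
    """Alleles as nodes; fail-to-complement pairs as edges; groups as components."""

    nodes: set = field(default_factory=set)
    fail_edges: set = field(default_factory=set)  # frozenset pairs
    complement_pairs: set = field(default_factory=set)
    unresolved: set = field(default_factory=set)

    @classmethod
    def from_tests(
        cls,
        tests: Iterable[ComplementationTest],
        fail_threshold: float = DEFAULT_FAIL_THRESHOLD,
        min_n: int = DEFAULT_MIN_N,
        singletons: Iterable[str] = (),
    ) -> "ComplementationGraph":
        g = cls()
        g.nodes.update(singletons)
        for t in tests:
            g.nodes.update((t.allele_a, t.allele_b))
            verdict = classify_test(t, fail_threshold, min_n)
            if verdict == FAIL:
                g.fail_edges.add(t.pair)
            elif verdict == COMPLEMENT:
                g.complement_pairs.add(t.pair)
            else:
                g.unresolved.add(t.pair)
        # a pair with both a fail and a complement call is contradictory: keep
        # the fail edge (conservative lumping) — the consistency report flags it
        return g

    def groups(self) -> list[list[str]]:
        graph = nx.Graph()
        graph.add_nodes_from(self.nodes)
        graph.add_edges_from(tuple(e) for e in self.fail_edges)
        comps = [sorted(c) for c in nx.connected_components(graph)]
        return sorted(comps, key=lambda members: members[0])


def group_alleles(
    tests: Iterable[ComplementationTest],
    fail_threshold: float = DEFAULT_FAIL_THRESHOLD,
    min_n: int = DEFAULT_MIN_N,
    singletons: Iterable[str] = (),
) -> list[list[str]]:
    """Partition alleles into complementation groups.

    Groups are connected components of the fail-to-complement graph; alleles
    appearing only in complementing or inconclusive tests (or declared via
    ``singletons``) form singleton groups.  Groups are ordered, and named, by
    their lexicographically smallest member.
    """
    graph = ComplementationGraph.from_tests(tests, fail_threshold, min_n, singletons)
    return graph.groups()


def _group_of(partition: Sequence[Sequence[str]]) -> Mapping[str, int]:
    return {a: i for i, grp in enumerate(partition) for a in grp}


def consistency_report(
    tests: Iterable[ComplementationTest],
    fail_threshold: float = DEFAULT_FAIL_THRESHOLD,
    min_n: int = DEFAULT_MIN_N,
    homozygote_ndj: Mapping[str, float] | None = None,
) -> list[str]:
    """List internal inconsistencies of a classified test set.

    Reports (a) intransitive triangles — fail(a,b) and fail(b,c) but a
    complement call for (a,c); (b) pairs carrying both a fail and a complement
    call; (c) alleles whose homozygote X-ND is below the fail threshold yet
    sit in a multi-allele group (their own phenotype contradicts the grouping,
    the situation that makes weak groups hard to resolve).
    """
    graph = ComplementationGraph.from_tests(tests, fail_threshold, min_n)
    violations: list[str] = []

    for pair in sorted(graph.fail_edges & graph.complement_pairs, key=sorted):
        a, b = sorted(pair)
        violations.append(f"contradictory calls for ({a}, {b}): both fail and complement")

    neighbours: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for pair in graph.fail_edges:
        a, b = tuple(pair)
        neighbours[a].add(b)
        neighbours[b].add(a)
    seen = set()
    for b in sorted(graph.nodes):
        for a in sorted(neighbours[b]):
            for c in sorted(neighbours[b]):
                if a >= c:
                    continue
                pair_ac = frozenset((a, c))
                if pair_ac in graph.complement_pairs and pair_ac not in graph.fail_edges:
                    key = (a, b, c)
                    if key not in seen:
                        seen.add(key)
                        violations.append(
                            f"intransitive triangle: fail({a}, {b}) and fail({b}, {c}) "
                            f"but complement({a}, {c})"
                        )

    if homozygote_ndj:
        group_of = _group_of(graph.groups())
        sizes: dict[int, int] = {}
        for g in group_of.values():
            sizes[g] = sizes.get(g, 0) + 1
        for allele in sorted(homozygote_ndj):
            if allele not in group_of:
                continue
            if sizes[group_of[allele]] > 1 and homozygote_ndj[allele] < fail_threshold:
                violations.append(
                    f"allele {allele} has homozygote X-ND "
                    f"{homozygote_ndj[allele]:.1f}% below the fail threshold "
                    f"{fail_threshold:.1f}% yet belongs to a multi-allele group"
                )
    return violations
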