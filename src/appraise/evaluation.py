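"""Recommender-comparison statistics.

Blau diversity over distinct recommendation sets, overlap concordance between
systems, a nomenclature-derived pharmacological distance between drugs (0-33,
with "no treatment" pinned at the maximum), a modified-Hausdorff lift of that
distance to recommendation sets, cohort-averaged system distances, and UPGMA
dendrograms with Newick serialization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import NO_TREATMENT, DrugInfo, DrugRegistry, default_registry

MAX_DISTANCE = 33.0


# ---------------------------------------------------------------------------
# diversity


def blau_index(category_counts: Sequence[int]) -> float:
    """Gini-Simpson style diversity 1 - sum(p_i^2) over category proportions."""
    counts = list(category_counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all-zero counts")
    return 1.0 - sum((c / total) ** 2 for c in counts)


@dataclass(frozen=True)
class SystemOutput:
    """Per-patient recommended drug sets for one recommender system."""

    system_id: str
    recommendations: tuple[frozenset[str], ...]  # aligned with the cohort order

    def __len__(self) -> int:
        return len(self.recommendations)


def distinct_recommendation_sets(output: SystemOutput) -> list[int]:
    """Counts of exact-set-equality categories; sums to the cohort size."""
    counter = Counter(output.recommendations)
    return sorted(counter.values(), reverse=True)


def overlap_concordance(
    engine: SystemOutput, comparator: SystemOutput, denominator: str = "all_patients"
) -> float:
    """Percent of patients whose two drug sets share at least one drug.

    ``favorable_only`` restricts both numerator and denominator to patients
    with a non-empty first-system (engine) set.
    """
    if len(engine) != len(comparator):
        raise ValueError("outputs cover different cohorts")
    pairs = list(zip(engine.recommendations, comparator.recommendations))
    if denominator == "favorable_only":
        pairs = [(a, b) for a, b in pairs if a]
        if not pairs:
            raise ValueError("favorable_only denominator with zero favorable patients")
    elif denominator != "all_patients":
        raise ValueError(f"unknown denominator {denominator!r}")
    n_overlap = sum(1 for a, b in pairs if a & b)
    return 100.0 * n_overlap / len(pairs)


# ---------------------------------------------------------------------------
# pharmacological distance


@dataclass(frozen=True)
class DistanceScheme:
    """Additive mismatch weights calibrated to the packaged anchor distances."""

    w_target: float = 8.0
    w_mode: float = 2.0
    w_family: float = 5.0
    w_relation_hop: float = 1.0
    no_treatment_distance: float = MAX_DISTANCE
    max_distance: float = MAX_DISTANCE


@dataclass
class DistanceMatrix:
    codes: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.codes), len(self.codes)):
            raise ValueError("matrix shape does not match code list")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = v
        self._index = {c: i for i, c in enumerate(self.codes)}

    def distance(self, a: str, b: str) -> float:
        for code in (a, b):
            if code not in self._index:
                raise KeyError(f"drug '{code}' absent from distance matrix")
        return float(self.values[self._index[a], self._index[b]])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.codes, columns=self.codes).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(codes=list(df.index), values=df.to_numpy(dtype=float))


def _relation_hops(profiles: Mapping[str, DrugInfo]) -> dict[frozenset[str], int]:
    """Shortest-path hop counts in the undirected enantiomer/prodrug graph."""
    adj: dict[str, set[str]] = {c: set() for c in profiles}
    for code, p in profiles.items():
        for rel in (p.enantiomer_of, p.prodrug_of):
            if rel and rel in adj:
                adj[code].add(rel)
                adj[rel].add(code)
    hops: dict[frozenset[str], int] = {}
    for start in profiles:
        seen, frontier, depth = {start}, {start}, 0
        while frontier:
            depth += 1
            frontier = {n for f in frontier for n in adj[f]} - seen
            for node in frontier:
                hops.setdefault(frozenset((start, node)), depth)
            seen |= frontier
    return hops


def build_distance_matrix(
    profiles: Optional[Iterable[DrugInfo]] = None,
    scheme: DistanceScheme = DistanceScheme(),
) -> DistanceMatrix:
    """Pairwise drug distances from target/mode/family mismatches plus a small
    step per enantiomer/prodrug relation hop; "no treatment" sits at the
    scheme maximum from every active drug."""
    if profiles is None:
        profiles = default_registry().drugs
    prof = {p.code: p for p in profiles}
    if NO_TREATMENT in prof:
        del prof[NO_TREATMENT]
    hops = _relation_hops(prof)
    codes = sorted(prof) + [NO_TREATMENT]
    n = len(codes)
    m = np.zeros((n, n))
    for i, a in enumerate(codes):
        for j, b in enumerate(codes):
            if j <= i:
                continue
            if NO_TREATMENT in (a, b):
                d = scheme.no_treatment_distance
            else:
                pa, pb = prof[a], prof[b]
                d = (
                    scheme.w_target * len(pa.targets ^ pb.targets)
                    + scheme.w_mode * len(pa.modes ^ pb.modes)
                    + scheme.w_family * (pa.chemical_family != pb.chemical_family)
                    + scheme.w_relation_hop * hops.get(frozenset((a, b)), 0)
                )
                if d > scheme.max_distance:
                    raise ValueError(
                        f"scheme violates the {scheme.max_distance:g} bound for ({a}, {b}): {d:g}"
                    )
            m[i, j] = m[j, i] = d
    return DistanceMatrix(codes=codes, values=m)


def recset_distance(
    set_a: Iterable[str], set_b: Iterable[str], matrix: DistanceMatrix
) -> float:
    """Modified-Hausdorff distance between two drug sets.

    Empty sets stand for "no treatment". Symmetric; zero when the sets are
    equal (under zero self-distance).
    """
    a = sorted(set(set_a)) or [NO_TREATMENT]
    b = sorted(set(set_b)) or [NO_TREATMENT]
    fwd = np.mean([min(matrix.distance(x, y) for y in b) for x in a])
    bwd = np.mean([min(matrix.distance(y, x) for x in a) for y in b])
    return float((fwd + bwd) / 2.0)


def system_distance_matrix(
    outputs: Sequence[SystemOutput], matrix: DistanceMatrix
) -> DistanceMatrix:
    """System-level dissimilarity: per-patient set distance averaged over the cohort."""
    if len(outputs) < 2:
        raise ValueError("need at least two systems")
    sizes = {len(o) for o in outputs}
    if len(sizes) != 1:
        raise ValueError("outputs cover different cohorts")
    n = len(outputs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.mean(
                [
                    recset_distance(a, b, matrix)
                    for a, b in zip(outputs[i].recommendations, outputs[j].recommendations)
                ]
            )
            m[i, j] = m[j, i] = d
    return DistanceMatrix(codes=[o.system_id for o in outputs], values=m)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass(frozen=True)
class Merge:
    left: str  # newick fragment of the left cluster
    right: str
    height: float
    members: frozenset[str]


@dataclass
class Dendrogram:
    leaves: list[str]
    merges: list[Merge] = field(default_factory=list)
    newick: str = ""

    @property
    def heights(self) -> list[float]:
        return [m.height for m in self.merges]


def upgma_tree(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with lexicographic tie-breaking.

    Branch lengths in the Newick string are half-heights (ultrametric), so
    leaf-to-leaf path lengths equal merge heights.
    """
    # cluster state: key -> (member set, newick fragment, height of its root)
    clusters: dict[str, tuple[frozenset[str], str, float]] = {
        c: (frozenset([c]), c, 0.0) for c in dist.codes
    }
    d: dict[frozenset[str], float] = {}
    names = list(dist.codes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d[frozenset((a, b))] = dist.distance(a, b)

    merges: list[Merge] = []
    while len(clusters) > 1:
        # nearest pair; ties broken by sorted key names for determinism
        best = min(
            (
                (d[frozenset((a, b))], tuple(sorted((a, b))))
                for i, a in enumerate(sorted(clusters))
                for b in sorted(clusters)[i + 1:]
            ),
            key=lambda t: (t[0], t[1]),
        )
        h, (a, b) = best
        ma, fa, ha = clusters.pop(a)
        mb, fb, hb = clusters.pop(b)
        new_members = ma | mb
        frag = f"({fa}:{h / 2 - ha:g},{fb}:{h / 2 - hb:g})"
        merges.append(Merge(left=fa, right=fb, height=h, members=new_members))
        new_key = min(a, b)
        # UPGMA: size-weighted average of the two merged clusters' distances
        for other, (mo, _, _) in clusters.items():
            dao = d[frozenset((a, other))]
            dbo = d[frozenset((b, other))]
            d[frozenset((new_key, other))] = (len(ma) * dao + len(mb) * dbo) / len(new_members)
        clusters[new_key] = (new_members, frag, h / 2)

    (_, frag, _), = clusters.values()
    return Dendrogram(leaves=list(dist.codes), merges=merges, newick=frag + ";")


# ---------------------------------------------------------------------------
# report table


def evaluation_summary(outputs: Sequence[SystemOutput]) -> pd.DataFrame:
    """Per-system distinct-set counts and Blau index (two-decimal rounding)."""
    rows = []
    for out in outputs:
        counts = distinct_recommendation_sets(out)
        rows.append(
            {
                "system": out.system_id,
                "n_patients": len(out),
                "distinct_recommendations": len(counts),
                "blau_index": round(blau_index(counts), 2),
            }
        )
    return pd.DataFrame(rows)
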