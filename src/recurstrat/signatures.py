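"""Gene signatures, disjoint set-overlap (Venn) partitions and
hypergeometric over-representation.

A signature is the pair of up- and down-regulated gene sets selected from
one contrast at the configured FDR; the overlap partition decomposes up to
five named gene sets into their 2^k - 1 disjoint membership regions; the
enrichment test is the right tail of the hypergeometric distribution
(one-sided Fisher's exact test) for an observed overlap between a query
set and an annotation set within a finite gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom

from .differential import ContrastResult
from .io_formats import GeneSetCollection

MAX_PARTITION_SETS = 5


@dataclass
class GeneSignature:
    """Named, disjoint up/down gene sets derived from a contrast."""

    name: str
    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")
        if not self.up and not self.down:
            raise ValueError(f"signature {self.name!r} has no genes")

    def to_collection(self) -> GeneSetCollection:
        """GMT-ready view: two sets named <name>_UP and <name>_DOWN."""
        sets = {}
        if self.up:
            sets[f"{self.name}_UP"] = set(self.up)
        if self.down:
            sets[f"{self.name}_DOWN"] = set(self.down)
        return GeneSetCollection(sets=sets)

    @staticmethod
    def from_collection(collection: GeneSetCollection, name: str) -> "GeneSignature":
        up = collection.sets.get(f"{name}_UP", set())
        down = collection.sets.get(f"{name}_DOWN", set())
        return GeneSignature(name=name, up=set(up), down=set(down))


@dataclass
class OverlapPartition:
    """Disjoint membership-pattern regions of k named sets.

    ``regions`` maps each non-empty membership pattern (a tuple of set
    names, in input order) to the genes belonging to exactly those sets.
    Regions are pairwise disjoint and their union equals the union of the
    inputs.
    """

    set_names: list[str]
    regions: dict[tuple[str, ...], set[str]]

    def sizes(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(pattern), "degree": len(pattern), "size": len(genes)}
            for pattern, genes in self.regions.items()
        ]
        return pd.DataFrame(rows)

    def region(self, *names: str) -> set[str]:
        key = tuple(n for n in self.set_names if n in names)
        return self.regions.get(key, set())


@dataclass
class EnrichmentResult:
    """Right-tailed Fisher/hypergeometric over-representation result."""

    query_size: int
    annotation_size: int
    universe_size: int
    overlap: int
    p: float


def build_signature(contrast: ContrastResult, name: str | None = None) -> GeneSignature:
    """Select the passing up- and down-regulated genes of a contrast."""
    up = contrast.passing("up")
    down = contrast.passing("down")
    if not up and not down:
        raise ValueError(
            f"contrast {contrast.name!r} has no passing genes; "
            "signature would be unusable for scoring"
        )
    return GeneSignature(name=name or contrast.name, up=up, down=down)


def overlap_partition(sets: dict[str, set[str]]) -> OverlapPartition:
    """Partition k (2 <= k <= 5) named sets into disjoint Venn regions."""
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets to partition")
    if len(names) > MAX_PARTITION_SETS:
        raise ValueError(f"at most {MAX_PARTITION_SETS} sets supported")
    regions: dict[tuple[str, ...], set[str]] = {}
    for degree in range(1, len(names) + 1):
        for pattern in combinations(names, degree):
            inside = set.intersection(*(set(sets[n]) for n in pattern))
            outside = set().union(
                *(set(sets[n]) for n in names if n not in pattern), set()
            )
            regions[pattern] = inside - outside
    return OverlapPartition(set_names=names, regions=regions)


def fisher_right_tail(
    overlap: int, query: int, annotation: int, universe: int
) -> EnrichmentResult:
    """P(X >= overlap) for X hypergeometric(universe, annotation, query).

    The probability that a random query of the given size drawn from the
    universe hits the annotation at least ``overlap`` times. ``overlap=0``
    gives p = 1 exactly. scipy evaluates the tail via logarithms of the
    hypergeometric pmf, so small tail masses remain accurate.
    """
    counts = {"overlap": overlap, "query": query, "annotation": annotation, "universe": universe}
    for key, value in counts.items():
        if value < 0 or value != int(value):
            raise ValueError(f"{key} must be a non-negative integer")
    if overlap > query or overlap > annotation:
        raise ValueError("overlap exceeds query or annotation size")
    if query > universe or annotation > universe:
        raise ValueError("query/annotation exceed universe")
    if query + annotation - overlap > universe:
        raise ValueError("counts inconsistent with the universe size")
    p = float(hypergeom.sf(overlap - 1, universe, annotation, query))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(
        query_size=query,
        annotation_size=annotation,
        universe_size=universe,
        overlap=overlap,
        p=p,
    )


def enrich_sets(
    queries: GeneSetCollection,
    annotations: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation of every (query, annotation) pair within universe.

    Genes outside the universe are ignored; the universe defaults, at the
    pipeline level, to the post-filter gene list of the analyzed matrix.
    """
    rows = []
    universe = set(universe)
    for qname in queries.names():
        qset = queries[qname] & universe
        for aname in annotations.names():
            aset = annotations[aname] & universe
            res = fisher_right_tail(
                overlap=len(qset & aset),
                query=len(qset),
                annotation=len(aset),
                universe=len(universe),
            )
            rows.append(
                {
                    "query": qname,
                    "annotation": aname,
                    "query_size": res.query_size,
                    "annotation_size": res.annotation_size,
                    "overlap": res.overlap,
                    "universe_size": res.universe_size,
                    "p_right_tail": res.p,
                }
            )
    return pd.DataFrame(rows)
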