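"""KEGG Orthology (KO) and pathway-category assignment for ortholog clusters.

Each cluster's designated representative (the member from the first genome
in the configured order) is searched against a KO-labelled reference; the
KO of the best passing hit is assigned to the cluster.  The KO then maps to
a category through its pathways:

* no passing hit           -> category "unknown" (no KO)
* KO in no pathway         -> "Undecided"
* KO pathways span several categories -> "Multiple"
* all KO pathways share one category  -> that category

The KO mapping bundle is three TSVs: gene2ko (reference gene -> KO),
ko2pathway (KO -> pathway, one row per pair) and pathway2category.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .sequence_io import ParseError, SimilarityHit

UNKNOWN = "unknown"
UNDECIDED = "Undecided"
MULTIPLE = "Multiple"


@dataclass
class KOMap:
    gene2ko: dict[str, str]
    ko2pathways: dict[str, set[str]]
    pathway2category: dict[str, str]

    def __post_init__(self) -> None:
        for ko, pathways in self.ko2pathways.items():
            missing = pathways - self.pathway2category.keys()
            if missing:
                raise ValueError(f"KO {ko}: pathways without a category: {sorted(missing)}")


@dataclass
class FunctionAssignment:
    cluster_id: str
    ko: str | None
    category: str

    def __post_init__(self) -> None:
        if (self.ko is None) != (self.category == UNKNOWN):
            raise ValueError("category must be 'unknown' exactly when no KO is assigned")


def _read_two_column(path: Path, what: str) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for idx, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: row {idx}: expected 2 fields for {what}")
            rows.append((parts[0], parts[1]))
    return rows


def load_ko_map(directory: str | Path) -> KOMap:
    """Load the three-TSV KO bundle (gene2ko, ko2pathway, pathway2category)."""
    directory = Path(directory)
    gene2ko = dict(_read_two_column(directory / "gene2ko.tsv", "gene2ko"))
    ko2pathways: dict[str, set[str]] = {}
    for ko, pw in _read_two_column(directory / "ko2pathway.tsv", "ko2pathway"):
        ko2pathways.setdefault(ko, set()).add(pw)
    pathway2category = dict(_read_two_column(directory / "pathway2category.tsv", "pathway2category"))
    return KOMap(gene2ko, ko2pathways, pathway2category)


def write_ko_map(komap: KOMap, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "gene2ko.tsv", "w") as fh:
        for gene in sorted(komap.gene2ko):
            fh.write(f"{gene}\t{komap.gene2ko[gene]}\n")
    with open(directory / "ko2pathway.tsv", "w") as fh:
        for ko in sorted(komap.ko2pathways):
            for pw in sorted(komap.ko2pathways[ko]):
                fh.write(f"{ko}\t{pw}\n")
    with open(directory / "pathway2category.tsv", "w") as fh:
        for pw in sorted(komap.pathway2category):
            fh.write(f"{pw}\t{komap.pathway2category[pw]}\n")


def assign_ko(
    hits: list[SimilarityHit],
    gene2ko: dict[str, str],
    max_evalue: float = 1e-5,
) -> str | None:
    """KO of the representative's best passing hit, or None without hits.

    Ranking is bitscore descending (ties: e-value ascending, subject id
    ascending).  A passing hit whose subject has no KO label is an error:
    the KO reference must be fully labelled.
    """
    retained = [h for h in hits if h.evalue <= max_evalue]
    if not retained:
        return None
    retained.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    best = retained[0]
    if best.subject_id not in gene2ko:
        raise KeyError(f"subject {best.subject_id!r} has no KO label")
    return gene2ko[best.subject_id]


def categorize_ko(ko: str, komap: KOMap) -> str:
    """Category of a KO through its pathways (Undecided/Multiple/category)."""
    pathways = komap.ko2pathways.get(ko, set())
    if not pathways:
        return UNDECIDED
    categories = set()
    for pw in pathways:
        if pw not in komap.pathway2category:
            raise KeyError(f"pathway {pw!r} has no category")
        categories.add(komap.pathway2category[pw])
    if len(categories) > 1:
        return MULTIPLE
    return categories.pop()


def assign_cluster_function(
    cluster_id: str,
    representative_hits: list[SimilarityHit],
    komap: KOMap,
    max_evalue: float = 1e-5,
) -> FunctionAssignment:
    ko = assign_ko(representative_hits, komap.gene2ko, max_evalue)
    category = UNKNOWN if ko is None else categorize_ko(ko, komap)
    return FunctionAssignment(cluster_id, ko, category)


@dataclass
class FunctionalSummary:
    """Category-by-subset cross-tab plus no/multiple assignment counts.

    ``no_assignment`` pools "unknown" and "Undecided" (also reported
    separately); subsets are "All" plus every phylum label observed.
    """

    crosstab: pd.DataFrame
    no_assignment: dict[str, int]
    multiple_assignment: dict[str, int]
    unknown: dict[str, int]
    undecided: dict[str, int]
    subset_sizes: dict[str, int]


def functional_summary(
    functions: list[FunctionAssignment],
    cog_labels: dict[str, str],
) -> FunctionalSummary:
    """Cross-tabulate categories against phylum subsets of the clusters.

    ``cog_labels`` maps cluster_id to its taxon label; both inputs must
    cover exactly the same cluster universe.
    """
    fun_ids = {f.cluster_id for f in functions}
    if fun_ids != set(cog_labels):
        extra = sorted(fun_ids ^ set(cog_labels))[:5]
        raise ValueError(f"cluster universes differ between inputs (e.g. {extra})")
    subsets = ["All"] + sorted(
        {lab for lab in cog_labels.values()}
    )
    category_counts: dict[str, Counter] = {s: Counter() for s in subsets}
    no = dict.fromkeys(subsets, 0)
    multi = dict.fromkeys(subsets, 0)
    unknown = dict.fromkeys(subsets, 0)
    undecided = dict.fromkeys(subsets, 0)
    sizes = dict.fromkeys(subsets, 0)
    for fun in functions:
        label = cog_labels[fun.cluster_id]
        for subset in ("All", label):
            sizes[subset] += 1
            if fun.category == UNKNOWN:
                no[subset] += 1
                unknown[subset] += 1
            elif fun.category == UNDECIDED:
                no[subset] += 1
                undecided[subset] += 1
            elif fun.category == MULTIPLE:
                multi[subset] += 1
            else:
                category_counts[subset][fun.category] += 1
    categories = sorted({c for counter in category_counts.values() for c in counter})
    crosstab = pd.DataFrame(
        {s: [category_counts[s].get(c, 0) for c in categories] for s in subsets},
        index=categories,
        dtype=int,
    )
    return FunctionalSummary(crosstab, no, multi, unknown, undecided, sizes)
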