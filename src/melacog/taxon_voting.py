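"""Phylum assignment: per gene by the identical-positions margin rule, per
cluster by majority vote.

Each gene is compared against a taxon-labelled reference.  Hits passing the
e-value cut are ranked by bitscore, and the top two are compared by their
number of identical positions, IP = alignment_length * %identity / 100.
The top hit wins outright only when IP1 >= IP2 * (1 + margin) (default
margin 0.05, i.e. "at least 5% more", inclusive); otherwise the gene is
labelled "Multiple".  A gene with no passing hit is "No hit"; a single
passing hit assigns its phylum.

A cluster's label is then the plurality phylum over its member genes.  All
members "No hit" gives "No hit"; two or more member-level "Multiple" votes,
or a tied plurality, give "Multiple".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .sequence_io import SimilarityHit

NO_HIT = "No hit"
MULTIPLE = "Multiple"

#: absolute slack on the identical-positions margin comparison, so the
#: inclusive boundary IP1 == IP2 * (1 + margin) survives float rounding
_MARGIN_TOL = 1e-9


@dataclass
class VotingConfig:
    evalue_cut: float = 1e-5
    margin: float = 0.05
    #: member-level "Multiple" votes required to call the cluster "Multiple"
    multiple_threshold: int = 2
    #: when True, two non-separable top hits from the same phylum yield
    #: that phylum instead of "Multiple"
    collapse_same_phylum: bool = False

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.evalue_cut <= 0:
            raise ValueError("evalue_cut must be positive")


@dataclass
class GeneTaxonAssignment:
    gene_id: str
    label: str
    top_hits: list[SimilarityHit] = field(default_factory=list)
    identical_positions: list[float] = field(default_factory=list)


def identical_positions(hit: SimilarityHit) -> float:
    """Identical columns of the alignment: length * %identity / 100."""
    return hit.length * hit.pident / 100.0


def assign_gene_phylum(
    gene_id: str,
    hits: list[SimilarityHit],
    taxonomy: dict[str, str],
    cfg: VotingConfig = VotingConfig(),
) -> GeneTaxonAssignment:
    """Label one gene from its reference hits via the margin rule."""
    retained = [h for h in hits if h.evalue <= cfg.evalue_cut]
    if not retained:
        return GeneTaxonAssignment(gene_id, NO_HIT)
    for h in retained:
        if h.subject_id not in taxonomy:
            raise KeyError(f"subject {h.subject_id!r} missing from the taxonomy map")
    retained.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    top = retained[:2]
    ips = [identical_positions(h) for h in top]
    if len(top) == 1:
        return GeneTaxonAssignment(gene_id, taxonomy[top[0].subject_id], top, ips)
    phylum1 = taxonomy[top[0].subject_id]
    phylum2 = taxonomy[top[1].subject_id]
    if ips[0] >= ips[1] * (1.0 + cfg.margin) - _MARGIN_TOL:
        label = phylum1
    elif cfg.collapse_same_phylum and phylum1 == phylum2:
        label = phylum1
    else:
        label = MULTIPLE
    return GeneTaxonAssignment(gene_id, label, top, ips)


def assign_cog_phylum(labels: list[str], cfg: VotingConfig = VotingConfig()) -> str:
    """Majority vote over the member-gene labels of one cluster.

    A vote with phylum evidence but no resolvable plurality (all phylum
    votes absent or tied, or too many member-level "Multiple" calls)
    returns "Multiple"; only a cluster whose members all lack hits returns
    "No hit".
    """
    if not labels:
        raise ValueError("empty label list")
    if all(lab == NO_HIT for lab in labels):
        return NO_HIT
    if sum(lab == MULTIPLE for lab in labels) >= cfg.multiple_threshold:
        return MULTIPLE
    counts = Counter(lab for lab in labels if lab not in (NO_HIT, MULTIPLE))
    if not counts:
        return MULTIPLE
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[1][1] == ranked[0][1]:
        return MULTIPLE
    return ranked[0][0]


def summarize_phylum_fractions(labels: list[str]) -> pd.DataFrame:
    """Count and fraction per label, sorted by count desc then label."""
    if not labels:
        raise ValueError("no labels to summarize")
    counts = Counter(labels)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["label", "count"])
    df["fraction"] = df["count"] / len(labels)
    return df.set_index("label")
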