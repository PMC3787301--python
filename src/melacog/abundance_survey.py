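"""16S rRNA survey tallying and group comparison.

Reads matched against a target-lineage 16S reference are retained at >= 97%
identity (one assignment per read, by top bitscore), tallied per sample,
and expressed as relative abundance, 100 * target_reads / total_reads.
Before plotting or comparison, samples with zero retained reads are
removed, and whole sample types whose summed retained reads fall below five
are dropped.  Abundances are reported log10-transformed (10^-1 = 0.1%).

The two-group comparison is a two-tailed Student t-test with pooled
variance by default (Welch's correction by flag), typically applied to the
log-abundances of two sample-type groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .sequence_io import SimilarityHit


@dataclass
class SampleTally:
    sample_id: str
    sample_type: str
    total_reads: int
    target_reads: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError(f"sample {self.sample_id}: non-positive total reads")
        if not 0 <= self.target_reads <= self.total_reads:
            raise ValueError(f"sample {self.sample_id}: target reads out of range")

    @property
    def rel_abundance_pct(self) -> float:
        return 100.0 * self.target_reads / self.total_reads

    @property
    def log10_pct(self) -> float:
        if self.target_reads == 0:
            raise ValueError(f"sample {self.sample_id}: log10 undefined at zero reads")
        return math.log10(self.rel_abundance_pct)


def filter_hits(
    hits: list[SimilarityHit], min_pident: float = 97.0
) -> dict[str, SimilarityHit]:
    """Retain hits at >= min_pident (inclusive) and keep one assignment per
    read: the top bitscore (ties: e-value ascending, subject ascending)."""
    best: dict[str, SimilarityHit] = {}
    for hit in hits:
        if hit.pident < min_pident:
            continue
        cur = best.get(hit.query_id)
        if cur is None or (-hit.bitscore, hit.evalue, hit.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[hit.query_id] = hit
    return best


def _sample_of_read(read_id: str) -> str:
    """Reads are named ``<sample>|<read>``; the sample is the first token."""
    return read_id.split("|", 1)[0]


def tally(
    assignments: dict[str, SimilarityHit],
    sample_totals: dict[str, int],
    sample_types: dict[str, str],
) -> list[SampleTally]:
    """Per-sample target-read counts and relative abundances.

    Every sample in ``sample_totals`` appears in the output (zero-read
    samples included; they are removed later by :func:`group_filter`).
    An assignment from a sample without a total is an error.
    """
    counts: dict[str, int] = dict.fromkeys(sample_totals, 0)
    for read_id in assignments:
        sample = _sample_of_read(read_id)
        if sample not in sample_totals:
            raise KeyError(f"sample {sample!r} has no read total")
        counts[sample] += 1
    out = []
    for sample in sample_totals:
        if sample not in sample_types:
            raise KeyError(f"sample {sample!r} has no sample type")
        out.append(
            SampleTally(
                sample_id=sample,
                sample_type=sample_types[sample],
                total_reads=sample_totals[sample],
                target_reads=counts[sample],
            )
        )
    return out


def group_filter(
    tallies: list[SampleTally], min_type_reads: int = 5
) -> pd.DataFrame:
    """Apply the plotting filters and emit (type, sample, log10_pct) rows.

    Drops samples with zero target reads, then whole sample types whose
    summed target reads (over all their samples) fall below
    ``min_type_reads``.  Idempotent: refiltering the survivors changes
    nothing.
    """
    type_sums: dict[str, int] = {}
    for t in tallies:
        type_sums[t.sample_type] = type_sums.get(t.sample_type, 0) + t.target_reads
    rows = [
        (t.sample_type, t.sample_id, t.log10_pct)
        for t in tallies
        if t.target_reads > 0 and type_sums[t.sample_type] >= min_type_reads
    ]
    rows.sort()
    return pd.DataFrame(rows, columns=["sample_type", "sample_id", "log10_pct"])


def compare_two_groups(
    values_a: list[float], values_b: list[float], welch: bool = False
) -> dict[str, float]:
    """Two-tailed t-test between two groups of (log-)abundances.

    Pooled-variance Student t by default; ``welch=True`` drops the
    equal-variance assumption.  Each group needs at least two values.
    """
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("each group needs at least two values")
    result = stats.ttest_ind(values_a, values_b, equal_var=not welch)
    return {"t_statistic": float(result.statistic), "p_two_tailed": float(result.pvalue)}
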