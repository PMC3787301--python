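"""RnpB conserved-motif scanning and flagellin TLR5-region extraction.

RnpB (the RNA subunit of RNase P) is located by exact matches to its highly
conserved motif 5'-GAGGAAAGUCC-3' (U == T on the DNA strand), searched on
both strands, with the surrounding region reported for downstream structure
analysis.

For flagellins, the span governing Toll-like receptor 5 recognition is
residues 88-103 in reference (E. coli FliC) coordinates.  The module
extracts each flagellin's residues aligned to that span via global pairwise
alignment; whether TLR5 would recognise the protein is deliberately NOT
called — the extracted regions are emitted for human inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import biotite.sequence as bseq
import biotite.sequence.align as balign

RNPB_MOTIF = "GAGGAAAGTCC"

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifMatch:
    scaffold_id: str
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int
    strand: str
    flank: str


def _scan_one_strand(seq: str, motif: str, max_mismatch: int) -> list[int]:
    """0-based start positions of (near-)exact motif occurrences."""
    positions: list[int] = []
    if max_mismatch == 0:
        idx = seq.find(motif)
        while idx != -1:
            positions.append(idx)
            idx = seq.find(motif, idx + 1)
        return positions
    k = len(motif)
    for idx in range(len(seq) - k + 1):
        window = seq[idx : idx + k]
        mismatches = sum(a != b for a, b in zip(window, motif))
        if mismatches <= max_mismatch:
            positions.append(idx)
    return positions


def find_rnpb_loci(
    scaffolds: dict[str, str],
    flank_size: int = 500,
    max_mismatch: int = 0,
) -> list[MotifMatch]:
    """Every occurrence of the RnpB motif on both strands of each scaffold.

    Coordinates are 1-based inclusive on the forward strand; a minus-strand
    match is the segment whose reverse complement equals the motif.  Flanks
    extend ``flank_size`` bases on each side, truncated at scaffold ends.
    """
    motif = RNPB_MOTIF
    rc_motif = reverse_complement(motif)
    k = len(motif)
    matches: list[MotifMatch] = []
    for scaffold_id in scaffolds:
        seq = scaffolds[scaffold_id].upper()
        found = [(pos, "+") for pos in _scan_one_strand(seq, motif, max_mismatch)]
        found += [(pos, "-") for pos in _scan_one_strand(seq, rc_motif, max_mismatch)]
        for pos, strand in sorted(found):
            lo = max(0, pos - flank_size)
            hi = min(len(seq), pos + k + flank_size)
            matches.append(
                MotifMatch(
                    scaffold_id=scaffold_id,
                    start=pos + 1,
                    end=pos + k,
                    strand=strand,
                    flank=seq[lo:hi],
                )
            )
    return matches


@dataclass
class Tlr5Region:
    """A flagellin's residues aligned to reference positions 88-103."""

    source_id: str
    region: str
    gapped: bool


def extract_tlr5_region(
    flagellin,
    reference,
    ref_start: int = 88,
    ref_end: int = 103,
) -> Tlr5Region:
    """Query columns globally aligned to reference residues 88-103.

    Global alignment uses BLOSUM62 with affine gaps (existence 11,
    extension 1).  The region string carries '-' where a reference position
    aligns to a gap in the query (``gapped`` is then True) and includes
    query insertions falling strictly inside the span.
    """
    source_id = getattr(flagellin, "id", "query")
    flagellin = getattr(flagellin, "sequence", flagellin)
    reference = getattr(reference, "sequence", reference)
    if len(reference) < ref_end:
        raise ValueError(
            f"reference has {len(reference)} residues; needs >= {ref_end}"
        )
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    alignment = balign.align_optimal(
        bseq.ProteinSequence(flagellin),
        bseq.ProteinSequence(reference),
        matrix,
        gap_penalty=(-11, -1),
    )[0]
    trace = alignment.trace  # columns x (query, reference), -1 = gap
    lo = ref_start - 1
    hi = ref_end - 1
    pieces: list[str] = []
    pending: list[str] = []  # insertions only count when flanked in-span
    gapped = False
    started = False
    for qi, ri in trace:
        if ri != -1:
            if lo <= ri <= hi:
                if started:
                    pieces.extend(pending)
                pending = []
                started = True
                if qi == -1:
                    pieces.append("-")
                    gapped = True
                else:
                    pieces.append(flagellin[qi])
            elif ri > hi:
                break
        elif started and qi != -1:
            pending.append(flagellin[qi].lower())
    return Tlr5Region(source_id=source_id, region="".join(pieces), gapped=gapped)


def region_identity(a: str, b: str) -> float:
    """Column identity of two extracted regions (padded to equal length)."""
    n = max(len(a), len(b))
    if n == 0:
        return 1.0
    a = a.upper().ljust(n, "-")
    b = b.upper().ljust(n, "-")
    return sum(x == y and x != "-" for x, y in zip(a, b)) / n


def order_by_region_similarity(regions: list[Tlr5Region]) -> list[Tlr5Region]:
    """Deterministic display order by average-linkage clustering on region
    identity; ties and the initial order are fixed by sorting on id."""
    if not regions:
        raise ValueError("no regions to order")
    ordered_in = sorted(regions, key=lambda r: r.source_id)
    if len(ordered_in) == 1:
        return ordered_in
    n = len(ordered_in)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - region_identity(ordered_in[i].region, ordered_in[j].region)
            dist[i, j] = dist[j, i] = d
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(linkage)
    return [ordered_in[i] for i in leaves]
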