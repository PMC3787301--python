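"""Seeded generator for every input the pipeline consumes, with planted truth.

The generator emulates the statistical structure of a small comparative
study of four related genomes:

* ortholog families: an ancestral protein per family, drawn residue-wise
  from background amino-acid frequencies, copied into each genome with
  per-site substitutions at the configured divergence, optionally with
  gene loss and duplicated paralogs at elevated divergence;
* a taxon-labelled reference database (the stand-in for nr): per family a
  close homolog carrying the family's designated nearest phylum plus one
  more-distant decoy per other phylum, so the per-gene margin rule is
  actually exercised;
* a KO annotation bundle with planted expected categories;
* nucleotide scaffolds obtained by back-translating the proteins with
  uniform codon choice, joined by random spacers, fragmented, with the
  RnpB motif planted at recorded positions and a partial linkage table;
* a 16S survey with per-sample-type log-normal abundances.

Substitutions are i.i.d. replacements drawn from the background
frequencies (no rate matrix): the pipeline's decision rules only see
identity levels, which this controls directly.  One integer seed drives a
hierarchical stream (one substream per generator stage) so stages can be
regenerated independently; identical seeds reproduce byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .genome_assessment import BACKGROUND_FREQS, MarkerSet, ScaffoldSet, default_marker_set
from .kegg_assignment import KOMap, write_ko_map
from .marker_scan import RNPB_MOTIF, reverse_complement
from .sequence_io import ProteinRecord, SimilarityHit, write_fasta, write_hit_table, write_taxonomy_map

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: KEGG-style pathway categories used for the planted KO catalog.
PATHWAY_CATEGORIES = [
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Amino acid metabolism",
    "Nucleotide metabolism",
    "Membrane transport",
]


@dataclass
class SurveyTypeConfig:
    """Log-normal relative-abundance model of one sample type.

    ``median_pct`` is the median relative abundance in percent; per-sample
    abundances are 10^(log10(median) + Normal(0, sigma_log10)).
    """

    median_pct: float
    sigma_log10: float = 0.4
    n_samples: int = 12


def _default_survey() -> dict[str, SurveyTypeConfig]:
    return {
        "feces_foregut": SurveyTypeConfig(0.60),
        "feces_hindgut": SurveyTypeConfig(0.15),
        "water": SurveyTypeConfig(1.0, n_samples=10),
        "soil": SurveyTypeConfig(0.02, n_samples=10),
        "air": SurveyTypeConfig(0.0005, n_samples=6),
    }


def _default_phyla() -> dict[str, float]:
    # fractions of families whose nearest reference phylum is planted;
    # the remainder have no reference counterpart ("No hit" families)
    return {
        "Firmicutes": 0.30,
        "Cyanobacteria": 0.15,
        "Proteobacteria": 0.30,
        "Bacteroidetes": 0.15,
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genomes: int = 4
    n_families: int = 200
    #: per-site substitution probability applied to each genome copy
    divergence: float = 0.05
    p_loss: float = 0.0
    p_dup: float = 0.0
    paralog_extra_divergence: float = 0.2
    protein_length_mean: float = 250.0
    protein_length_sd: float = 50.0
    min_protein_length: int = 60
    phylum_fractions: dict[str, float] = field(default_factory=_default_phyla)
    #: divergence of the nearest-phylum reference homolog from the ancestor
    near_divergence: float = 0.10
    #: divergence of the per-other-phylum decoy homologs
    decoy_divergence: float = 0.35
    p_family_has_ko: float = 0.7
    p_ko_no_pathway: float = 0.10
    p_ko_multi_category: float = 0.10
    marker_insertion: bool = True
    scaffold_mean_length: int = 50_000
    linkage_completeness: float = 1.0
    n_motifs_per_genome: int = 3
    spacer_length_range: tuple[int, int] = (50, 200)
    survey: dict[str, SurveyTypeConfig] = field(default_factory=_default_survey)
    survey_decoy_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least two genomes")
        for p in (self.divergence, self.p_loss, self.p_dup):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if sum(self.phylum_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("phylum fractions must sum to at most 1")

    @property
    def genome_ids(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genomes)]


@dataclass
class GroundTruth:
    """Planted facts, kept consistent with the emitted files."""

    families: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    family_of: dict[str, str] = field(default_factory=dict)
    ancestral: dict[str, str] = field(default_factory=dict)
    nearest_phylum: dict[str, str | None] = field(default_factory=dict)
    family_ko: dict[str, str | None] = field(default_factory=dict)
    ko_expected_category: dict[str, str] = field(default_factory=dict)
    motif_positions: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    survey_true_counts: dict[str, int] = field(default_factory=dict)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ["proteomes", "reference", "ko_catalog", "scaffolds", "survey"]
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _draw_sequence(rng: np.random.Generator, length: int) -> str:
    codes = rng.choice(20, size=length, p=BACKGROUND_FREQS)
    return "".join(_ALPHABET[c] for c in codes)


def mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Replace each site independently with prob ``rate`` by a background draw."""
    if rate <= 0:
        return sequence
    mask = rng.random(len(sequence)) < rate
    n_mut = int(mask.sum())
    if n_mut == 0:
        return sequence
    new_codes = rng.choice(20, size=n_mut, p=BACKGROUND_FREQS)
    chars = list(sequence)
    for pos, code in zip(np.nonzero(mask)[0], new_codes):
        chars[pos] = _ALPHABET[code]
    return "".join(chars)


def simulate_proteomes(
    config: SimulationConfig,
) -> tuple[dict[str, list[ProteinRecord]], GroundTruth]:
    """Per-genome predicted proteomes with planted ortholog families.

    Family ``F####`` has one ortholog per genome (unless lost), optional
    paralogs, and — when ``marker_insertion`` — the 16 default single-copy
    marker representatives inserted once per genome as families ``MK_*``.
    """
    rng = _streams(config.seed)["proteomes"]
    truth = GroundTruth()
    proteomes: dict[str, list[ProteinRecord]] = {g: [] for g in config.genome_ids}
    for fam_idx in range(config.n_families):
        fam = f"F{fam_idx:04d}"
        length = max(
            config.min_protein_length,
            int(round(rng.normal(config.protein_length_mean, config.protein_length_sd))),
        )
        ancestor = _draw_sequence(rng, length)
        truth.ancestral[fam] = ancestor
        truth.families[fam] = {}
        for genome in config.genome_ids:
            members: list[str] = []
            if rng.random() >= config.p_loss:
                pid = f"{genome}|{fam}"
                seq = mutate(ancestor, config.divergence, rng)
                proteomes[genome].append(ProteinRecord(pid, genome, seq))
                members.append(pid)
                truth.family_of[pid] = fam
                if rng.random() < config.p_dup:
                    dup_id = f"{genome}|{fam}p"
                    dup_seq = mutate(seq, config.paralog_extra_divergence, rng)
                    proteomes[genome].append(ProteinRecord(dup_id, genome, dup_seq))
                    members.append(dup_id)
                    truth.family_of[dup_id] = fam
            truth.families[fam][genome] = members
    if config.marker_insertion:
        markers = default_marker_set()
        for name, seqs in markers.representatives.items():
            fam = f"MK_{name}"
            truth.ancestral[fam] = seqs[0]
            truth.families[fam] = {}
            for genome in config.genome_ids:
                pid = f"{genome}|{fam}"
                proteomes[genome].append(ProteinRecord(pid, genome, seqs[0]))
                truth.family_of[pid] = fam
                truth.families[fam][genome] = [pid]
    return proteomes, truth


def simulate_reference_db(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[list[ProteinRecord], dict[str, str], KOMap]:
    """Taxon-labelled reference proteins plus the planted KO bundle.

    For each family with a designated nearest phylum: one close homolog of
    the ancestor labelled with that phylum, and one more-distant decoy per
    other phylum.  Families without a phylum emit nothing ("No hit").
    Marker families never get a reference.
    """
    rng = _streams(config.seed)["reference"]
    ko_rng = _streams(config.seed)["ko_catalog"]
    protein_fams = sorted(f for f in truth.families if f.startswith("F"))
    order = list(protein_fams)
    rng.shuffle(order)
    assignment: dict[str, str | None] = dict.fromkeys(protein_fams, None)
    pos = 0
    for phylum, fraction in config.phylum_fractions.items():
        n = int(round(fraction * len(protein_fams)))
        for fam in order[pos : pos + n]:
            assignment[fam] = phylum
        pos += n
    phyla = list(config.phylum_fractions)
    references: list[ProteinRecord] = []
    taxonomy: dict[str, str] = {}
    gene2ko: dict[str, str] = {}
    family_ko: dict[str, str | None] = {}
    ko_counter = 0
    for fam in protein_fams:
        phylum = assignment[fam]
        truth.nearest_phylum[fam] = phylum
        if phylum is None:
            family_ko[fam] = None
            continue
        ancestor = truth.ancestral[fam]
        fam_refs = []
        near_id = f"REF|{fam}|near"
        references.append(
            ProteinRecord(near_id, "REF", mutate(ancestor, config.near_divergence, rng))
        )
        taxonomy[near_id] = phylum
        fam_refs.append(near_id)
        for other in phyla:
            if other == phylum:
                continue
            decoy_id = f"REF|{fam}|{other}"
            references.append(
                ProteinRecord(decoy_id, "REF", mutate(ancestor, config.decoy_divergence, rng))
            )
            taxonomy[decoy_id] = other
            fam_refs.append(decoy_id)
        if ko_rng.random() < config.p_family_has_ko:
            ko = f"K{ko_counter:05d}"
            ko_counter += 1
            family_ko[fam] = ko
            for ref_id in fam_refs:
                gene2ko[ref_id] = ko
        else:
            family_ko[fam] = None
    for fam in truth.families:
        if fam.startswith("MK_"):
            truth.nearest_phylum[fam] = None
            family_ko[fam] = None
    truth.family_ko = family_ko
    komap = _build_ko_catalog(
        sorted({ko for ko in family_ko.values() if ko}), gene2ko, config, ko_rng, truth
    )
    return references, taxonomy, komap


def _build_ko_catalog(
    kos: list[str],
    gene2ko: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: GroundTruth,
) -> KOMap:
    pathways_by_cat = {
        cat: [f"map{100 * (i + 1) + j:05d}" for j in range(4)]
        for i, cat in enumerate(PATHWAY_CATEGORIES)
    }
    pathway2category = {
        pw: cat for cat, pws in pathways_by_cat.items() for pw in pws
    }
    ko2pathways: dict[str, set[str]] = {}
    for ko in kos:
        roll = rng.random()
        if roll < config.p_ko_no_pathway:
            ko2pathways[ko] = set()
            truth.ko_expected_category[ko] = "Undecided"
        elif roll < config.p_ko_no_pathway + config.p_ko_multi_category:
            cats = rng.choice(len(PATHWAY_CATEGORIES), size=2, replace=False)
            chosen = {
                pathways_by_cat[PATHWAY_CATEGORIES[c]][
                    int(rng.integers(0, 4))
                ]
                for c in cats
            }
            ko2pathways[ko] = chosen
            truth.ko_expected_category[ko] = "Multiple"
        else:
            cat = PATHWAY_CATEGORIES[int(rng.integers(0, len(PATHWAY_CATEGORIES)))]
            n_pw = int(rng.integers(1, 3))
            chosen = set(
                rng.choice(pathways_by_cat[cat], size=n_pw, replace=False).tolist()
            )
            ko2pathways[ko] = chosen
            truth.ko_expected_category[ko] = cat
    return KOMap(gene2ko, ko2pathways, pathway2category)


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        mapping.setdefault(aa, []).append(codon)
    return mapping


def back_translate(protein: str, rng: np.random.Generator, codons: dict[str, list[str]]) -> str:
    """Uniform synonymous-codon choice per residue (X becomes NNN)."""
    parts = []
    for aa in protein:
        options = codons.get(aa)
        if options is None:
            parts.append("NNN")
        else:
            parts.append(options[int(rng.integers(0, len(options)))])
    return "".join(parts)


def simulate_scaffolds(
    config: SimulationConfig,
    truth: GroundTruth,
    proteomes: dict[str, list[ProteinRecord]],
) -> dict[str, ScaffoldSet]:
    """Fragmented nucleotide scaffolds with planted motifs and partial linkage.

    Genes are back-translated, concatenated with random spacers and cut
    into scaffolds of roughly ``scaffold_mean_length``; the RnpB motif is
    planted at recorded positions (both strands); the linkage table chains
    a ``linkage_completeness`` fraction of each genome's scaffolds.
    """
    rng = _streams(config.seed)["scaffolds"]
    codons = _codon_map()
    lo, hi = config.spacer_length_range
    out: dict[str, ScaffoldSet] = {}
    for genome in config.genome_ids:
        records = proteomes[genome]
        scaffolds: dict[str, str] = {}
        coding: dict[str, int] = {}
        pieces: list[str] = []
        genes_here = 0
        current_len = 0

        def close(final: bool = False) -> None:
            nonlocal pieces, genes_here, current_len
            if not pieces:
                return
            sid = f"{genome}|scaf{len(scaffolds) + 1:03d}"
            scaffolds[sid] = "".join(pieces)
            coding[sid] = genes_here
            pieces = []
            genes_here = 0
            current_len = 0

        for rec in records:
            spacer_len = int(rng.integers(lo, hi + 1))
            spacer = "".join("ACGT"[c] for c in rng.integers(0, 4, spacer_len))
            pieces.append(spacer)
            pieces.append(back_translate(rec.sequence, rng, codons))
            genes_here += 1
            current_len += spacer_len + 3 * len(rec.sequence)
            if current_len >= config.scaffold_mean_length:
                close()
        close(final=True)
        # plant RnpB motifs, inserting within each scaffold in descending
        # position order so recorded coordinates stay valid
        truth.motif_positions[genome] = []
        sids = sorted(scaffolds)
        n_insert = min(config.n_motifs_per_genome, len(sids))
        chosen = rng.choice(len(sids), size=n_insert, replace=False) if n_insert else []
        plans: dict[str, list[tuple[int, str]]] = {}
        for idx in sorted(int(i) for i in chosen):
            sid = sids[idx]
            pos = int(rng.integers(0, len(scaffolds[sid]) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            plans.setdefault(sid, []).append((pos, strand))
        for sid, inserts in plans.items():
            seq = scaffolds[sid]
            for pos, strand in sorted(inserts, reverse=True):
                motif = RNPB_MOTIF if strand == "+" else reverse_complement(RNPB_MOTIF)
                seq = seq[:pos] + motif + seq[pos:]
            scaffolds[sid] = seq
            offset = 0
            for pos, strand in sorted(inserts):
                truth.motif_positions[genome].append((sid, pos + offset + 1, strand))
                offset += len(RNPB_MOTIF)
        n = len(sids)
        k = int(round(config.linkage_completeness * n))
        linkage = {(sids[i], sids[i + 1]) for i in range(max(0, k - 1))}
        out[genome] = ScaffoldSet(sequences=scaffolds, linkage=linkage, coding_count=coding)
    return out


def simulate_16s_survey(
    config: SimulationConfig,
) -> tuple[list[SimilarityHit], dict[str, int], dict[str, str], GroundTruth | dict]:
    """Read-vs-reference 16S hit rows plus sample totals and type map.

    Target reads carry identities drawn uniformly in [97, 100]; an extra
    ``survey_decoy_fraction`` of near-miss reads sits below 97% identity
    and must be removed by the identity filter.  Returns (hits, totals,
    types, true_counts) with true_counts the planted >= 97% read count per
    sample.
    """
    rng = _streams(config.seed)["survey"]
    hits: list[SimilarityHit] = []
    totals: dict[str, int] = {}
    types: dict[str, str] = {}
    true_counts: dict[str, int] = {}
    for sample_type in sorted(config.survey):
        params = config.survey[sample_type]
        for i in range(params.n_samples):
            sample = f"{sample_type}.s{i:02d}"
            total = int(rng.integers(5000, 15001))
            if params.median_pct <= 0:
                pct = 0.0
            else:
                pct = 10 ** (math.log10(params.median_pct) + rng.normal(0.0, params.sigma_log10))
            p = min(1.0, pct / 100.0)
            target = int(rng.binomial(total, p))
            n_decoy = int(rng.binomial(target, config.survey_decoy_fraction)) if target else 0
            target = min(target, total)
            totals[sample] = total
            types[sample] = sample_type
            true_counts[sample] = target
            read_no = 0
            for _ in range(target):
                pident = float(rng.uniform(97.0, 100.0))
                hits.append(_survey_hit(sample, read_no, pident))
                read_no += 1
            for _ in range(n_decoy):
                pident = float(rng.uniform(90.0, 96.9))
                hits.append(_survey_hit(sample, read_no, pident))
                read_no += 1
    return hits, totals, types, true_counts


def _survey_hit(sample: str, read_no: int, pident: float) -> SimilarityHit:
    length = 250
    mismatch = int(round(length * (100.0 - pident) / 100.0))
    return SimilarityHit(
        query_id=f"{sample}|r{read_no:05d}",
        subject_id="MEL_16S_ref",
        pident=round(pident, 1),
        length=length,
        mismatch=mismatch,
        gapopen=0,
        qstart=1,
        qend=length,
        sstart=1,
        send=length,
        evalue=1e-100,
        bitscore=round(2.0 * (length - mismatch), 1),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "families": truth.families,
        "family_of": truth.family_of,
        "nearest_phylum": truth.nearest_phylum,
        "family_ko": truth.family_ko,
        "ko_expected_category": truth.ko_expected_category,
        "motif_positions": truth.motif_positions,
        "survey_true_counts": truth.survey_true_counts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_simulation(
    out_dir: str | Path,
    config: SimulationConfig,
    proteomes: dict[str, list[ProteinRecord]],
    truth: GroundTruth,
    references: list[ProteinRecord],
    taxonomy: dict[str, str],
    komap: KOMap,
    scaffolds: dict[str, ScaffoldSet],
    survey_hits: list[SimilarityHit],
    survey_totals: dict[str, int],
    survey_types: dict[str, str],
) -> None:
    """Write every simulated input in its standard on-disk format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for genome in config.genome_ids:
        write_fasta(proteomes[genome], out / f"{genome}.faa")
        scafs = scaffolds[genome]
        nt_records = [
            ProteinRecord(sid, genome, seq) for sid, seq in sorted(scafs.sequences.items())
        ]
        write_fasta(nt_records, out / f"{genome}.fna")
        with open(out / f"{genome}.links.tsv", "w") as fh:
            for a, b in sorted(scafs.linkage):
                fh.write(f"{a}\t{b}\n")
    write_fasta(references, out / "reference.faa")
    write_taxonomy_map(taxonomy, out / "taxonomy.tsv")
    write_ko_map(komap, out / "ko_map")
    write_hit_table(survey_hits, out / "survey_hits.tsv")
    with open(out / "survey_totals.tsv", "w") as fh:
        for sample in sorted(survey_totals):
            fh.write(f"{sample}\t{survey_totals[sample]}\n")
    with open(out / "survey_types.tsv", "w") as fh:
        for sample in sorted(survey_types):
            fh.write(f"{sample}\t{survey_types[sample]}\n")
    write_ground_truth(truth, out / "ground_truth.json")
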