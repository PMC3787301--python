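"""End-to-end pipeline on simulated inputs, with evaluation against the
planted truth.

Stages: simulate -> all-vs-all pairwise proteome search -> reciprocal-best-
hit graph -> ortholog clusters -> per-gene and per-cluster phylum voting ->
KO / pathway-category assignment -> per-genome marker inventory, status and
assembly statistics -> RnpB motif scan -> 16S survey tallying and the
foregut-vs-hindgut comparison.

All outputs (when an output directory is given) are written with stable
ordering and formatting, so identical seeds give byte-identical trees.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic_data as sd
from .abundance_survey import compare_two_groups, filter_hits, group_filter, tally
from .genome_assessment import GenomeStatusReport, assembly_stats, assess_genome
from .kegg_assignment import FunctionAssignment, KOMap, assign_cluster_function, functional_summary
from .marker_scan import find_rnpb_loci
from .ortholog_clustering import COGCluster, build_rbh_graph, form_clusters, write_clusters
from .sequence_io import ProteinRecord, SimilarityHit, write_hit_table
from .similarity_search import DEFAULT_SCHEME, ScoringScheme, search, search_pair_bidirectional
from .taxon_voting import (
    GeneTaxonAssignment,
    VotingConfig,
    assign_cog_phylum,
    assign_gene_phylum,
    summarize_phylum_fractions,
)


@dataclass
class PipelineResult:
    config: sd.SimulationConfig
    truth: sd.GroundTruth
    proteomes: dict[str, list[ProteinRecord]]
    clusters: list[COGCluster]
    gene_assignments: dict[str, GeneTaxonAssignment]
    cog_labels: dict[str, str]
    phylum_fractions: pd.DataFrame
    functions: list[FunctionAssignment]
    status_reports: dict[str, GenomeStatusReport]
    assembly: dict[str, dict]
    rnpb_matches: dict[str, list]
    survey_table: pd.DataFrame
    survey_test: dict[str, float] | None
    metrics: dict[str, float] = field(default_factory=dict)


def evaluate_clusters(
    clusters: list[COGCluster], truth: sd.GroundTruth, genome_ids: list[str]
) -> dict[str, float]:
    """Precision/recall of recovered clusters against planted families.

    A cluster is correct when all its members belong to one planted family;
    a family is recovered when some correct cluster covers it.  Families
    with a member in every genome are the recoverable universe.
    """
    family_of = truth.family_of
    correct_families = set()
    n_correct = 0
    for cl in clusters:
        fams = {family_of.get(pid) for pid in cl.members.values()}
        if len(fams) == 1 and None not in fams:
            n_correct += 1
            correct_families.add(fams.pop())
    expected = {
        fam
        for fam, per_genome in truth.families.items()
        if all(per_genome.get(g) for g in genome_ids)
    }
    precision = n_correct / len(clusters) if clusters else 0.0
    recall = len(correct_families & expected) / len(expected) if expected else 1.0
    return {
        "cluster_precision": precision,
        "cluster_recall": recall,
        "n_clusters": float(len(clusters)),
        "n_expected_families": float(len(expected)),
    }


def evaluate_gene_phyla(
    gene_assignments: dict[str, GeneTaxonAssignment], truth: sd.GroundTruth
) -> dict[str, float]:
    """Accuracy of per-gene labels against the planted nearest phylum.

    Genes of families with a planted phylum must recover that phylum; genes
    of families without a reference must come out "No hit"."""
    n_phylum = correct_phylum = 0
    n_nohit = correct_nohit = 0
    for gene_id, assignment in gene_assignments.items():
        fam = truth.family_of.get(gene_id)
        if fam is None:
            continue
        planted = truth.nearest_phylum.get(fam)
        if planted is None:
            n_nohit += 1
            correct_nohit += assignment.label == "No hit"
        else:
            n_phylum += 1
            correct_phylum += assignment.label == planted
    return {
        "gene_phylum_accuracy": correct_phylum / n_phylum if n_phylum else 1.0,
        "gene_nohit_accuracy": correct_nohit / n_nohit if n_nohit else 1.0,
        "n_genes_with_planted_phylum": float(n_phylum),
    }


def run_pipeline(
    config: sd.SimulationConfig,
    out_dir: str | Path | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_evalue: float = 1e-5,
    voting: VotingConfig | None = None,
) -> PipelineResult:
    voting = voting or VotingConfig()
    genome_ids = config.genome_ids

    proteomes, truth = sd.simulate_proteomes(config)
    references, taxonomy, komap = sd.simulate_reference_db(config, truth)
    scaffolds = sd.simulate_scaffolds(config, truth, proteomes)
    survey_hits, survey_totals, survey_types, true_counts = sd.simulate_16s_survey(config)
    truth.survey_true_counts = true_counts

    # --- ortholog clustering over all unordered genome pairs
    hit_tables: dict[tuple[str, str], list[SimilarityHit]] = {}
    for ga, gb in itertools.combinations(genome_ids, 2):
        ab, ba = search_pair_bidirectional(
            proteomes[ga], proteomes[gb], scheme, max_evalue
        )
        hit_tables[(ga, gb)] = ab
        hit_tables[(gb, ga)] = ba
    genomes_map = {g: [r.id for r in proteomes[g]] for g in genome_ids}
    graph = build_rbh_graph(genomes_map, hit_tables)
    clusters = form_clusters(graph, n_genomes=config.n_genomes)

    # --- per-gene phylum voting for every clustered gene
    records_by_id = {r.id: r for recs in proteomes.values() for r in recs}
    member_records = [
        records_by_id[pid] for cl in clusters for pid in cl.members.values()
    ]
    gene_assignments: dict[str, GeneTaxonAssignment] = {}
    ref_hits_by_query: dict[str, list[SimilarityHit]] = {r.id: [] for r in member_records}
    if references:
        for hit in search(member_records, references, scheme, max_evalue):
            ref_hits_by_query[hit.query_id].append(hit)
    for rec in member_records:
        gene_assignments[rec.id] = assign_gene_phylum(
            rec.id, ref_hits_by_query[rec.id], taxonomy, voting
        )
    cog_labels = {
        cl.cluster_id: assign_cog_phylum(
            [gene_assignments[pid].label for _, pid in sorted(cl.members.items())], voting
        )
        for cl in clusters
    }
    phylum_fractions = (
        summarize_phylum_fractions(list(cog_labels.values())) if cog_labels else pd.DataFrame()
    )

    # --- KO / category assignment from the first genome's representative;
    # the KO-labelled reference is the gene2ko-covered subset, so the
    # representative's reference hits are reused
    functions: list[FunctionAssignment] = []
    for cl in clusters:
        rep = cl.members[genome_ids[0]]
        ko_hits = [
            h for h in ref_hits_by_query.get(rep, []) if h.subject_id in komap.gene2ko
        ]
        functions.append(
            assign_cluster_function(cl.cluster_id, ko_hits, komap, max_evalue)
        )

    # --- genome assessment and motif scan
    status_reports = {}
    assembly = {}
    rnpb_matches = {}
    for genome in genome_ids:
        status_reports[genome] = assess_genome(
            genome, proteomes[genome], scaffolds[genome], scheme=scheme, max_evalue=max_evalue
        )
        assembly[genome] = assembly_stats(scaffolds[genome])
        rnpb_matches[genome] = find_rnpb_loci(scaffolds[genome].sequences)

    # --- 16S survey
    assignments = filter_hits(survey_hits)
    tallies = tally(assignments, survey_totals, survey_types)
    survey_table = group_filter(tallies)
    survey_test = None
    fg = survey_table[survey_table.sample_type == "feces_foregut"].log10_pct.tolist()
    hg = survey_table[survey_table.sample_type == "feces_hindgut"].log10_pct.tolist()
    if len(fg) >= 2 and len(hg) >= 2:
        survey_test = compare_two_groups(fg, hg)

    # --- evaluation against planted truth
    metrics = {}
    metrics.update(evaluate_clusters(clusters, truth, genome_ids))
    metrics.update(evaluate_gene_phyla(gene_assignments, truth))
    n_labelled = sum(1 for lab in cog_labels.values() if lab not in ("No hit", "Multiple"))
    correct_cogs = 0
    for cl in clusters:
        fams = {truth.family_of.get(pid) for pid in cl.members.values()}
        if len(fams) != 1:
            continue
        fam = fams.pop()
        planted = truth.nearest_phylum.get(fam) if fam else None
        if planted and cog_labels[cl.cluster_id] == planted:
            correct_cogs += 1
    n_planted_cogs = sum(
        1
        for cl in clusters
        if len({truth.family_of.get(p) for p in cl.members.values()}) == 1
        and truth.nearest_phylum.get(next(iter({truth.family_of.get(p) for p in cl.members.values()})))
    )
    metrics["cog_phylum_accuracy"] = (
        correct_cogs / n_planted_cogs if n_planted_cogs else 1.0
    )
    ko_correct = ko_total = 0
    fun_by_id = {f.cluster_id: f for f in functions}
    for cl in clusters:
        fams = {truth.family_of.get(pid) for pid in cl.members.values()}
        if len(fams) != 1:
            continue
        fam = fams.pop()
        if fam is None:
            continue
        planted_ko = truth.family_ko.get(fam)
        fun = fun_by_id[cl.cluster_id]
        ko_total += 1
        if planted_ko is None:
            ko_correct += fun.ko is None
        else:
            expected_cat = truth.ko_expected_category[planted_ko]
            ko_correct += fun.ko == planted_ko and fun.category == expected_cat
    metrics["ko_assignment_accuracy"] = ko_correct / ko_total if ko_total else 1.0
    planted = [
        (g, sid, start, strand)
        for g, entries in truth.motif_positions.items()
        for sid, start, strand in entries
    ]
    recovered = {
        (g, m.scaffold_id, m.start, m.strand)
        for g, matches in rnpb_matches.items()
        for m in matches
    }
    metrics["motif_recovery"] = (
        sum(1 for p in planted if p in recovered) / len(planted) if planted else 1.0
    )
    if config.marker_insertion and config.linkage_completeness >= 1.0:
        metrics["fraction_genomes_complete"] = sum(
            r.status == "Complete" for r in status_reports.values()
        ) / len(status_reports)
    if survey_test:
        metrics["survey_t_statistic"] = survey_test["t_statistic"]
        metrics["survey_p_two_tailed"] = survey_test["p_two_tailed"]

    result = PipelineResult(
        config=config,
        truth=truth,
        proteomes=proteomes,
        clusters=clusters,
        gene_assignments=gene_assignments,
        cog_labels=cog_labels,
        phylum_fractions=phylum_fractions,
        functions=functions,
        status_reports=status_reports,
        assembly=assembly,
        rnpb_matches=rnpb_matches,
        survey_table=survey_table,
        survey_test=survey_test,
        metrics=metrics,
    )
    if out_dir is not None:
        _write_outputs(
            Path(out_dir),
            result,
            references,
            taxonomy,
            komap,
            scaffolds,
            survey_hits,
            survey_totals,
            survey_types,
            hit_tables,
        )
    return result


def _write_outputs(
    out: Path,
    result: PipelineResult,
    references,
    taxonomy,
    komap: KOMap,
    scaffolds,
    survey_hits,
    survey_totals,
    survey_types,
    hit_tables,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sd.write_simulation(
        out / "inputs",
        result.config,
        result.proteomes,
        result.truth,
        references,
        taxonomy,
        komap,
        scaffolds,
        survey_hits,
        survey_totals,
        survey_types,
    )
    hits_dir = out / "hits"
    hits_dir.mkdir(exist_ok=True)
    for (ga, gb), hits in sorted(hit_tables.items()):
        write_hit_table(hits, hits_dir / f"{ga}_vs_{gb}.tsv")
    genome_order = result.config.genome_ids
    write_clusters(result.clusters, genome_order, out / "cogs.tsv")
    with open(out / "cog_taxa.tsv", "w") as fh:
        fh.write("cluster_id\t" + "\t".join(genome_order) + "\tlabel\n")
        for cl in result.clusters:
            per_gene = [
                result.gene_assignments[cl.members[g]].label for g in genome_order
            ]
            fh.write(
                f"{cl.cluster_id}\t" + "\t".join(per_gene) + f"\t{result.cog_labels[cl.cluster_id]}\n"
            )
    with open(out / "cog_functions.tsv", "w") as fh:
        fh.write("cluster_id\tko\tcategory\n")
        for fun in result.functions:
            fh.write(f"{fun.cluster_id}\t{fun.ko or '-'}\t{fun.category}\n")
    with open(out / "genome_status.tsv", "w") as fh:
        fh.write("genome\tstatus\tlinked_fraction\tsize_bp\tpct_gc\tn_scaffolds\tn50\tcoding_features\tmissing_markers\n")
        for genome in genome_order:
            rep = result.status_reports[genome]
            stats = result.assembly[genome]
            missing = ",".join(
                sorted(m for m, c in rep.copy_number.items() if c == 0)
            ) or "-"
            fh.write(
                f"{genome}\t{rep.status}\t{rep.linked_fraction:.4f}\t{stats['size_bp']}\t"
                f"{stats['pct_gc']:.1f}\t{stats['n_scaffolds']}\t{stats['n50']}\t"
                f"{stats['coding_features']}\t{missing}\n"
            )
    with open(out / "rnpb.tsv", "w") as fh:
        fh.write("genome\tscaffold\tstart\tend\tstrand\n")
        for genome in genome_order:
            for m in result.rnpb_matches[genome]:
                fh.write(f"{genome}\t{m.scaffold_id}\t{m.start}\t{m.end}\t{m.strand}\n")
    result.survey_table.to_csv(out / "survey.tsv", sep="\t", index=False, float_format="%.6f")
    with open(out / "metrics.json", "w") as fh:
        json.dump(
            {k: round(v, 10) for k, v in sorted(result.metrics.items())}, fh, indent=1
        )
        fh.write("\n")
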