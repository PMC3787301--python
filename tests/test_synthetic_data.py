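import filecmp
import itertools

import numpy as np
import pytest

from melacog.genome_assessment import BACKGROUND_FREQS
from melacog.marker_scan import RNPB_MOTIF, find_rnpb_loci, reverse_complement
from melacog.sequence_io import read_fasta
from melacog.synthetic_data import (
    SimulationConfig,
    mutate,
    simulate_16s_survey,
    simulate_proteomes,
    simulate_reference_db,
    simulate_scaffolds,
    write_simulation,
)


def small_config(**kwargs):
    defaults = dict(
        seed=7,
        n_families=30,
        protein_length_mean=120,
        protein_length_sd=20,
        scaffold_mean_length=10_000,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def identity(a, b):
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestSimulateProteomes:
    def test_zero_divergence_copies_identical(self):
        proteomes, truth = simulate_proteomes(small_config(divergence=0.0))
        by_id = {r.id: r.sequence for recs in proteomes.values() for r in recs}
        for fam, per_genome in truth.families.items():
            seqs = {by_id[pid] for ids in per_genome.values() for pid in ids}
            assert len(seqs) == 1

    def test_total_loss_leaves_only_markers(self):
        proteomes, _ = simulate_proteomes(small_config(p_loss=1.0))
        for genome, recs in proteomes.items():
            assert len(recs) == 16
            assert all("MK_" in r.id for r in recs)

    def test_duplication_adds_paralogs(self):
        proteomes, truth = simulate_proteomes(small_config(p_dup=1.0))
        fams = [f for f in truth.families if f.startswith("F")]
        for fam in fams:
            for members in truth.families[fam].values():
                assert len(members) == 2

    def test_identity_to_ancestor_matches_expectation(self):
        """Per-site substitution at rate d leaves each copy at expected
        identity (1-d) + d*sum(f^2) to the ancestor — within 2 points of
        100*(1-d) at moderate divergence."""
        d = 0.05
        config = SimulationConfig(seed=3, n_families=200, divergence=d, marker_insertion=False)
        proteomes, truth = simulate_proteomes(config)
        by_id = {r.id: r.sequence for recs in proteomes.values() for r in recs}
        idents = [
            identity(by_id[pid], truth.ancestral[fam])
            for fam, per_genome in truth.families.items()
            for ids in per_genome.values()
            for pid in ids
        ]
        mean_pct = 100 * np.mean(idents)
        assert mean_pct == pytest.approx(100 * (1 - d), abs=2.0)
        f2 = float(np.sum(BACKGROUND_FREQS**2))
        expected = 100 * ((1 - d) + d * f2)
        assert mean_pct == pytest.approx(expected, abs=0.5)

    def test_copy_copy_identity_matches_exact_closed_form(self):
        d = 0.05
        config = SimulationConfig(seed=3, n_families=200, divergence=d, marker_insertion=False)
        proteomes, truth = simulate_proteomes(config)
        by_id = {r.id: r.sequence for recs in proteomes.values() for r in recs}
        idents = []
        for fam, per_genome in truth.families.items():
            ids = [pid for members in per_genome.values() for pid in members]
            for a, b in itertools.combinations(ids, 2):
                idents.append(identity(by_id[a], by_id[b]))
        f2 = float(np.sum(BACKGROUND_FREQS**2))
        expected = (1 - d) ** 2 + 2 * d * (1 - d) * f2 + d**2 * f2
        assert np.mean(idents) == pytest.approx(expected, abs=0.005)

    def test_mutate_rate_zero_is_identity(self, rng):
        assert mutate("MKVLA", 0.0, rng) == "MKVLA"


class TestSimulateReference:
    def test_nearest_reference_carries_planted_phylum(self):
        config = small_config()
        proteomes, truth = simulate_proteomes(config)
        references, taxonomy, _ = simulate_reference_db(config, truth)
        ref_by_fam = {}
        for rec in references:
            ref_by_fam.setdefault(rec.id.split("|")[1], []).append(rec)
        for fam, phylum in truth.nearest_phylum.items():
            if phylum is None:
                assert fam not in ref_by_fam
                continue
            best = max(
                ref_by_fam[fam], key=lambda r: identity(r.sequence, truth.ancestral[fam])
            )
            assert taxonomy[best.id] == phylum

    def test_phylum_fractions_respected(self):
        config = small_config(n_families=100)
        proteomes, truth = simulate_proteomes(config)
        simulate_reference_db(config, truth)
        planted = [p for f, p in truth.nearest_phylum.items() if f.startswith("F")]
        for phylum, fraction in config.phylum_fractions.items():
            assert planted.count(phylum) == round(fraction * 100)

    def test_ko_catalog_consistent_with_expected_categories(self):
        config = small_config()
        proteomes, truth = simulate_proteomes(config)
        _, _, komap = simulate_reference_db(config, truth)
        from melacog.kegg_assignment import categorize_ko

        for ko, expected in truth.ko_expected_category.items():
            assert categorize_ko(ko, komap) == expected


class TestSimulateScaffolds:
    def test_planted_motifs_all_recovered(self):
        config = small_config()
        proteomes, truth = simulate_proteomes(config)
        scaffolds = simulate_scaffolds(config, truth, proteomes)
        for genome, planted in truth.motif_positions.items():
            found = {
                (m.scaffold_id, m.start, m.strand)
                for m in find_rnpb_loci(scaffolds[genome].sequences)
            }
            assert set(planted) <= found

    def test_motif_sequence_at_recorded_position(self):
        config = small_config()
        proteomes, truth = simulate_proteomes(config)
        scaffolds = simulate_scaffolds(config, truth, proteomes)
        for genome, planted in truth.motif_positions.items():
            for sid, start, strand in planted:
                segment = scaffolds[genome].sequences[sid][start - 1 : start + 10]
                expected = RNPB_MOTIF if strand == "+" else reverse_complement(RNPB_MOTIF)
                assert segment == expected

    def test_full_linkage_chains_all_scaffolds(self):
        config = small_config(linkage_completeness=1.0)
        proteomes, truth = simulate_proteomes(config)
        scaffolds = simulate_scaffolds(config, truth, proteomes)
        for genome, scafs in scaffolds.items():
            assert len(scafs.linkage) == len(scafs.sequences) - 1

    def test_coding_counts_cover_proteome(self):
        config = small_config()
        proteomes, truth = simulate_proteomes(config)
        scaffolds = simulate_scaffolds(config, truth, proteomes)
        for genome in config.genome_ids:
            assert sum(scaffolds[genome].coding_count.values()) == len(proteomes[genome])


class TestSimulateSurvey:
    def test_zero_decoys_tally_equals_planted(self):
        from melacog.abundance_survey import filter_hits, tally

        config = small_config(survey_decoy_fraction=0.0)
        hits, totals, types, true_counts = simulate_16s_survey(config)
        tallies = tally(filter_hits(hits), totals, types)
        for t in tallies:
            assert t.target_reads == true_counts[t.sample_id]

    def test_decoys_are_removed_by_identity_filter(self):
        from melacog.abundance_survey import filter_hits

        config = small_config(survey_decoy_fraction=0.3)
        hits, totals, types, true_counts = simulate_16s_survey(config)
        retained = filter_hits(hits)
        by_sample = {}
        for read_id in retained:
            sample = read_id.split("|")[0]
            by_sample[sample] = by_sample.get(sample, 0) + 1
        for sample, count in by_sample.items():
            assert count == true_counts[sample]

    def test_type_median_recovered_within_tolerance(self):
        from melacog.synthetic_data import SurveyTypeConfig

        config = small_config()
        config.survey = {
            "feces": SurveyTypeConfig(0.5, n_samples=50),
            "water": SurveyTypeConfig(1.0, n_samples=50),
        }
        hits, totals, types, true_counts = simulate_16s_survey(config)
        for stype, params in config.survey.items():
            pcts = [
                100 * true_counts[s] / totals[s]
                for s in totals
                if types[s] == stype
            ]
            assert np.median(pcts) == pytest.approx(params.median_pct, rel=0.25)


class TestDeterminism:
    def _write(self, config, out):
        proteomes, truth = simulate_proteomes(config)
        references, taxonomy, komap = simulate_reference_db(config, truth)
        scaffolds = simulate_scaffolds(config, truth, proteomes)
        hits, totals, types, true_counts = simulate_16s_survey(config)
        truth.survey_true_counts = true_counts
        write_simulation(
            out, config, proteomes, truth, references, taxonomy, komap,
            scaffolds, hits, totals, types,
        )

    def test_same_seed_byte_identical(self, tmp_path):
        self._write(small_config(), tmp_path / "a")
        self._write(small_config(), tmp_path / "b")
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert not cmp.diff_files and not cmp.left_only and not cmp.right_only
        sub = filecmp.dircmp(tmp_path / "a" / "ko_map", tmp_path / "b" / "ko_map")
        assert not sub.diff_files

    def test_different_seed_differs(self, tmp_path):
        self._write(small_config(seed=7), tmp_path / "a")
        self._write(small_config(seed=8), tmp_path / "b")
        a = (tmp_path / "a" / "G1.faa").read_text()
        b = (tmp_path / "b" / "G1.faa").read_text()
        assert a != b

    def test_emitted_files_parse_cleanly(self, tmp_path):
        self._write(small_config(), tmp_path / "a")
        for genome in ("G1", "G2", "G3", "G4"):
            assert read_fasta(tmp_path / "a" / f"{genome}.faa")
            assert read_fasta(tmp_path / "a" / f"{genome}.fna", moltype="dna")
        assert read_fasta(tmp_path / "a" / "reference.faa")
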