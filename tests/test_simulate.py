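import math
from collections import Counter

import pytest

from olsp.demux import demultiplex, dereplicate
from olsp.design import validate_tagset
from olsp.simulate import (
    CENSUS,
    MOCK_PANEL,
    PRIMERS,
    SimConfig,
    generate_design,
    generate_reference,
    generate_tags,
    simulate_run,
    small_config,
)

import numpy as np


class TestGenerateReference:
    def test_fixed_seed_is_reproducible(self):
        a = generate_reference(SimConfig(seed=5))
        b = generate_reference(SimConfig(seed=5))
        assert [t.template for t in a] == [t.template for t in b]

    def test_record_count(self):
        taxa = generate_reference(SimConfig(seed=1, n_taxa=10))
        assert len(taxa) == len(MOCK_PANEL) + 10

    def test_planted_dropout_blocks_amplification(self):
        taxa = generate_reference(SimConfig(seed=2))
        dropped = [(t, m) for t in taxa for m in PRIMERS if t.amplicons[m] is None]
        assert dropped, "some (taxon, marker) pairs should be dropouts"
        # every mock-panel taxon keeps at least one marker
        mock_species = {sp for sp, *_ in MOCK_PANEL}
        for t in taxa:
            if t.species in mock_species:
                assert any(t.amplicons[m] is not None for m in PRIMERS)

    def test_predator_amplifies_with_all_markers(self):
        taxa = generate_reference(SimConfig(seed=3))
        predator = next(t for t in taxa if t.species == "Zingel asper")
        assert all(predator.amplicons[m] is not None for m in PRIMERS)

    def test_amplicon_windows_overlap_across_markers(self):
        taxa = generate_reference(SimConfig(seed=4, n_taxa=5))
        full = next(t for t in taxa if all(t.amplicons.values()))
        for m, amp in full.amplicons.items():
            assert amp in full.template


class TestGenerateDesign:
    def test_nine_pcrs_per_sample(self):
        designs, _, _ = generate_design(SimConfig(seed=1, n_edna_samples=4))
        rd = next(iter(designs.values()))
        for sample in rd.samples:
            pcrs = [p for p in rd.pcrs() if p[0] == sample]
            assert len(pcrs) == 9  # 3 markers x 3 replicates

    def test_census_totals(self):
        assert sum(n for _, n, _ in CENSUS) == 107

    def test_tagsets_pass_validation(self):
        designs, tags_fwd, tags_rev = generate_design(SimConfig(seed=2, n_edna_samples=4))
        assert len(tags_fwd) == 12 and len(tags_rev) == 8
        assert validate_tagset(tags_fwd)[1]
        assert validate_tagset(tags_rev)[1]

    def test_generated_tags_meet_mismatch_floor(self):
        rng = np.random.default_rng(7)
        tags = generate_tags(rng, 12)
        min_mm, ok = validate_tagset(tags)
        assert ok and min_mm >= 3
        assert all(11 <= len(t) <= 13 for t in tags)

    def test_every_run_has_mocks_and_four_negative_kinds(self):
        designs, _, _ = generate_design(SimConfig(seed=3, n_edna_samples=30, samples_per_run=12))
        assert len(designs) > 1
        for rd in designs.values():
            categories = Counter(rec.category for rec in rd.samples.values())
            assert categories["mock"] == 2
            for kind in ("neg_extraction", "neg_aerosol", "neg_pcr", "neg_tag"):
                assert categories[kind] == 1

    def test_fixed_seed_identical_design(self):
        d1, _, _ = generate_design(SimConfig(seed=4, n_edna_samples=6))
        d2, _, _ = generate_design(SimConfig(seed=4, n_edna_samples=6))
        assert {r: d.tag_map for r, d in d1.items()} == {r: d.tag_map for r, d in d2.items()}


class TestSimulateReads:
    def test_byte_identical_with_fixed_seed(self):
        a = simulate_run(small_config(seed=6))
        b = simulate_run(small_config(seed=6))
        assert a.reads == b.reads

    def test_noiseless_recovers_exact_composition(self):
        run = simulate_run(
            small_config(seed=8, sub_rate=0.0, tag_switch_rate=0.0,
                         neg_contam_mean=0.0, contaminant_rate=0.0,
                         n_edna_samples=2, reads_per_pcr=50)
        )
        by_species = {t.species: t for t in run.reference}
        for run_id, reads in run.reads.items():
            per_pcr, stats, _ = demultiplex(reads, run.designs[run_id])
            assert stats.unassigned_reads == 0
            table, discarded = dereplicate(per_pcr)
            assert discarded == 0
            observed = {}
            for row in table.df.itertuples():
                seq = table.variants[row.variant].seq
                marker = table.variants[row.variant].marker
                observed[(row.sample, marker, row.replicate, seq)] = row.count
            expected = {}
            for (rid, sample, marker, rep), comp in run.truth.per_pcr_composition.items():
                if rid != run_id:
                    continue
                for sp, n in comp.items():
                    seq = by_species[sp].amplicons[marker]
                    expected[(sample, marker, rep, seq)] = (
                        expected.get((sample, marker, rep, seq), 0) + n
                    )
            assert observed == expected

    def test_mock_reads_follow_concentrations(self):
        run = simulate_run(small_config(seed=9, n_edna_samples=0, reads_per_pcr=2000,
                                        sub_rate=0.0, tag_switch_rate=0.0))
        conc = {sp: c for sp, c, *_ in MOCK_PANEL}
        for (rid, sample, marker, rep), comp in run.truth.per_pcr_composition.items():
            if not sample.startswith("Tpos"):
                continue
            total = sum(comp.values())
            if total == 0:
                continue
            weights = sum(conc[sp] for sp in comp)
            for sp, n in comp.items():
                expect = conc[sp] / weights
                assert abs(n / total - expect) < 5 * math.sqrt(expect * (1 - expect) / total)

    def test_tag_switch_rate_binomial(self):
        rate = 0.01
        run = simulate_run(
            small_config(seed=10, tag_switch_rate=rate, sub_rate=0.0,
                         n_edna_samples=4, reads_per_pcr=250)
        )
        prov = run.truth.provenance["run01"]
        n = len(prov)
        assert n > 10000
        switched = sum(1 for *_x, sw in prov.values() if sw)
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(switched - n * rate) < 3 * sd

    def test_switched_reads_explain_all_misassignments(self):
        run = simulate_run(
            small_config(seed=13, tag_switch_rate=0.02, sub_rate=0.0,
                         n_edna_samples=2, reads_per_pcr=80)
        )
        prov = run.truth.provenance["run01"]
        per_pcr, _, _ = demultiplex(run.reads["run01"], run.designs["run01"])
        # reconstruct assignment per read is not tracked; instead verify
        # aggregate: non-switched read counts match truth exactly
        expected = Counter()
        for (sample, marker, rep, _sp, switched) in prov.values():
            if not switched:
                expected[(sample, marker, rep)] += 1
        observed_min = Counter()
        for key, counter in per_pcr.items():
            observed_min[key] = sum(counter.values())
        for key, n_true in expected.items():
            assert observed_min.get(key, 0) >= n_true  # switched reads only add

    def test_negatives_carry_only_contamination(self):
        run = simulate_run(small_config(seed=14, neg_contam_mean=3.0))
        for (rid, sample, marker, rep), comp in run.truth.per_pcr_composition.items():
            if "neg" in sample:
                assert sum(comp.values()) <= 25  # Poisson(3) tail

    def test_written_outputs_are_deterministic(self, tmp_path):
        cfg = small_config(seed=15, n_edna_samples=2, reads_per_pcr=30)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_run(cfg).write(d1)
        simulate_run(cfg).write(d2)
        for name in ("design.tsv", "reference.fasta", "taxonomy.tsv",
                     "habitat.tsv", "reads_run01.fastq", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
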