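"""Generator properties: composition, divergence, determinism, coverage
signatures of the packaging models, and truth bookkeeping."""

import math

import numpy as np
import pytest

import phage_profiler as pp
from phage_profiler.synthetic import write_fastq, write_read_truth


class TestGenerateGenome:
    def test_length_is_exact(self):
        assert len(pp.generate_genome(10000, 0.5, 1)) == 10000

    def test_degenerate_gc_composition(self):
        assert set(pp.generate_genome(10000, 1.0, 1)) == {"G", "C"}
        assert set(pp.generate_genome(10000, 0.0, 1)) <= {"A", "T"}

    def test_gc_fraction_within_binomial_bound(self):
        n, gc = 50000, 0.72
        seq = pp.generate_genome(n, gc, 3)
        observed = (seq.count("G") + seq.count("C")) / n
        assert abs(observed - gc) <= 3 * math.sqrt(gc * (1 - gc) / n)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pp.generate_genome(0, 0.5, 1)
        with pytest.raises(ValueError):
            pp.generate_genome(100, 1.5, 1)

    def test_deterministic_under_seed(self):
        assert pp.generate_genome(5000, 0.6, 9) == pp.generate_genome(5000, 0.6, 9)


class TestEvolveVariant:
    def test_zero_rate_is_identity(self):
        g = pp.generate_genome(2000, 0.5, 1)
        assert pp.evolve_variant(g, 0.0, 2) == g

    def test_hamming_fraction_within_binomial_bound(self):
        n, p = 50000, 0.05
        g = pp.generate_genome(n, 0.6, 1)
        v = pp.evolve_variant(g, p, 2)
        ham = sum(a != b for a, b in zip(g, v)) / n
        assert abs(ham - p) <= 3 * math.sqrt(p * (1 - p) / n)
        assert len(v) == len(g)

    def test_substituted_bases_always_differ(self):
        g = "A" * 5000
        v = pp.evolve_variant(g, 0.5, 3)
        # every substituted position must hold a different base
        changed = sum(b != "A" for b in v)
        assert abs(changed / 5000 - 0.5) < 0.05

    def test_deterministic_under_seed(self):
        g = pp.generate_genome(3000, 0.5, 1)
        assert pp.evolve_variant(g, 0.1, 7) == pp.evolve_variant(g, 0.1, 7)

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            pp.evolve_variant("ACGT", 1.0, 1)


class TestPlantCommunity:
    def test_genome_and_label_counts(self):
        spec = pp.CommunitySpec(
            clusters=[pp.ClusterSpec(3, 5000, 0.5, 0.02, 10, 5)] * 3,
            n_singletons=1,
            seed=1,
        )
        records, tables, truth = pp.plant_community(spec)
        assert len(records) == 10
        assert len(set(truth.labels.values())) == 4
        assert len(truth.singletons) == 1
        assert set(tables) == {r.id for r in records}

    def test_disjoint_domain_pools_when_unshared(self, small_community):
        records, tables, truth = small_community
        by_label: dict[str, set] = {}
        for r in records:
            accs = {h.domain_accession for h in tables[r.id]}
            by_label.setdefault(truth.labels[r.id], set()).update(accs)
        labels = sorted(by_label)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert not (by_label[a] & by_label[b])

    def test_domain_evalues_below_parse_cutoff(self, small_community):
        _, tables, _ = small_community
        assert all(h.evalue <= 0.001 for hits in tables.values() for h in hits)

    def test_byte_identical_under_seed(self, tmp_path):
        spec = pp.CommunitySpec(
            clusters=[pp.ClusterSpec(2, 4000, 0.5, 0.02, 8, 4)], n_singletons=1, seed=5
        )
        paths = []
        for run in range(2):
            records, tables, truth = pp.plant_community(spec)
            p = tmp_path / f"run{run}.fasta"
            pp.write_fasta(records, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestSimulatePackagedReads:
    def test_dtr_repeat_to_core_depth_ratio(self):
        g = pp.generate_genome(40000, 0.6, 11)
        model = pp.TerminiModel(kind="DTR", repeat_length=1000)
        rs = pp.simulate_packaged_reads(g, model, 30, 150, 0.0, 12)
        cov = rs.true_coverage()
        ratio = cov[:1000].mean() / cov[1000:].mean()
        assert 1.8 <= ratio <= 2.2

    def test_headful_start_pileup_at_pac(self):
        g = pp.generate_genome(30000, 0.6, 13)
        model = pp.TerminiModel(kind="HEADFUL_PAC", pac_position=5000)
        rs = pp.simulate_packaged_reads(g, model, 30, 150, 0.0, 14)
        fwd, _ = rs.true_start_counts()
        assert int(np.argmax(fwd)) == 5000
        others = np.delete(fwd, 5000)
        assert fwd[5000] > others.max()

    def test_error_free_reads_are_virion_substrings(self):
        g = pp.generate_genome(20000, 0.55, 15)
        model = pp.TerminiModel(kind="DTR", repeat_length=800)
        rs = pp.simulate_packaged_reads(g, model, 10, 100, 0.0, 16)
        virion = g + g[:800]
        rc = pp.reverse_complement(virion)
        assert all(
            read.sequence in (virion if read.strand == "+" else rc) for read in rs
        )

    def test_depth_conservation(self):
        g = pp.generate_genome(40000, 0.6, 17)
        model = pp.TerminiModel(kind="DTR", repeat_length=1000)
        rs = pp.simulate_packaged_reads(g, model, 30, 150, 0.0, 18)
        achieved = rs.total_bases() / (40000 + 1000)  # DTR: relative to virion
        assert abs(achieved - 30) / 30 <= 0.05
        model2 = pp.TerminiModel(kind="NONE")
        rs2 = pp.simulate_packaged_reads(g, model2, 30, 150, 0.0, 19)
        achieved2 = rs2.total_bases() / 40000
        assert abs(achieved2 - 30) / 30 <= 0.05

    def test_oversized_repeat_rejected(self):
        g = pp.generate_genome(2000, 0.5, 1)
        with pytest.raises(ValueError):
            pp.simulate_packaged_reads(
                g, pp.TerminiModel(kind="DTR", repeat_length=1200), 10, 100, 0.0, 1
            )

    def test_fastq_and_truth_are_consistent(self, tmp_path):
        g = pp.generate_genome(8000, 0.5, 20)
        rs = pp.simulate_packaged_reads(
            g, pp.TerminiModel(kind="NONE"), 10, 100, 0.01, 21
        )
        fq = tmp_path / "r.fastq"
        truth = tmp_path / "r.truth.tsv"
        write_fastq(rs, fq)
        write_read_truth(rs, truth)
        fq_ids = [l[1:].strip() for l in fq.read_text().splitlines()[::4]]
        truth_ids = [l.split("\t")[0] for l in truth.read_text().splitlines()[1:]]
        assert fq_ids == truth_ids == rs.ids
        assert len(set(fq_ids)) == len(fq_ids)

    def test_byte_identical_fastq_under_seed(self, tmp_path):
        g = pp.generate_genome(6000, 0.5, 22)
        outs = []
        for run in range(2):
            rs = pp.simulate_packaged_reads(
                g, pp.TerminiModel(kind="HEADFUL_PAC", pac_position=100), 15, 120, 0.005, 23
            )
            p = tmp_path / f"{run}.fastq"
            write_fastq(rs, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]
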