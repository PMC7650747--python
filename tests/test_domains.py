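"""Domain-hit parsing, presence-absence matrices, Ward clustering and the
singleton / lifestyle rules."""

import numpy as np
import pandas as pd
import pytest

import phage_profiler as pp
from phage_profiler.domains import (
    DomainHit,
    build_pa_matrix,
    cut_and_flag,
    lifestyle_flags,
    parse_domain_hits,
    ward_dendrogram,
)

from _oracles import lance_williams_ward

HEADER = "genome_id\tprotein_id\tdomain_accession\tdomain_name\tevalue\tbitscore\n"


def _write(tmp_path, rows, header=HEADER):
    path = tmp_path / "hits.tsv"
    path.write_text(header + "".join(rows))
    return path


def _hit(g, acc, e=1e-6, prot="p1"):
    return DomainHit(genome_id=g, protein_id=prot, domain_accession=acc, evalue=e)


class TestParseDomainHits:
    def test_evalue_cutoff_is_inclusive(self, tmp_path):
        rows = [
            f"g1\tp1\tPF00001\tx\t1e-5\t100\n",
            f"g1\tp2\tPF00002\tx\t0.01\t100\n",
            f"g1\tp3\tPF00003\tx\t0.0005\t100\n",
        ]
        hits = parse_domain_hits(_write(tmp_path, rows), evalue_cutoff=0.001)
        assert {h.domain_accession for h in hits} == {"PF00001", "PF00003"}
        boundary = [f"g1\tp1\tPF00001\tx\t0.001\t100\n"]
        assert len(parse_domain_hits(_write(tmp_path, boundary), 0.001)) == 1

    def test_empty_table(self, tmp_path):
        assert parse_domain_hits(_write(tmp_path, [])) == []

    def test_zero_cutoff_keeps_only_exact_zero(self, tmp_path):
        rows = ["g1\tp1\tPF00001\tx\t0.0\t100\n", "g1\tp2\tPF00002\tx\t1e-300\t100\n"]
        hits = parse_domain_hits(_write(tmp_path, rows), evalue_cutoff=0.0)
        assert [h.domain_accession for h in hits] == ["PF00001"]

    def test_unparseable_evalue_dropped_with_warning(self, tmp_path, caplog):
        rows = ["g1\tp1\tPF00001\tx\tnot_a_number\t100\n", "g1\tp2\tPF00002\tx\t1e-9\t100\n"]
        with caplog.at_level("WARNING"):
            hits = parse_domain_hits(_write(tmp_path, rows))
        assert [h.domain_accession for h in hits] == ["PF00002"]
        assert any("e-value" in r.message for r in caplog.records)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(ValueError, match="malformed header"):
            parse_domain_hits(path)

    def test_headerless_with_column_map(self, tmp_path):
        path = tmp_path / "noheader.tsv"
        path.write_text("g1\tp1\tPF00001\t1e-8\n")
        hits = parse_domain_hits(
            path, columns=["genome_id", "protein_id", "domain_accession", "evalue"]
        )
        assert len(hits) == 1 and hits[0].bitscore == 0.0

    def test_duplicates_retained_at_parse_stage(self, tmp_path):
        rows = ["g1\tp1\tPF00001\tx\t1e-8\t50\n", "g1\tp2\tPF00001\tx\t1e-9\t60\n"]
        assert len(parse_domain_hits(_write(tmp_path, rows))) == 2


class TestBuildPaMatrix:
    def test_union_columns_and_rows(self):
        m = build_pa_matrix(
            {"A": [_hit("A", "PF00001"), _hit("A", "PF00002")],
             "B": [_hit("B", "PF00002"), _hit("B", "PF00003")]}
        )
        assert list(m.columns) == ["PF00001", "PF00002", "PF00003"]
        assert m.loc["A"].tolist() == [1, 1, 0]
        assert m.loc["B"].tolist() == [0, 1, 1]

    def test_duplicate_hits_collapse_to_single_presence(self):
        m = build_pa_matrix(
            {"A": [_hit("A", "PF00001", prot="p1"), _hit("A", "PF00001", prot="p2")]}
        )
        assert m.loc["A", "PF00001"] == 1

    def test_idempotent_under_row_duplication(self):
        hits = [_hit("A", "PF00001"), _hit("A", "PF00002")]
        m1 = build_pa_matrix({"A": hits, "B": [_hit("B", "PF00002")]})
        m2 = build_pa_matrix({"A": hits * 3, "B": [_hit("B", "PF00002")] * 2})
        pd.testing.assert_frame_equal(m1, m2)

    def test_zero_hit_genome_keeps_all_zero_row(self):
        m = build_pa_matrix({"A": [_hit("A", "PF00001")], "B": []})
        assert m.loc["B"].sum() == 0
        assert (m.sum(axis=0) > 0).all()  # no all-zero columns

    def test_pfam_filter_default_on(self):
        m = build_pa_matrix({"A": [_hit("A", "PF00001"), _hit("A", "cd00123")]})
        assert list(m.columns) == ["PF00001"]
        m2 = build_pa_matrix(
            {"A": [_hit("A", "PF00001"), _hit("A", "cd00123")]}, pfam_only=False
        )
        assert list(m2.columns) == ["PF00001", "cd00123"]

    def test_column_count_matches_planted_pools(self, small_community):
        _, tables, _ = small_community
        m = build_pa_matrix(tables)
        planted = {h.domain_accession for hits in tables.values() for h in hits}
        assert m.shape[1] == len(planted)


class TestWardDendrogram:
    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]], index=["a", "b", "c"])
        tree = ward_dendrogram(m)
        assert tree.heights()[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_point_instance_matches_lance_williams(self):
        """Rows [1,0,0],[0,1,0],[1,1,1]: all pairs at distance sqrt(2); the
        Ward update gives a second merge height of sqrt(2) as well."""
        m = pd.DataFrame([[1, 0, 0], [0, 1, 0], [1, 1, 1]], index=["a", "b", "c"])
        tree = ward_dendrogram(m)
        assert np.allclose(tree.heights(), [np.sqrt(2), np.sqrt(2)])

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(6, 8))
        ids = [f"g{i}" for i in range(6)]
        m = pd.DataFrame(X, index=ids)
        perm = m.iloc[[3, 1, 5, 0, 2, 4]]
        t1, t2 = ward_dendrogram(m), ward_dendrogram(perm)
        assert t1.ids == t2.ids
        assert np.allclose(t1.heights(), t2.heights())
        assert t1.to_newick() == t2.to_newick()

    def test_single_genome_trivial_tree(self):
        tree = ward_dendrogram(pd.DataFrame([[1, 0]], index=["solo"]))
        assert tree.n_leaves == 1 and tree.to_newick() == "solo;"

    def test_heights_match_bruteforce_oracle_on_small_sweep(self):
        """Merge heights equal a direct Lance-Williams evaluation on random
        binary matrices of 3-6 rows (tie-degenerate instances are skipped:
        with tied dissimilarities the merge sequence is not unique, so the
        comparison would be ill-posed)."""
        rng = np.random.default_rng(1234)
        checked = 0
        attempts = 0
        while checked < 20 and attempts < 400:
            attempts += 1
            n = int(rng.integers(3, 7))
            X = rng.integers(0, 2, size=(n, 10)).astype(float)
            try:
                oracle_heights, _ = lance_williams_ward(X)
            except ValueError:
                continue
            ids = [f"g{i}" for i in range(n)]
            tree = ward_dendrogram(pd.DataFrame(X, index=ids))
            assert np.allclose(
                np.asarray(oracle_heights), tree.heights(), rtol=1e-9, atol=1e-12
            )
            checked += 1
        assert checked == 20


class TestCutAndFlag:
    def test_recovers_planted_partition(self, small_community):
        _, tables, truth = small_community
        pa = build_pa_matrix(tables)
        tree = ward_dendrogram(pa)
        assign = cut_and_flag(tree, pa, n_clusters=4)
        assert pp.adjusted_rand(assign, truth.labels) == 1.0
        assert assign.singletons == truth.singletons

    def test_disjoint_genome_flagged_singleton(self):
        hits = {
            "A": [_hit("A", "PF00001"), _hit("A", "PF00002"), _hit("A", "PF00003")],
            "B": [_hit("B", "PF00001"), _hit("B", "PF00002"), _hit("B", "PF00003")],
            "C": [_hit("C", "PF00008"), _hit("C", "PF00009")],
        }
        pa = build_pa_matrix(hits)
        assign = cut_and_flag(ward_dendrogram(pa), pa, n_clusters=2)
        assert assign.singletons == {"C"}

    def test_k_equals_n_gives_all_own_clusters(self):
        rng = np.random.default_rng(5)
        pa = pd.DataFrame(rng.integers(0, 2, (4, 9)), index=list("abcd"))
        assign = cut_and_flag(ward_dendrogram(pa), pa, n_clusters=4, singleton_min_shared=0)
        assert len(set(assign.labels.values())) == 4

    def test_exactly_one_cut_parameter_required(self):
        pa = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        tree = ward_dendrogram(pa)
        with pytest.raises(ValueError):
            cut_and_flag(tree, pa)
        with pytest.raises(ValueError):
            cut_and_flag(tree, pa, n_clusters=2, height=1.0)
        with pytest.raises(ValueError):
            cut_and_flag(tree, pa, n_clusters=5)


class TestLifestyleFlags:
    def test_integrase_accession_gives_temperate_evidence(self):
        assert lifestyle_flags([_hit("A", "PF00589")]) == "temperate-evidence"

    def test_empty_hits_give_no_evidence(self):
        assert lifestyle_flags([]) == "no-temperate-evidence"

    def test_accession_matching_case_insensitive(self):
        assert lifestyle_flags([_hit("A", "pf00589")]) == "temperate-evidence"
        assert lifestyle_flags([_hit("A", "PF99999")]) == "no-temperate-evidence"

    def test_custom_marker_list(self):
        assert (
            lifestyle_flags([_hit("A", "XY1")], marker_accessions=["xy1"])
            == "temperate-evidence"
        )
        with pytest.raises(ValueError):
            lifestyle_flags([], marker_accessions=[])
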