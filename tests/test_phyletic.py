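import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from rhizomics import (
    DataError,
    PhyleticProfileSpec,
    ProteinRecord,
    ReferenceFamilySet,
    agglomerative_cluster,
    build_phyletic_matrix,
    cut_and_score,
    detect_family_presence,
    euclidean_distance_matrix,
    generate_phyletic_cohort,
    mutate_sequence,
    select_marker_hits,
    write_newick,
)
from rhizomics.errors import ConfigError
from rhizomics.homology import PHYLETIC_THRESHOLDS, search_database, passes_thresholds
from rhizomics.phyletic import Dendrogram, PhyleticMatrix

from oracles import average_linkage_merges


def dist_df(values, labels):
    return pd.DataFrame(np.asarray(values, dtype=float), index=labels, columns=labels)


class TestDetectFamilyPresence:
    def test_exact_copy_detected(self, matrix, make_protein):
        rep = make_protein(120)
        genome = [make_protein(100), ProteinRecord("carrier", rep.sequence)]
        assert detect_family_presence(genome, [rep], matrix=matrix) == 1

    def test_unrelated_genome_absent(self, matrix, make_protein):
        genome = [make_protein(120) for _ in range(3)]
        assert detect_family_presence(genome, [make_protein(120)], matrix=matrix) == 0

    def test_mutated_copy_matches_all_pairs_oracle(self, matrix, make_protein):
        """A 50%-identity homolog must get the same verdict as exhaustive
        gene x representative search."""
        rep = make_protein(150)
        genome = [make_protein(120), ProteinRecord("mut", mutate_sequence(rep.sequence, 0.5, 7))]
        reps = [rep, make_protein(150)]
        oracle = int(
            any(
                passes_thresholds(r, PHYLETIC_THRESHOLDS)
                for g in genome
                for r in search_database(
                    g, reps, PHYLETIC_THRESHOLDS, matrix=matrix
                )
            )
        )
        assert detect_family_presence(genome, reps, matrix=matrix) == oracle

    def test_no_representatives_rejected(self, make_protein):
        with pytest.raises(DataError):
            detect_family_presence([make_protein(100)], [])


class TestBuildPhyleticMatrix:
    @pytest.fixture
    def families(self, make_protein):
        return {
            "famA": make_protein(120),
            "famB": make_protein(130),
            "famC": make_protein(140),
        }

    def test_constructed_fixture_matches_per_cell_oracle(self, families, matrix, make_protein):
        fs = ReferenceFamilySet("fix", {k: (v,) for k, v in families.items()})
        genomes = {
            "g1": [ProteinRecord("c1", families["famA"].sequence), make_protein(100)],
            "g2": [
                ProteinRecord("c2", families["famB"].sequence),
                ProteinRecord("c3", families["famC"].sequence),
            ],
        }
        got = build_phyletic_matrix(genomes, fs, matrix=matrix)
        expected = pd.DataFrame(
            [[1, 0, 0], [0, 1, 1]], index=["g1", "g2"], columns=["famA", "famB", "famC"]
        )
        assert got.data.astype(int).equals(expected)

    def test_duplicated_genome_gives_identical_rows(self, families, matrix, make_protein):
        fs = ReferenceFamilySet("fix", {k: (v,) for k, v in families.items()})
        genes = [ProteinRecord("c1", families["famA"].sequence)]
        got = build_phyletic_matrix({"g1": genes, "g1copy": list(genes)}, fs, matrix=matrix)
        assert (got.data.loc["g1"] == got.data.loc["g1copy"]).all()

    def test_family_absent_everywhere_keeps_all_zero_column(self, families, matrix, make_protein):
        fs = ReferenceFamilySet("fix", {"famA": (families["famA"],), "ghost": (make_protein(200),)})
        genomes = {
            "g1": [ProteinRecord("c1", families["famA"].sequence)],
            "g2": [make_protein(90)],
        }
        got = build_phyletic_matrix(genomes, fs, matrix=matrix)
        assert "ghost" in got.family_ids
        assert got.data["ghost"].sum() == 0

    def test_single_genome_rejected(self, families, matrix):
        fs = ReferenceFamilySet("fix", {"famA": (families["famA"],)})
        with pytest.raises(DataError):
            build_phyletic_matrix({"g1": [families["famA"]]}, fs)


class TestEuclideanDistance:
    def test_identical_rows_at_zero(self):
        m = PhyleticMatrix(pd.DataFrame([[1, 0], [1, 0]], index=["a", "b"]))
        assert euclidean_distance_matrix(m).loc["a", "b"] == 0.0

    def test_closed_form_two_flips(self):
        m = PhyleticMatrix(pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["a", "b"]))
        assert euclidean_distance_matrix(m).loc["a", "b"] == pytest.approx(math.sqrt(2))

    def test_random_binary_matrix_equals_sqrt_hamming(self, rng):
        values = rng.integers(0, 2, size=(5, 8))
        df = pd.DataFrame(values, index=[f"g{i}" for i in range(5)])
        dist = euclidean_distance_matrix(PhyleticMatrix(df))
        for i in range(5):
            for j in range(5):
                hamming = int((values[i] != values[j]).sum())
                assert dist.iloc[i, j] == pytest.approx(math.sqrt(hamming))

    def test_metric_axioms_on_random_instances(self, rng):
        values = rng.integers(0, 2, size=(6, 10))
        d = euclidean_distance_matrix(
            PhyleticMatrix(pd.DataFrame(values, index=list("abcdef")))
        ).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        n = len(d)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_non_binary_entry_rejected(self):
        df = pd.DataFrame([[1, 2], [0, 1]], index=["a", "b"])
        with pytest.raises(DataError):
            euclidean_distance_matrix(df)


class TestAgglomerativeCluster:
    def test_two_genomes_merge_at_their_distance(self):
        den = agglomerative_cluster(dist_df([[0, 3.5], [3.5, 0]], ["A", "B"]))
        assert den.merge_heights().tolist() == [3.5]
        assert den.to_newick() == "(A:3.5,B:3.5);"

    def test_close_pair_merges_first(self):
        d = dist_df([[0, 1, 10], [1, 0, 10], [10, 10, 0]], ["a", "b", "c"])
        den = agglomerative_cluster(d)
        assert den.merge_heights()[0] == pytest.approx(1.0)
        parts, _ = cut_and_score(den, 2, {"a": "x", "b": "x", "c": "y"})
        assert parts["a"] == parts["b"] != parts["c"]

    def test_six_point_instance_matches_naive_average_linkage_oracle(self, rng):
        pts = rng.normal(size=(6, 4))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"g{i}" for i in range(6)]
        den = agglomerative_cluster(dist_df(d, labels), linkage="average")
        expected = average_linkage_merges(d.tolist())
        assert den.merge_heights() == pytest.approx(expected)

    def test_duplicate_genome_adds_zero_height_merge(self, rng):
        """Duplicating a genome prepends a zero-height merge; under
        linkages whose cluster distance is multiplicity-free (weighted,
        single, complete) every other merge height is unchanged.  Under
        size-weighted UPGMA the duplicate re-weights later averages, so
        only the zero merge is asserted there."""
        pts = rng.normal(size=(5, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"g{i}" for i in range(5)]
        d2 = np.zeros((6, 6))
        d2[:5, :5] = d
        d2[5, :5] = d[0, :]  # g5 duplicates g0
        d2[:5, 5] = d[:, 0]
        for linkage in ("weighted", "single", "complete"):
            base = agglomerative_cluster(dist_df(d, labels), linkage).merge_heights()
            dup = agglomerative_cluster(dist_df(d2, labels + ["g5"]), linkage).merge_heights()
            assert dup[0] == pytest.approx(0.0)
            assert dup[1:] == pytest.approx(base)
        dup_avg = agglomerative_cluster(dist_df(d2, labels + ["g5"]), "average").merge_heights()
        assert dup_avg[0] == pytest.approx(0.0)

    def test_heights_invariant_under_genome_order(self, rng):
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"g{i}" for i in range(7)]
        base = agglomerative_cluster(dist_df(d, labels)).merge_heights()
        perm = rng.permutation(7)
        shuffled = agglomerative_cluster(
            dist_df(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        ).merge_heights()
        assert sorted(shuffled) == pytest.approx(sorted(base))

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ConfigError, match="linkage"):
            agglomerative_cluster(dist_df([[0, 1], [1, 0]], ["a", "b"]), linkage="mev")

    def test_newick_written_to_file(self, tmp_path):
        den = agglomerative_cluster(dist_df([[0, 2.0], [2.0, 0]], ["A", "B"]))
        out = tmp_path / "tree.nwk"
        write_newick(den, out)
        assert out.read_text().strip() == "(A:2,B:2);"


class TestCutAndScore:
    def test_singleton_cut_agrees_with_singleton_truth(self, rng):
        pts = rng.normal(size=(5, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"g{i}" for i in range(5)]
        den = agglomerative_cluster(dist_df(d, labels))
        _, ari = cut_and_score(den, 5, {l: l for l in labels})
        assert ari == pytest.approx(1.0)

    def test_well_separated_blocks_recovered(self):
        spec = PhyleticProfileSpec(n_groups=2, genomes_per_group=6, n_families=60, seed=5)
        m, truth = generate_phyletic_cohort(spec)
        den = agglomerative_cluster(euclidean_distance_matrix(m))
        _, ari = cut_and_score(den, 2, truth)
        assert ari == pytest.approx(1.0)

    def test_random_labeling_scores_near_zero(self, rng):
        """ARI is chance-corrected: random truth on 40 leaves must land
        near 0 even though the dendrogram structure is real."""
        values = rng.integers(0, 2, size=(40, 30))
        m = PhyleticMatrix(pd.DataFrame(values, index=[f"g{i}" for i in range(40)]))
        den = agglomerative_cluster(euclidean_distance_matrix(m))
        truth = {f"g{i}": f"c{rng.integers(4)}" for i in range(40)}
        _, ari = cut_and_score(den, 4, truth)
        assert abs(ari) < 0.2

    def test_k_out_of_range_rejected(self):
        den = agglomerative_cluster(dist_df([[0, 1], [1, 0]], ["a", "b"]))
        with pytest.raises(ConfigError):
            cut_and_score(den, 3, {"a": "x", "b": "y"})
        with pytest.raises(ConfigError):
            cut_and_score(den, 0, {"a": "x", "b": "y"})


def marker_hit(length, identity=50.0, evalue=1e-10):
    return SimpleNamespace(
        query_id="q", alignment_length=length, identity_pct=identity, evalue=evalue
    )


class TestSelectMarkerHits:
    def test_short_alignment_removed(self):
        assert select_marker_hits([marker_hit(69)]) == []

    def test_boundary_hit_retained(self):
        h = marker_hit(70, identity=20.0, evalue=0.001)
        assert select_marker_hits([h]) == [h]

    def test_mixed_list_equals_predicate_oracle(self):
        hits = [
            marker_hit(69), marker_hit(70), marker_hit(200, identity=19.9),
            marker_hit(200, identity=20.0), marker_hit(90, evalue=0.01),
            marker_hit(90, evalue=0.001), marker_hit(500, identity=95.0, evalue=0.0),
            marker_hit(10, identity=100.0), marker_hit(71, identity=20.1, evalue=0.0005),
            marker_hit(150, identity=15.0, evalue=0.1),
        ]
        expected = [
            h for h in hits
            if h.alignment_length >= 70 and h.identity_pct >= 20 and h.evalue <= 1e-3
        ]
        assert select_marker_hits(hits) == expected

    def test_missing_alignment_length_rejected(self):
        bad = SimpleNamespace(query_id="q", alignment_length=None, identity_pct=50.0, evalue=0.0)
        with pytest.raises(DataError):
            select_marker_hits([bad])


class TestDendrogramInvariants:
    def test_decreasing_heights_rejected(self):
        Z = np.array([[0, 1, 2.0, 2], [2, 3, 1.0, 3]])
        with pytest.raises(DataError):
            Dendrogram(labels=("a", "b", "c"), linkage_matrix=Z)
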