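"""Sequence handling, pairing classification, distances, neighbor-joining."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from obptools.seqcore import (
    ADJACENT_LABEL,
    KIMURA_P_MAX,
    Bridge,
    DistanceMatrix,
    ProteinRecord,
    classify_pairing,
    distance_matrix_from_alignment,
    kimura_distance,
    nj_tree,
    pairwise_identity,
    read_fasta,
)

# the four proteins' six-cysteine layouts and bridge evidence (positions)
EVIDENCE_BRIDGES = {
    (57, 77, 102, 145, 166, 175): {(57, 175), (77, 102), (145, 166)},
    (56, 76, 101, 144, 169, 178): {(56, 178), (76, 101), (144, 169)},
    (30, 50, 75, 118, 139, 148): {(30, 148), (50, 75), (118, 139)},
    (41, 61, 86, 129, 150, 159): {(41, 159), (61, 86), (129, 150)},
}


class TestReadFasta:
    def test_basic_records(self, tmp_path):
        fa = tmp_path / "p.fasta"
        fa.write_text(">p1\nTCLK\n>p\nACDC\n")
        recs = read_fasta(fa)
        assert [(r.id, r.sequence, r.cys_positions) for r in recs] == [
            ("p1", "TCLK", (2,)),
            ("p", "ACDC", (2, 4)),
        ]

    def test_lowercase_normalized(self, tmp_path):
        fa = tmp_path / "p.fasta"
        fa.write_text(">p\nacdc\n")
        (rec,) = read_fasta(fa)
        assert rec.sequence == "ACDC" and rec.cys_positions == (2, 4)

    def test_malformed_header_names_line(self, tmp_path):
        fa = tmp_path / "bad.fasta"
        fa.write_text("TCLK\n>p\nACDC\n")
        with pytest.raises(ValueError, match=":1:"):
            read_fasta(fa)

    def test_non_amino_acid_rejected(self, tmp_path):
        fa = tmp_path / "bad.fasta"
        fa.write_text(">p\nAC1DC\n")
        with pytest.raises(ValueError, match="non-amino-acid"):
            read_fasta(fa)


class TestClassifyPairing:
    def test_adjacent_motif(self):
        call = classify_pairing(
            {(57, 175), (77, 102), (145, 166)}, [57, 77, 102, 145, 166, 175]
        )
        assert call.ordinal_label == ADJACENT_LABEL
        assert call.pattern == "adjacent (Chelicerata)"

    def test_interlocked_motif(self):
        call = classify_pairing(
            {(10, 30), (20, 50), (40, 60)}, [10, 20, 30, 40, 50, 60]
        )
        assert call.ordinal_label == "C1-C3,C2-C5,C4-C6"
        assert call.pattern == "interlocked (insect)"

    def test_empty_bridges(self):
        call = classify_pairing(set(), [10, 20])
        assert call.ordinal_label == "" and call.pattern == "other"

    @pytest.mark.parametrize("cys, bridges", EVIDENCE_BRIDGES.items())
    def test_all_four_proteins_are_adjacent(self, cys, bridges):
        assert classify_pairing(bridges, cys).ordinal_label == ADJACENT_LABEL

    def test_non_cysteine_endpoint_rejected(self):
        with pytest.raises(ValueError, match="not a cysteine"):
            classify_pairing({(1, 99)}, [1, 2])

    def test_shared_cysteine_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            classify_pairing({(1, 2), (2, 3)}, [1, 2, 3])

    @given(st.integers(0, 10_000))
    def test_invariant_under_position_shift(self, shift):
        cys = [10, 20, 30, 40, 50, 60]
        bridges = {(10, 60), (20, 30), (40, 50)}
        shifted = classify_pairing(
            {(a + shift, b + shift) for a, b in bridges},
            [c + shift for c in cys],
        )
        assert shifted.ordinal_label == ADJACENT_LABEL


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a, b, frac, n",
        [
            ("PEPTIDE", "PEPTIDE", 1.0, 7),
            ("AAAA", "AAAT", 0.75, 4),
            ("XXPEPA", "PEPT", 0.75, 4),
        ],
    )
    def test_ungapped_examples(self, a, b, frac, n):
        a = a.replace("X", "G")  # placeholder flanking residues
        got_frac, got_n = pairwise_identity(a, b)
        assert (got_frac, got_n) == (pytest.approx(frac), n)

    def test_c_anchored_equals_best_over_offsets(self):
        # brute force over all ungapped offsets of the shorter sequence
        a, b = "GGPEPA", "PEPT"
        best = max(
            sum(x == y for x, y in zip(a[off:off + len(b)], b)) / len(b)
            for off in range(len(a) - len(b) + 1)
        )
        # the C-anchored overlap is one particular offset, never above best
        frac, _ = pairwise_identity(a, b)
        assert frac <= best + 1e-12

    def test_aligned_mode_skips_gap_columns(self):
        frac, n = pairwise_identity("PE-TA", "PEPT-", mode="aligned")
        assert (frac, n) == (1.0, 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "PEP")

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ValueError, match="zero overlap"):
            pairwise_identity("A--", "-AA", mode="aligned")


class TestKimuraDistance:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.0, 0.0), (0.1, 0.10758), (0.5, 0.79851)],
    )
    def test_closed_form_values(self, p, expected):
        assert kimura_distance(p) == pytest.approx(expected, abs=1e-5)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            kimura_distance(KIMURA_P_MAX + 1e-6)
        with pytest.raises(ValueError):
            kimura_distance(0.99)

    @given(st.floats(0.0, KIMURA_P_MAX - 1e-6))
    def test_correction_never_below_p(self, p):
        d = kimura_distance(p)
        assert d >= p - 1e-12
        if p > 1e-6:  # strict inequality, away from float round-off
            assert d > p


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns the leaf
    path-length matrix computed directly on the generating tree (oracle)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # each cluster tracks accumulated distance of every leaf to cluster root
    clusters = [({lab: 0.0}) for lab in labels]
    d = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        bi, bj = rng.uniform(0.1, 2.0, size=2)
        ci, cj = clusters[i], clusters[j]
        for la, da in ci.items():
            for lb, db in cj.items():
                d[frozenset((la, lb))] = da + bi + db + bj
        merged = {la: da + bi for la, da in ci.items()}
        merged.update({lb: db + bj for lb, db in cj.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    mat = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            mat[a, b] = mat[b, a] = d[frozenset((labels[a], labels[b]))]
    return labels, mat


def patristic_matrix(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4)) -> path lengths
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        newick = nj_tree(DistanceMatrix(tuple(labels), d))
        assert np.allclose(patristic_matrix(newick, labels), d, atol=1e-9)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        newick = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        # three-point formulas: la=1, lb=2, lc=3
        assert np.allclose(patristic_matrix(newick, ["A", "B", "C"]), d,
                           atol=1e-9)
        assert "A:1.000000" in newick

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        labels = ("D", "C", "B", "A")
        t1 = nj_tree(DistanceMatrix(labels, d))
        t2 = nj_tree(DistanceMatrix(labels, d))
        assert t1 == t2

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0.0]])))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0.0]]))

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(5, 9))
            labels, d = random_additive_tree(rng, n)
            newick = nj_tree(DistanceMatrix(tuple(labels), d))
            assert np.allclose(patristic_matrix(newick, labels), d, atol=1e-8)


class TestDistanceMatrixFromAlignment:
    def test_kimura_correction_applied(self):
        rows = [("a", "PEPTIDE"), ("b", "PEPTIDO"), ("c", "PAPTIDO")]
        dm = distance_matrix_from_alignment(rows)
        p_ab = 1 / 7
        assert dm.d[0, 1] == pytest.approx(-math.log(1 - p_ab - p_ab**2 / 5))

    def test_round_trips_through_tsv(self, tmp_path):
        rows = [("a", "PEPTIDE"), ("b", "PEPTIDO"), ("c", "PAPTIDO")]
        dm = distance_matrix_from_alignment(rows, correction="p")
        import pandas as pd

        path = tmp_path / "d.tsv"
        pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(
            path, sep="\t"
        )
        dm2 = DistanceMatrix.from_tsv(path)
        assert dm2.labels == dm.labels
        assert np.allclose(dm2.d, dm.d)


class TestProteinRecord:
    def test_cys_positions_derived(self):
        rec = ProteinRecord("p", "ACDC")
        assert rec.cys_positions == (2, 4)

    def test_wrong_cys_position_rejected(self):
        with pytest.raises(ValueError, match="not a cysteine"):
            ProteinRecord("p", "ACDC", (3,))

    def test_bridge_orientation_enforced(self):
        with pytest.raises(ValueError):
            Bridge(5, 5)
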