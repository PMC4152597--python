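"""Polymorphism statistics, distances, chi-square, and NJ trees.

Formula results are checked against hand enumeration, closed forms, and the
independent dendropy / scikit-bio implementations.
"""

import itertools
import math
import random

import numpy as np
import pytest

from amplifam.io_formats import Alignment, SequenceRecord, TreeNode, write_newick
from amplifam.popgen import (
    DistanceMatrix,
    aa_p_distance,
    chi_square_differentiation,
    group_distances,
    harmonic_number,
    kimura_2p,
    nj_tree,
    nucleotide_distance_matrix,
    polymorphism_stats,
    transition_transversion_proportions,
    tree_path_distances,
    _ng86_codon_sites,
)


def _alignment(rows):
    return Alignment(
        records=tuple(
            SequenceRecord(id=f"s{i}", sequence=r) for i, r in enumerate(rows)
        )
    )


def _random_alignment(rng, n, length):
    base = [rng.choice("ACGT") for _ in range(length)]
    rows = []
    for _ in range(n):
        row = list(base)
        for pos in rng.sample(range(length), rng.randint(0, length // 4)):
            row[pos] = rng.choice("ACGT")
        rows.append("".join(row))
    return rows


# --- polymorphism statistics ---------------------------------------------


def test_hand_enumerated_three_sequence_stats():
    stats = polymorphism_stats(
        _alignment(["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT"])
    )
    assert stats.S == 2
    assert stats.k == pytest.approx((1 + 2 + 1) / 3)
    assert stats.pi == pytest.approx(0.13333, abs=1e-5)


def test_watterson_theta_closed_form():
    # N=4, S=3, L=100: theta = 3 / ((1 + 1/2 + 1/3) * 100)
    rows = ["A" * 100 for _ in range(4)]
    rows[1] = "T" + rows[1][1:]
    rows[2] = rows[2][:50] + "G" + rows[2][51:]
    rows[3] = rows[3][:99] + "C"
    stats = polymorphism_stats(_alignment(rows))
    assert stats.S == 3
    assert stats.theta_W == pytest.approx(0.016364, abs=1e-6)


def test_monomorphic_alignment_is_all_zero():
    stats = polymorphism_stats(_alignment(["ACGTAC"] * 5))
    assert (stats.S, stats.k, stats.pi, stats.theta_W) == (0, 0.0, 0.0, 0.0)


def test_gap_and_n_columns_are_excluded_everywhere():
    stats = polymorphism_stats(_alignment(["AC-TAN", "ACGTAA", "ACCTAA"]))
    # columns 2 (gap) and 5 (N) dropped: L = 4, no variation remains
    assert stats.L == 4
    assert stats.S == 0


def test_pi_equals_k_over_L_on_random_alignments():
    rng = random.Random(0)
    for _ in range(10):
        rows = _random_alignment(rng, rng.randint(2, 8), 60)
        stats = polymorphism_stats(_alignment(rows))
        assert stats.pi == pytest.approx(stats.k / stats.L, rel=1e-12)


def test_ng86_codon_site_counts():
    # TTT (Phe): only position 3 T->C is synonymous among 9 single changes
    syn, nonsyn = _ng86_codon_sites("TTT")
    assert syn == pytest.approx(1 / 3)
    assert nonsyn == pytest.approx(8 / 3)
    # independent brute force against the standard code for several codons
    from Bio.Seq import Seq

    for codon in ["ATG", "GCT", "AAA", "CGG", "TGG"]:
        expect_syn = 0.0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if str(Seq(mutant).translate()) == "*":
                    continue  # stop-creating changes count as nonsynonymous
                if str(Seq(mutant).translate()) == str(Seq(codon).translate()):
                    expect_syn += 1 / 3
        syn, nonsyn = _ng86_codon_sites(codon)
        assert syn == pytest.approx(expect_syn)
        assert syn + nonsyn == pytest.approx(3.0)


def test_site_counts_conserve_codon_sites():
    # stop-free rows: conservation syn + nonsyn == codon-complete sites
    rng = random.Random(1)
    stops = {"TAA", "TAG", "TGA"}
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in stops]
    rows = ["".join(rng.choice(codons) for _ in range(20)) for _ in range(4)]
    stats = polymorphism_stats(_alignment(rows))
    # no gaps/N: every column is included, 20 codons per sequence
    assert stats.n_codons == 20
    assert stats.syn_sites + stats.nonsyn_sites == pytest.approx(60.0)


def test_stats_require_two_sequences_and_usable_columns():
    with pytest.raises(ValueError):
        polymorphism_stats(_alignment(["ACGT"]))
    with pytest.raises(ValueError):
        polymorphism_stats(_alignment(["----", "ACGT"]))


def test_stats_cross_checked_against_dendropy():
    import dendropy
    from dendropy.calculate import popgenstat

    rng = random.Random(2)
    rows = _random_alignment(rng, 6, 90)
    stats = polymorphism_stats(_alignment(rows))
    fasta = "".join(f">s{i}\n{r}\n" for i, r in enumerate(rows))
    matrix = dendropy.DnaCharacterMatrix.get(data=fasta, schema="fasta")
    assert stats.S == popgenstat.num_segregating_sites(matrix)
    assert stats.pi == pytest.approx(
        popgenstat.nucleotide_diversity(matrix), rel=1e-9
    )
    assert stats.k == pytest.approx(
        popgenstat.average_number_of_pairwise_differences(matrix), rel=1e-9
    )
    # dendropy's Watterson theta is per alignment, ours per site
    assert stats.theta_W * stats.L == pytest.approx(
        popgenstat.wattersons_theta(matrix), rel=1e-9
    )


# --- distances ------------------------------------------------------------


def test_k2p_zero_for_identical():
    assert kimura_2p("ACGTACGT", "ACGTACGT") == 0.0


def test_k2p_closed_forms():
    # 100 sites, 10 transitions (A<->G), 5 transversions (A<->C)
    a = "A" * 100
    b = "G" * 10 + "C" * 5 + "A" * 85
    P, Q, L = transition_transversion_proportions(a, b)
    assert (P, Q, L) == (0.10, 0.05, 100)
    assert kimura_2p(a, b) == pytest.approx(0.17018, abs=1e-5)
    # transversion-free case: d = -0.5 ln(0.8)
    c = "G" * 10 + "A" * 90
    assert kimura_2p(a, c) == pytest.approx(0.11157, abs=1e-5)


def test_k2p_log_domain_violation_is_nan_not_raise():
    assert math.isnan(kimura_2p("AAAA", "GGGG"))  # P=1: 1-2P-Q < 0
    assert math.isnan(kimura_2p("NNNN", "ACGT"))  # nothing comparable


def test_k2p_dominates_p_distance():
    rng = random.Random(3)
    for _ in range(20):
        a = "".join(rng.choice("ACGT") for _ in range(300))
        b = list(a)
        for pos in rng.sample(range(300), rng.randint(1, 60)):
            b[pos] = rng.choice("ACGT")
        b = "".join(b)
        P, Q, L = transition_transversion_proportions(a, b)
        d = kimura_2p(a, b)
        if not math.isnan(d):
            assert d >= P + Q - 1e-12


def test_aa_p_distance_and_group_means():
    assert aa_p_distance("MKV", "MKV") == 0.0
    assert aa_p_distance("MKV", "MRV") == pytest.approx(1 / 3)
    assert math.isnan(aa_p_distance("---", "MKV"))
    matrix = DistanceMatrix(
        ids=["a", "b"], distances=np.array([[0.0, 0.25], [0.25, 0.0]])
    )
    means = group_distances(matrix, {"g1": ["a"], "g2": ["b"]})
    assert means[("g1", "g2")] == pytest.approx(0.25)
    assert math.isnan(means[("g1", "g1")])  # no within pair


# --- chi-square -----------------------------------------------------------


def test_chi_square_identical_multisets_is_zero():
    seqs = ["AAA"] * 5 + ["TTT"] * 5
    stat, df = chi_square_differentiation(seqs, list(seqs))
    assert stat == pytest.approx(0.0)
    assert df == 1


def test_chi_square_disjoint_haplotypes():
    stat, df = chi_square_differentiation(["AAA"] * 10, ["TTT"] * 10)
    assert stat == pytest.approx(20.0)
    assert df == 1


def test_chi_square_single_haplotype_degenerate():
    assert chi_square_differentiation(["AAA"], ["AAA", "AAA"]) == (0.0, 0)


def test_chi_square_matches_scipy_contingency():
    from scipy.stats import chi2_contingency

    a = ["h1"] * 8 + ["h2"] * 3 + ["h3"] * 2
    b = ["h1"] * 2 + ["h2"] * 9 + ["h4"] * 4
    stat, df = chi_square_differentiation(a, b)
    table = np.array([[8, 3, 2, 0], [2, 9, 0, 4]])
    expected = chi2_contingency(table, correction=False)
    assert stat == pytest.approx(expected.statistic)
    # scipy df is (rows-1)(cols-1) == H-1 for two populations
    assert df == expected.dof


# --- neighbor joining -----------------------------------------------------


def _additive_matrix_from_tree(tree: TreeNode, ids):
    paths = tree_path_distances(tree)
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        key = (min(ids[i], ids[j]), max(ids[i], ids[j]))
        d[i, j] = d[j, i] = paths[key]
    return DistanceMatrix(ids=list(ids), distances=d)


def test_nj_recovers_additive_four_taxon_metric_exactly():
    source = TreeNode(children=[
        TreeNode(children=[TreeNode("A", 1.0), TreeNode("B", 2.0)],
                 branch_length=1.0),
        TreeNode(children=[TreeNode("C", 3.0), TreeNode("D", 4.0)]),
    ])
    matrix = _additive_matrix_from_tree(source, ["A", "B", "C", "D"])
    recovered = nj_tree(matrix)
    paths = tree_path_distances(recovered)
    for (i, j), expect in tree_path_distances(source).items():
        assert paths[(i, j)] == pytest.approx(expect, abs=1e-9)
    # the four-point condition picks the AB|CD split; verify independently
    d = matrix.distances
    sums = {
        "AB|CD": d[0, 1] + d[2, 3],
        "AC|BD": d[0, 2] + d[1, 3],
        "AD|BC": d[0, 3] + d[1, 2],
    }
    assert min(sums, key=sums.get) == "AB|CD"
    newick = write_newick(recovered)
    assert ("A" in newick) and newick.endswith(";")


def test_nj_recovers_random_additive_five_taxon_metrics():
    rng = random.Random(4)
    for _ in range(10):
        # random caterpillar/balanced topology with positive lengths
        leaves = [TreeNode(name, rng.uniform(0.5, 3.0)) for name in "ABCDE"]
        rng.shuffle(leaves)
        inner1 = TreeNode(children=[leaves[0], leaves[1]],
                          branch_length=rng.uniform(0.5, 2.0))
        inner2 = TreeNode(children=[inner1, leaves[2]],
                          branch_length=rng.uniform(0.5, 2.0))
        root = TreeNode(children=[inner2, leaves[3], leaves[4]])
        ids = sorted(root.leaf_names())
        matrix = _additive_matrix_from_tree(root, ids)
        paths = tree_path_distances(nj_tree(matrix))
        for (i, j), expect in tree_path_distances(root).items():
            assert paths[(i, j)] == pytest.approx(expect, abs=1e-9)


def test_nj_three_taxon_closed_form():
    matrix = DistanceMatrix(
        ids=["A", "B", "C"],
        distances=np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0],
                            [4.0, 5.0, 0.0]]),
    )
    tree = nj_tree(matrix)
    lengths = {c.name: c.branch_length for c in tree.children}
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}


def test_nj_ties_are_deterministic():
    d = np.ones((4, 4)) - np.eye(4)
    matrix = DistanceMatrix(ids=list("ABCD"), distances=d)
    first = write_newick(nj_tree(matrix))
    second = write_newick(nj_tree(matrix))
    assert first == second
    tree = nj_tree(matrix)
    assert sorted(tree.leaf_names()) == list("ABCD")


def test_nj_rejects_undefined_distances_and_tiny_inputs():
    d = np.array([[0.0, np.nan], [np.nan, 0.0]])
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(ids=["a", "b"], distances=d))
    with pytest.raises(ValueError, match=">= 3"):
        nj_tree(DistanceMatrix(ids=["a", "b"],
                               distances=np.zeros((2, 2))))


def test_nj_cross_checked_against_skbio():
    import skbio

    rng = random.Random(5)
    leaves = [TreeNode(name, rng.uniform(0.5, 3.0)) for name in "ABCDEF"]
    inner1 = TreeNode(children=[leaves[0], leaves[1]], branch_length=1.1)
    inner2 = TreeNode(children=[leaves[2], leaves[3]], branch_length=0.7)
    root = TreeNode(children=[inner1, inner2, leaves[4], leaves[5]])
    ids = sorted(root.leaf_names())
    matrix = _additive_matrix_from_tree(root, ids)
    # jitter off additivity slightly so the check exercises the algorithm,
    # keeping distances far from NJ ties
    jitter = matrix.distances + 0.013
    np.fill_diagonal(jitter, 0.0)
    matrix = DistanceMatrix(ids=ids, distances=jitter)

    mine = tree_path_distances(nj_tree(matrix))
    ref_tree = skbio.tree.nj(
        skbio.DistanceMatrix(matrix.distances, ids=ids)
    )
    for i, j in itertools.combinations(ids, 2):
        ref = ref_tree.find(i).distance(ref_tree.find(j))
        assert mine[(i, j)] == pytest.approx(ref, abs=1e-6)


def test_nucleotide_matrix_is_symmetric_with_zero_diagonal():
    rng = random.Random(6)
    base = "".join(rng.choice("ACGT") for _ in range(120))
    seqs = [base]
    for _ in range(4):
        row = list(base)
        for pos in rng.sample(range(120), 12):
            row[pos] = rng.choice("ACGT")
        seqs.append("".join(row))
    matrix = nucleotide_distance_matrix([f"s{i}" for i in range(5)], seqs)
    assert np.allclose(matrix.distances, matrix.distances.T)
    assert np.allclose(np.diag(matrix.distances), 0.0)
    assert matrix.undefined_pairs() == []
    # saturated pairs are reported as undefined, not raised
    sat = nucleotide_distance_matrix(["a", "b"], ["A" * 50, "G" * 50])
    assert sat.undefined_pairs() == [("a", "b")]


def test_harmonic_number():
    assert harmonic_number(3) == pytest.approx(1 + 0.5 + 1 / 3)
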