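"""Alignment, identity, NJ trees, bootstrap, and clade labeling.

Oracles: all-alignment enumeration for pairwise alignment scores,
four-point-condition split detection for NJ topology recovery on
additive matrices, and direct recomputation for matrix entries.
"""

import io
import itertools

import numpy as np
import pytest
from skbio.tree import TreeNode

from zogscan import (
    GROUP_D,
    GROUP_O,
    UNCLASSIFIED,
    GroupCall,
    ProteinRecord,
    align_pair,
    bootstrap_support,
    distance_matrix,
    identity_matrix,
    label_clades,
    nj_tree,
    percent_identity,
    tree_bipartitions,
)
from zogscan.identity_phylo import AlignmentScoring, DistanceResult, IdentityMatrix


# ---------------------------------------------------------------- oracles

def enumerate_alignments(a, b):
    """Every gapped global alignment of a and b (no gap-gap columns)."""
    if not a and not b:
        yield ("", "")
        return
    if a and b:
        for xa, xb in enumerate_alignments(a[:-1], b[:-1]):
            yield (xa + a[-1], xb + b[-1])
    if a:
        for xa, xb in enumerate_alignments(a[:-1], b):
            yield (xa + a[-1], xb + "-")
    if b:
        for xa, xb in enumerate_alignments(a, b[:-1]):
            yield (xa + "-", xb + b[-1])


def alignment_score(xa, xb, scoring=AlignmentScoring()):
    score = 0.0
    for ca, cb in zip(xa, xb):
        if ca == "-" or cb == "-":
            score += scoring.gap
        else:
            score += scoring.match if ca == cb else scoring.mismatch
    return score


def splits_by_four_point(d, labels):
    """Size-2 splits supported by the four-point condition of an additive matrix."""
    index = {l: i for i, l in enumerate(labels)}
    splits = set()
    for pair in itertools.combinations(labels, 2):
        rest = [l for l in labels if l not in pair]
        i, j = (index[p] for p in pair)
        ok = True
        for k, l in itertools.combinations(rest, 2):
            k, l = index[k], index[l]
            near = d[i, j] + d[k, l]
            if near >= min(d[i, k] + d[j, l], d[i, l] + d[j, k]):
                ok = False
                break
        if ok:
            splits.add(frozenset({frozenset(pair), frozenset(rest)}))
    return splits


def additive_matrix(newick, labels):
    """Tip-to-tip path lengths of a branch-length tree."""
    tree = TreeNode.read(io.StringIO(newick))
    n = len(labels)
    d = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        d[i, j] = d[j, i] = tips[a].distance(tips[b])
    return d


def records(seqs):
    return [ProteinRecord(name, "sp", seq) for name, seq in seqs.items()]


# ---------------------------------------------------------------- alignment

class TestAlignPair:
    def test_identical_sequences_align_without_gaps(self):
        assert align_pair("ACDE", "ACDE") == ("ACDE", "ACDE")

    def test_single_deletion_is_gapped(self):
        assert align_pair("ACDE", "ACE") == ("ACDE", "AC-E")

    def test_single_column_mismatch_score(self):
        xa, xb = align_pair("W", "F")
        assert alignment_score(xa, xb) == AlignmentScoring().mismatch

    def test_outputs_always_equal_length(self):
        xa, xb = align_pair("WSPQ", "GG")
        assert len(xa) == len(xb)

    @pytest.mark.parametrize("seed", range(15))
    def test_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join("ACDE"[i] for i in rng.integers(0, 4, rng.integers(1, 6)))
        b = "".join("ACDE"[i] for i in rng.integers(0, 4, rng.integers(1, 6)))
        xa, xb = align_pair(a, b)
        best = max(alignment_score(*aln) for aln in enumerate_alignments(a, b))
        assert alignment_score(xa, xb) == pytest.approx(best)
        assert xa.replace("-", "") == a and xb.replace("-", "") == b

    def test_substitution_matrix_scoring(self):
        xa, xb = align_pair("WW", "WW", AlignmentScoring(substitution_matrix="BLOSUM62"))
        assert (xa, xb) == ("WW", "WW")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            align_pair("", "ACDE")


class TestPercentIdentity:
    def test_identical_motifs_are_100(self, d_motif):
        assert percent_identity(d_motif, d_motif) == 100.0

    def test_three_matches_over_four_columns(self):
        assert percent_identity("ACDE", "AC-E") == 75.0

    def test_symmetric(self):
        assert percent_identity("AC-E", "ACDE") == percent_identity("ACDE", "AC-E")

    def test_both_gap_columns_excluded_from_denominator(self):
        assert percent_identity("A-C", "A-C") == 100.0
        assert percent_identity("A--", "A-C") == 50.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="lengths differ"):
            percent_identity("AC", "ACD")


class TestDistanceMatrix:
    def test_identical_pair_distance_zero(self):
        result = distance_matrix(records({"a": "ACDE", "b": "ACDE"}))
        assert result.distances[0, 1] == 0.0

    def test_fully_mismatched_equal_length_pair_distance_one(self):
        result = distance_matrix(records({"a": "AAAA", "b": "CCCC"}))
        assert result.distances[0, 1] == 1.0

    def test_matrix_matches_independent_pairwise_calls(self):
        seqs = {"a": "ACDEFG", "b": "ACDFG", "c": "MKVWYH"}
        result = distance_matrix(records(seqs))
        for (i, x), (j, y) in itertools.combinations(enumerate(seqs), 2):
            pid = percent_identity(*align_pair(seqs[x], seqs[y]))
            assert result.identity.values[i, j] == pytest.approx(pid)
            assert result.distances[i, j] == pytest.approx(1 - pid / 100)

    def test_aligned_method_matches_pairwise_on_equal_length_gapless(self):
        seqs = {"a": "ACDEAC", "b": "ACDFAC", "c": "MKVWYH"}
        aligned = identity_matrix(records(seqs), method="aligned")
        for i, j in itertools.combinations(range(3), 2):
            a, b = list(seqs.values())[i], list(seqs.values())[j]
            assert aligned.values[i, j] == pytest.approx(percent_identity(a, b))

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            distance_matrix(records({"a": "ACDE"}))

    def test_identity_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            IdentityMatrix(labels=["a", "b"],
                           values=np.array([[100.0, 50.0], [60.0, 100.0]]))


# ---------------------------------------------------------------- NJ trees

class TestNJTree:
    def test_three_taxa_closed_form_branch_lengths(self):
        # x+y=6, x+z=8, y+z=10 -> x=2, y=4, z=6
        d = np.array([[0.0, 6, 8], [6, 0, 10], [8, 10, 0]]) / 10
        labels = ["a", "b", "c"]
        from skbio import DistanceMatrix
        tree = nj_tree(DistanceMatrix(d, labels))
        tips = {t.name: t for t in tree.tips()}
        for (i, x), (j, y) in itertools.combinations(enumerate(labels), 2):
            assert tips[x].distance(tips[y]) == pytest.approx(d[i, j])

    def test_recovers_additive_five_taxon_topology(self):
        labels = list("ABCDE")
        newick = "((A:2,B:3):1,(C:1,D:4):2,E:6);"
        d = additive_matrix(newick, labels)
        from skbio import DistanceMatrix
        tree = nj_tree(DistanceMatrix(d, labels))
        assert tree_bipartitions(tree) == splits_by_four_point(d, labels)

    def test_recovers_additive_six_taxon_topology(self):
        labels = list("ABCDEF")
        newick = "(((A:1,B:2):1,(C:2,D:1):3):1,(E:2,F:1):2);"
        d = additive_matrix(newick, labels)
        from skbio import DistanceMatrix
        tree = nj_tree(DistanceMatrix(d, labels))
        assert tree_bipartitions(tree) >= splits_by_four_point(d, labels)

    def test_taxon_order_permutation_gives_isomorphic_tree(self):
        labels = list("ABCDE")
        d = additive_matrix("((A:2,B:3):1,(C:1,D:4):2,E:6);", labels)
        from skbio import DistanceMatrix
        tree1 = nj_tree(DistanceMatrix(d, labels))
        perm = [3, 1, 4, 0, 2]
        d2 = d[np.ix_(perm, perm)]
        tree2 = nj_tree(DistanceMatrix(d2, [labels[i] for i in perm]))
        assert tree_bipartitions(tree1) == tree_bipartitions(tree2)

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 4))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        from skbio import DistanceMatrix
        tree = nj_tree(DistanceMatrix(d, [f"t{i}" for i in range(6)]))
        assert all((n.length or 0) >= 0 for n in tree.traverse())

    def test_too_few_taxa_rejected(self):
        result = distance_matrix(records({"a": "ACDE", "b": "ACDF"}))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(result)


# ---------------------------------------------------------------- bootstrap

class TestBootstrapSupport:
    # every column carries the same 2-vs-2 split
    clean_labels = ["a", "b", "c", "d"]
    clean_seqs = ["AAAAAAAAAA", "AAAAAAAAAA", "CCCCCCCCCC", "CCCCCCCCCC"]

    def test_clean_split_supported_at_100_for_any_seed(self):
        for seed in (0, 1, 99):
            _, supports = bootstrap_support(
                self.clean_labels, self.clean_seqs, n_reps=20, seed=seed
            )
            split = frozenset({frozenset("ab"), frozenset("cd")})
            assert supports[split] == 100.0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        labels = ["a", "b", "c", "d", "e"]
        rng = np.random.default_rng(3)
        seqs = ["".join("ACDE"[i] for i in rng.integers(0, 4, 30)) for _ in labels]
        _, supports = bootstrap_support(labels, seqs, n_reps=1, seed=11)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproduces_support_vector(self):
        labels = ["a", "b", "c", "d", "e"]
        rng = np.random.default_rng(4)
        seqs = ["".join("ACDE"[i] for i in rng.integers(0, 4, 40)) for _ in labels]
        run1 = bootstrap_support(labels, seqs, n_reps=25, seed=7)[1]
        run2 = bootstrap_support(labels, seqs, n_reps=25, seed=7)[1]
        assert run1 == run2

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            bootstrap_support(["a", "b"], ["AAA", "AAAA"], n_reps=5, seed=0)


# ---------------------------------------------------------------- clades

def make_call(accession, group):
    res = {"O": ("H", "S"), "D": ("F", "G"), UNCLASSIFIED: ("Y", "W")}[group]
    return GroupCall(
        accession=accession, species="sp", group=group, res41=res[0],
        res42=res[1], hs_present=group == "O", submotif_hits_o=0,
        submotif_hits_d=0, motif_found=True,
    )


class TestLabelClades:
    def tree(self, newick):
        return TreeNode.read(io.StringIO(newick))

    def test_all_o_leaves_form_one_clade(self):
        tree = self.tree("((a,b),(c,(d,(e,f))));")
        calls = [make_call(x, GROUP_O) for x in "abcdef"]
        assignment = label_clades(tree, calls)
        assert len(assignment.clades) == 1
        clade = assignment.clades[0]
        assert clade.label == GROUP_O and set(clade.members) == set("abcdef")

    def test_unclassified_leaf_in_o_clade_gets_yellow_flag(self):
        tree = self.tree("((a,b),(c,(d,u)));")
        calls = [make_call(x, GROUP_O) for x in "abcd"] + [make_call("u", UNCLASSIFIED)]
        assignment = label_clades(tree, calls, purity_threshold=0.8)
        assert len(assignment.clades) == 1
        assert assignment.clades[0].yellow_flags == ("u",)

    def test_purity_one_splits_mixed_clade(self):
        tree = self.tree("((a,b),(c,(d,x)));")
        calls = [make_call(l, GROUP_O) for l in "abcd"] + [make_call("x", GROUP_D)]
        assignment = label_clades(tree, calls, purity_threshold=1.0)
        assert len(assignment.clades) > 1
        for clade in assignment.clades:
            assert clade.purity == 1.0
        assert assignment.partition() == set("abcdx")

    def test_low_support_edges_are_not_cut_points(self):
        # internal node labels are supports; 10 < min_support forces a split
        tree = self.tree("((a:1,b:1)90:1,((c:1,d:1)10:1,(e:1,f:1)95:1)90:1);")
        calls = [make_call(x, GROUP_O) for x in "ab"] + [
            make_call(x, GROUP_D) for x in "cdef"
        ]
        assignment = label_clades(tree, calls, min_support=50, purity_threshold=0.9)
        members = {c.members for c in assignment.clades}
        assert ("c", "d") not in members  # its edge support is only 10
        assert assignment.partition() == set("abcdef")

    def test_leaf_without_call_raises(self):
        tree = self.tree("((a,b),c);")
        with pytest.raises(KeyError, match="c"):
            label_clades(tree, [make_call("a", GROUP_O), make_call("b", GROUP_O)])

    def test_clades_partition_leaves(self):
        tree = self.tree("(((a,b),(c,d)),(e,(f,g)));")
        groups = dict(zip("abcdefg", ["O", "O", "D", "D", "O", "D", "O"]))
        calls = [make_call(x, g) for x, g in groups.items()]
        assignment = label_clades(tree, calls, purity_threshold=0.9)
        assert assignment.partition() == set("abcdefg")
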