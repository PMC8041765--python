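"""Pairwise identity, distance matrices, NJ trees, bootstrap, clade labels.

Distance-based desk-scale phylogenetics for the ZOG census: global
pairwise alignment (Needleman-Wunsch, linear gap penalty), percent
identity, identity-derived distances (d = 1 - identity/100),
neighbor-joining tree construction, nonparametric bootstrap over
alignment columns, and extraction of group-labeled clades from the tree.

Neighbor joining deliberately replaces maximum-likelihood / parsimony
search here: tree inference is standard plumbing around the motif and
census logic, and NJ with bootstrap preserves everything the downstream
clade labeling consumes (topology, branch support, leaf groups) at a
cost that allows exhaustive oracle testing. The NJ step itself is
delegated to scikit-bio, with negative branch lengths clamped to zero.

Identity convention: matches are identical aligned non-gap residues; the
denominator excludes columns gapped in *both* sequences (terminal gaps
count). The convention is recorded in matrix output metadata because no
single standard exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .group_classify import GROUP_D, GROUP_O, UNCLASSIFIED, GroupCall

__all__ = [
    "GAP",
    "AlignmentScoring",
    "IdentityMatrix",
    "DistanceResult",
    "LabeledClade",
    "CladeAssignment",
    "align_pair",
    "percent_identity",
    "identity_matrix",
    "distance_matrix",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
    "label_clades",
    "write_matrix_tsv",
]

GAP = "-"
_SYM_TOL = 1e-9


@dataclass(frozen=True)
class AlignmentScoring:
    """Linear-gap global alignment scores.

    Defaults (match +1, mismatch 0, gap -1) keep every optimum exactly
    enumerable by brute force in tests; a substitution matrix name from
    Bio.Align.substitution_matrices (e.g. "BLOSUM62") can replace the
    match/mismatch scheme.
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -1.0
    substitution_matrix: str | None = None

    def score_pair(self, a: str, b: str) -> float:
        if self.substitution_matrix is not None:
            return float(self._matrix()[a, b])
        return self.match if a == b else self.mismatch

    def _matrix(self):
        from Bio.Align import substitution_matrices

        return substitution_matrices.load(self.substitution_matrix)


def align_pair(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> tuple[str, str]:
    """Global Needleman-Wunsch alignment with a linear gap penalty.

    Tie-breaking is deterministic: on equal score the traceback prefers a
    match/mismatch column, then a gap inserted in ``a`` (consuming a
    residue of ``b``), then a gap inserted in ``b``. Both returned
    strings have equal length.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    scoring = scoring or AlignmentScoring()
    g = scoring.gap
    n, m = len(a), len(b)

    # per-row substitution scores against b
    if scoring.substitution_matrix is not None:
        matrix = scoring._matrix()
        sub = np.array([[float(matrix[x, y]) for y in b] for x in a])
    else:
        b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
        a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
        sub = np.where(a_arr[:, None] == b_arr[None, :], scoring.match, scoring.mismatch)

    H = np.empty((n + 1, m + 1))
    H[0, :] = g * np.arange(m + 1)
    H[:, 0] = g * np.arange(n + 1)
    j_idx = np.arange(m + 1)
    for i in range(1, n + 1):
        best = np.empty(m + 1)
        best[0] = H[i, 0]
        vertical = np.maximum(H[i - 1, 1:] + g, H[i - 1, :-1] + sub[i - 1])
        best[1:] = vertical
        # resolve the left-gap recurrence in one prefix-max scan:
        # H[i,j] = max_{k<=j} (best[k] + g*(j-k))
        H[i] = np.maximum.accumulate(best - g * j_idx) + g * j_idx

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = H[i, j]
        if i > 0 and j > 0 and abs(here - (H[i - 1, j - 1] + sub[i - 1, j - 1])) < _SYM_TOL:
            i -= 1
            j -= 1
            out_a.append(a[i])
            out_b.append(b[j])
        elif j > 0 and abs(here - (H[i, j - 1] + g)) < _SYM_TOL:
            j -= 1
            out_a.append(GAP)
            out_b.append(b[j])
        else:
            i -= 1
            out_a.append(a[i])
            out_b.append(GAP)
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """100 × matches / columns where not both sequences are gapped."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}"
        )
    matches = 0
    columns = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP and y == GAP:
            continue
        columns += 1
        if x == y:
            matches += 1
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over labeled sequences."""

    labels: list[str]
    values: np.ndarray  # percentages in [0, 100]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.diag(self.values), 100.0, atol=0):
            raise ValueError("identity diagonal must be exactly 100")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise ValueError("identity matrix must be symmetric")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


@dataclass
class DistanceResult:
    """Identity-derived distances d = 1 - identity/100 in [0, 1]."""

    labels: list[str]
    distances: np.ndarray
    identity: IdentityMatrix

    def to_skbio(self) -> DistanceMatrix:
        return DistanceMatrix(self.distances, self.labels)


def _aligned_identity_matrix(labels: Sequence[str], seqs: Sequence[str]) -> np.ndarray:
    """Vectorized percent identity over pre-aligned equal-length rows."""
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must share one length")
    enc = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    gap_code = ord(GAP)
    n = len(labels)
    values = np.full((n, n), 100.0)
    is_gap = enc == gap_code
    for i in range(n):
        eq = enc[i + 1 :] == enc[i]
        both_gap = is_gap[i + 1 :] & is_gap[i]
        matches = (eq & ~both_gap).sum(axis=1)
        columns = length - both_gap.sum(axis=1)
        with np.errstate(invalid="ignore"):
            pid = np.where(columns > 0, 100.0 * matches / np.maximum(columns, 1), 0.0)
        values[i, i + 1 :] = pid
        values[i + 1 :, i] = pid
    return values


def identity_matrix(
    records: Sequence,
    method: str = "pairwise",
    scoring: AlignmentScoring | None = None,
) -> IdentityMatrix:
    """All-pairs percent identity.

    method="pairwise" aligns each pair globally before measuring;
    method="aligned" treats the inputs as rows of one multiple alignment
    (all equal length, gaps allowed) and compares columns directly.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    labels = [r.accession for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate accessions in identity matrix input")
    seqs = [r.sequence for r in records]
    if method == "aligned":
        values = _aligned_identity_matrix(labels, seqs)
    elif method == "pairwise":
        n = len(seqs)
        values = np.full((n, n), 100.0)
        for i in range(n):
            for j in range(i + 1, n):
                pid = percent_identity(*align_pair(seqs[i], seqs[j], scoring))
                values[i, j] = values[j, i] = pid
    else:
        raise ValueError(f"unknown method {method!r}")
    return IdentityMatrix(labels=labels, values=values)


def distance_matrix(
    records: Sequence,
    method: str = "pairwise",
    scoring: AlignmentScoring | None = None,
) -> DistanceResult:
    """Identity-derived distance matrix, d = 1 - identity/100."""
    identity = identity_matrix(records, method=method, scoring=scoring)
    distances = 1.0 - identity.values / 100.0
    np.fill_diagonal(distances, 0.0)
    return DistanceResult(
        labels=list(identity.labels), distances=distances, identity=identity
    )


def nj_tree(distances: DistanceResult | DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if isinstance(distances, DistanceResult):
        dm = distances.to_skbio()
    else:
        dm = distances
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # DistanceMatrix construction already rejects asymmetric input
    return nj(dm, neg_as_zero=True)


def tree_bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of the leaf set, orientation-free.

    Each internal edge splits the leaves in two; the bipartition is
    stored as the frozenset of both sides so rootings and rotations of
    the same unrooted tree compare equal.
    """
    tips = frozenset(t.name for t in tree.tips())
    bips: set[frozenset[frozenset[str]]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) >= 2 and len(other) >= 2:
            bips.add(frozenset({side, other}))
    return bips


def bootstrap_support(
    labels: Sequence[str],
    aligned_seqs: Sequence[str],
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[frozenset[str]], float]]:
    """Column-resampling bootstrap over one multiple alignment.

    Rebuilds a distance + NJ tree from columns drawn with replacement in
    each replicate and reports, per internal edge of the original tree,
    the percentage of replicates whose tree contains the same
    bipartition. Supports are written onto the original tree's internal
    nodes (``node.support``, mirrored into the node name for Newick
    output). Fully reproducible under ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    length = len(aligned_seqs[0])
    if any(len(s) != length for s in aligned_seqs):
        raise ValueError("bootstrap needs column-aligned (equal-length) input")

    @dataclass(frozen=True)
    class _Row:
        accession: str
        sequence: str

    def tree_from_columns(cols: np.ndarray) -> TreeNode:
        sub = ["".join(s[c] for c in cols) for s in aligned_seqs]
        rows = [_Row(l, s) for l, s in zip(labels, sub)]
        return nj_tree(distance_matrix(rows, method="aligned"))

    all_cols = np.arange(length)
    original = tree_from_columns(all_cols)
    target = tree_bipartitions(original)
    hits = {bip: 0 for bip in target}

    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        replicate = tree_bipartitions(tree_from_columns(cols))
        for bip in target & replicate:
            hits[bip] += 1

    supports = {bip: 100.0 * count / n_reps for bip, count in hits.items()}

    tips = frozenset(t.name for t in original.tips())
    for node in original.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = frozenset({side, tips - side})
        if key in supports:
            node.support = supports[key]
            node.name = f"{supports[key]:g}"
    return original, supports


@dataclass(frozen=True)
class LabeledClade:
    """A supported clade with a dominant group label."""

    clade_id: str
    members: tuple[str, ...]
    label: str
    purity: float
    support: float
    yellow_flags: tuple[str, ...]  # UNCLASSIFIED leaves inside an O-dominant clade


@dataclass
class CladeAssignment:
    """A tree together with the clades labeled on it (a leaf partition)."""

    tree: TreeNode
    clades: list[LabeledClade]

    def partition(self) -> set[str]:
        leaves: list[str] = []
        for clade in self.clades:
            leaves.extend(clade.members)
        if len(leaves) != len(set(leaves)):
            raise ValueError("clades overlap")
        return set(leaves)


def _node_support(node: TreeNode) -> float:
    support = getattr(node, "support", None)
    if support is not None:
        return float(support)
    if node.name:
        try:
            return float(node.name)
        except ValueError:
            pass
    return 100.0  # unannotated edges are not support-filtered


def _dominant_label(groups: Sequence[str]) -> tuple[str, float]:
    counts = {g: 0 for g in (GROUP_O, GROUP_D, UNCLASSIFIED)}
    for g in groups:
        counts[g] += 1
    if counts[GROUP_O] or counts[GROUP_D]:
        label = max((GROUP_O, GROUP_D), key=lambda g: counts[g])
    else:
        label = UNCLASSIFIED
    return label, counts[label] / len(groups)


def label_clades(
    tree: TreeNode,
    calls: Iterable[GroupCall] | Mapping[str, GroupCall],
    min_support: float = 50.0,
    purity_threshold: float = 0.8,
) -> CladeAssignment:
    """Cut the tree into maximal supported, label-coherent clades.

    Walking from the root, a subtree is emitted as one clade when its
    edge support reaches ``min_support`` and the most common group label
    among its leaves has frequency >= ``purity_threshold``; otherwise the
    walk recurses. Leaves always terminate the recursion, so the clades
    partition the leaf set. UNCLASSIFIED leaves inside an O-dominant
    clade are flagged — motif-degenerate sequences placed among cisZOGs.
    """
    if not isinstance(calls, Mapping):
        calls = {c.accession: c for c in calls}
    missing = [t.name for t in tree.tips() if t.name not in calls]
    if missing:
        raise KeyError(f"tree leaves without group calls: {sorted(missing)}")

    clades: list[LabeledClade] = []

    def emit(node: TreeNode, support: float) -> None:
        members = tuple(sorted(t.name for t in node.tips(include_self=True)))
        labels = [calls[m].group for m in members]
        label, purity = _dominant_label(labels)
        yellow = tuple(
            m for m in members
            if label == GROUP_O and calls[m].group == UNCLASSIFIED
        )
        clades.append(
            LabeledClade(
                clade_id=f"C{len(clades) + 1}",
                members=members,
                label=label,
                purity=purity,
                support=support,
                yellow_flags=yellow,
            )
        )

    def walk(node: TreeNode, is_root: bool) -> None:
        support = 100.0 if is_root else _node_support(node)
        if node.is_tip():
            emit(node, support)
            return
        labels = [calls[t.name].group for t in node.tips()]
        _, purity = _dominant_label(labels)
        if support >= min_support and purity >= purity_threshold:
            emit(node, support)
            return
        for child in node.children:
            walk(child, is_root=False)

    walk(tree, is_root=True)
    return CladeAssignment(tree=tree, clades=clades)


def write_matrix_tsv(
    labels: Sequence[str], values: np.ndarray, path, fmt: str = "%.6g"
) -> None:
    """Square labeled matrix as TSV (header row + row labels)."""
    with open(path, "w") as handle:
        handle.write("\t".join(["id", *labels]) + "\n")
        for label, row in zip(labels, values):
            handle.write("\t".join([label, *(fmt % v for v in row)]) + "\n")
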