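"""The 44-column PSPG consensus frame and windowed motif location.

The Plant Secondary Product Glycosyltransferase (PSPG) motif is a 44
amino-acid consensus near the C-terminus of family-1 UDP-glycosyltransferases
(UGTs) that binds the UDP-sugar donor. Its columns are conventionally
numbered 1..44. The frame used here encodes three layers of information:

* **anchors** — sugar-donor contact residues invariant across groups:
  W1, P3, H19, W22, E27, D43, Q44;
* **group-O columns** — residues from the three boxed group-O submotifs
  (cis-zeatin O-glucosyltransferases, cisZOG): PQLEIL at columns 3-8,
  FMSHCGWNS at 16-24, WPMHSDQ at 38-44, which place the diagnostic
  His-Ser pair at columns 41-42;
* **group-D columns** — the full 44-residue motif of the Arabidopsis
  cisZOG1 entry AY573820.1 (a UGT73C / group-D protein), which carries
  Phe-Gly at 41-42 instead of His-Ser.

Motif location is ungapped: every 44-residue window of a protein is
scored as the sum of per-column weights over columns whose residue is
allowed there, and the best window wins (ties broken toward the C
terminus, where the motif biologically sits). There are no insert/delete
states — the motif is treated as a rigid frame so that column numbers
keep their meaning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MOTIF_LENGTH",
    "ANCHOR_RESIDUES",
    "GROUP_O_SUBMOTIFS",
    "GROUP_D_SUBMOTIFS",
    "GROUP_D_REFERENCE_MOTIF",
    "ConsensusProfile",
    "PSPGMotif",
    "build_default_profile",
    "group_o_consensus",
    "locate_pspg",
    "motif_residue",
]

MOTIF_LENGTH = 44

#: Sugar-donor contact residues, invariant across UGT groups (1-based column).
ANCHOR_RESIDUES: dict[int, str] = {1: "W", 3: "P", 19: "H", 22: "W", 27: "E", 43: "D", 44: "Q"}

#: Boxed group-O (cisZOG) submotifs, keyed by 1-based start column.
GROUP_O_SUBMOTIFS: dict[int, str] = {3: "PQLEIL", 16: "FMSHCGWNS", 38: "WPMHSDQ"}

#: Boxed group-D submotifs shared with group O, keyed by 1-based start column.
GROUP_D_SUBMOTIFS: dict[int, str] = {3: "PQ", 19: "HCGWNS", 43: "DQ"}

#: Full 44-aa PSPG motif of the Arabidopsis thaliana cisZOG1 entry
#: AY573820.1 (group D / UGT73C): Phe at 41, Gly at 42.
GROUP_D_REFERENCE_MOTIF = "WSPQMLILTHPAVGGFLTHCGWNSTLEGITSGVPLLTWPLFGDQ"

# default per-column weights by information content of the column
ANCHOR_WEIGHT = 3.0
GROUP_WEIGHT = 2.0
WILDCARD_WEIGHT = 1.0
DEFAULT_PRESENCE_THRESHOLD = 0.55


def _expand_submotifs(submotifs: dict[int, str]) -> dict[int, str]:
    """Place each submotif at its 1-based start column; returns column→residue."""
    columns: dict[int, str] = {}
    for start, residues in submotifs.items():
        for offset, residue in enumerate(residues):
            col = start + offset
            if not 1 <= col <= MOTIF_LENGTH:
                raise ValueError(f"submotif {residues!r} overruns the 44-column frame")
            if columns.get(col, residue) != residue:
                raise ValueError(f"conflicting residues at column {col}")
            columns[col] = residue
    return columns


@dataclass(frozen=True)
class ConsensusProfile:
    """The 44-column PSPG scoring frame.

    ``anchors``, ``group_o_columns`` and ``group_d_columns`` map 1-based
    columns to residues. A window residue matches a column if it equals
    the anchor or either group residue defined there; matched columns
    contribute ``column_weights[col]``, columns defined by no map accept
    any residue (except X) at the wildcard weight. ``presence_threshold``
    is the fraction of the maximum attainable window score above which a
    window counts as a PSPG motif.
    """

    anchors: dict[int, str]
    group_o_columns: dict[int, str]
    group_d_columns: dict[int, str]
    column_weights: dict[int, float]
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    n_columns: int = MOTIF_LENGTH

    def __post_init__(self) -> None:
        if self.n_columns != MOTIF_LENGTH:
            raise ValueError("the PSPG frame is fixed at 44 columns")
        if not 0.0 < self.presence_threshold <= 1.0:
            raise ValueError("presence_threshold must lie in (0, 1]")
        for col, residue in self.anchors.items():
            for name, group in (("group_o", self.group_o_columns),
                                ("group_d", self.group_d_columns)):
                if col in group and group[col] != residue:
                    raise ValueError(
                        f"anchor {residue}@{col} conflicts with {name} column"
                    )
        if any(w <= 0 for w in self.column_weights.values()):
            raise ValueError("column weights must be positive")
        if len(self.column_weights) != self.n_columns:
            raise ValueError("need one weight per column")

    # -- scoring machinery -------------------------------------------------

    def allowed_residues(self, col: int) -> frozenset[str]:
        """Residues scoring at column ``col`` (empty set = wildcard column)."""
        allowed = set()
        for source in (self.anchors, self.group_o_columns, self.group_d_columns):
            if col in source:
                allowed.add(source[col])
        return frozenset(allowed)

    @property
    def max_score(self) -> float:
        return float(sum(self.column_weights[c] for c in range(1, self.n_columns + 1)))

    def _score_lut(self) -> tuple[np.ndarray, dict[str, int]]:
        """(44 × alphabet) weight lookup; X never scores, wildcards score all."""
        alphabet = "ACDEFGHIKLMNPQRSTVWYX"
        index = {aa: i for i, aa in enumerate(alphabet)}
        lut = np.zeros((self.n_columns, len(alphabet)), dtype=float)
        for col in range(1, self.n_columns + 1):
            allowed = self.allowed_residues(col)
            w = self.column_weights[col]
            if allowed:
                for aa in allowed:
                    lut[col - 1, index[aa]] = w
            else:
                lut[col - 1, :] = w
            lut[col - 1, index["X"]] = 0.0  # ambiguous residues never score
        return lut, index

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_columns": self.n_columns,
            "anchors": {str(k): v for k, v in sorted(self.anchors.items())},
            "group_o_columns": {str(k): v for k, v in sorted(self.group_o_columns.items())},
            "group_d_columns": {str(k): v for k, v in sorted(self.group_d_columns.items())},
            "column_weights": {str(k): v for k, v in sorted(self.column_weights.items())},
            "presence_threshold": self.presence_threshold,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ConsensusProfile":
        """Rebuild a profile from `to_json` output (a JSON string or a path)."""
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = source
        payload = json.loads(text)
        return cls(
            anchors={int(k): v for k, v in payload["anchors"].items()},
            group_o_columns={int(k): v for k, v in payload["group_o_columns"].items()},
            group_d_columns={int(k): v for k, v in payload["group_d_columns"].items()},
            column_weights={int(k): float(v) for k, v in payload["column_weights"].items()},
            presence_threshold=float(payload["presence_threshold"]),
            n_columns=int(payload["n_columns"]),
        )


@dataclass(frozen=True)
class PSPGMotif:
    """A located 44-residue PSPG window.

    ``start`` is the 0-based offset of motif column 1 in the source
    sequence; ``score``/``max_score`` are profile window scores. When
    ``found`` is false the best window (if any) is still reported with
    ``status`` explaining why it was rejected.
    """

    accession: str
    start: int
    motif_seq: str
    score: float
    max_score: float
    found: bool
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.found and len(self.motif_seq) != MOTIF_LENGTH:
            raise ValueError("a found motif must span exactly 44 residues")
        if self.score < 0 or self.score > self.max_score + 1e-9:
            raise ValueError("score outside [0, max_score]")


def build_default_profile(
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> ConsensusProfile:
    """Build the frame from the anchors, the group-O boxed submotifs and
    the AY573820.1 group-D reference motif.

    Weights: anchors 3, columns constrained by a group map 2, remaining
    columns 1. The group-D map covers all 44 columns (it comes from a
    complete printed motif), so with the default maps no column is a pure
    wildcard; the wildcard weight applies to custom profiles.
    """
    group_o = _expand_submotifs(GROUP_O_SUBMOTIFS)
    group_d = {i + 1: aa for i, aa in enumerate(GROUP_D_REFERENCE_MOTIF)}
    weights: dict[int, float] = {}
    for col in range(1, MOTIF_LENGTH + 1):
        if col in ANCHOR_RESIDUES:
            weights[col] = ANCHOR_WEIGHT
        elif col in group_o or col in group_d:
            weights[col] = GROUP_WEIGHT
        else:
            weights[col] = WILDCARD_WEIGHT
    return ConsensusProfile(
        anchors=dict(ANCHOR_RESIDUES),
        group_o_columns=group_o,
        group_d_columns=group_d,
        column_weights=weights,
        presence_threshold=presence_threshold,
    )


def group_o_consensus(profile: ConsensusProfile | None = None) -> str:
    """A 44-aa string realizing the group-O consensus.

    Columns constrained by an anchor or a group-O submotif take that
    residue; columns constrained only by the group-D map fall back to the
    group-D residue (those positions are not group-diagnostic); pure
    wildcard columns take alanine.
    """
    profile = profile or build_default_profile()
    out = []
    for col in range(1, profile.n_columns + 1):
        residue = (
            profile.anchors.get(col)
            or profile.group_o_columns.get(col)
            or profile.group_d_columns.get(col)
            or "A"
        )
        out.append(residue)
    return "".join(out)


def locate_pspg(record, profile: ConsensusProfile) -> PSPGMotif:
    """Score every ungapped 44-residue window and return the best.

    ``found`` is true when the best score reaches
    ``presence_threshold × max_score``. Ties go to the most C-terminal
    window. Sequences shorter than 44 residues yield ``found=False`` with
    an explanatory status rather than an exception.
    """
    sequence = record.sequence
    max_score = profile.max_score
    if len(sequence) < MOTIF_LENGTH:
        return PSPGMotif(
            accession=record.accession, start=0, motif_seq="", score=0.0,
            max_score=max_score, found=False,
            status=f"sequence length {len(sequence)} < {MOTIF_LENGTH}",
        )
    lut, index = profile._score_lut()
    encoded = np.fromiter((index[aa] for aa in sequence), dtype=np.intp, count=len(sequence))
    windows = np.lib.stride_tricks.sliding_window_view(encoded, MOTIF_LENGTH)
    scores = lut[np.arange(MOTIF_LENGTH), windows].sum(axis=1)
    # argmax of the reversed array → last (most C-terminal) maximum
    best = len(scores) - 1 - int(np.argmax(scores[::-1]))
    score = float(scores[best])
    found = score >= profile.presence_threshold * max_score - 1e-9
    return PSPGMotif(
        accession=record.accession,
        start=best,
        motif_seq=sequence[best : best + MOTIF_LENGTH],
        score=score,
        max_score=max_score,
        found=found,
        status="ok" if found else "best window below presence threshold",
    )


def motif_residue(motif: PSPGMotif, pos: int) -> str:
    """Residue at 1-based PSPG column ``pos`` of a found motif."""
    if not motif.found:
        raise ValueError("motif was not found; no residues to read")
    if not 1 <= pos <= MOTIF_LENGTH:
        raise ValueError(f"PSPG columns run 1..{MOTIF_LENGTH}, got {pos}")
    return motif.motif_seq[pos - 1]
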