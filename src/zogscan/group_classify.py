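"""Diagnostic-residue group assignment, homolog census, presence/absence.

Group calls follow the diagnostic-residue logic of the PSPG frame:

* **group O** (cisZOG, cis-zeatin O-glucosyltransferases) is defined by
  the His-Ser pair at PSPG columns 41-42;
* **group D** (UGT73-like trans-zeatin-active enzymes) carries Phe-Gly
  or Phe-Ala at 41-42 *and* must match all three group-D boxed submotifs
  (PQ at 3-4, HCGWNS at 19-24, DQ at 43-44) — the Phe diagnostic alone
  also occurs in unrelated UGT groups, so the submotif conjunction guards
  specificity;
* everything else that still carries a locatable PSPG motif is
  UNCLASSIFIED — including group-H-like (UGT76) sequences, for which no
  complete diagnostic residue set is encoded, and the "yellow-box" state:
  motif-bearing sequences lacking His-Ser that may nevertheless sit
  inside an O-dominated clade of the tree.

The census tallies calls per species into O / D / UNCLASSIFIED /
no-motif counts, and the presence/absence step collapses the census over
a species→clade map, exposing clades in which every species lacks
group-O copies (the Brassicaceae pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pspg_profile import (
    GROUP_D_SUBMOTIFS,
    GROUP_O_SUBMOTIFS,
    PSPGMotif,
)

__all__ = [
    "GROUP_O",
    "GROUP_D",
    "UNCLASSIFIED",
    "GroupCall",
    "HomologCensus",
    "CladePresence",
    "classify_group",
    "census",
    "presence_absence",
]

GROUP_O = "O"
GROUP_D = "D"
UNCLASSIFIED = "UNCLASSIFIED"

#: Residue pairs accepted at columns 41-42 for the group-D diagnostic.
GROUP_D_4142 = {("F", "G"), ("F", "A")}


@dataclass(frozen=True)
class GroupCall:
    """One record's group assignment plus the evidence it rests on."""

    accession: str
    species: str
    group: str
    res41: str
    res42: str
    hs_present: bool
    submotif_hits_o: int
    submotif_hits_d: int
    motif_found: bool
    motif_start: int = -1

    def __post_init__(self) -> None:
        if self.group not in (GROUP_O, GROUP_D, UNCLASSIFIED):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == GROUP_O and not self.hs_present:
            raise ValueError("group O requires the His-Ser diagnostic")
        if self.hs_present != (self.res41 == "H" and self.res42 == "S"):
            raise ValueError("hs_present inconsistent with res41/res42")
        if not (0 <= self.submotif_hits_o <= 3 and 0 <= self.submotif_hits_d <= 3):
            raise ValueError("submotif hit counts are bounded by 3")


def _count_submotif_hits(motif_seq: str, submotifs: Mapping[int, str]) -> int:
    hits = 0
    for start, residues in submotifs.items():
        if motif_seq[start - 1 : start - 1 + len(residues)] == residues:
            hits += 1
    return hits


def classify_group(motif: PSPGMotif, species: str = "") -> GroupCall:
    """Assign group O, D or UNCLASSIFIED from a located PSPG window.

    Total and deterministic: any valid `PSPGMotif` yields a call. A
    motif that was not found yields an UNCLASSIFIED call with empty
    residue evidence.
    """
    if not motif.found:
        return GroupCall(
            accession=motif.accession, species=species, group=UNCLASSIFIED,
            res41="", res42="", hs_present=False,
            submotif_hits_o=0, submotif_hits_d=0, motif_found=False,
        )
    res41 = motif.motif_seq[40]
    res42 = motif.motif_seq[41]
    hs = res41 == "H" and res42 == "S"
    hits_o = _count_submotif_hits(motif.motif_seq, GROUP_O_SUBMOTIFS)
    hits_d = _count_submotif_hits(motif.motif_seq, GROUP_D_SUBMOTIFS)
    if hs:
        group = GROUP_O
    elif (res41, res42) in GROUP_D_4142 and hits_d == 3:
        group = GROUP_D
    else:
        group = UNCLASSIFIED
    return GroupCall(
        accession=motif.accession, species=species, group=group,
        res41=res41, res42=res42, hs_present=hs,
        submotif_hits_o=hits_o, submotif_hits_d=hits_d,
        motif_found=True, motif_start=motif.start,
    )


CENSUS_CATEGORIES = (GROUP_O, GROUP_D, UNCLASSIFIED, "no_motif")


@dataclass
class HomologCensus:
    """Per-species homolog counts by group category.

    ``counts[species]`` maps each of O / D / UNCLASSIFIED / no_motif to a
    non-negative tally; categories sum to the number of that species'
    input records. UNCLASSIFIED covers motif-bearing records without a
    group diagnostic; no_motif covers records in which no PSPG window
    reached the presence threshold.
    """

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def total(self) -> int:
        return sum(sum(per.values()) for per in self.counts.values())

    def species(self) -> list[str]:
        return sorted(self.counts)

    def count(self, species: str, category: str) -> int:
        return self.counts.get(species, {}).get(category, 0)


def census(calls: Iterable[GroupCall]) -> HomologCensus:
    """Tally group calls per species; permutation-invariant."""
    counts: dict[str, dict[str, int]] = {}
    for call in calls:
        per = counts.setdefault(
            call.species, {category: 0 for category in CENSUS_CATEGORIES}
        )
        category = call.group if call.motif_found else "no_motif"
        per[category] += 1
    return HomologCensus(counts=counts)


@dataclass(frozen=True)
class CladePresence:
    """Boolean group presence per clade plus supporting species lists."""

    clade: str
    o_present: bool
    d_present: bool
    n_species: int
    zero_o_species: tuple[str, ...]


def presence_absence(
    homolog_census: HomologCensus,
    clade_map: Mapping[str, str],
) -> list[CladePresence]:
    """Collapse a census over a species→clade map.

    A clade is marked present for a group when *any* member species has
    at least one copy; the species with zero group-O copies are listed
    per clade so a whole-clade loss (the Brassicaceae analogue) is
    directly readable. Clades are returned sorted by name.
    """
    missing = sorted(set(homolog_census.counts) - set(clade_map))
    if missing:
        raise KeyError(f"species missing from clade map: {missing}")
    clades: dict[str, list[str]] = {}
    for species in homolog_census.counts:
        clades.setdefault(clade_map[species], []).append(species)
    out = []
    for clade in sorted(clades):
        members = sorted(clades[clade])
        o_present = any(homolog_census.count(s, GROUP_O) > 0 for s in members)
        d_present = any(homolog_census.count(s, GROUP_D) > 0 for s in members)
        zero_o = tuple(s for s in members if homolog_census.count(s, GROUP_O) == 0)
        out.append(
            CladePresence(
                clade=clade, o_present=o_present, d_present=d_present,
                n_species=len(members), zero_o_species=zero_o,
            )
        )
    return out
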