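"""Synthetic UGT gene families with known ground truth.

Generates protein datasets that emulate the regime the ZOG census
operates in: plant UGT-like proteins of ~470 residues carrying a 44-aa
PSPG motif near the C-terminus, 1-5 (occasionally more) homologs per
species arising from duplication and loss, species grouped into clades,
and one designated clade in which every group-O lineage has been lost
while group-D copies persist — the Brassicaceae pattern.

The model is deliberately minimal:

* species sit in clades on a star-within-clades topology; each clade is
  seeded with a small number of ancestral gene lineages ("families"),
  each assigned group O or group D;
* along the branch to each species, each family undergoes Bernoulli
  duplication events (geometric copy-number growth, damped beyond the
  target range and hard-capped) and a Bernoulli loss event;
* each gene copy is the clade ancestor sequence with i.i.d. per-site
  substitutions at ``mutation_rate``, reduced by ``anchor_conservation``
  at the seven sugar-donor anchor columns of the motif;
* background (non-motif) sequence is i.i.d. uniform over the 20 amino
  acids, so spurious motif hits are improbable and quantifiable;
* substitutions only, no indels — motif columns stay in frame, matching
  the ungapped scanner contract.

Every dataset is accompanied by a `SimTruth` carrying the generator's
true labels, so classifier and census accuracy are measurable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .group_classify import (
    GROUP_D,
    GROUP_O,
    GroupCall,
    census,
    presence_absence,
)
from .pspg_profile import (
    ANCHOR_RESIDUES,
    GROUP_D_REFERENCE_MOTIF,
    MOTIF_LENGTH,
    build_default_profile,
    group_o_consensus,
)
from .seqio import ProteinRecord

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimTruth",
    "make_clades",
    "default_config",
    "generate_dataset",
    "RecoveryReport",
    "truth_accuracy",
    "write_truth_tsv",
]

AMINO20 = "ACDEFGHIKLMNPQRSTVWY"
HARD_COPY_CAP = 9  # most homologs seen per species in the emulated regime


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; a fixed seed makes the output byte-reproducible."""

    clades: Mapping[str, tuple[str, ...]]
    loss_clade: str | None = None
    dup_rate: float = 0.35
    loss_rate: float = 0.1
    target_copies: tuple[int, int] = (1, 5)
    families_per_clade: int = 2
    group_mix: float = 0.5
    mutation_rate: float = 0.02
    anchor_conservation: float = 0.1
    protein_length: int = 470
    motif_tail: int = 8  # residues C-terminal of the motif
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("dup_rate", self.dup_rate),
            ("loss_rate", self.loss_rate),
            ("group_mix", self.group_mix),
            ("mutation_rate", self.mutation_rate),
            ("anchor_conservation", self.anchor_conservation),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.protein_length < MOTIF_LENGTH:
            raise ValueError("protein_length must fit the 44-aa motif")
        if self.protein_length < MOTIF_LENGTH + self.motif_tail:
            raise ValueError("protein_length must fit motif plus tail")
        if self.loss_clade is not None and self.loss_clade not in self.clades:
            raise ValueError(
                f"loss_clade {self.loss_clade!r} is not one of the clades"
            )
        if self.families_per_clade < 1:
            raise ValueError("need at least one seed family per clade")
        lo, hi = self.target_copies
        if not 1 <= lo <= hi <= HARD_COPY_CAP:
            raise ValueError(f"target_copies must satisfy 1 <= lo <= hi <= {HARD_COPY_CAP}")
        species = [s for members in self.clades.values() for s in members]
        if len(species) != len(set(species)):
            raise ValueError("clades must partition the species (no overlap)")

    @property
    def species(self) -> list[str]:
        return [s for members in self.clades.values() for s in members]

    def clade_of(self) -> dict[str, str]:
        return {s: c for c, members in self.clades.items() for s in members}


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted protein record."""

    accession: str
    group: str  # O or D, the seeded family group
    species: str
    clade: str
    family: str  # ancestral lineage id (the "parent copy")


@dataclass
class SimTruth:
    """Ground-truth labels and events for a generated dataset."""

    records: dict[str, TruthRecord]
    species_counts: dict[str, dict[str, int]]  # species -> {O: n, D: n}
    loss_events: list[tuple[str, str, str]]  # (clade, species, family)
    clade_map: dict[str, str]
    loss_clade: str | None


def make_clades(
    n_species: int = 50,
    n_clades: int = 6,
    loss_clade_size: int = 8,
    loss_clade_name: str = "Brassicaceae-like",
) -> tuple[dict[str, tuple[str, ...]], str]:
    """Partition ``n_species`` synthetic species into clades.

    The first ``loss_clade_size`` species form the designated loss clade;
    the rest are split as evenly as possible into ``n_clades - 1`` more.
    Returns (clades, loss_clade_name).
    """
    if loss_clade_size >= n_species:
        raise ValueError("loss clade must leave species for other clades")
    species = [f"Species_{i:03d}" for i in range(1, n_species + 1)]
    clades: dict[str, tuple[str, ...]] = {
        loss_clade_name: tuple(species[:loss_clade_size])
    }
    rest = species[loss_clade_size:]
    n_other = max(1, n_clades - 1)
    bounds = np.linspace(0, len(rest), n_other + 1).astype(int)
    for k in range(n_other):
        members = tuple(rest[bounds[k] : bounds[k + 1]])
        if members:
            clades[f"clade_{k + 1:02d}"] = members
    return clades, loss_clade_name


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard study conditions: 50 species, 6 clades, an 8-species
    loss clade, 1-5 typical copies per species."""
    clades, loss = make_clades()
    base = dict(clades=clades, loss_clade=loss, seed=seed)
    base.update(overrides)
    return SimConfig(**base)


def _seed_family_groups(config: SimConfig) -> list[str]:
    """Deterministic O/D allocation of a clade's seed families.

    The count of O families is round(group_mix × families); when the mix
    is strictly between 0 and 1 both groups are guaranteed at least one
    family, so presence/absence contrasts are always evaluable.
    """
    n = config.families_per_clade
    n_o = int(round(config.group_mix * n))
    if 0.0 < config.group_mix < 1.0:
        n_o = min(max(n_o, 1), n - 1) if n > 1 else n_o
    return [GROUP_O] * n_o + [GROUP_D] * (n - n_o)


def _mutate(
    sequence: np.ndarray,
    rng: np.random.Generator,
    rate: float,
    anchor_positions: np.ndarray,
    anchor_rate: float,
) -> np.ndarray:
    """Per-site substitution; anchors mutate at the reduced rate."""
    rates = np.full(sequence.size, rate)
    rates[anchor_positions] = anchor_rate
    hit = rng.random(sequence.size) < rates
    out = sequence.copy()
    if hit.any():
        # draw replacements that differ from the current residue
        shift = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 20
    return out


def _copies_for_branch(config: SimConfig, rng: np.random.Generator) -> int:
    """Copy number after duplication/loss on one species branch."""
    copies = 1
    _, target_hi = config.target_copies
    while copies < HARD_COPY_CAP:
        p = config.dup_rate if copies < target_hi else config.dup_rate / 4.0
        if rng.random() >= p:
            break
        copies += 1
    if rng.random() < config.loss_rate:
        copies -= 1
    return copies


def generate_dataset(config: SimConfig) -> tuple[list[ProteinRecord], SimTruth]:
    """Evolve gene copies per species from clade ancestors.

    Deterministic under ``config.seed``. In the loss clade every group-O
    lineage is deleted outright (recorded as a loss event per species),
    reproducing a whole-clade gene loss.
    """
    rng = np.random.default_rng(config.seed)
    profile = build_default_profile()
    o_template = group_o_consensus(profile)
    d_template = GROUP_D_REFERENCE_MOTIF

    records: list[ProteinRecord] = []
    truth_records: dict[str, TruthRecord] = {}
    species_counts: dict[str, dict[str, int]] = {
        s: {GROUP_O: 0, GROUP_D: 0} for s in config.species
    }
    loss_events: list[tuple[str, str, str]] = []

    aa_index = {aa: i for i, aa in enumerate(AMINO20)}

    for clade, members in config.clades.items():
        family_groups = _seed_family_groups(config)
        for fam_idx, group in enumerate(family_groups, start=1):
            family_id = f"{clade}.fam{fam_idx}"
            motif_start = config.protein_length - MOTIF_LENGTH - config.motif_tail
            # ancestral sequence: uniform background + group motif template
            ancestor = rng.integers(0, 20, size=config.protein_length)
            template = o_template if group == GROUP_O else d_template
            ancestor[motif_start : motif_start + MOTIF_LENGTH] = [
                aa_index[c] for c in template
            ]
            anchor_positions = np.array(
                [motif_start + col - 1 for col in sorted(ANCHOR_RESIDUES)]
            )
            for species in members:
                if config.loss_clade == clade and group == GROUP_O:
                    loss_events.append((clade, species, family_id))
                    continue
                n_copies = _copies_for_branch(config, rng)
                if n_copies == 0:
                    loss_events.append((clade, species, family_id))
                    continue
                for copy_idx in range(1, n_copies + 1):
                    mutated = _mutate(
                        ancestor,
                        rng,
                        config.mutation_rate,
                        anchor_positions,
                        config.mutation_rate * config.anchor_conservation,
                    )
                    sequence = "".join(AMINO20[c] for c in mutated)
                    accession = f"{species}.{family_id}.c{copy_idx}"
                    records.append(
                        ProteinRecord(
                            accession=accession,
                            species=species,
                            sequence=sequence,
                            lineage_tags=(clade,),
                        )
                    )
                    truth_records[accession] = TruthRecord(
                        accession=accession, group=group, species=species,
                        clade=clade, family=family_id,
                    )
                    species_counts[species][group] += 1

    truth = SimTruth(
        records=truth_records,
        species_counts=species_counts,
        loss_events=loss_events,
        clade_map=config.clade_of(),
        loss_clade=config.loss_clade,
    )
    return records, truth


@dataclass(frozen=True)
class RecoveryReport:
    """How well the pipeline's calls recover the generator's truth."""

    label_accuracy: float
    census_error: dict[str, int]  # per-species |called - true| summed over O, D
    loss_clade_detected: bool


def truth_accuracy(
    calls: Iterable[GroupCall] | Mapping[str, GroupCall],
    truth: SimTruth,
) -> RecoveryReport:
    """Compare classifier calls against the generator's ground truth.

    ``label_accuracy`` is the fraction of records whose called group
    equals the seeded group. ``census_error`` is, per species, the sum of
    absolute differences between called and true O and D counts.
    ``loss_clade_detected`` is true when presence/absence over the true
    clade map reports group O absent in the designated loss clade and
    present in at least one other clade.
    """
    if not isinstance(calls, Mapping):
        calls = {c.accession: c for c in calls}
    if set(calls) != set(truth.records):
        only_calls = sorted(set(calls) - set(truth.records))[:5]
        only_truth = sorted(set(truth.records) - set(calls))[:5]
        raise ValueError(
            "calls and truth cover different accessions "
            f"(e.g. calls-only {only_calls}, truth-only {only_truth})"
        )
    if not calls:
        raise ValueError("no records to compare")

    correct = sum(
        1 for acc, rec in truth.records.items() if calls[acc].group == rec.group
    )
    accuracy = correct / len(truth.records)

    called_census = census(calls.values())
    errors: dict[str, int] = {}
    for species, true_counts in truth.species_counts.items():
        err = sum(
            abs(called_census.count(species, g) - true_counts[g])
            for g in (GROUP_O, GROUP_D)
        )
        errors[species] = err

    detected = False
    if truth.loss_clade is not None:
        clade_rows = presence_absence(called_census, truth.clade_map)
        by_name = {row.clade: row for row in clade_rows}
        loss_row = by_name.get(truth.loss_clade)
        others = [row for name, row in by_name.items() if name != truth.loss_clade]
        detected = (
            loss_row is not None
            and not loss_row.o_present
            and any(row.o_present for row in others)
        )

    return RecoveryReport(
        label_accuracy=accuracy, census_error=errors, loss_clade_detected=detected
    )


def write_truth_tsv(truth: SimTruth, path) -> None:
    """Ground-truth labels as TSV (accession, group, species, clade, family)."""
    with open(path, "w") as handle:
        handle.write("accession\tgroup\tspecies\tclade\tfamily\n")
        for accession in sorted(truth.records):
            rec = truth.records[accession]
            handle.write(
                f"{rec.accession}\t{rec.group}\t{rec.species}\t{rec.clade}\t{rec.family}\n"
            )
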