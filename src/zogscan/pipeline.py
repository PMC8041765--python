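"""End-to-end orchestration: load/simulate → scan → classify → census →
presence/absence → distances → NJ + bootstrap → clade labels.

A pipeline run is a pure function of (inputs, config, seed): every
artifact except the timestamped ``run.log`` is byte-identical across
reruns. All thresholds in force are echoed both to the log and into
``summary.json``.

Outputs written to the configured directory:

* ``records.fasta`` / ``metadata.tsv`` / ``truth.tsv`` — when simulating;
* ``calls.tsv`` — per-record motif location and group call;
* ``census.tsv`` — per-species homolog counts by category;
* ``presence_absence.tsv`` — per-clade group presence and zero-O species;
* ``identity.tsv`` / ``distances.tsv`` — pairwise matrices;
* ``tree.nwk`` — NJ tree, bootstrap supports as internal node labels;
* ``summary.json`` — machine-readable run summary;
* ``run.log`` — the only non-deterministic artifact (timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import seqio
from .group_classify import (
    CENSUS_CATEGORIES,
    GROUP_D,
    GROUP_O,
    UNCLASSIFIED,
    census,
    classify_group,
    presence_absence,
)
from .identity_phylo import (
    bootstrap_support,
    distance_matrix,
    label_clades,
    nj_tree,
    write_matrix_tsv,
)
from .pspg_profile import ConsensusProfile, build_default_profile, locate_pspg
from .synthetic_data import SimConfig, generate_dataset, truth_accuracy, write_truth_tsv

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failure, annotated with the stage name; partial outputs remain."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage '{stage}' failed: {error}")
        self.stage = stage
        self.error = error


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through JSON."""

    outdir: str
    fasta: str | None = None
    metadata: str | None = None
    sim: SimConfig | None = None
    presence_threshold: float = 0.55
    min_support: float = 50.0
    purity_threshold: float = 0.8
    bootstrap_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.fasta is None) == (self.sim is None):
            raise ValueError("configure exactly one of 'fasta' or 'sim'")
        if not 0.0 < self.presence_threshold <= 1.0:
            raise ValueError("presence_threshold must lie in (0, 1]")
        if not 0.0 <= self.min_support <= 100.0:
            raise ValueError("min_support is a percentage in [0, 100]")
        if not 0.0 < self.purity_threshold <= 1.0:
            raise ValueError("purity_threshold must lie in (0, 1]")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")

    def to_json(self, include_outdir: bool = True) -> str:
        payload = dataclasses.asdict(self)
        if self.sim is not None:
            payload["sim"]["clades"] = {
                k: list(v) for k, v in self.sim.clades.items()
            }
        if not include_outdir:
            payload.pop("outdir")
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        payload = json.loads(text)
        payload.setdefault("outdir", ".")
        sim = payload.get("sim")
        if sim is not None:
            sim["clades"] = {k: tuple(v) for k, v in sim["clades"].items()}
            sim["target_copies"] = tuple(sim["target_copies"])
            payload["sim"] = SimConfig(**sim)
        return cls(**payload)


def _make_logger(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"zogscan.run.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.propagate = False
    return logger


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and return the summary dictionary.

    Any stage error propagates as `PipelineStageError` carrying the stage
    name; artifacts written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = _make_logger(outdir)
    logger.info(
        "thresholds: presence=%.3f min_support=%.1f purity=%.2f bootstrap=%d seed=%d",
        config.presence_threshold, config.min_support,
        config.purity_threshold, config.bootstrap_reps, config.seed,
    )
    summary: dict[str, Any] = {
        "thresholds": {
            "presence_threshold": config.presence_threshold,
            "min_support": config.min_support,
            "purity_threshold": config.purity_threshold,
            "bootstrap_reps": config.bootstrap_reps,
            "seed": config.seed,
        }
    }

    def stage(name: str):
        logger.info("stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise PipelineStageError(name, exc) from exc
                return False

        return _Ctx()

    truth = None
    clade_map: dict[str, str] | None = None
    with stage("load"):
        if config.sim is not None:
            records, truth = generate_dataset(config.sim)
            if not records:
                raise ValueError("no records (simulation produced an empty dataset)")
            seqio.write_fasta(records, outdir / "records.fasta")
            seqio.write_metadata_tsv(records, outdir / "metadata.tsv")
            write_truth_tsv(truth, outdir / "truth.tsv")
            clade_map = dict(truth.clade_map)
        else:
            records = seqio.load_records(config.fasta, config.metadata)
            # lineage tag 1 (family) doubles as the clade key when present
            if all(r.lineage_tags for r in records):
                clade_map = {r.species: r.lineage_tags[0] for r in records}
        logger.info("loaded %d records, %d species", len(records),
                    len({r.species for r in records}))

    with stage("scan"):
        profile = build_default_profile(config.presence_threshold)
        motifs = [locate_pspg(rec, profile) for rec in records]

    with stage("classify"):
        calls = [
            classify_group(motif, species=rec.species)
            for rec, motif in zip(records, motifs)
        ]
        seqio.write_calls_tsv(calls, outdir / "calls.tsv")
        summary["n_records"] = len(records)
        summary["n_species"] = len({r.species for r in records})
        summary["motif_found"] = sum(c.motif_found for c in calls)
        summary["hs_present"] = sum(c.hs_present for c in calls)

    with stage("census"):
        tally = census(calls)
        summary["group_counts"] = {
            cat: sum(per[cat] for per in tally.counts.values())
            for cat in CENSUS_CATEGORIES
        }
        with open(outdir / "census.tsv", "w") as handle:
            handle.write("species\tO\tD\tUNCLASSIFIED\tno_motif\n")
            for species in tally.species():
                row = tally.counts[species]
                handle.write(
                    f"{species}\t{row[GROUP_O]}\t{row[GROUP_D]}\t"
                    f"{row[UNCLASSIFIED]}\t{row['no_motif']}\n"
                )

    with stage("presence_absence"):
        if clade_map is not None:
            rows = presence_absence(tally, clade_map)
            with open(outdir / "presence_absence.tsv", "w") as handle:
                handle.write("clade\tO\tD\tn_species\tzero_O_species\n")
                for row in rows:
                    handle.write(
                        f"{row.clade}\t{int(row.o_present)}\t{int(row.d_present)}\t"
                        f"{row.n_species}\t{','.join(row.zero_o_species)}\n"
                    )
            summary["clades_without_group_O"] = [
                row.clade for row in rows if not row.o_present
            ]
        else:
            logger.info("no clade map available; presence/absence skipped")
            summary["clades_without_group_O"] = None

    with stage("distances"):
        if len(records) >= 2:
            lengths = {len(r.sequence) for r in records}
            method = "aligned" if len(lengths) == 1 else "pairwise"
            logger.info("distance method: %s", method)
            dist = distance_matrix(records, method=method)
            write_matrix_tsv(dist.labels, dist.identity.values,
                             outdir / "identity.tsv")
            write_matrix_tsv(dist.labels, dist.distances, outdir / "distances.tsv")
            summary["distance_method"] = method
        else:
            dist = None
            summary["distance_method"] = None

    with stage("tree"):
        if dist is not None and len(records) >= 3:
            if summary["distance_method"] == "aligned" and config.bootstrap_reps > 0:
                tree, supports = bootstrap_support(
                    [r.accession for r in records],
                    [r.sequence for r in records],
                    n_reps=config.bootstrap_reps,
                    seed=config.seed,
                )
                summary["bootstrap_reps"] = config.bootstrap_reps
            else:
                tree = nj_tree(dist)
                supports = {}
                summary["bootstrap_reps"] = 0
            tree.write(str(outdir / "tree.nwk"), format="newick")
            assignment = label_clades(
                tree, calls, min_support=config.min_support,
                purity_threshold=config.purity_threshold,
            )
            summary["n_clades_labeled"] = len(assignment.clades)
            summary["clade_labels"] = {
                c.clade_id: {
                    "label": c.label,
                    "n_members": len(c.members),
                    "purity": round(c.purity, 6),
                    "yellow_flags": list(c.yellow_flags),
                }
                for c in assignment.clades
            }
        else:
            logger.info("fewer than 3 records; tree stage skipped")
            summary["n_clades_labeled"] = 0

    with stage("recovery"):
        if truth is not None:
            report = truth_accuracy(calls, truth)
            summary["label_accuracy"] = report.label_accuracy
            summary["census_error_total"] = sum(report.census_error.values())
            summary["loss_clade_detected"] = report.loss_clade_detected

    with stage("summary"):
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        # outdir is implied by the file's location; omitting it keeps the
        # echoed config byte-identical across runs into different directories
        (outdir / "config.json").write_text(config.to_json(include_outdir=False) + "\n")
    logger.info("done")
    for handler in logger.handlers:
        handler.close()
    logger.handlers.clear()
    return summary
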