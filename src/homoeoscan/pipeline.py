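"""End-to-end orchestration: pair -> quantify -> classify -> plot -> blocks.

Every stage logs a genes-in / genes-out audit line, the resolved
configuration (all defaults filled) is persisted next to the outputs, and
reruns with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats as iof
from .blocks import aneuploidy_screen, call_blocks, direction_bias, he_frequency
from .dosage import classify_panel, split_call_tables
from .pairing import attach_order, pairs_to_groups, reciprocal_best_pairs
from .quantify import compute_rpkm, filter_low_expression
from .tdtp import encode_cmyk, render_tdtp
from .types import ExpressionPanel, HomoeoscanError, ValidationError

logger = logging.getLogger("homoeoscan")

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(HomoeoscanError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Resolved parameters for a full run.

    Thresholds default to the published operating point: RBH E-value
    1e-30, low-abundance filter 0.4 RPKM (mRNA-seq) or 0.01 (DNA
    coverage), t-test alpha 0.01; block calling uses min_run 10 genes with
    max_gap 2.
    """

    out_dir: str
    mode: str = "mrnaseq"
    # inputs: either a ready RPKM matrix or counts + lengths + totals
    counts: str | None = None
    gene_lengths: str | None = None
    aligned_totals: str | None = None
    rpkm: str | None = None
    sample_sheet: str | None = None
    gene_order: str | None = None
    groups: str | None = None
    alignments: dict = field(default_factory=dict)  # "A-C": path, "C-A": path
    ordering_genome: str = "C"
    max_evalue: float = 1e-30
    min_mean_rpkm: float | None = None  # default by mode
    alpha: float = 0.01
    min_run: int = 10
    max_gap: int = 2
    channel_map: dict | None = None
    tile_size: tuple = (2, 2)
    chromosome_gap: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("mrnaseq", "dnaseq"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        for name in ("max_evalue", "alpha"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.min_mean_rpkm is None:
            self.min_mean_rpkm = 0.4 if self.mode == "mrnaseq" else 0.01

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["tile_size"] = list(self.tile_size)
        return d


def _audit(log: list, stage: str, n_in: int, n_out: int, note: str = "") -> None:
    line = f"{stage}: in={n_in} out={n_out}" + (f" ({note})" if note else "")
    logger.info(line)
    log.append(line)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write all outputs under ``config.out_dir``.

    Returns the run directory. Any stage failure raises
    :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit: list[str] = []
    stage = "setup"
    try:
        # ---- pair ------------------------------------------------------
        stage = "pair"
        order_table = iof.read_gene_order(config.gene_order)
        if config.groups:
            groups = iof.read_groups(config.groups)
            _audit(audit, stage, len(groups), len(groups), "groups supplied")
        else:
            keys = sorted(config.alignments)
            if len(keys) != 2:
                raise ValidationError(
                    "need exactly two alignment tables (both directions) "
                    "or a precomputed groups file"
                )
            hits = {k: iof.read_alignment_table(config.alignments[k]) for k in keys}
            g1, g2 = keys[0].split("-")
            pairs = reciprocal_best_pairs(
                hits[f"{g1}-{g2}"], hits[f"{g2}-{g1}"], config.max_evalue
            )
            raw_groups = pairs_to_groups(
                pairs, tuple(sorted((g1, g2))), config.ordering_genome
            )
            groups, excluded = attach_order(
                raw_groups, order_table, config.ordering_genome
            )
            _audit(audit, stage, len(raw_groups), len(groups),
                   f"{len(excluded)} unplaced")
        groups, excluded = attach_order(groups, order_table, config.ordering_genome)
        if excluded:
            _audit(audit, "order", len(groups) + len(excluded), len(groups),
                   f"{len(excluded)} unplaced")
        iof.write_groups(groups, out / "groups.tsv")

        # ---- quantify --------------------------------------------------
        stage = "quantify"
        sheet = iof.read_sample_sheet(config.sample_sheet)
        if config.rpkm:
            values = iof.read_expression_matrix(config.rpkm)
            panel = ExpressionPanel(
                values=values[sheet.sample_ids], sample_sheet=sheet,
                assay=config.mode,
            )
        else:
            counts = iof.read_expression_matrix(config.counts)
            lengths = iof.read_gene_lengths(config.gene_lengths)
            totals = iof.read_aligned_totals(config.aligned_totals)
            panel = compute_rpkm(
                counts[sheet.sample_ids], lengths, totals,
                sample_sheet=sheet, assay=config.mode,
            )
        retained, removed, rep = filter_low_expression(
            panel, groups, config.min_mean_rpkm
        )
        _audit(audit, stage, rep["groups_in"], rep["groups_retained"],
               f"filter < {rep['min_mean_rpkm']} RPKM")
        iof.write_expression_matrix(panel.values, out / "rpkm.tsv")
        pd.DataFrame(
            {"group_id": [g.group_id for g in removed]}
        ).to_csv(out / "removed_groups.tsv", sep="\t", index=False)

        # ---- classify --------------------------------------------------
        stage = "classify"
        calls = classify_panel(panel, retained, alpha=config.alpha)
        calls.to_csv(out / "dosage_calls.tsv", sep="\t", index=False,
                     float_format="%.6g")
        for name, sub in split_call_tables(calls).items():
            sub.to_csv(out / f"calls_{name}.tsv", sep="\t", index=False,
                       float_format="%.6g")
        _audit(audit, stage, len(retained),
               int((calls["category"] != "No difference").sum()),
               "non-'No difference' calls")

        # ---- plot ------------------------------------------------------
        stage = "plot"
        from .tdtp import normalize_abundance

        norm = normalize_abundance(panel, retained)
        spec = encode_cmyk(
            norm, retained, channel_map=config.channel_map,
            row_order=panel.sample_sheet.sample_ids,
        )
        render_tdtp(spec, out / "tdtp.png", tile_size=config.tile_size,
                    chromosome_gap=config.chromosome_gap)
        render_tdtp(spec, out / "tdtp.svg", tile_size=config.tile_size,
                    chromosome_gap=config.chromosome_gap)
        spec.to_frame().to_csv(out / "tdtp_tiles.tsv", sep="\t", index=False,
                               float_format="%.6g")
        _audit(audit, stage, len(retained), len(retained))

        # ---- callblocks ------------------------------------------------
        stage = "callblocks"
        blocks = call_blocks(calls, min_run=config.min_run,
                             max_gap=config.max_gap)
        iof.write_he_blocks_tsv(blocks, out / "he_blocks.tsv")
        iof.write_he_blocks_bed(blocks, out / "he_blocks.bed")
        freq = he_frequency(blocks, retained, panel.sample_sheet.accessions)
        freq.to_csv(out / "he_frequency.tsv", sep="\t", index=False,
                    float_format="%.6g")
        aneu = aneuploidy_screen(calls)
        aneu.to_csv(out / "aneuploidy.tsv", sep="\t", index=False,
                    float_format="%.6g")
        bias = direction_bias(blocks)
        summary = {
            "n_groups": len(retained),
            "n_blocks": len(blocks),
            "direction_bias": {k: int(v) for k, v in bias.items()},
            "n_aneuploidies": int(len(aneu)),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        _audit(audit, stage, len(calls), len(blocks), "blocks")
    except HomoeoscanError as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (out / "audit.log").write_text("\n".join(audit) + "\n")
    (out / "config.resolved.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True)
    )
    return out
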