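"""End-to-end orchestration on synthetic fixtures.

`run_demo` generates synthetic stacks, sections and counts from a single
seed, runs every quantification stage, and writes the study-style result
tables (percent positive per group, hydraulic-radius summary, DE gene
counts, stereology estimate) plus a markdown report.  `run_stage` runs a
single named stage from a config dict and records a JSON provenance
sidecar (config hash, seed, package version) next to its outputs.

All randomness flows from the single top-level seed; per-dataset seeds
are derived deterministically from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, morphometry, stereology, transcriptomics
from . import synthetic_data as sd
from . import transfer_quant as tq

__all__ = ["run_demo", "run_stage", "StageError", "STAGES"]

STAGES = ("simulate", "morph", "transfer", "rnaseq", "stereology")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and its config."""

    def __init__(self, stage: str, config: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}\nconfig: {config}")
        self.stage = stage
        self.config = config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _provenance(out_dir: Path, stage: str, config: dict, seed: int) -> None:
    sidecar = dict(stage=stage, seed=seed, config=config,
                   config_hash=_config_hash(config), version=__version__)
    (out_dir / f"{stage}.provenance.json").write_text(
        json.dumps(sidecar, indent=1, default=str))


def _seed_for(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: dict, out_dir: Path) -> dict:
    seed = int(config.get("seed", 0))
    stack_cfg = sd.StackSimConfig(seed=_seed_for(seed, "stack"),
                                  **config.get("stack", {}))
    section_cfg = sd.SectionSimConfig(seed=_seed_for(seed, "section"),
                                      **config.get("section", {}))
    count_cfg = sd.CountSimConfig(seed=_seed_for(seed, "counts"),
                                  **config.get("counts", {}))
    stack, stack_truth = sd.make_confocal_stack(stack_cfg)
    section, section_truth = sd.make_section_image(section_cfg)
    cm, count_truth = sd.make_count_matrix(count_cfg)

    io.write_stack(out_dir / "stack.tiff", stack)
    stack_truth.cells.to_csv(out_dir / "stack_truth.csv", index=False)
    io.write_section(out_dir / "section.tiff", section)
    section_truth.cells.to_csv(out_dir / "section_truth.csv", index=False)
    io.write_counts(out_dir / "counts.tsv", cm, out_dir / "samples.csv")
    count_truth.genes.to_csv(out_dir / "count_truth.csv", index=False)
    return dict(stack="stack.tiff", section="section.tiff", counts="counts.tsv")


def _stage_morph(config: dict, out_dir: Path) -> dict:
    section = io.read_section(config["section"])
    regions = morphometry.segment_cell_bodies(
        section, area_min_px=int(config.get("area_min_px", morphometry.AREA_MIN_PX)))
    selected = morphometry.select_cells(regions, mode=config.get("mode", "auto"))
    records = morphometry.measure_regions(regions, section.pixel_size,
                                          selected_ids=selected)
    records.to_csv(out_dir / "morphometry.csv", index=False)
    return dict(n_regions=len(regions), n_selected=len(selected),
                table="morphometry.csv")


def _stage_transfer(config: dict, out_dir: Path) -> dict:
    if "channel_map" not in config and "channels" not in config:
        raise KeyError("transfer stage requires a 'channel_map' (or 'channels' "
                       "JSON path) naming the dapi/green/red/syn channels")
    stack = io.read_stack(config["stack"])
    if "channels" in config:
        stack.channel_map = json.loads(Path(config["channels"]).read_text())
    elif "channel_map" in config:
        stack.channel_map = dict(config["channel_map"])
    table = tq.classify_stack(stack,
                              animal_id=str(config.get("animal_id", "a1")),
                              group=str(config.get("group", "control")))
    table.to_csv(out_dir / "cell_calls.csv", index=False)
    return dict(n_cells=len(table), table="cell_calls.csv")


def _stage_rnaseq(config: dict, out_dir: Path) -> dict:
    cm = io.read_counts(config["counts"], config["samples"])
    cm = transcriptomics.filter_min_cpm(cm)
    cm.norm_factors = transcriptomics.tmm_norm_factors(cm)
    lcpm = transcriptomics.log2cpm(cm)
    keep = transcriptomics.filter_group_mean(lcpm, cm.groups)
    cm2 = cm.subset_genes(keep)
    det = transcriptomics.de_test(cm2)
    sig, high = transcriptomics.apply_de_thresholds(det)
    det.drop(columns="gene_id").to_csv(out_dir / "de_table.csv")
    mds = transcriptomics.mds_coordinates(lcpm)
    mds.to_csv(out_dir / "mds_coordinates.csv", index_label="sample_id")
    return dict(n_genes_filtered=len(cm.counts), n_genes_tested=len(cm2.counts),
                n_significant=len(sig), n_high_magnitude=len(high),
                table="de_table.csv")


def _stage_stereology(config: dict, out_dir: Path) -> dict:
    counts = pd.read_csv(config["counts"])["Q"].to_numpy()
    design = (stereology.GRAFT_DESIGN if config.get("design", "graft") == "graft"
              else stereology.NIGRAL_DESIGN)
    if isinstance(config.get("design"), dict):
        design = stereology.StereologyDesign(**config["design"])
    n_hat = stereology.fractionator_estimate(counts, design)
    result = dict(sum_q=int(counts.sum()), n_estimate=n_hat,
                  ce_m0=stereology.gundersen_ce(counts, m=0),
                  ce_m1=stereology.gundersen_ce(counts, m=1))
    (out_dir / "stereology.json").write_text(json.dumps(result, indent=1))
    return result


_STAGE_FN = dict(simulate=_stage_simulate, morph=_stage_morph,
                 transfer=_stage_transfer, rnaseq=_stage_rnaseq,
                 stereology=_stage_stereology)


def run_stage(stage: str, config: dict, out_dir) -> dict:
    """Run one named stage; writes outputs plus a provenance sidecar."""
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        result = _STAGE_FN[stage](config, out_dir)
    except StageError:
        raise
    except Exception as exc:  # surface which stage failed, echo the config
        raise StageError(stage, config, exc) from exc
    _provenance(out_dir, stage, config, int(config.get("seed", 0)))
    return result


# ---------------------------------------------------------------------------
# demo
# ---------------------------------------------------------------------------


def run_demo(seed: int, out_dir, scale: str = "small") -> dict:
    """Generate synthetic data and run all stages end to end.

    ``scale='small'`` keeps the demo quick (small images, few cells).
    Writes result tables (CSV) and a markdown report; returns the report
    quantities as a dict.  Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    small = scale == "small"

    # --- transfer: one small stack per simulated animal/group --------------
    groups = {"control": 0.2, "LPS": 0.5, "IL4": 0.15}
    calls = []
    for gi, (group, frac) in enumerate(groups.items()):
        for animal in range(2):
            cfg = sd.StackSimConfig(
                seed=_seed_for(seed, f"stack:{group}:{animal}"),
                width=256 if small else 1024, height=256 if small else 1024,
                n_z=16 if small else 80, n_cells=8 if small else 10,
                frac_positive=frac)
            stack, _ = sd.make_confocal_stack(cfg)
            calls.append(tq.classify_stack(stack, animal_id=f"{group}_{animal}",
                                           group=group))
    table = pd.concat(calls, ignore_index=True)
    per_animal, per_group = tq.percent_positive(table)
    per_group.to_csv(out_dir / "percent_positive_per_group.csv", index=False)

    # --- morphometry: amoeboid-rich vs ramified-rich sections --------------
    morph_rows = []
    for group, (n_ram, n_amo) in {"LPS": (2, 8), "control": (8, 2)}.items():
        for animal in range(2):
            cfg = sd.SectionSimConfig(
                seed=_seed_for(seed, f"section:{group}:{animal}"),
                width=512 if small else 768, height=512 if small else 768,
                n_ramified=n_ram // (2 if small else 1),
                n_amoeboid=n_amo // (2 if small else 1))
            section, truth = sd.make_section_image(cfg)
            for cid, mask in truth.masks.items():
                rec = morphometry.hydraulic_radius(mask, section.pixel_size,
                                                   cell_id=cid)
                morph_rows.append(dict(group=group, animal_id=f"{group}_{animal}",
                                       **rec.__dict__))
    morph = pd.DataFrame(morph_rows)
    morph_summary = morphometry.activation_index_summary(morph)
    morph_summary.to_csv(out_dir / "hydraulic_radius_summary.csv", index=False)

    # --- rnaseq -------------------------------------------------------------
    cm, _ = sd.make_count_matrix(sd.CountSimConfig(
        seed=_seed_for(seed, "counts"), n_genes=1000 if small else 5000))
    cm = transcriptomics.filter_min_cpm(cm)
    cm.norm_factors = transcriptomics.tmm_norm_factors(cm)
    keep = transcriptomics.filter_group_mean(transcriptomics.log2cpm(cm), cm.groups)
    det = transcriptomics.de_test(cm.subset_genes(keep))
    sig, high = transcriptomics.apply_de_thresholds(det)
    det.drop(columns="gene_id").to_csv(out_dir / "de_table.csv")

    # --- stereology ---------------------------------------------------------
    rng = np.random.default_rng(_seed_for(seed, "stereo"))
    pts = stereology.simulate_point_population(3000, (1000, 1000, 600), rng)
    q = stereology.sample_fractionator_counts(pts, (1000, 1000, 600),
                                              stereology.GRAFT_DESIGN, rng)
    n_hat = stereology.fractionator_estimate(q, stereology.GRAFT_DESIGN)

    report = dict(
        seed=seed,
        percent_positive={r["group"]: round(r["mean"], 2)
                          for _, r in per_group.iterrows()},
        hydraulic_radius={r["group"]: round(r["mean"], 3)
                          for _, r in morph_summary.iterrows()},
        n_genes_tested=int(len(det)),
        n_significant=int(len(sig)),
        n_high_magnitude=int(len(high)),
        stereology_estimate=round(n_hat, 1),
        stereology_ce_m1=round(stereology.gundersen_ce(q, m=1), 4),
    )
    lines = ["# synspread demo report", "",
             f"seed: {seed}", "",
             "## Percent huα-syn-positive cells per group (mean over animals)"]
    lines += [f"- {g}: {v}%" for g, v in report["percent_positive"].items()]
    lines += ["", "## Hydraulic radius (area:perimeter, um) per group"]
    lines += [f"- {g}: {v}" for g, v in report["hydraulic_radius"].items()]
    lines += ["", "## Differential expression (LPS vs IL-4)",
              f"- genes tested: {report['n_genes_tested']}",
              f"- FDR < 0.05: {report['n_significant']}",
              f"- |log2FC| > 1: {report['n_high_magnitude']}",
              "", "## Stereology (graft design)",
              f"- estimated total: {report['stereology_estimate']}",
              f"- CE (m=1): {report['stereology_ce_m1']}", ""]
    (out_dir / "report.md").write_text("\n".join(lines))
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report
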