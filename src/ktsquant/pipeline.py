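"""Config-driven end-to-end runs.

A run config (JSON or YAML-compatible mapping) names the inputs of either
pipeline arm and the comparisons to make:

.. code-block:: json

    {
      "seed": 1,
      "junction_spec": { "strand": "+", "donor_minus": 1000, "acceptor": 2000 },
      "reads": {
        "simulate": {
          "groups": [
            {"name": "XY_WT", "genotype": "WT/WT", "n_cells": 200},
            {"name": "XY_plusKTS_KO", "genotype": "FRASIER/FRASIER", "n_cells": 200}
          ],
          "depth": 100, "error_rate": 0.02, "compensation": true
        }
      },
      "images": { "simulate": {"n_nuclei": [6, 10], "marker_positive_fraction": 0.4} },
      "comparisons": [
        {"kind": "fold_change", "a": "XY_WT", "b": "XY_plusKTS_KO"},
        {"kind": "dose_trend", "groups": ["XY_compound", "XY_plusKTS_KO"]}
      ]
    }

``reads`` may instead point at existing alignments
(``{"alignments": "x.sam", "dialect": "SAM", "cell_labels": "labels.tsv"}``)
and ``images`` at an existing TIFF
(``{"tiff": "scene.tiff", "pixel_size_um": 0.5}``). All inputs are
validated before any stage runs; outputs are TSV tables plus a JSON
manifest that fully determines a re-run.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .alignio import load_alignments, write_alignments
from .genotypes import GenotypeModel
from .image_sim import (
    ImageSceneConfig,
    random_scene_config,
    read_image_stack,
    simulate_basescope_image,
    write_image_stack,
)
from .imaging import (
    SegmentationParams,
    SpotParams,
    assign_spots,
    classify_marker_positive,
    detect_spots_multichannel,
    nucleus_centroids,
    per_nucleus_area,
    segment_nuclei,
)
from .junctions import JunctionSpec, add_ratio_columns, aggregate_groups, classify_reads, count_cells
from .read_sim import simulate_population
from .stats import compare_table, dose_trend


class ConfigError(ValueError):
    """Raised when a run config is incomplete or references missing files."""


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _validate(cfg: dict) -> None:
    """Fail fast on missing inputs, before anything is computed or written."""
    reads = cfg.get("reads")
    if reads is not None and "simulate" not in reads:
        p = reads.get("alignments")
        if p is None:
            raise ConfigError("reads section needs 'simulate' or 'alignments'")
        if not Path(p).exists():
            raise ConfigError(f"alignments file not found: {p}")
        labels = reads.get("cell_labels")
        if labels is not None and not Path(labels).exists():
            raise ConfigError(f"cell_labels file not found: {labels}")
    images = cfg.get("images")
    if images is not None and "simulate" not in images:
        p = images.get("tiff")
        if p is None:
            raise ConfigError("images section needs 'simulate' or 'tiff'")
        if not Path(p).exists():
            raise ConfigError(f"tiff file not found: {p}")
    if reads is None and images is None:
        raise ConfigError("config has neither a 'reads' nor an 'images' section")


def _reads_stage(cfg: dict, spec: JunctionSpec, seed: int, out: Path) -> dict:
    reads_cfg = cfg["reads"]
    if "simulate" in reads_cfg:
        sim = reads_cfg["simulate"]
        groups = {}
        for g in sim["groups"]:
            model = GenotypeModel.from_string(
                g["genotype"],
                wt_plus_fraction=sim.get("wt_plus_fraction", 0.5),
                compensation=sim.get("compensation", False),
                name=g.get("name", g["genotype"]),
            )
            groups[g.get("name", g["genotype"])] = (model, int(g["n_cells"]))
        records, truth = simulate_population(
            groups,
            depth=sim.get("depth", 50.0),
            error_rate=sim.get("error_rate", 0.0),
            spec=spec,
            seed=seed,
        )
        dialect = sim.get("dialect", "TSV")
        aln_path = out / ("alignments.sam" if dialect == "SAM" else "alignments.tsv")
        write_alignments(records, aln_path, dialect)
        truth.to_csv(out / "cell_truth.tsv", sep="\t", index=False)
        labels = truth[["cell", "group", "genotype"]]
    else:
        records = load_alignments(reads_cfg["alignments"], reads_cfg.get("dialect"))
        labels_path = reads_cfg.get("cell_labels")
        labels = pd.read_csv(labels_path, sep="\t") if labels_path else None

    calls = classify_reads(records, spec)
    counts = count_cells(calls, dedup_umi=cfg.get("dedup_umi", True), cell_labels=labels)
    counts = add_ratio_columns(counts, ci_method=cfg.get("ci_method", "wilson"))
    counts.to_csv(out / "cell_counts.tsv", sep="\t", index=False)

    keys = cfg.get("group_keys") or (["group"] if labels is not None and "group" in counts else None)
    if keys:
        groups_table = aggregate_groups(counts, keys)
        groups_table.to_csv(out / "group_summary.tsv", sep="\t", index=False)

    summary = {"n_reads": len(records), "n_cells": int(len(counts))}
    comparisons = cfg.get("comparisons", [])
    if comparisons and labels is not None:
        group_col = cfg.get("group_col", "group")
        fc_pairs = [
            (c["a"], c["b"]) for c in comparisons if c.get("kind", "fold_change") == "fold_change"
        ]
        if fc_pairs:
            table = compare_table(
                counts,
                group_col,
                fc_pairs,
                value_col=cfg.get("value_col", "n_minus"),
                seed=seed + 101,
            )
            table.to_csv(out / "comparisons.tsv", sep="\t", index=False)
            summary["comparisons"] = table.to_dict(orient="records")
        trend_rows = []
        for c in comparisons:
            if c.get("kind") != "dose_trend":
                continue
            order = c["groups"]  # low dose first
            sub = counts[counts[group_col].isin(order)]
            dose = sub[group_col].map({g: i for i, g in enumerate(order)})
            res = dose_trend(
                sub[cfg.get("value_col", "n_minus")], dose, seed=seed + 202
            )
            trend_rows.append(
                {"groups": "<".join(order), "statistic": res.statistic, "p_value": res.p_value}
            )
        if trend_rows:
            pd.DataFrame(trend_rows).to_csv(out / "dose_trend.tsv", sep="\t", index=False)
            summary["dose_trend"] = trend_rows
    return summary


def _images_stage(cfg: dict, seed: int, out: Path) -> dict:
    img_cfg = cfg["images"]
    if "simulate" in img_cfg:
        sim = dict(img_cfg["simulate"])
        scene_kw = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in sim.items()
            if k != "scene"
        }
        if "scene" in sim:
            scene = ImageSceneConfig.from_json(sim["scene"])
        else:
            scene = random_scene_config(seed=seed, **scene_kw)
        channels, nuclei_truth, dots_truth = simulate_basescope_image(scene)
        pixel_size = scene.pixel_size
        write_image_stack(channels, out / "scene.tiff", pixel_size)
        nuclei_truth.to_csv(out / "nuclei_truth.tsv", sep="\t", index=False)
        dots_truth.to_csv(out / "dots_truth.tsv", sep="\t", index=False)
    else:
        channel_map = img_cfg.get("channels")
        channels, pixel_size = read_image_stack(
            img_cfg["tiff"], channel_map, img_cfg.get("pixel_size_um")
        )

    seg = SegmentationParams(**cfg.get("segmentation", {}))
    spot = SpotParams(**cfg.get("spot_detection", {}))
    labels = segment_nuclei(channels["DAPI"], seg)
    nucleus_centroids(labels).to_csv(out / "nuclei.tsv", sep="\t", index=False)
    spots = detect_spots_multichannel(channels, pixel_size, spot)
    spots = assign_spots(spots, labels, pixel_size, cfg.get("max_dist_um", 10.0))
    spots.to_csv(out / "spots.tsv", sep="\t", index=False)
    per_nuc = per_nucleus_area(spots, labels)
    per_nuc.to_csv(out / "per_nucleus_area.tsv", sep="\t", index=False)

    summary = {
        "n_nuclei": int(labels.max()),
        "n_spots": int(len(spots)),
        "total_area_um2": float(spots["area_um2"].sum()) if len(spots) else 0.0,
    }
    if "MARKER" in channels:
        table, marker = classify_marker_positive(
            labels, channels["MARKER"], cfg.get("marker_rule", "otsu")
        )
        table.to_csv(out / "marker_calls.tsv", sep="\t", index=False)
        summary["marker"] = asdict(marker)
    return summary


def run_pipeline(config, out_dir) -> dict:
    """Execute the configured stages and write all outputs under
    ``out_dir``. Returns the run manifest (also written as
    ``manifest.json``)."""
    cfg = _load_config(config)
    _validate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    spec = JunctionSpec.from_json(cfg["junction_spec"]) if "junction_spec" in cfg else JunctionSpec()

    manifest = {
        "ktsquant_version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "config": cfg,
        "junction_spec": spec.to_dict(),
        "stages": {},
    }
    if cfg.get("reads") is not None:
        manifest["stages"]["reads"] = _reads_stage(cfg, spec, seed, out)
    if cfg.get("images") is not None:
        manifest["stages"]["images"] = _images_stage(cfg, seed, out)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    lines = [f"ktsquant {__version__} run (seed={seed})"]
    for stage, info in manifest["stages"].items():
        lines.append(f"[{stage}]")
        for key, val in info.items():
            lines.append(f"  {key}: {val}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return manifest
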