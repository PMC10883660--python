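"""End-to-end orchestration: synthesize -> extract -> tune -> binocular ->
voxels -> overlap, with deterministic seeding and a run manifest.

Each stage reads only the files written by earlier stages, so the verbs
can be re-run individually. Analysis constants default to the study
values: the 2-SD response criterion, 1,000 shuffles at alpha = 0.05 for
direction selectivity, a 10,000-resample bootstrap null for the matching
index with Bonferroni correction over six comparisons (99.17th
percentile), and a 10-pixel KDE kernel.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as omio
from .binocular import binocular_analysis
from .overlap import (KdeConfig, PIXEL_UM, match_analysis, mirror_pool,
                      pairing_claim, skeleton_endpoints)
from .protocol import generate_protocol
from .responses import extract_responses, ResponseTable
from .synthetic import (PopulationSpec, generate_population,
                        generate_skeletons, generate_voxel_volume)
from .tuning import tuning_analysis
from .voxels import VoxelCategoryConfig, build_voxel_maps

__all__ = ["RunConfig", "StageError", "run_pipeline", "summarize",
           "format_fraction"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the study constants."""

    seed: int = 0
    outdir: str = "olivemap_run"
    # protocol
    monocular_blocks: bool = True
    include_conv_div: bool = True
    frame_period_s: float = 0.3456
    phase_durations_s: tuple[float, float, float] = (6.0, 10.0, 5.4)
    # population overrides (class name -> neuron count); None keeps defaults
    class_counts: dict | None = None
    n_repetitions: int = 3
    noise_sd: float = 3.0
    # analysis constants
    sd_criterion: float = 2.0
    n_shuffles: int = 1000
    alpha: float = 0.05
    n_boot: int = 10000
    n_comparisons: int = 6
    kernel_sd_px: float = 10.0
    voxel_size_um: float = 2.0
    voxel_thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("sd_criterion", "n_shuffles", "alpha", "n_boot",
                     "n_comparisons", "kernel_sd_px", "voxel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "phase_durations_s" in raw:
            raw["phase_durations_s"] = tuple(raw["phase_durations_s"])
        return cls(**raw)

    def population_spec(self) -> PopulationSpec:
        spec = PopulationSpec(seed=self.seed, n_repetitions=self.n_repetitions,
                              noise_sd=self.noise_sd)
        if self.class_counts is not None:
            for name, n in self.class_counts.items():
                if name not in spec.classes:
                    raise ValueError(f"unknown population class {name!r}")
                spec.classes[name].n = int(n)
        return spec

    def voxel_config(self) -> VoxelCategoryConfig:
        return VoxelCategoryConfig(**self.voxel_thresholds)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    spec = config.population_spec()
    if sum(c.n for c in spec.classes.values()) == 0:
        raise StageError("simulate", "empty_population",
                         "configured population has zero neurons")
    protocol = generate_protocol(
        monocular_blocks=config.monocular_blocks,
        include_conv_div=config.include_conv_div,
        frame_period_s=config.frame_period_s,
        phase_durations_s=config.phase_durations_s, seed=config.seed)
    dataset = generate_population(spec, protocol=protocol)
    dataset.validate()
    omio.save_dataset(dataset, outdir / "dataset.h5")
    dataset.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    dataset.anatomy.to_csv(outdir / "anatomy.csv", index=False)
    dataset.function_terminals.to_csv(outdir / "function_terminals.csv",
                                      index=False)
    (outdir / "protocol.json").write_text(protocol.to_json())
    return {"n_neurons": len(dataset.neurons),
            "n_epochs": len(protocol.epochs)}


def stage_extract(config: RunConfig, outdir: Path) -> dict:
    dataset = omio.load_dataset(outdir / "dataset.h5")
    table = extract_responses(dataset.neurons, dataset.protocol)
    table.to_csv(outdir / "responses.csv")
    active = table.active("both" if config.monocular_blocks else None)
    return {"n_rows": len(table.df), "n_active": int(active.sum()),
            "n_neurons": int(active.size)}


def stage_tuning(config: RunConfig, outdir: Path) -> dict:
    dataset = omio.load_dataset(outdir / "dataset.h5")
    table = ResponseTable.from_csv(outdir / "responses.csv")
    df = tuning_analysis(dataset.neurons, dataset.protocol, table, eye="both",
                         n_shuffles=config.n_shuffles, alpha=config.alpha,
                         seed=config.seed + 1)
    df.to_csv(outdir / "tuning.csv", index=False)
    counts = df[df["selective"]]["rotation_class"].value_counts().to_dict()
    return {"n_active": int(df["active"].sum()),
            "n_selective": int(df["selective"].sum()),
            "class_counts": {k: int(v) for k, v in counts.items()}}


def stage_binocular(config: RunConfig, outdir: Path) -> dict:
    if not config.monocular_blocks:
        return {"skipped": "no monocular blocks in the protocol"}
    dataset = omio.load_dataset(outdir / "dataset.h5")
    table = ResponseTable.from_csv(outdir / "responses.csv")
    df = binocular_analysis(dataset.neurons, dataset.protocol, table,
                            n_shuffles=config.n_shuffles, alpha=config.alpha,
                            seed=config.seed + 2)
    df.to_csv(outdir / "binocular.csv", index=False)
    defined = df["monocular_index"].dropna()
    groups = df["quadrant_group"].value_counts().to_dict()
    return {"n_analyzed": len(df),
            "median_monocular_index": (float(defined.median())
                                       if len(defined) else None),
            "quadrant_counts": {k: int(v) for k, v in groups.items()}}


def stage_voxels(config: RunConfig, outdir: Path) -> dict:
    dataset = omio.load_dataset(outdir / "dataset.h5")
    volume = generate_voxel_volume(dataset,
                                   voxel_size_um=config.voxel_size_um,
                                   seed=config.seed + 3)
    maps = build_voxel_maps(volume, config=config.voxel_config())
    omio.save_volume_tiff(maps.mask, outdir / "voxel_mask.tif")
    counts = {}
    for name, vol in maps.categories.items():
        omio.save_volume_tiff(vol, outdir / f"voxels_{name}.tif")
        omio.save_volume_tiff(maps.projections[name],
                              outdir / f"projection_{name}.tif")
        counts[name] = int(vol.sum())
    return {"n_labeled": int(maps.mask.sum()), "category_counts": counts}


def _soma_points_px(dataset, tuning_df) -> dict[str, np.ndarray]:
    """Functional soma classes (forward/backward PDs) in the lateral
    (rc x dv) projection, pixel units."""
    sel = tuning_df[tuning_df["selective"]].copy()
    cos = np.cos(np.deg2rad(sel["pd_deg"].to_numpy(dtype=float)))
    cents = {n.id: n.centroid_um for n in dataset.neurons}
    pts = np.stack([cents[i] for i in sel["neuron_id"]]) if len(sel) else \
        np.empty((0, 3))
    out = {}
    for name, keep in (("forward", cos > 0), ("backward", cos < 0)):
        p = pts[keep][:, [0, 2]] / PIXEL_UM  # (rc, dv) in px
        out[name] = p
    return out


def _anatomy_soma_px(dataset) -> dict[str, np.ndarray]:
    out = {}
    for name in ("unipolar", "multipolar"):
        p = dataset.points(name, kind="soma")[:, [0, 2]] / PIXEL_UM
        out[name] = p
    return out


def _terminal_endpoints_px(dataset, seed) -> dict[str, np.ndarray]:
    """Anatomical terminal endpoints per class: skeletonize each class's
    terminals from its somata, rasterize the z-projection, extract
    endpoints (pixel units, common canvas)."""
    rng = np.random.default_rng(seed)
    all_pts = np.vstack([dataset.points(n, "terminal")
                         for n in ("unipolar", "multipolar")] +
                        [dataset.points(n, "soma")
                         for n in ("unipolar", "multipolar")])
    origin = all_pts[:, [0, 1]].min(axis=0) / PIXEL_UM - 4
    shape = tuple((all_pts[:, [0, 1]].max(axis=0) / PIXEL_UM
                   - origin + 8).astype(int))
    out = {}
    for name in ("unipolar", "multipolar"):
        somata = dataset.points(name, kind="soma")
        terms = dataset.points(name, kind="terminal")
        per = max(1, len(terms) // max(1, len(somata)))
        groups, k = [], 0
        for i in range(len(somata)):
            hi = len(terms) if i == len(somata) - 1 else k + per
            if k >= len(terms):
                break
            groups.append(terms[k:hi])
            k = hi
        skels = generate_skeletons(groups, somata[:len(groups)],
                                   seed=rng.integers(2**31))
        eps = []
        for sk in skels:
            mask = sk.rasterize(axes=(0, 1), scale_um=PIXEL_UM,
                                origin_um=origin * PIXEL_UM,
                                shape=shape)
            # canvas indices -> absolute pixel coordinates
            eps.append(skeleton_endpoints(mask) + origin)
        out[name] = np.vstack(eps).astype(float)
    return out


def _function_terminals_px(dataset) -> dict[str, np.ndarray]:
    out = {}
    for name in ("forward", "backward"):
        sel = dataset.function_terminals
        p = sel[sel["class_label"] == name][["rc_um", "lr_um"]].to_numpy()
        out[name] = p / PIXEL_UM
    return out


def stage_overlap(config: RunConfig, outdir: Path) -> dict:
    dataset = omio.load_dataset(outdir / "dataset.h5")
    tuning_df = pd.read_csv(outdir / "tuning.csv")
    kde = KdeConfig(kernel_sd=config.kernel_sd_px)
    report = {}

    # soma region: lateral projection, no midline pooling needed
    anat_soma = _anatomy_soma_px(dataset)
    func_soma = _soma_points_px(dataset, tuning_df)
    if min(len(v) for v in func_soma.values()) < 2:
        raise StageError("overlap", "too_few_points",
                         "need >= 2 selective neurons per functional class")
    res_soma = match_analysis(anat_soma, func_soma, n_boot=config.n_boot,
                              alpha=config.alpha,
                              n_comparisons=config.n_comparisons,
                              config=kde, seed=config.seed + 4)
    report["soma"] = res_soma.to_dict()

    # neuropil region: z projection, mirror-pooled about the midline
    anat_np = _terminal_endpoints_px(dataset, seed=config.seed + 5)
    func_np = _function_terminals_px(dataset)
    if min(len(v) for v in func_np.values()) < 2:
        raise StageError("overlap", "too_few_points",
                         "need >= 2 functional terminal points per class")
    anat_np = {k: mirror_pool(v, midline=0.0, axis=1)
               for k, v in anat_np.items()}
    func_np = {k: mirror_pool(v, midline=0.0, axis=1)
               for k, v in func_np.items()}
    res_np = match_analysis(anat_np, func_np, n_boot=config.n_boot,
                            alpha=config.alpha,
                            n_comparisons=config.n_comparisons,
                            config=kde, seed=config.seed + 6)
    report["neuropil"] = res_np.to_dict()
    report["pairing_significant"] = pairing_claim(
        [res_soma.significant, res_np.significant])
    _write_json(report, outdir / "overlap.json")
    return {"mi_soma": res_soma.mi, "mi_neuropil": res_np.mi,
            "pairing_significant": report["pairing_significant"]}


STAGES = [("simulate", stage_simulate), ("extract", stage_extract),
          ("tuning", stage_tuning), ("binocular", stage_binocular),
          ("voxels", stage_voxels), ("overlap", stage_overlap)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write the manifest and report.

    Identical config and seed give byte-identical table outputs. Any
    stage failure aborts with a :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # fail fast on an empty population before any stage writes output
    spec = config.population_spec()
    if sum(c.n for c in spec.classes.values()) == 0:
        raise StageError("validate", "empty_population",
                         "configured population has zero neurons")
    manifest = {"config": asdict(config), "stages": {}}
    report = {"seed": config.seed}
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            out = fn(config, outdir)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise StageError(name, "stage_failure", str(e)) from e
        manifest["stages"][name] = {"elapsed_s": round(time.perf_counter() - t0,
                                                       3), "outputs": out}
        report[name] = out
        log.info("stage %s done in %.2fs", name, manifest["stages"][name][
            "elapsed_s"])
    _write_json(manifest, outdir / "manifest.json")
    _write_json(report, outdir / "report.json")
    return report


def format_fraction(n: int, total: int, decimals: int = 0) -> str:
    """Fractions in the reporting style ``"891/1,106 (81%)"``.

    Integer percent for whole-population fractions (``decimals=0``), one
    decimal for subgroup fractions.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * n / total
    pct_str = f"{pct:.{decimals}f}".rstrip("0").rstrip(".") if decimals else \
        f"{round(pct):d}"
    return f"{n:,}/{total:,} ({pct_str}%)"


def summarize(report: dict) -> str:
    """Human-readable summary of a completed run report."""
    for key in ("extract", "tuning"):
        if key not in report:
            raise ValueError(f"incomplete report: missing stage {key!r}")
    lines = []
    ex, tu = report["extract"], report["tuning"]
    lines.append("active neurons: "
                 + format_fraction(ex["n_active"], ex["n_neurons"]))
    if tu["n_active"]:
        lines.append("direction-selective (of active): "
                     + format_fraction(tu["n_selective"], tu["n_active"]))
    for cls, n in sorted(tu.get("class_counts", {}).items()):
        lines.append(f"  {cls}: "
                     + format_fraction(n, tu["n_selective"], decimals=1))
    bi = report.get("binocular", {})
    if bi and "median_monocular_index" in bi and \
            bi["median_monocular_index"] is not None:
        lines.append(f"median monocular index: "
                     f"{bi['median_monocular_index']:.2f}")
    ov = report.get("overlap", {})
    if ov:
        lines.append(f"matching index (soma): {ov['mi_soma']:.3f}")
        lines.append(f"matching index (neuropil): {ov['mi_neuropil']:.3f}")
        verdict = "significant" if ov["pairing_significant"] else \
            "not significant"
        lines.append(f"anatomy/function pairing: {verdict} in both regions"
                     if ov["pairing_significant"] else
                     f"anatomy/function pairing: {verdict}")
    return "\n".join(lines)
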