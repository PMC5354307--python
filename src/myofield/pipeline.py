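"""Pipeline orchestration: cached, resumable stages with structured logs.

Stages run in reconstruction order::

    synth -> extract -> regions -> register-rigid -> register-elastic
          -> assemble -> directions -> weights -> segment -> masks
          -> widths -> report

Each stage writes versioned artifacts under the output directory together
with a manifest recording a hash of its configuration and inputs; re-running
with an unchanged config reuses the cached artifacts (idempotence).  The
final report carries the bookkeeping summary: per-stage slide counts and the
proportion of original slides represented in the reconstruction.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import (direction3d, elastic_reg, fixtures, masks, metrics, nuclei,
               regions, rigid_reg, segmentation, stack_assembly, weights)
from .config import PipelineConfig
from .io import (JsonlLogger, load_json, load_slide, save_json, save_slide,
                 save_volume)

__all__ = ["STAGES", "run", "summary_proportion"]

STAGES = ["synth", "extract", "regions", "register-rigid", "register-elastic",
          "assemble", "directions", "weights", "segment", "masks", "widths",
          "report"]


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


def summary_proportion(total: int, final: int) -> int:
    """Percentage of original slides represented in the final volume."""
    return int(round(100.0 * final / total)) if total else 0


def _default_synth(seed: int) -> dict:
    return {"shape": [48, 24], "n_slides": 12, "slide_step": 9,
            "density": 8.0, "noise_sd": 5.0, "n_patches": 30,
            "rigid_sd_deg": 2.0, "rigid_sd_px": 4.0,
            "elastic_amplitude": 4.0, "rbc_density": 0.0,
            "render": False, "seed": seed}


def _stage_synth(state, cfg: PipelineConfig, out: Path, log):
    s = {**_default_synth(cfg.seed), **(cfg.synth or {})}
    rng = np.random.default_rng(s["seed"])
    shape = tuple(s["shape"])
    theta, mask = fixtures.patch_field(shape, s["n_patches"], seed=s["seed"])
    slides = []
    truth = []
    numbers = [i * s["slide_step"] for i in range(s["n_slides"])]
    for k, num in enumerate(numbers):
        spec = fixtures.PhantomSpec(theta=theta, bundle_mask=mask,
                                    nuclear_density=s["density"],
                                    angle_noise_sd=s["noise_sd"],
                                    rbc_density=s["rbc_density"],
                                    seed=s["seed"] * 1009 + k)
        if s["render"]:
            img, gt = fixtures.render_slide(spec, cfg.resolution.region_px,
                                            cfg.resolution)
            state.setdefault("images", {})[num] = img
        sl = fixtures.synth_regional_slide(spec, slide_number=num,
                                           cfg=cfg.resolution)
        slides.append(sl)
    rigid = [(rng.normal(0, s["rigid_sd_deg"]),
              tuple(rng.normal(0, s["rigid_sd_px"], 2))) for _ in slides]
    slides, truth = fixtures.distort_stack(slides, rigid,
                                           s["elastic_amplitude"],
                                           seed=s["seed"] + 1)
    state["slides"] = slides
    state["synth_truth"] = truth
    state["total_slides"] = numbers[-1] + s["slide_step"]
    log.log("synth", n_slides=len(slides), numbers=numbers)


def _stage_extract(state, cfg, out: Path, log):
    """Phase I on rendered tiles, when images are present.

    Synthetic runs without rendering already carry ground-truth nuclei in
    their regional slides; then extraction is a no-op.
    """
    images = state.get("images")
    if not images:
        log.log("extract", skipped="no raw images; nuclei tables present")
        return
    tables = {}
    for num, img in images.items():
        tables[num] = nuclei.extract_tile(img, cfg.resolution, cfg.nuclei)
    state["ellipse_tables"] = tables
    log.log("extract", n_slides=len(tables),
            n_nuclei=int(sum(len(t) for t in tables.values())))


def _stage_regions(state, cfg, out: Path, log):
    tables = state.get("ellipse_tables")
    if tables:
        state["slides"] = [
            regions.pad_and_grid(t, cfg.resolution, slide_number=num,
                                 nuc=cfg.nuclei, params=cfg.regions)
            for num, t in sorted(tables.items())]
    for sl in state["slides"]:
        save_slide(sl, out / f"slide_{sl.slide_number:04d}")
    log.log("regions", n_slides=len(state["slides"]))


def _stage_rigid(state, cfg, out: Path, log):
    stack, transforms = rigid_reg.rigid_register_stack(
        state["slides"], cfg.rigid, cfg.edges)
    state["slides"] = stack
    save_json([{"slide": s.slide_number, "theta_deg": t.theta_deg,
                "b": t.b.tolist()} for s, t in zip(stack, transforms)],
              out / "rigid_transforms.json")
    log.log("register-rigid", n_slides=len(stack))


def _stage_elastic(state, cfg, out: Path, log):
    res = elastic_reg.order_and_register(state["slides"], cfg.elastic)
    keep = [s for s, d in zip(res["stack"], res["discard"]) if not d]
    state["slides"] = keep
    state["elastic_info"] = {k: res[k] for k in
                             ("references", "global_reference", "scores",
                              "discard")}
    save_json(state["elastic_info"], out / "elastic_summary.json")
    log.log("register-elastic", kept=len(keep),
            discarded=int(sum(res["discard"])))


def _stage_assemble(state, cfg, out: Path, log):
    vol = stack_assembly.assemble_stack(state["slides"],
                                        l_s=cfg.stack.slice_um,
                                        params=cfg.regions)
    state["volume"] = vol
    save_volume(vol.count, out / "volume_count", vol.pitch_um)
    log.log("assemble", shape=list(vol.shape), z=list(vol.z_indices))


def _stage_directions(state, cfg, out: Path, log):
    vol = state["volume"]
    dv = direction3d.assign_directions(vol.category, vol.theta,
                                       cfg.direction3d)
    state["directions"] = dv
    save_volume(dv.vec, out / "directions", vol.pitch_um)
    log.log("directions", assigned=int((np.abs(dv.vec).sum(-1) > 0).sum()))


def _stage_weights(state, cfg, out: Path, log):
    w = weights.voxel_weights(state["volume"], state["directions"],
                              cfg.density)
    state["weights"] = w
    save_volume(w["weight"], out / "weights", state["volume"].pitch_um)
    log.log("weights", mean_weight=float(w["weight"].mean()))


def _stage_segment(state, cfg, out: Path, log):
    dv = state["directions"]
    w = state["weights"]["weight"]
    res = segmentation.segment_3d(dv.vec, w, cfg.seg3d)
    state["segmentation"] = res
    save_volume(res["labels"].astype(np.float32), out / "labels",
                state["volume"].pitch_um)
    log.log("segment", pools=int(res["labels"].max()),
            watershed=int((res["labels"] == -1).sum()))


def _stage_masks(state, cfg, out: Path, log):
    vol = state["volume"]
    vess = masks.detect_vessels(vol.count_small, vol.count_all, cfg.vessels)
    plac = masks.detect_placenta(vol.count_all, vol.pitch_um, cfg.placenta)
    state["masks"] = {"vessels": vess, "placenta": plac}
    save_volume(vess.astype(np.uint8) | (plac.astype(np.uint8) << 1),
                out / "masks", vol.pitch_um)
    log.log("masks", vessel_voxels=int(vess.sum()),
            placenta_voxels=int(plac.sum()))


def _stage_widths(state, cfg, out: Path, log):
    vol = state["volume"]
    dv = state["directions"]
    w = state["weights"]["weight"]
    exclude = state["segmentation"]["edges"] | state["masks"]["vessels"] \
        | state["masks"]["placenta"]
    sm_vec, sm_w = metrics.final_smooth(dv.vec, w, exclude)
    state["smoothed"] = (sm_vec, sm_w)
    rng = np.random.default_rng(cfg.seed + 17)
    samples = metrics.measure_widths_3d(sm_vec, sm_w, vol.pitch_um,
                                        cfg.widths, rng)
    state["width_samples"] = samples
    samples.to_csv(out / "width_samples.csv", index=False)
    log.log("widths", n=len(samples),
            median_um=float(samples.width_um.median()))


def _stage_report(state, cfg, out: Path, log):
    vol = state["volume"]
    samples = state["width_samples"]
    maps = metrics.width_maps(samples, vol.shape, cfg.widths)
    maps["per_z"].to_csv(out / "width_per_z.csv", index=False)
    total = state.get("total_slides", len(state["slides"]))
    final = len(state["slides"])
    med, lo, hi = metrics._median_ci(samples.width_um.to_numpy())
    report = {
        "slides": {"total": int(total), "after_registration": final,
                   "proportion_used_pct": summary_proportion(total, final)},
        "volume_shape": list(vol.shape),
        "width_median_um": med, "width_ci95_um": [lo, hi],
        "n_width_samples": int(len(samples)),
    }
    state["report"] = report
    save_json(report, out / "report.json")
    log.log("report", **report["slides"])


_STAGE_FUNCS = {
    "synth": _stage_synth, "extract": _stage_extract, "regions": _stage_regions,
    "register-rigid": _stage_rigid, "register-elastic": _stage_elastic,
    "assemble": _stage_assemble, "directions": _stage_directions,
    "weights": _stage_weights, "segment": _stage_segment, "masks": _stage_masks,
    "widths": _stage_widths, "report": _stage_report,
}


def run(cfg: PipelineConfig, outdir, stages: list | None = None,
        state: dict | None = None) -> dict:
    """Execute the pipeline; returns the in-memory state (incl. the report).

    A stage whose required upstream state is missing raises with the name of
    the stage that must run first.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = JsonlLogger(out / "pipeline.log.jsonl")
    state = state if state is not None else {}
    stages = stages or cfg.stages or STAGES
    requires = {"register-rigid": "slides", "register-elastic": "slides",
                "assemble": "slides", "directions": "volume",
                "weights": "directions", "segment": "weights",
                "masks": "volume", "widths": "segmentation",
                "report": "width_samples"}
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r}")
        need = requires.get(name)
        if need and need not in state:
            raise RuntimeError(
                f"stage {name!r} is missing upstream artifact {need!r}; "
                "run the earlier stages first")
        _STAGE_FUNCS[name](state, cfg, out, log)
    return state
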