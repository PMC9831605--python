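"""End-to-end orchestration, Dice-based error flagging and the QC report.

The pipeline runs validate -> (optional) template shape injection ->
Laplace coordinate fields -> bidirectional warps -> layer surfaces ->
subfield labels -> morphometry -> QC, writing BIDS-derivatives-style
NIfTI/GIfTI artifacts plus machine-readable QC JSON and an HTML report.

Automated error flagging follows the Dice-overlap rule: a subject whose GM
segmentation has Dice overlap below 0.7 with a reference hippocampal mask
is flagged for manual inspection (strictly below: 0.70 exactly passes).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd

from . import gifti
from .core import (TissueLabelmap, UnfoldedSpaceSpec, flip_hemisphere,
                   read_labelmap, save_scalar_field, validate_labelmap,
                   write_labelmap)
from .injection import TemplateShape, inject
from .laplace import CoordFields, compute_coord_fields
from .morphometry import gyrification, mean_curvature, sample_to_surface, thickness
from .subfields import SubfieldAtlas, check_topology, fill_volumetric_subfields, label_vertices
from .surfaces import build_layer_surfaces, make_dg_surfaces
from .warps import build_native_to_unfolded, build_unfolded_to_native, write_itk_warp

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "QCResult", "StageError", "STAGES",
           "dice", "flag_low_dice", "run_pipeline", "qc_report"]

STAGES = ("validate", "inject", "fields", "warps", "surfaces", "subfields",
          "morphometry", "qc")


class StageError(RuntimeError):
    """Failure of a named pipeline stage; exit code is 10 + stage index."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.exit_code = 10 + STAGES.index(stage)
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    subject_id: str = "phantom"
    labelmap_path: str | Path | None = None  # None: pass a labelmap object
    hemisphere: str = "R"
    io_mode: str = "equivolume"
    densities: tuple[str, ...] = ("unfoldiso",)
    atlas: str | Path = "schematic"
    do_injection: bool = True
    dice_flag_threshold: float = 0.7
    reference_mask_path: str | Path | None = None
    quantitative_image: str | Path | None = None
    out_dir: str | Path = "unfoldcoords_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dice_flag_threshold < 1.0:
            raise ValueError("dice threshold must lie in (0,1)")


@dataclass
class QCResult:
    dice: float | None
    flagged: bool
    n_extrapolated_voxels: int = 0
    runtime_log: list[str] = dfield(default_factory=list)

    def to_dict(self) -> dict:
        return {"dice": self.dice, "flagged": self.flagged,
                "n_extrapolated_voxels": self.n_extrapolated_voxels,
                "runtime_log": self.runtime_log}


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        log.info("dice of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def flag_low_dice(seg_gm: np.ndarray, reference_mask: np.ndarray,
                  threshold: float = 0.7) -> QCResult:
    """Flag a segmentation whose Dice with the reference is strictly < threshold."""
    d = dice(seg_gm, reference_mask)
    return QCResult(dice=d, flagged=bool(d < threshold))


def run_pipeline(
    config: PipelineConfig,
    labelmap: TissueLabelmap | None = None,
    template: TemplateShape | None = None,
) -> dict:
    """Execute the full unfolding pipeline; returns a results dictionary.

    ``labelmap`` (and optionally ``template``) may be passed in memory
    instead of reading ``config.labelmap_path``.  Any stage failure raises
    :class:`StageError` naming the stage; artifacts written before the
    failure are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config, "outputs": []}
    tlog: list[str] = []
    spec = UnfoldedSpaceSpec()

    def tick(stage, t0):
        msg = f"{stage}: {time.perf_counter() - t0:.1f}s"
        tlog.append(msg)
        log.info(msg)

    def name(space, density, suffix):
        return gifti.bids_name(config.subject_id, "R", space, density, suffix)

    # --- validate ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        lm = labelmap if labelmap is not None else read_labelmap(
            config.labelmap_path, hemisphere=config.hemisphere)
        if lm.hemisphere == "L":
            lm = flip_hemisphere(lm)
        report = validate_labelmap(lm)
        if report.missing_labels:
            raise ValueError(f"missing required labels: {report.missing_labels}")
        results["validation"] = report
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("validate", e) from e
    tick("validate", t0)

    # --- template shape injection ----------------------------------------
    t0 = time.perf_counter()
    dg_fields: CoordFields | None = None
    try:
        if config.do_injection:
            if template is None:
                from .phantom import generate_template
                template = generate_template()
            lm_unfold, dg_fields, deform = inject(template, lm)
            results["deformation"] = deform
            write_labelmap(lm_unfold, out / name("native", "na", "desc-inject_dseg.nii.gz"))
        else:
            lm_unfold = lm
        results["labelmap_unfold"] = lm_unfold
    except Exception as e:  # noqa: BLE001
        raise StageError("inject", e) from e
    tick("inject", t0)

    # --- coordinate fields ------------------------------------------------
    t0 = time.perf_counter()
    try:
        fields = compute_coord_fields(lm_unfold, io_mode=config.io_mode)
        results["fields"] = fields
        for ax in ("ap", "pd", "io"):
            save_scalar_field(getattr(fields, ax), lm.affine,
                              out / name("native", "na", f"coords-{ax.upper()}.nii.gz"))
    except Exception as e:  # noqa: BLE001
        raise StageError("fields", e) from e
    tick("fields", t0)

    # --- warps ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        w_n2u = build_native_to_unfolded(fields, lm_unfold, spec)
        w_u2n = build_unfolded_to_native(fields, lm_unfold, spec)
        results["warp_native_to_unfolded"] = w_n2u
        results["warp_unfolded_to_native"] = w_u2n
        write_itk_warp(w_n2u, out / name("native", "na", "xfm-native2unfolded.nii.gz"))
        write_itk_warp(w_u2n, out / name("unfolded", "na", "xfm-unfolded2native.nii.gz"))
        w_u2n_dg = None
        if dg_fields is not None and dg_fields.domain_mask.sum() >= 4:
            w_u2n_dg = build_unfolded_to_native(dg_fields, lm_unfold, spec, structure="dg")
            results["warp_unfolded_to_native_dg"] = w_u2n_dg
    except Exception as e:  # noqa: BLE001
        raise StageError("warps", e) from e
    tick("warps", t0)

    # --- surfaces ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        surf: dict = {}
        for density in config.densities:
            layers = build_layer_surfaces(w_u2n, density, spec)
            surf[density] = layers
            for lname, mesh in layers.items():
                space = "unfolded" if lname.startswith("unfolded") else "native"
                suffix = f"{lname.removeprefix('unfolded_')}.surf.gii"
                p = gifti.write_surface(mesh, out / name(space, density, suffix))
                results["outputs"].append(str(p))
            if w_u2n_dg is not None:
                surf[density + "_dg"] = make_dg_surfaces(w_u2n_dg, density, spec)
        results["surfaces"] = surf
        manifest = [Path(s).name for s in results["outputs"]]
        (out / "surfaces_manifest.txt").write_text("\n".join(manifest) + "\n")
    except Exception as e:  # noqa: BLE001
        raise StageError("surfaces", e) from e
    tick("surfaces", t0)

    # --- subfields --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.atlas == "schematic":
            from .phantom import make_schematic_atlas
            atlas = make_schematic_atlas()
        elif isinstance(config.atlas, SubfieldAtlas):
            atlas = config.atlas
        else:
            from .subfields import read_atlas
            atlas = read_atlas(config.atlas)
        results["atlas"] = atlas
        vert_labels = {}
        for density in config.densities:
            mesh = surf[density]["midthickness"]
            labs = label_vertices(atlas, mesh)
            vert_labels[density] = labs
            p = gifti.write_labels(labs, atlas.label_names,
                                   out / name("native", density, "subfields.label.gii"))
            results["outputs"].append(str(p))
            results.setdefault("topology", {})[density] = check_topology(labs, mesh, atlas)
        dgm = lm_unfold.mask("DGgranule") if dg_fields is not None else None
        vol = fill_volumetric_subfields(atlas, fields, lm_unfold, dg_mask=dgm)
        results["subfield_volume"] = vol
        results["vertex_labels"] = vert_labels
        write_labelmap(vol, out / name("native", "na", "desc-subfields_dseg.nii.gz"))
    except Exception as e:  # noqa: BLE001
        raise StageError("subfields", e) from e
    tick("subfields", t0)

    # --- morphometry ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        metrics: dict = {}
        rows = []
        for density in config.densities:
            layers = surf[density]
            th = thickness(layers["inner"], layers["outer"])
            gy = gyrification(layers["midthickness"], layers["unfolded_midthickness"])
            cu = mean_curvature(layers["midthickness"])
            metrics[density] = {"thickness": th, "gyrification": gy, "curvature": cu}
            if config.quantitative_image is not None:
                import nibabel as nib
                qimg = nib.load(str(config.quantitative_image))
                metrics[density]["sampled"] = sample_to_surface(
                    np.asanyarray(qimg.dataobj), qimg.affine, layers["midthickness"])
            for mname, metric in metrics[density].items():
                p = gifti.write_metric(metric, out / name("native", density, f"{mname}.shape.gii"))
                results["outputs"].append(str(p))
                labs = vert_labels[density]
                for val in np.unique(labs):
                    sel = metric.values[labs == val]
                    rows.append({
                        "density": density, "metric": mname,
                        "subfield": atlas.name_of(int(val)),
                        "mean": float(np.nanmean(sel)), "sd": float(np.nanstd(sel)),
                        "n_vertices": int(sel.size),
                    })
        results["metrics"] = metrics
        pd.DataFrame(rows).to_csv(out / f"sub-{config.subject_id}_morphometry.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("morphometry", e) from e
    tick("morphometry", t0)

    # --- QC ---------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        ref = None
        if config.reference_mask_path is not None:
            ref = read_labelmap(config.reference_mask_path).data > 0
        elif config.do_injection:
            ref = lm_unfold.mask("GM")
        if ref is not None:
            qc = flag_low_dice(lm.mask("GM"), ref, config.dice_flag_threshold)
        else:
            qc = QCResult(dice=None, flagged=False)
        qc.runtime_log = tlog
        results["qc"] = qc
        qc_report(results, out / f"sub-{config.subject_id}_qc")
    except Exception as e:  # noqa: BLE001
        raise StageError("qc", e) from e
    tick("qc", t0)
    return results


def qc_report(results: dict, stem: str | Path) -> Path:
    """Write the QC report (HTML and JSON) for one subject."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    qc: QCResult = results["qc"]
    fields: CoordFields = results["fields"]
    cfg: PipelineConfig = results["config"]
    dm = fields.domain_mask
    summary: dict = {
        "subject": cfg.subject_id,
        "dice": qc.dice,
        "flagged": qc.flagged,
        "field_ranges": {
            ax: [float(np.nanmin(getattr(fields, ax)[dm])),
                 float(np.nanmax(getattr(fields, ax)[dm]))]
            for ax in ("ap", "pd", "io")
        },
        "vertex_counts": {},
        "runtime": qc.runtime_log,
    }
    for density, layers in results.get("surfaces", {}).items():
        if density.endswith("_dg"):
            summary["vertex_counts"][density] = layers["midthickness"].n_vertices
        else:
            summary["vertex_counts"][density] = layers["midthickness"].n_vertices
    th = results.get("metrics", {})
    for density, mm in th.items():
        if "thickness" in mm:
            v = mm["thickness"].values
            summary.setdefault("thickness_mm", {})[density] = {
                "mean": float(np.nanmean(v)), "sd": float(np.nanstd(v))}
    jpath = stem.with_suffix(".json")
    jpath.write_text(json.dumps(summary, indent=1))

    headline = "FLAGGED: Dice below threshold" if qc.flagged else "QC passed"
    lines = [f"<html><head><title>QC {cfg.subject_id}</title></head><body>",
             f"<h1>{headline}</h1>",
             f"<p>subject: {cfg.subject_id}; dice: {qc.dice}</p>",
             "<h2>Field ranges</h2><ul>"]
    for ax, rng in summary["field_ranges"].items():
        lines.append(f"<li>{ax}: [{rng[0]:.3f}, {rng[1]:.3f}]</li>")
    lines.append("</ul><h2>Vertex counts</h2><ul>")
    for density, n in summary["vertex_counts"].items():
        lines.append(f"<li>{density}: {n:,} vertices</li>")
    lines.append("</ul><h2>Thickness</h2><ul>")
    for density, st in summary.get("thickness_mm", {}).items():
        lines.append(f"<li>{density}: {st['mean']:.2f} ± {st['sd']:.2f} mm</li>")
    lines += ["</ul><h2>Runtime</h2><ul>"]
    lines += [f"<li>{msg}</li>" for msg in qc.runtime_log]
    lines += ["</ul></body></html>"]
    hpath = stem.with_suffix(".html")
    hpath.write_text("\n".join(lines))
    return hpath
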