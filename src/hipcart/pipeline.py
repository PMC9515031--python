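"""End-to-end analysis pipeline: volumes in, section report + maps out.

``analyze`` wires the stages together: load the aligned T1 map and
cartilage mask (the mask may come from any external segmenter, from the
majority-vote/largest-component fusion of per-plane predictions, or from
the phantom generator), fit the femoral-head sphere, build the anatomical
frame, section the cartilage, and compute the per-section quality metrics
and 2D projection maps. Every parameter is logged in the report's
provenance block so the identical analysis can be re-run; the analysis path
is fully deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import HipcartError, PipelineError
from .geometry import ANTERIOR_LPS, frame_from_mask
from .metrics import (
    DEFAULT_N_POINTS,
    DEFAULT_SEARCH_MM,
    build_section_report,
)
from .postproc import largest_component, majority_vote
from .projection import DEFAULT_BINS, dgemric_map, save_map, thickness_map
from .sectioning import clock_offset_from_landmark, section_label
from .volumes import ImageVolume, LabelVolume, read_volume, write_volume

log = logging.getLogger("hipcart")

__all__ = ["AnalyzeConfig", "AnalysisResult", "analyze"]


@dataclass
class AnalyzeConfig:
    """Configuration of one analysis run (file paths or in-memory volumes)."""

    t1: ImageVolume | str | Path = None
    mask: LabelVolume | str | Path = None
    plane_masks: list | None = None  # 3 per-plane masks -> vote + LCC
    side: str = "right"
    sections: int = 4
    layers: bool = True
    central_peripheral: bool = True
    cone_half_angle: float | str = "auto"
    clock_offset_deg: float = 0.0
    six_oclock_landmark: list | None = None  # world mm; overrides clock offset
    n_points: int = DEFAULT_N_POINTS
    search_mm: float = DEFAULT_SEARCH_MM
    map_bins: tuple = DEFAULT_BINS
    anterior_dir: tuple = tuple(ANTERIOR_LPS)
    out: str | Path | None = None


@dataclass
class AnalysisResult:
    report: "pandas.DataFrame"  # noqa: F821 - avoid import for typing only
    sphere: "Sphere"  # noqa: F821
    frame: "AnatomicalFrame"  # noqa: F821
    labeling: "SectionLabeling"  # noqa: F821
    thickness: "ProjectionMap"  # noqa: F821
    dgemric_maps: dict
    provenance: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except HipcartError as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def _load(vol, label):
    if vol is None:
        return None
    if isinstance(vol, (str, Path)):
        return read_volume(vol, label=label)
    return vol.canonicalized()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def analyze(config: AnalyzeConfig) -> AnalysisResult:
    """Run the full sectioning/metrics pipeline described by ``config``."""
    t1 = _stage("load_t1")(_load)(config.t1, label=False)
    mask = _stage("load_mask")(_load)(config.mask, label=True)
    if mask is None and config.plane_masks:
        planes = [_stage("load_plane_masks")(_load)(m, label=True)
                  for m in config.plane_masks]
        mask = _stage("fusion")(majority_vote)(planes)
        mask = _stage("postprocessing")(largest_component)(mask)
    if t1 is None or mask is None:
        raise PipelineError(
            "inputs", HipcartError("need a T1 map and a cartilage mask "
                                   "(or three plane masks)")
        )

    sphere, frame = _stage("sphere_and_frame")(frame_from_mask)(
        mask, side=config.side, anterior_dir=np.asarray(config.anterior_dir)
    )
    log.info("fitted sphere r=%.2f mm at %s", sphere.radius, sphere.centre)

    offset = config.clock_offset_deg
    if config.six_oclock_landmark is not None:
        offset = clock_offset_from_landmark(frame, config.six_oclock_landmark)
    labeling = _stage("sectioning")(section_label)(
        mask,
        frame,
        sphere,
        n_sectors=config.sections,
        layers=config.layers,
        regions=config.central_peripheral,
        cone_half_angle=config.cone_half_angle,
        clock_offset_deg=offset,
    )

    report = _stage("metrics")(build_section_report)(
        t1, mask, labeling, sphere,
        n_points=config.n_points, search_mm=config.search_mm,
    )

    tmap = _stage("projection")(thickness_map)(mask, sphere, frame, config.map_bins)
    dmaps = {
        layer: _stage("projection")(dgemric_map)(
            t1, mask, sphere, frame, config.map_bins, layer=layer
        )
        for layer in (("femoral", "acetabular", "both") if config.layers else ("both",))
    }

    provenance = {
        "software": {"name": "hipcart", "version": __version__},
        "sphere": sphere.to_dict(),
        "frame": frame.to_dict(),
        "n_sectors": config.sections,
        "layers": config.layers,
        "central_peripheral": config.central_peripheral,
        "cone_half_angle_deg": labeling.cone_half_angle_deg,
        "clock_offset_deg": offset,
        "n_points": config.n_points,
        "search_mm": config.search_mm,
        "map_bins": list(config.map_bins),
        "side": config.side,
        "anterior_dir": list(config.anterior_dir),
    }
    result = AnalysisResult(
        report=report,
        sphere=sphere,
        frame=frame,
        labeling=labeling,
        thickness=tmap,
        dgemric_maps=dmaps,
        provenance=provenance,
    )
    if config.out is not None:
        _write_outputs(result, Path(config.out))
    return result


def _write_outputs(result: AnalysisResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    df = result.report
    df.to_csv(out / "section_report.csv", index=False)
    payload = {
        "provenance": result.provenance,
        "sections": json.loads(df.to_json(orient="records")),
    }
    (out / "section_report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
    )
    write_volume(result.labeling.sector, out / "sector_labels.nii")
    if result.labeling.layer is not None:
        write_volume(result.labeling.layer, out / "layer_labels.nii")
    if result.labeling.region is not None:
        write_volume(result.labeling.region, out / "region_labels.nii")
    save_map(result.thickness, out / "thickness_map.png")
    for layer, pmap in result.dgemric_maps.items():
        save_map(pmap, out / f"dgemric_map_{layer}.png")
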