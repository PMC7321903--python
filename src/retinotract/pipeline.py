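"""End-to-end orchestration: phantom -> tensor fit -> ensemble tracking ->
pruning -> subdivision -> maps, profiles and statistics, with every
intermediate written in its standard format and a JSON run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .errors import RetinotractError, UsageError
from .formats_io import Tractogram, VolumeGrid, write_tractogram, write_volume
from .maps_profiles import consistency_map, density_map, tract_profile
from .phantom import Phantom, PhantomSpec, build_phantom, write_phantom
from .streamline_ops import ExclusionPlane, crosses_plane, streamline_length
from .subdivision_stats import (
    ClassificationResult,
    LABELS,
    RoiSplit,
    classify_by_endpoint,
    detection_stats_from_counts,
    endpoint_histogram,
    roi_endpoints,
    split_roi,
)
from .tensor_model import fit_tensor, tensor_scalars
from .tracking_life import TrackingConfig, ensemble_track, life_prune

__all__ = [
    "RunConfig",
    "run_pipeline",
    "classify_by_planes",
    "classify_manual_vs_automatic",
]

log = logging.getLogger("retinotract")


@dataclasses.dataclass
class RunConfig:
    phantom: PhantomSpec = dataclasses.field(default_factory=PhantomSpec)
    tracking: TrackingConfig = dataclasses.field(
        default_factory=lambda: TrackingConfig(max_fibers=150, max_trials=3000, rng_seed=7)
    )
    classification_max_dist: float = 2.0
    orientation_hint: str = "y"
    maps_fwhm: float = 2.0
    binarize_eps: float = 1e-6
    consistency_threshold: int | None = None
    outputs: str = "retinotract_out"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "phantom" in d:
            d["phantom"] = PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in d["phantom"].items()})
        if "tracking" in d:
            tr = dict(d["tracking"])
            if "curvature_radii" in tr:
                tr["curvature_radii"] = tuple(tr["curvature_radii"])
            d["tracking"] = TrackingConfig(**tr)
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def classify_by_planes(
    t: Tractogram,
    pro1_planes: list[ExclusionPlane],
    pro2_planes: list[ExclusionPlane],
) -> ClassificationResult:
    """Plane-based ("manual") subdivision: a streamline crossing only the
    PRO1 planes is PRO1, only the PRO2 planes is PRO2, otherwise
    UNASSIGNED."""
    if len(t) == 0:
        raise UsageError("cannot classify an empty tractogram")
    labels = []
    for s in t:
        c1 = any(crosses_plane(s, p) for p in pro1_planes)
        c2 = any(crosses_plane(s, p) for p in pro2_planes)
        if c1 and not c2:
            labels.append("PRO1")
        elif c2 and not c1:
            labels.append("PRO2")
        else:
            labels.append("UNASSIGNED")
    n = len(labels)
    return ClassificationResult(labels=labels, proportions={l: labels.count(l) / n for l in LABELS})


def classify_manual_vs_automatic(
    t: Tractogram,
    pro1_planes: list[ExclusionPlane],
    pro2_planes: list[ExclusionPlane],
    split: RoiSplit,
    max_dist: float = 2.0,
) -> dict[str, Any]:
    """3x3 contingency of plane-based vs endpoint-based labels plus the
    percent agreement on streamlines both methods assign."""
    manual = classify_by_planes(t, pro1_planes, pro2_planes)
    auto = classify_by_endpoint(t, split, max_dist=max_dist)
    table = {m: {a: 0 for a in LABELS} for m in LABELS}
    for m, a in zip(manual.labels, auto.labels):
        table[m][a] += 1
    assigned = [
        (m, a)
        for m, a in zip(manual.labels, auto.labels)
        if m != "UNASSIGNED" and a != "UNASSIGNED"
    ]
    if assigned:
        agreement = sum(m == a for m, a in assigned) / len(assigned)
    else:
        agreement = float("nan")
        log.warning("no streamline assigned by both methods; agreement undefined")
    return {
        "contingency": table,
        "n_assigned_by_both": len(assigned),
        "percent_agreement": 100.0 * agreement,
        "manual": manual,
        "automatic": auto,
    }


def _length_stats(t: Tractogram) -> dict[str, float]:
    if len(t) == 0:
        return {"n": 0, "mean_mm": float("nan"), "sd_mm": float("nan")}
    lengths = np.array([streamline_length(s) for s in t])
    return {"n": int(len(lengths)), "mean_mm": float(lengths.mean()), "sd_mm": float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0}


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute every stage in order and return the run report (also written
    to ``<outputs>/report.json``)."""
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    t0 = time.time()
    out = Path(cfg.outputs)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    stage = "phantom"
    try:
        log.info("stage %s", stage)
        phantom = build_phantom(cfg.phantom)
        paths.update(write_phantom(phantom, out / "phantom"))

        stage = "tensor_fit"
        log.info("stage %s", stage)
        tensors = fit_tensor(phantom.dwi, phantom.gtab, phantom.wm_mask)
        scalars = tensor_scalars(tensors)
        for name, vol in (("fa", scalars.fa), ("md", scalars.md), ("rd", scalars.rd)):
            paths[name] = str(write_volume(vol, out / f"{name}.nii.gz"))

        stage = "tracking"
        log.info("stage %s", stage)
        if cfg.tracking.max_trials == 0:
            raise UsageError("tracking budget max_trials = 0: no streamlines can be attempted")
        from .streamline_ops import dilate_mask

        seed_union = phantom.seed_roi.with_data(
            (
                (np.asarray(dilate_mask(phantom.seed_roi, 2).data) > 0)
                | (np.asarray(phantom.target_roi.data) > 0)
            ).astype(np.uint8)
        )
        candidates, per_radius = ensemble_track(
            tensors, phantom.wm_mask, seed_union, cfg.tracking,
            roi_a=phantom.seed_roi, roi_b=phantom.target_roi,
        )
        if len(candidates) == 0:
            raise UsageError("tracking produced no candidate streamlines")
        paths["candidates"] = str(write_tractogram(candidates, out / "candidates.tck"))

        stage = "prune"
        log.info("stage %s (%d candidates)", stage, len(candidates))
        pruned = life_prune(candidates, phantom.dwi, phantom.gtab, phantom.wm_mask)
        kept = pruned.kept
        paths["kept"] = str(write_tractogram(kept, out / "kept.tck"))
        with open(out / "weights.json", "w") as fh:
            json.dump({"weights": pruned.weights.tolist(), "kept_indices": pruned.kept_indices.tolist()}, fh)
        paths["weights"] = str(out / "weights.json")

        stage = "classify"
        log.info("stage %s (%d kept)", stage, len(kept))
        split = split_roi(phantom.target_roi, cfg.orientation_hint)
        auto = classify_by_endpoint(kept, split, max_dist=cfg.classification_max_dist)
        dorsal_plane, ventral_plane = phantom.crossing_planes()
        comparison = classify_manual_vs_automatic(
            kept, [dorsal_plane], [ventral_plane], split, max_dist=cfg.classification_max_dist
        )
        ends = roi_endpoints(kept, phantom.target_roi)
        df = auto.to_frame(endpoints=ends)
        paths["classification"] = str(out / "classification.csv")
        df.to_csv(paths["classification"], index=False, float_format="%.6f")

        stage = "detection_stats"
        counts = {
            m: {a: comparison["contingency"][m][a] for a in LABELS} for m in LABELS
        }
        det = {}
        for label, ref, opp in (("PRO1", "PRO1", "PRO2"), ("PRO2", "PRO2", "PRO1")):
            n_ref, n_opp = counts[label][ref], counts[label][opp]
            if n_ref + n_opp > 0:
                s = detection_stats_from_counts(n_ref, n_opp)
                det[label] = {"hits": s.hits, "false_alarms": s.false_alarms, "d_prime": s.d_prime, "n": s.n}
            else:
                det[label] = None
        with open(out / "detection_stats.json", "w") as fh:
            json.dump(det, fh, indent=2)
        paths["detection_stats"] = str(out / "detection_stats.json")

        stage = "maps_profiles"
        log.info("stage %s", stage)
        subsets = {"FULL": kept}
        for lab in ("PRO1", "PRO2"):
            idx = [i for i, l in enumerate(auto.labels) if l == lab]
            if idx:
                subsets[lab] = kept.subset(idx)
        lengths = {lab: _length_stats(tr) for lab, tr in subsets.items()}
        grid = phantom.wm_mask
        for lab, tr in subsets.items():
            dm = density_map(tr, grid)
            paths[f"density_{lab}"] = str(write_volume(dm, out / f"density_{lab.lower()}.nii.gz"))
            cm = consistency_map([tr], grid, fwhm=cfg.maps_fwhm, binarize_eps=cfg.binarize_eps,
                                 threshold=cfg.consistency_threshold)
            paths[f"consistency_{lab}"] = str(
                write_volume(cm.counts, out / f"consistency_{lab.lower()}.nii.gz")
            )
            prof = tract_profile(tr, scalars, n_nodes=100, tract_label=lab)
            paths[f"profile_{lab}"] = str(out / f"profile_{lab.lower()}.csv")
            prof.to_frame().to_csv(paths[f"profile_{lab}"], index=False, float_format="%.8g")
            hist = endpoint_histogram(tr, phantom.seed_roi)
            paths[f"histogram_{lab}"] = str(out / f"histogram_{lab.lower()}.csv")
            hist.to_csv(paths[f"histogram_{lab}"], index=False, float_format="%.6f")
    except RetinotractError as exc:
        raise type(exc)(f"pipeline failed at stage {stage!r}: {exc} (artifacts so far: {sorted(paths)})") from exc

    report = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seeds": {"phantom": cfg.phantom.rng_seed, "tracking": cfg.tracking.rng_seed},
        "n_candidates": len(candidates),
        "per_radius_counts": {str(k): v for k, v in per_radius.items()},
        "n_kept": len(kept),
        "proportions": auto.proportions,
        "label_counts": auto.counts,
        "detection_stats": det,
        "tract_lengths": lengths,
        "manual_vs_automatic": {
            "contingency": comparison["contingency"],
            "percent_agreement": comparison["percent_agreement"],
            "n_assigned_by_both": comparison["n_assigned_by_both"],
        },
        "artifacts": paths,
        "checksums": {k: _checksum(v) for k, v in paths.items()},
        "runtime_s": time.time() - t0,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
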