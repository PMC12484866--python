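"""Readers, writers, run configuration and run reports.

Particle tables are delimited text with header columns ``x, y, z, weight``
followed either by one column per feature or by a single ``label`` column
for one-hot discrete data.  Coordinates are converted to millimeters on read
(``unit`` declares the file's unit).  Labeled atlas volumes are read from
integer-valued NIfTI images; one particle is emitted per foreground voxel
(0-based, half-open indexing, physical position at the voxel center), or per
aggregated block with region-membership fractions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

log = logging.getLogger("varimap")

from .lddmm import AtlasMeasure, MappingResult
from .varifold import FeatureSpace, ParticleMeasure

__all__ = [
    "RunConfig",
    "read_particles",
    "write_particles",
    "read_label_volume",
    "volume_to_particles",
    "run_report",
]

_UNIT_TO_MM = {"mm": 1.0, "um": 1e-3, "micron": 1e-3, "m": 1e3}


class RunConfig(BaseModel):
    """Validated configuration of a mapping run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    varifold_scales: list[tuple[float, float]] = [(0.1, 1.0)]  # (sigma mm, weight)
    flow_sigma: float = 0.2
    reg_weight: float = 1.0
    data_weight: float = 1.0
    kl_weight: float = 1.0
    censor_weight: float = 1.0
    n_steps: int = 10
    max_iter: int = 150
    seed: int = 0
    unit: str = "mm"
    censor_mode: str = "none"  # "none" | "planar" | "learned"

    def mapping_config(self):
        from .lddmm import FlowKernel, MappingConfig
        from .varifold import SpaceKernel

        return MappingConfig(
            flow_kernel=FlowKernel(self.flow_sigma),
            space_kernel=SpaceKernel(tuple(self.varifold_scales)),
            reg_weight=self.reg_weight, data_weight=self.data_weight,
            kl_weight=self.kl_weight, censor_weight=self.censor_weight,
            n_steps=self.n_steps, max_iter=self.max_iter, seed=self.seed,
        )


def _unit_factor(unit: str) -> float:
    try:
        return _UNIT_TO_MM[unit]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r}; expected one of "
                         f"{sorted(_UNIT_TO_MM)}") from None


def read_particles(path, unit: str = "mm",
                   feature_space: FeatureSpace | None = None) -> ParticleMeasure:
    """Read a particle table; returns coordinates in mm."""
    factor = _unit_factor(unit)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"x", "y", "z", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"particle table missing columns {sorted(missing)}")
    pos = df[["x", "y", "z"]].to_numpy(float) * factor
    w = df["weight"].to_numpy(float)
    if np.any(w < 0):
        raise ValueError("negative weights in particle table")
    if "label" in df.columns:
        labels = df["label"].astype(str).to_numpy()
        if feature_space is None:
            feature_space = FeatureSpace(tuple(sorted(set(labels))))
        feats = np.zeros((len(df), len(feature_space)))
        for i, lab in enumerate(labels):
            feats[i, feature_space.index(lab)] = 1.0
        normalized = True
    else:
        fcols = [c for c in df.columns if c not in ("x", "y", "z", "weight")]
        if not fcols:
            raise ValueError("particle table has no feature columns")
        if feature_space is None:
            feature_space = FeatureSpace(tuple(fcols))
        feats = df[fcols].to_numpy(float)
        normalized = bool(np.allclose(feats.sum(axis=1), 1.0, atol=1e-9))
    log.info("read %d particles (%d features) from %s [%s]",
             len(df), len(feature_space), path, unit)
    return ParticleMeasure(pos, w, feats, feature_space, normalized=normalized)


def write_particles(mu: ParticleMeasure, path, unit: str = "mm",
                    as_label: bool = False) -> None:
    """Write a particle table in the same dialect ``read_particles`` reads."""
    factor = _unit_factor(unit)
    out = {
        "x": mu.positions[:, 0] / factor,
        "y": mu.positions[:, 1] / factor,
        "z": mu.positions[:, 2] / factor,
        "weight": mu.weights,
    }
    if as_label:
        idx = mu.feature_dists.argmax(axis=1)
        out["label"] = [mu.feature_space.labels[i] for i in idx]
    else:
        for f, lab in enumerate(mu.feature_space.labels):
            out[lab] = mu.feature_dists[:, f]
    # %.17g guarantees exact float64 round-trips through the text dialect
    pd.DataFrame(out).to_csv(path, index=False, float_format="%.17g")
    log.info("wrote %d particles to %s [%s]", len(mu), path, unit)


def volume_to_particles(volume: np.ndarray, spacing, background: int = 0,
                        block: int = 1) -> AtlasMeasure:
    """Integer label volume -> atlas particle measure.

    One particle per foreground voxel with mass = voxel volume and a one-hot
    region law, or one per ``block``^3 aggregate with mass = foreground
    volume and region fractions; block aggregation conserves per-label
    volume exactly.  Positions are voxel/block centers in mm.
    """
    volume = np.asarray(volume)
    if not np.issubdtype(volume.dtype, np.integer):
        if not np.all(volume == np.round(volume)):
            raise ValueError("label volume must be integer-valued")
        volume = volume.astype(np.int64)
    spacing = np.asarray(spacing, float).ravel()
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be three positive lengths (mm)")
    labels = sorted(int(v) for v in np.unique(volume) if v != background)
    if not labels:
        raise ValueError("volume contains no foreground labels")
    space = FeatureSpace(tuple(str(v) for v in labels))
    voxvol = float(np.prod(spacing))
    lab_index = {v: i for i, v in enumerate(labels)}

    if block == 1:
        idx = np.argwhere(volume != background)
        pos = (idx + 0.5) * spacing
        w = np.full(len(idx), voxvol)
        pi = np.zeros((len(idx), len(labels)))
        vals = volume[tuple(idx.T)]
        pi[np.arange(len(idx)), [lab_index[int(v)] for v in vals]] = 1.0
        return AtlasMeasure(pos, w, pi, space)

    shape = volume.shape
    nblocks = [int(np.ceil(s / block)) for s in shape]
    positions, weights, pis = [], [], []
    for bx in range(nblocks[0]):
        for by in range(nblocks[1]):
            for bz in range(nblocks[2]):
                sub = volume[bx * block:(bx + 1) * block,
                             by * block:(by + 1) * block,
                             bz * block:(bz + 1) * block]
                fg = sub[sub != background]
                if fg.size == 0:
                    continue
                counts = np.zeros(len(labels))
                for v in fg:
                    counts[lab_index[int(v)]] += 1
                lo = np.array([bx, by, bz]) * block
                hi = np.minimum(lo + block, shape)
                center = (lo + hi) / 2.0 * spacing
                positions.append(center)
                weights.append(counts.sum() * voxvol)
                pis.append(counts / counts.sum())
    return AtlasMeasure(np.array(positions), np.array(weights),
                        np.array(pis), space)


def read_label_volume(path, spacing=None, background: int = 0,
                      block: int = 1) -> AtlasMeasure:
    """Read an integer-labeled NIfTI volume as an atlas particle measure.

    ``spacing`` (mm per voxel, 3-tuple) overrides the header zooms.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if spacing is None:
        spacing = img.header.get_zooms()[:3]
    return volume_to_particles(data, spacing, background=background,
                               block=block)


def run_report(result: MappingResult, cfg=None) -> dict:
    """Machine-readable summary of a mapping run."""
    report = {
        "objective": result.objective,
        "objective_trajectory": [float(v) for v in result.trajectory],
        "iterations": len(result.trajectory),
        "censor_lambda": result.censor_lambda,
        "n_particles": len(result.deformed),
        "total_mass": result.deformed.total_mass,
        "jacobian_det_range": [float(result.diffeo.jacobian_dets.min()),
                               float(result.diffeo.jacobian_dets.max())],
    }
    if result.feature_laws is not None:
        report["feature_laws"] = np.asarray(result.feature_laws).tolist()
    if cfg is not None:
        report["config"] = cfg.model_dump() if hasattr(cfg, "model_dump") \
            else str(cfg)
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
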