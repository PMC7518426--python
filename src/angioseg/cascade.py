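"""Cascade plumbing: region partition, bone subtraction, result container.

The pipeline mirrors the clinical postprocessing chain: two cascaded nets
segment and subtract bone, the volume is partitioned into three z-bands
(aorta, carotid, intracranial) so the vessel net can specialize per size
regime, per-region vessel masks are merged back, and a repair stage restores
continuity of ruptured segments. The trained estimators live in
:mod:`angioseg.estimators`; this module holds the deterministic glue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import Volume


@dataclass
class RegionPartition:
    """Three disjoint z-bands: aorta below, carotid middle, intracranial top.

    Cut indices are ``floor(Z * fraction)``; the last band absorbs the
    remainder. Degenerate (zero-thickness) bands are rejected.
    """

    fractions: tuple[float, float]
    z_dim: int

    def __post_init__(self) -> None:
        f1, f2 = self.fractions
        if not 0.0 < f1 < f2 < 1.0:
            raise ValueError("fractions must be strictly increasing in (0, 1)")
        self.cuts = (int(self.z_dim * f1), int(self.z_dim * f2))
        z1, z2 = self.cuts
        if z1 < 1 or z2 - z1 < 1 or self.z_dim - z2 < 1:
            raise ValueError(
                f"degenerate band: cuts {self.cuts} on z-dim {self.z_dim}")

    @property
    def bands(self) -> list[slice]:
        z1, z2 = self.cuts
        return [slice(0, z1), slice(z1, z2), slice(z2, self.z_dim)]

    def region_of_z(self) -> np.ndarray:
        """Per-slice region index (0 aorta, 1 carotid, 2 intracranial)."""
        out = np.empty(self.z_dim, dtype=np.int8)
        for r, band in enumerate(self.bands):
            out[band] = r
        return out


def split_regions(data: np.ndarray, partition: RegionPartition) -> list[np.ndarray]:
    """Cut a volume into the three z-band subvolumes (views, lossless)."""
    if data.shape[0] != partition.z_dim:
        raise ValueError(f"z-dim {data.shape[0]} != partition z-dim {partition.z_dim}")
    return [data[band] for band in partition.bands]


def merge_regions(subvolumes: list[np.ndarray], partition: RegionPartition) -> np.ndarray:
    """Inverse of :func:`split_regions`: concatenate the bands along z."""
    if len(subvolumes) != 3:
        raise ValueError("expected three band subvolumes")
    for sub, band in zip(subvolumes, partition.bands):
        if sub.shape[0] != band.stop - band.start:
            raise ValueError("subvolume thickness does not match its band")
    return np.concatenate(subvolumes, axis=0)


def subtract_bone(volume: Volume | np.ndarray, bone_mask: np.ndarray,
                  fill_value: float = 40.0) -> Volume | np.ndarray:
    """Replace bone voxels with a background fill; all others untouched."""
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    bone_mask = np.asarray(bone_mask, dtype=bool)
    if bone_mask.shape != data.shape:
        raise ValueError(f"mask shape {bone_mask.shape} != volume shape {data.shape}")
    out = data.copy()
    out[bone_mask] = fill_value
    if isinstance(volume, Volume):
        return Volume(out, volume.spacing)
    return out


@dataclass
class CascadeResult:
    """Every intermediate and final mask produced by one pipeline run."""

    bone_prob: np.ndarray | None
    bone_mask: np.ndarray
    subtracted: Volume
    partition: RegionPartition
    vessel_classes: np.ndarray          # {0, 2, 3, 4} labels pre-repair
    vessel_mask_pre: np.ndarray         # vessel union before repair
    vessel_mask_repaired: np.ndarray    # after repair; superset of pre
    labels_clean: np.ndarray            # repaired classes after small-component cleanup
    metrics: dict = field(default_factory=dict)

    def check_invariants(self) -> None:
        assert self.vessel_mask_repaired[self.vessel_mask_pre].all(), \
            "repair must only add voxels"
        assert not (self.bone_mask & self.vessel_mask_pre).any(), \
            "bone and vessel masks must be disjoint after subtraction"


# Thin functional wrappers over the estimator objects -----------------------

def segment_bone(volume, bone_segmenter) -> np.ndarray:
    """Two-stage bone mask: the refiner consumes the first net's probability."""
    return bone_segmenter.predict(volume)


def segment_vessels(volume, vessel_segmenter, partition: RegionPartition | None = None
                    ) -> np.ndarray:
    """Per-region vessel class mask merged into global coordinates."""
    return vessel_segmenter.predict(volume, partition=partition)


def cgpm_repair(volume, vessel_mask, repairer) -> np.ndarray:
    """Connectivity repair: fills predicted gap voxels near mask endpoints."""
    return repairer.predict(volume, vessel_mask)


def run_pipeline(volume, bundle, truth=None, weights=None, **variant) -> CascadeResult:
    """Execute the full cascade with a fitted :class:`~angioseg.estimators.CascadePipeline`."""
    return bundle.predict(volume, truth=truth, truth_weights=weights, **variant)


def run_ablation(bundle, phantoms, variants=None) -> dict:
    """Run pipeline variants on (volume, label[, weights]) cases; return metrics.

    Mirrors the component-contribution study: the full pipeline against
    versions without the repair stage, without the region split, and without
    the bone stage.
    """
    if variants is None:
        variants = {
            "full": {},
            "no_cgpm": {"use_cgpm": False},
            "no_region_split": {"use_region": False},
            "no_bone_stage": {"use_bone": False},
        }
    report: dict[str, dict] = {}
    for name, flags in variants.items():
        rows = []
        for case in phantoms:
            vol, lab = case[0], case[1]
            w = case[2] if len(case) > 2 else None
            res = bundle.predict(vol, truth=lab, truth_weights=w, **flags)
            rows.append(res.metrics)
        report[name] = {
            k: float(np.mean([r[k] for r in rows]))
            for k in rows[0]
            if all(k in r for r in rows)
        }
    return report
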