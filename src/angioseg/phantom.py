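"""Synthetic CTA phantoms: vascular trees, adjacent bone, noise, and ruptures.

The phantom emulates the statistical structure a head-and-neck CTA cascade
relies on: a single connected arterial tree spanning three size regimes along
the scan axis (a thick aorta trunk low in the volume, paired carotids in the
middle band, thin branching intracranial vessels at the top), bright bone
adjacent to the intracranial vessels (a skull-like shell plus vertebra-like
blobs — the tissue-adhesion hazard), contrast-like intensity separation, and
additive Gaussian noise. Controlled "ruptures" (severed vessel segments) are
injected to exercise the connectivity-repair stage.

Geometry is centerline-first: each branch is a polyline with a radius, and
tubes are rasterized by thresholding a distance transform. Centerlines are
returned to the caller because the continuity-weight map and the
centerline-weighted training loss are built from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .volume_io import LabelVolume, Volume

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)  # project-wide 26-connectivity

BONE, AORTA, CAROTID, INTRACRANIAL = 1, 2, 3, 4
VESSEL_CLASSES = (AORTA, CAROTID, INTRACRANIAL)


class GenerationError(RuntimeError):
    """Raised when a phantom spec cannot be hosted by the requested shape."""


@dataclass
class PhantomSpec:
    """Parameters of the synthetic scan; defaults are the desk-scale 64³ setup."""

    shape: tuple[int, int, int] = (64, 64, 64)
    region_z_fractions: tuple[float, float] = (1 / 3, 2 / 3)
    aorta_radius_range: tuple[float, float] = (4.0, 5.5)
    carotid_radius_range: tuple[float, float] = (2.0, 2.8)
    intracranial_radius_range: tuple[float, float] = (1.0, 1.6)
    intracranial_depth: int = 2  # binary branchings above the second cut
    background_intensity: float = 40.0
    vessel_intensity: float = 250.0
    bone_intensity: float = 300.0
    noise_sigma: float = 15.0
    skull_thickness: float = 2.5
    bone_vessel_clearance: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        f1, f2 = self.region_z_fractions
        if not 0.0 < f1 < f2 < 1.0:
            raise ValueError("region_z_fractions must be strictly increasing in (0, 1)")
        for name in ("aorta_radius_range", "carotid_radius_range",
                     "intracranial_radius_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be positive and ordered")
        if self.vessel_intensity <= self.background_intensity:
            raise ValueError("vessel intensity must exceed background")
        if self.bone_intensity < self.vessel_intensity:
            raise ValueError("bone intensity must be >= vessel intensity")


@dataclass
class Branch:
    """One vessel branch: an ordered proximal→distal centerline with a radius."""

    id: int
    region: str  # "aorta" | "carotid" | "intracranial"
    parent: int | None
    points: np.ndarray  # (M, 3) float voxel coordinates, (z, y, x)
    radius: float


@dataclass
class RuptureSpec:
    count: int = 3
    gap_length: float = 3.0
    seed: int = 0


@dataclass
class RuptureRecord:
    """Ground truth of injected gaps, for oracle testing of the repair stage."""

    gaps: list[dict] = field(default_factory=list)

    @property
    def n_effective(self) -> int:
        return sum(g["effective"] for g in self.gaps)

    def removed_voxels(self) -> np.ndarray:
        if not self.gaps:
            return np.empty((0, 3), dtype=np.int64)
        return np.concatenate([g["voxels"] for g in self.gaps], axis=0)


def _densify(points: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Resample a polyline so consecutive points are at most ``step`` apart."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        for t in np.linspace(0, 1, n + 1)[1:]:
            out.append(a + t * (b - a))
    return np.asarray(out)


def _grow_branches(spec: PhantomSpec, rng: np.random.Generator) -> list[Branch]:
    Z, Y, X = spec.shape
    z1 = int(Z * spec.region_z_fractions[0])
    z2 = int(Z * spec.region_z_fractions[1])
    margin = 3.0
    branches: list[Branch] = []
    next_id = 0

    def add(region, parent, pts, radius):
        nonlocal next_id
        pts = _densify(np.asarray(pts, dtype=np.float64))
        pts[:, 0] = np.clip(pts[:, 0], margin, Z - 1 - margin)
        pts[:, 1] = np.clip(pts[:, 1], margin, Y - 1 - margin)
        pts[:, 2] = np.clip(pts[:, 2], margin, X - 1 - margin)
        branches.append(Branch(next_id, region, parent, pts, float(radius)))
        next_id += 1
        return branches[-1]

    # Aorta: one thick trunk rising through the bottom band with a gentle bend.
    r_a = rng.uniform(*spec.aorta_radius_range)
    zs = np.arange(margin, z1 + 1.0)
    bend = 0.08 * Y * np.sin(np.linspace(0, np.pi, len(zs)))
    trunk_pts = np.stack([zs, Y * 0.55 + bend, np.full_like(zs, X * 0.5)], axis=1)
    trunk = add("aorta", None, trunk_pts, r_a)

    # Carotids: two branches drifting laterally through the middle band.
    carotids = []
    for side in (-1.0, 1.0):
        r_c = rng.uniform(*spec.carotid_radius_range)
        zs = np.arange(z1, z2 + 1.0)
        t = np.linspace(0, 1, len(zs))
        xs = X * 0.5 + side * X * 0.16 * t + rng.normal(0, 0.3)
        ys = Y * 0.55 + (Y * 0.45 - Y * 0.55) * t * 0.3
        pts = np.stack([zs, ys, xs], axis=1)
        pts[0] = trunk.points[-1]  # attach to the trunk tip
        carotids.append(add("carotid", trunk.id, pts, r_c))

    # Intracranial: binary tree above the second cut, thin and jittered.
    top = Z - 1 - margin
    for carotid in carotids:
        tips = [(carotid, carotid.points[-1], np.array([1.0, -0.15, 0.0]))]
        for level in range(spec.intracranial_depth):
            new_tips = []
            rise = (top - z2) / spec.intracranial_depth
            for parent, start, heading in tips:
                for side in (-1.0, 1.0):
                    r_i = rng.uniform(*spec.intracranial_radius_range)
                    spread = (0.14 - 0.04 * level) * min(Y, X)
                    jitter = rng.normal(0, 0.08, size=2)
                    end = start + np.array([
                        rise,
                        heading[1] * rise * 0.3 + side * spread * 0.4 + jitter[0] * spread,
                        side * spread + jitter[1] * spread,
                    ])
                    br = add("intracranial", parent.id, [start, end], r_i)
                    new_tips.append((br, br.points[-1], end - start))
            tips = new_tips
    return branches


def rasterize_centerlines(branches: list[Branch], shape) -> np.ndarray:
    """Boolean volume marking every voxel a centerline passes through."""
    mask = np.zeros(shape, dtype=bool)
    for br in branches:
        idx = np.rint(br.points).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


def _tube_mask(branch: Branch, shape) -> np.ndarray:
    center = rasterize_centerlines([branch], shape)
    dist = ndimage.distance_transform_edt(~center)
    return dist <= branch.radius


def _bone_mask(spec: PhantomSpec, vessel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Skull-like shell capping the intracranial band plus vertebra-like blobs."""
    Z, Y, X = spec.shape
    z2 = int(Z * spec.region_z_fractions[1])
    zz, yy, xx = np.meshgrid(np.arange(Z), np.arange(Y), np.arange(X),
                             indexing="ij", sparse=True)

    # Shell radius: just clear of the intracranial vessels by the configured gap.
    center = np.array([z2, Y * 0.5, X * 0.5])
    upper = vessel.copy()
    upper[: z2] = False
    if upper.any():
        pts = np.argwhere(upper)
        r_inner = float(np.linalg.norm(pts - center, axis=1).max()) + spec.bone_vessel_clearance
    else:
        r_inner = 0.38 * min(Y, X)
    r_inner = min(r_inner, 0.5 * min(Y, X) - 1 - spec.skull_thickness)
    dist = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    shell = (dist >= r_inner) & (dist <= r_inner + spec.skull_thickness) & (zz >= z2)

    # Vertebra-like blobs behind the carotids in the middle band.
    z1 = int(Z * spec.region_z_fractions[0])
    blobs = np.zeros(spec.shape, dtype=bool)
    for zc in np.linspace(z1 + 3, z2 - 3, 3):
        yc = Y * 0.78 + rng.normal(0, 0.5)
        xc = X * 0.5 + rng.normal(0, 0.5)
        d2 = ((zz - zc) / 3.5) ** 2 + ((yy - yc) / 4.5) ** 2 + ((xx - xc) / 4.5) ** 2
        blobs |= d2 <= 1.0
    return shell | blobs


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelVolume, list[Branch]]:
    """Build one phantom: intensity volume, 4-class labels, and centerlines.

    Deterministic for a fixed ``spec.seed``. The vessel union is a single
    26-connected component, and vessel region classes are assigned by z-band,
    so every aorta-labelled voxel lies below the first cut and every
    intracranial voxel above the second.
    """
    Z, Y, X = spec.shape
    if min(spec.shape) < 24:
        raise GenerationError(f"shape {spec.shape} too small to host the vessel tree")
    z1, z2 = int(Z * spec.region_z_fractions[0]), int(Z * spec.region_z_fractions[1])
    if z1 < 6 or z2 - z1 < 6 or Z - z2 < 8:
        raise GenerationError("region bands too thin for the requested tree")

    rng = np.random.default_rng(spec.seed)
    branches = _grow_branches(spec, rng)

    vessel = np.zeros(spec.shape, dtype=bool)
    for br in branches:
        vessel |= _tube_mask(br, spec.shape)

    bone = _bone_mask(spec, vessel, rng) & ~vessel  # vessels win where they overlap

    label = np.zeros(spec.shape, dtype=np.int16)
    label[bone] = BONE
    zz = np.arange(Z)[:, None, None]
    label[vessel & (zz < z1)] = AORTA
    label[vessel & (zz >= z1) & (zz < z2)] = CAROTID
    label[vessel & (zz >= z2)] = INTRACRANIAL

    data = np.full(spec.shape, spec.background_intensity, dtype=np.float32)
    data[vessel] = spec.vessel_intensity
    data[bone] = spec.bone_intensity
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, spec.shape).astype(np.float32)

    return Volume(data), LabelVolume(label), branches


def inject_ruptures(
    label: LabelVolume,
    branches: list[Branch],
    rupture_spec: RuptureSpec,
) -> tuple[LabelVolume, RuptureRecord]:
    """Sever vessel branches at interior centerline points.

    Each gap removes the vessel voxels inside a ball centred on an interior
    centerline point (radius = branch radius + gap_length/2), which severs the
    tube locally under 26-connectivity. The record stores the removed voxels
    per gap and whether the gap actually increased the component count
    (a gap may be bridged elsewhere by an adjacent branch).
    """
    if rupture_spec.count < 0:
        raise ValueError("rupture count must be >= 0")
    out = label.data.copy()
    record = RuptureRecord()
    if rupture_spec.count == 0:
        return LabelVolume(out, label.spacing), record
    candidates = [br for br in branches if len(br.points) >= 8]
    if rupture_spec.count > len(candidates):
        raise ValueError(
            f"requested {rupture_spec.count} gaps but only {len(candidates)} branches "
            "have enough interior centerline length")

    rng = np.random.default_rng(rupture_spec.seed)
    order = rng.permutation(len(candidates))[: rupture_spec.count]
    vessel = np.isin(out, VESSEL_CLASSES)
    n_before, _ = _count_components(vessel)

    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in label.shape],
                             indexing="ij", sparse=True)
    for k in order:
        br = candidates[k]
        lo, hi = int(len(br.points) * 0.35), int(len(br.points) * 0.65)
        center = br.points[rng.integers(lo, max(hi, lo + 1))]
        ball_r = br.radius + rupture_spec.gap_length / 2.0
        d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        removed = (d2 <= ball_r ** 2) & np.isin(out, VESSEL_CLASSES)
        voxels = np.argwhere(removed)
        out[removed] = 0
        n_now, _ = _count_components(np.isin(out, VESSEL_CLASSES))
        effective = n_now > n_before
        n_before = n_now
        record.gaps.append({
            "branch": br.id,
            "center": center.copy(),
            "voxels": voxels,
            "effective": bool(effective),
        })
    return LabelVolume(out, label.spacing), record


def _count_components(mask: np.ndarray) -> tuple[int, np.ndarray]:
    labeled, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    return n, labeled


def count_vessel_components(label_or_mask) -> int:
    """26-connected component count of the vessel union."""
    arr = (label_or_mask.data if isinstance(label_or_mask, (Volume, LabelVolume))
           else np.asarray(label_or_mask))
    if arr.dtype == bool:
        mask = arr
    else:
        mask = np.isin(arr, VESSEL_CLASSES)
    return _count_components(mask)[0]


def centerline_geodesic_distances(
    branches: list[Branch],
    root_point,
) -> tuple[np.ndarray, np.ndarray]:
    """Geodesic (along-tree) distance of every centerline point from the root.

    Returns ``(points, distances)`` where points is the concatenation of all
    branch centerlines. The tree graph chains consecutive points within a
    branch and joins each child's first point to the nearest point of its
    parent. Raises if ``root_point`` does not lie on the tree.
    """
    pts = np.concatenate([br.points for br in branches], axis=0)
    offsets = np.cumsum([0] + [len(br.points) for br in branches])
    rows, cols, wts = [], [], []
    by_id = {br.id: i for i, br in enumerate(branches)}
    for i, br in enumerate(branches):
        o = offsets[i]
        seg = np.linalg.norm(np.diff(br.points, axis=0), axis=1)
        rows.extend(range(o, o + len(br.points) - 1))
        cols.extend(range(o + 1, o + len(br.points)))
        wts.extend(seg)
        if br.parent is not None:
            pi = by_id[br.parent]
            parent_pts = branches[pi].points
            d = np.linalg.norm(parent_pts - br.points[0], axis=1)
            j = int(np.argmin(d))
            rows.append(offsets[pi] + j)
            cols.append(o)
            wts.append(float(d[j]))
    n = len(pts)
    graph = coo_matrix((wts, (rows, cols)), shape=(n, n))
    root_point = np.asarray(root_point, dtype=np.float64)
    d_root = np.linalg.norm(pts - root_point, axis=1)
    root_idx = int(np.argmin(d_root))
    max_r = max(br.radius for br in branches)
    if d_root[root_idx] > max(max_r, 1.5):
        raise ValueError(f"root point {root_point} does not lie on the vessel tree")
    dist = dijkstra(graph, directed=False, indices=root_idx)
    return pts, dist


def vessel_weight_map(
    label: LabelVolume | np.ndarray,
    branches: list[Branch],
    root_point=None,
    decay: float = 0.05,
) -> np.ndarray:
    """Per-voxel continuity weights: ``exp(-decay * geodesic distance)``.

    Weights are positive on vessel voxels, zero elsewhere, and non-increasing
    with along-centerline distance from the root (strictly decreasing between
    distinct distances when ``decay > 0``). ``decay = 0`` gives uniform
    weights, under which the V-score degenerates to recall.
    """
    if decay < 0:
        raise ValueError("decay must be >= 0")
    arr = label.data if isinstance(label, (Volume, LabelVolume)) else np.asarray(label)
    vessel = np.isin(arr, VESSEL_CLASSES) if arr.dtype != bool else arr
    if root_point is None:
        root_point = min(branches, key=lambda b: (b.parent is not None,)).points[0]
    pts, dist = centerline_geodesic_distances(branches, root_point)
    weights = np.zeros(arr.shape, dtype=np.float64)
    vox = np.argwhere(vessel)
    if len(vox):
        tree = cKDTree(pts)
        _, nearest = tree.query(vox)
        weights[vox[:, 0], vox[:, 1], vox[:, 2]] = np.exp(-decay * dist[nearest])
    return weights


def make_toy_tube(
    length: int = 24,
    radius: float = 1.5,
    shape: tuple[int, int, int] | None = None,
) -> tuple[LabelVolume, Branch]:
    """A single straight unbranched tube along z — the workhorse test fixture."""
    if shape is None:
        pad = int(np.ceil(radius)) + 3
        shape = (length + 2 * pad, 2 * pad + 1, 2 * pad + 1)
    Z, Y, X = shape
    z0 = (Z - length) // 2
    pts = np.stack([np.arange(z0, z0 + length, 0.5),
                    np.full(length * 2, Y / 2.0),
                    np.full(length * 2, X / 2.0)], axis=1)
    branch = Branch(0, "carotid", None, pts, float(radius))
    label = np.zeros(shape, dtype=np.int16)
    label[_tube_mask(branch, shape)] = CAROTID
    return LabelVolume(label), branch
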