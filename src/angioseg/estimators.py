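"""Scikit-learn-style estimators for the segmentation cascade.

Each stage is an estimator with ``fit`` / ``predict`` and ``get_params`` /
``set_params`` (via :class:`sklearn.base.BaseEstimator`); fitted state lives
in trailing-underscore attributes. :class:`CascadePipeline` composes the
stages end-to-end and doubles as the "model bundle" the functional wrappers
in :mod:`angioseg.cascade` accept.

Inputs to ``fit`` are lists of volumes and 4-class label volumes (the
phantom module's output); ``predict`` consumes one volume at a time. The
voxel grid is the sample axis here, so these estimators do not validate
2D feature matrices the way tabular sklearn estimators do.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, skeletonize
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import metrics as _metrics
from .augment import remove_scattered_noise
from .cascade import CascadeResult, RegionPartition, split_regions, subtract_bone
from .network import NetworkConfig, build_resunet, load_network, save_network
from .phantom import (CONNECTIVITY_26, RuptureSpec, VESSEL_CLASSES,
                      count_vessel_components, inject_ruptures)
from .training import (Sample, TrainConfig, centerline_weight, predict_padded,
                       train)
from .volume_io import LabelVolume, Volume


def _data(v) -> np.ndarray:
    return v.data if isinstance(v, (Volume, LabelVolume)) else np.asarray(v)


def _check_fitted(est, attrs):
    for a in attrs:
        if not hasattr(est, a):
            raise NotFittedError(
                f"{type(est).__name__} is not fitted yet; call fit() first")


class _StageMixin:
    """Shared hyperparameters -> NetworkConfig / TrainConfig plumbing."""

    def _net_config(self, in_channels: int, n_classes: int) -> NetworkConfig:
        return NetworkConfig(
            in_channels=in_channels, n_classes=n_classes,
            base_width=self.base_width, levels=self.levels,
            n_blocks=self.n_blocks, negative_slope=self.negative_slope,
            head_bias=self.head_bias)

    def _train_config(self, steps: int, seed: int) -> TrainConfig:
        # eval_every=steps: score the fit once at the end; mid-run scoring is
        # pure observation but costs full-volume forward passes
        return TrainConfig(
            learning_rate=self.learning_rate, lr_decay=self.lr_decay,
            momentum=self.momentum, weight_decay=self.weight_decay,
            steps=steps, batch_size=self.batch_size,
            patch_size=self.patch_size, seed=seed, eval_every=steps)


class BoneSegmenter(_StageMixin, BaseEstimator):
    """Two cascaded nets for bone: a segmenter and a boundary refiner.

    The first net maps the intensity volume to a bone probability; the
    second consumes the volume plus that probability as a second channel and
    refines the boundary. ``predict`` thresholds the refined probability.
    """

    def __init__(self, base_width=8, levels=4, n_blocks=8, negative_slope=0.1,
                 threshold=0.5, steps=700, refine_steps=400, batch_size=1,
                 patch_size=32, learning_rate=0.01, lr_decay=0.99995,
                 momentum=0.9, weight_decay=1e-4, intensity_scale=300.0,
                 head_bias=-2.0, random_state=0):
        self.base_width = base_width
        self.levels = levels
        self.n_blocks = n_blocks
        self.negative_slope = negative_slope
        self.threshold = threshold
        self.steps = steps
        self.refine_steps = refine_steps
        self.head_bias = head_bias
        self.batch_size = batch_size
        self.patch_size = patch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.intensity_scale = intensity_scale
        self.random_state = random_state

    def fit(self, volumes, labels):
        xs = [(_data(v) / self.intensity_scale).astype(np.float32)[..., None]
              for v in volumes]
        ys = [(_data(l) == 1).astype(np.float32)[..., None] for l in labels]
        self.net1_ = build_resunet(self._net_config(1, 1), seed=self.random_state)
        self.history1_ = train(self.net1_, [Sample(x, y) for x, y in zip(xs, ys)],
                               self._train_config(self.steps, self.random_state),
                               val_dataset=[])
        refine_samples = []
        for x, y in zip(xs, ys):
            p1 = predict_padded(self.net1_, x)
            refine_samples.append(Sample(np.concatenate([x, p1], axis=-1), y))
        self.net2_ = build_resunet(self._net_config(2, 1), seed=self.random_state + 1)
        self.history2_ = train(self.net2_, refine_samples,
                               self._train_config(self.refine_steps,
                                                  self.random_state + 1),
                               val_dataset=[])
        return self

    def predict_proba(self, volume) -> np.ndarray:
        _check_fitted(self, ["net1_", "net2_"])
        x = (_data(volume) / self.intensity_scale).astype(np.float32)[..., None]
        p1 = predict_padded(self.net1_, x)
        p2 = predict_padded(self.net2_, np.concatenate([x, p1], axis=-1))
        return p2[..., 0]

    def predict(self, volume) -> np.ndarray:
        return _metrics.binarize(self.predict_proba(volume), self.threshold)


class VesselSegmenter(_StageMixin, BaseEstimator):
    """Region-conditioned vessel net covering the three arterial size regimes.

    One weight set serves all regions: the input carries three one-hot
    region-band channels (aorta / carotid / intracranial) alongside the
    intensity channel, and the net outputs one sigmoid vessel probability
    per voxel. The artery *class* of a predicted voxel is given by its
    anatomical band — that classification is precisely what the region
    split encodes. (A separate sigmoid head per artery class is the obvious
    alternative, but for the thinnest class its pure-Dice training has an
    all-positive equilibrium that traps a fraction of seeds; the shared
    vessel head has no such failure mode.) With
    ``use_region_channels=False`` the conditioning channels are dropped
    (the no-region-split ablation); classes are still banded.
    """

    def __init__(self, base_width=8, levels=4, n_blocks=8, negative_slope=0.1,
                 threshold=0.5, steps=500, batch_size=1, patch_size=32,
                 learning_rate=0.01, lr_decay=0.99995, momentum=0.9,
                 weight_decay=1e-4, intensity_scale=300.0,
                 region_fractions=(1 / 3, 2 / 3), use_region_channels=True,
                 centerline_weight_factor=2.0, head_bias=-2.0, random_state=0):
        self.base_width = base_width
        self.levels = levels
        self.n_blocks = n_blocks
        self.negative_slope = negative_slope
        self.threshold = threshold
        self.steps = steps
        self.batch_size = batch_size
        self.patch_size = patch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.intensity_scale = intensity_scale
        self.region_fractions = region_fractions
        self.use_region_channels = use_region_channels
        self.centerline_weight_factor = centerline_weight_factor
        self.head_bias = head_bias
        self.random_state = random_state

    def _region_channels(self, shape) -> np.ndarray:
        part = RegionPartition(tuple(self.region_fractions), shape[0])
        region = part.region_of_z()
        ch = np.zeros(shape + (3,), dtype=np.float32)
        for r in range(3):
            ch[region == r, :, :, r] = 1.0
        return ch

    def _build_input(self, data, region_channels=None) -> np.ndarray:
        x = (data / self.intensity_scale).astype(np.float32)[..., None]
        if not self.use_region_channels:
            return x
        if region_channels is None:
            region_channels = self._region_channels(data.shape)
        return np.concatenate([x, region_channels], axis=-1)

    def fit(self, volumes, labels, branches_list=None):
        samples = []
        for i, (v, l) in enumerate(zip(volumes, labels)):
            data, lab = _data(v), _data(l)
            y = np.isin(lab, VESSEL_CLASSES).astype(np.float32)[..., None]
            w = None
            if self.centerline_weight_factor > 1 and branches_list is not None:
                w = centerline_weight(lab, branches_list[i],
                                      self.centerline_weight_factor)
            samples.append(Sample(self._build_input(data), y, weight=w))
        cin = 4 if self.use_region_channels else 1
        self.net_ = build_resunet(self._net_config(cin, 1), seed=self.random_state)
        self.history_ = train(self.net_, samples,
                              self._train_config(self.steps, self.random_state),
                              val_dataset=[])
        return self

    def predict_proba(self, volume, partition: RegionPartition | None = None,
                      condition_regions: bool | None = None) -> np.ndarray:
        """Per-voxel vessel probability, run band-by-band and merged along z.

        ``condition_regions=False`` zeroes the conditioning channels and runs
        the whole volume at once (the no-region-split ablation).
        """
        _check_fitted(self, ["net_"])
        data = _data(volume)
        if condition_regions is None:
            condition_regions = self.use_region_channels
        if not self.use_region_channels:
            return predict_padded(self.net_, self._build_input(data))[..., 0]
        if not condition_regions:
            x = np.concatenate(
                [(data / self.intensity_scale).astype(np.float32)[..., None],
                 np.zeros(data.shape + (3,), dtype=np.float32)], axis=-1)
            return predict_padded(self.net_, x)[..., 0]
        if partition is None:
            partition = RegionPartition(tuple(self.region_fractions), data.shape[0])
        region_ch = np.zeros(data.shape + (3,), dtype=np.float32)
        for r, band in enumerate(partition.bands):
            region_ch[band, ..., r] = 1.0
        outs = []
        for sub, sub_ch in zip(split_regions(data, partition),
                               split_regions(region_ch, partition)):
            outs.append(predict_padded(self.net_, self._build_input(sub, sub_ch)))
        return np.concatenate(outs, axis=0)[..., 0]

    def predict(self, volume, partition: RegionPartition | None = None,
                condition_regions: bool | None = None) -> np.ndarray:
        """Class labels {0, 2, 3, 4}: thresholded vessel probability, with the
        artery class given by the voxel's anatomical z-band."""
        prob = self.predict_proba(volume, partition, condition_regions)
        if partition is None:
            partition = RegionPartition(tuple(self.region_fractions),
                                        prob.shape[0])
        out = np.zeros(prob.shape, dtype=np.int16)
        mask = prob >= self.threshold
        band_class = np.asarray(VESSEL_CLASSES, dtype=np.int16)[
            partition.region_of_z()]
        out[mask] = np.broadcast_to(band_class[:, None, None], prob.shape)[mask]
        return out


class RuptureRepairer(_StageMixin, BaseEstimator):
    """Connected-growth repair: predicts missing vessel voxels from the image
    and the current (possibly ruptured) segmentation, then fills them.

    Additions are restricted to a dilated corridor around endpoints of the
    input mask and must connect to it, so the repair only ever merges
    components: the output is a superset of the input and its 26-connected
    component count never exceeds the input's.
    """

    def __init__(self, base_width=8, levels=4, n_blocks=8, negative_slope=0.1,
                 threshold=0.5, steps=250, batch_size=1, patch_size=32,
                 learning_rate=0.01, lr_decay=0.99995, momentum=0.9,
                 weight_decay=1e-4, intensity_scale=300.0, corridor_radius=5,
                 head_bias=0.0, random_state=0):
        self.base_width = base_width
        self.levels = levels
        self.n_blocks = n_blocks
        self.negative_slope = negative_slope
        self.threshold = threshold
        self.steps = steps
        self.batch_size = batch_size
        self.patch_size = patch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.intensity_scale = intensity_scale
        self.corridor_radius = corridor_radius
        self.head_bias = head_bias
        self.random_state = random_state

    def _build_input(self, data, mask) -> np.ndarray:
        return np.stack([(data / self.intensity_scale).astype(np.float32),
                         mask.astype(np.float32)], axis=-1)

    def fit(self, volumes, broken_masks, intact_masks):
        samples = []
        for v, broken, intact in zip(volumes, broken_masks, intact_masks):
            data = _data(v)
            broken = np.asarray(broken, dtype=bool)
            missing = np.asarray(intact, dtype=bool) & ~broken
            samples.append(Sample(self._build_input(data, broken),
                                  missing.astype(np.float32)[..., None]))
        self.net_ = build_resunet(self._net_config(2, 1), seed=self.random_state)
        self.history_ = train(self.net_, samples,
                              self._train_config(self.steps, self.random_state),
                              val_dataset=[])
        return self

    def endpoint_corridor(self, mask: np.ndarray) -> np.ndarray:
        """Voxels near skeleton endpoints of the mask, excluding the mask."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return np.zeros_like(mask)
        skel = skeletonize(mask).astype(bool)
        neighbor_count = ndimage.convolve(
            skel.astype(np.int8), CONNECTIVITY_26.astype(np.int8), mode="constant")
        endpoints = skel & (neighbor_count <= 2)  # self + at most one neighbour
        if not endpoints.any():
            return np.zeros_like(mask)
        corridor = ndimage.binary_dilation(endpoints, structure=ball(self.corridor_radius))
        return corridor & ~mask

    def predict_proba(self, volume, mask) -> np.ndarray:
        _check_fitted(self, ["net_"])
        data = _data(volume)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise ValueError(f"mask shape {mask.shape} != volume shape {data.shape}")
        return predict_padded(self.net_, self._build_input(data, mask))[..., 0]

    def predict(self, volume, mask) -> np.ndarray:
        mask = np.asarray(mask, dtype=bool)
        prob = self.predict_proba(volume, mask)
        additions = _metrics.binarize(prob, self.threshold) & self.endpoint_corridor(mask)
        if not additions.any():
            return mask.copy()
        union = mask | additions
        labeled, _ = ndimage.label(union, structure=CONNECTIVITY_26)
        anchored = np.unique(labeled[mask])
        keep = additions & np.isin(labeled, anchored)
        return mask | keep


class CascadePipeline(_StageMixin, BaseEstimator):
    """End-to-end cascade: bone -> subtraction -> region split -> vessels ->
    repair -> small-component cleanup, with per-stage metrics.

    ``fit`` trains every stage on phantom (volume, label, centerlines)
    triples; ``predict`` returns a :class:`~angioseg.cascade.CascadeResult`.
    The ablation flags (``use_bone``, ``use_region``, ``use_cgpm``) select
    pipeline variants at prediction time.
    """

    def __init__(self, base_width=8, levels=4, n_blocks=8, negative_slope=0.1,
                 threshold=0.5, steps_bone=700, refine_steps=400,
                 steps_vessel=500, steps_repair=600, batch_size=1,
                 patch_size=32, learning_rate=0.01, lr_decay=0.99995,
                 momentum=0.9, weight_decay=1e-4, intensity_scale=300.0,
                 background_fill=40.0, region_fractions=(1 / 3, 2 / 3),
                 centerline_weight_factor=2.0, corridor_radius=5,
                 min_component_size=8, train_gap_count=2, train_gap_length=3.0,
                 use_bone=True, use_region=True, use_cgpm=True, random_state=0):
        self.base_width = base_width
        self.levels = levels
        self.n_blocks = n_blocks
        self.negative_slope = negative_slope
        self.threshold = threshold
        self.steps_bone = steps_bone
        self.refine_steps = refine_steps
        self.steps_vessel = steps_vessel
        self.steps_repair = steps_repair
        self.batch_size = batch_size
        self.patch_size = patch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.intensity_scale = intensity_scale
        self.background_fill = background_fill
        self.region_fractions = region_fractions
        self.centerline_weight_factor = centerline_weight_factor
        self.corridor_radius = corridor_radius
        self.min_component_size = min_component_size
        self.train_gap_count = train_gap_count
        self.train_gap_length = train_gap_length
        self.use_bone = use_bone
        self.use_region = use_region
        self.use_cgpm = use_cgpm
        self.random_state = random_state

    def _shared(self) -> dict:
        return dict(base_width=self.base_width, levels=self.levels,
                    n_blocks=self.n_blocks, negative_slope=self.negative_slope,
                    threshold=self.threshold, batch_size=self.batch_size,
                    patch_size=self.patch_size, learning_rate=self.learning_rate,
                    lr_decay=self.lr_decay, momentum=self.momentum,
                    weight_decay=self.weight_decay,
                    intensity_scale=self.intensity_scale)

    def fit(self, volumes, labels, branches_list=None):
        shared = self._shared()
        self.bone_ = BoneSegmenter(steps=self.steps_bone,
                                   refine_steps=self.refine_steps,
                                   random_state=self.random_state, **shared)
        self.bone_.fit(volumes, labels)

        # Vessel and repair nets train on volumes subtracted with the
        # *predicted* bone mask, matching what they will see at deployment
        # (residual bone is learned as background, erased voxels as absent).
        subtracted = [subtract_bone(_data(v), self.bone_.predict(v),
                                    self.background_fill) for v in volumes]
        self.vessel_ = VesselSegmenter(
            steps=self.steps_vessel, region_fractions=self.region_fractions,
            use_region_channels=self.use_region,
            centerline_weight_factor=self.centerline_weight_factor,
            random_state=self.random_state + 10, **shared)
        self.vessel_.fit(subtracted, labels, branches_list)

        broken_masks, intact_masks = [], []
        if branches_list is not None:
            for i, (l, br) in enumerate(zip(labels, branches_list)):
                lab = l if isinstance(l, LabelVolume) else LabelVolume(_data(l))
                spec = RuptureSpec(count=self.train_gap_count,
                                   gap_length=self.train_gap_length,
                                   seed=self.random_state + 100 + i)
                ruptured, _ = inject_ruptures(lab, br, spec)
                broken_masks.append(np.isin(ruptured.data, VESSEL_CLASSES))
                intact_masks.append(np.isin(lab.data, VESSEL_CLASSES))
        self.repair_ = RuptureRepairer(
            steps=self.steps_repair, corridor_radius=self.corridor_radius,
            random_state=self.random_state + 20, **shared)
        if broken_masks:
            self.repair_.fit(subtracted, broken_masks, intact_masks)
        return self

    def predict(self, volume, truth=None, truth_weights=None, *,
                use_bone=None, use_region=None, use_cgpm=None) -> CascadeResult:
        _check_fitted(self, ["bone_", "vessel_"])
        use_bone = self.use_bone if use_bone is None else use_bone
        use_region = self.use_region if use_region is None else use_region
        use_cgpm = self.use_cgpm if use_cgpm is None else use_cgpm

        data = _data(volume)
        if use_bone:
            bone_prob = self.bone_.predict_proba(volume)
            bone_mask = _metrics.binarize(bone_prob, self.threshold)
        else:
            bone_prob, bone_mask = None, np.zeros(data.shape, dtype=bool)
        spacing = volume.spacing if isinstance(volume, Volume) else (1.0, 1.0, 1.0)
        subtracted = Volume(
            subtract_bone(data, bone_mask, self.background_fill), spacing)

        partition = RegionPartition(tuple(self.region_fractions), data.shape[0])
        classes = self.vessel_.predict(subtracted, partition,
                                       condition_regions=use_region)
        pre = classes > 0
        bone_mask = bone_mask & ~pre  # vessels win ties: masks stay disjoint

        if use_cgpm and hasattr(self.repair_, "net_"):
            repaired = self.repair_.predict(subtracted, pre)
        else:
            repaired = pre.copy()

        # Added voxels inherit the class of the region band they fall in.
        labels_rep = classes.copy()
        added = repaired & ~pre
        if added.any():
            region = partition.region_of_z()
            band_class = np.asarray(VESSEL_CLASSES, dtype=np.int16)[region]
            labels_rep[added] = band_class[np.nonzero(added)[0]]
        cleaned = remove_scattered_noise(LabelVolume(labels_rep, spacing),
                                         self.min_component_size)

        result = CascadeResult(
            bone_prob=bone_prob, bone_mask=bone_mask, subtracted=subtracted,
            partition=partition, vessel_classes=classes, vessel_mask_pre=pre,
            vessel_mask_repaired=repaired, labels_clean=cleaned.data)
        if truth is not None:
            result.metrics = self._evaluate(result, truth, truth_weights)
        return result

    def _evaluate(self, result: CascadeResult, truth, weights=None) -> dict:
        """Score against ground truth: the headline vessel numbers are for the
        pipeline's final output (repaired + small-component cleanup); the
        ``*_pre`` entries score the pre-repair mask."""
        lab = _data(truth)
        truth_bone = lab == 1
        truth_vessel = np.isin(lab, VESSEL_CLASSES)
        final = result.labels_clean > 0
        out = {
            "vessel_dsc": _metrics.dsc(final, truth_vessel),
            "vessel_dsc_pre": _metrics.dsc(result.vessel_mask_pre, truth_vessel),
            "vessel_recall": _metrics.recall(final, truth_vessel),
            "vessel_recall_pre": _metrics.recall(result.vessel_mask_pre, truth_vessel),
            "components_pre": count_vessel_components(result.vessel_mask_pre),
            "components_post": count_vessel_components(result.vessel_mask_repaired),
        }
        if truth_bone.any() or result.bone_mask.any():
            out["bone_dsc"] = _metrics.dsc(result.bone_mask, truth_bone)
        if weights is not None:
            out["vessel_v_score"] = _metrics.v_score(final, truth_vessel, weights)
            out["vessel_v_score_pre"] = _metrics.v_score(
                result.vessel_mask_pre, truth_vessel, weights)
        return out

    # -- bundle persistence -------------------------------------------------
    def save_bundle(self, out_dir) -> None:
        _check_fitted(self, ["bone_", "vessel_"])
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_network(self.bone_.net1_, out / "bone1.npz", out / "bone1.json")
        save_network(self.bone_.net2_, out / "bone2.npz", out / "bone2.json")
        save_network(self.vessel_.net_, out / "vessel.npz", out / "vessel.json")
        if hasattr(self.repair_, "net_"):
            save_network(self.repair_.net_, out / "repair.npz", out / "repair.json")
        import json
        with open(out / "pipeline.json", "w") as fh:
            json.dump(self.get_params(), fh, indent=2, default=list)

    @classmethod
    def load_bundle(cls, bundle_dir) -> "CascadePipeline":
        import json
        d = Path(bundle_dir)
        with open(d / "pipeline.json") as fh:
            params = json.load(fh)
        params["region_fractions"] = tuple(params["region_fractions"])
        pipe = cls(**params)
        shared = pipe._shared()
        pipe.bone_ = BoneSegmenter(steps=pipe.steps_bone, refine_steps=pipe.refine_steps,
                                   random_state=pipe.random_state, **shared)
        pipe.bone_.net1_ = load_network(d / "bone1.npz", path_json=d / "bone1.json")
        pipe.bone_.net2_ = load_network(d / "bone2.npz", path_json=d / "bone2.json")
        pipe.vessel_ = VesselSegmenter(
            steps=pipe.steps_vessel, region_fractions=pipe.region_fractions,
            use_region_channels=pipe.use_region,
            centerline_weight_factor=pipe.centerline_weight_factor,
            random_state=pipe.random_state + 10, **shared)
        pipe.vessel_.net_ = load_network(d / "vessel.npz", path_json=d / "vessel.json")
        pipe.repair_ = RuptureRepairer(steps=pipe.steps_repair,
                                       corridor_radius=pipe.corridor_radius,
                                       random_state=pipe.random_state + 20, **shared)
        if (d / "repair.npz").exists():
            pipe.repair_.net_ = load_network(d / "repair.npz", path_json=d / "repair.json")
        return pipe
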