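"""Seeded intensity-range region growing ("masking wand") segmentation.

The workflow mirrors interactive per-cross-section labeling of a microCT
volume by a trained operator:

* the *masking wand* selects all pixels 4-connected to a seed click whose
  intensity lies in an operator-calibrated range;
* one layer of "medium gray" partial-volume border pixels on the outside
  edge of the wand selection is then included, gated by a second intensity
  band (the border calibration);
* the seed is propagated slice to slice automatically (centroid-nearest
  in-mask pixel of the previous slice), standing in for the operator's
  repeated clicking;
* for four-material samples the materials are claimed sequentially —
  lumen, then heat-shrink tubing, then graft wall — and the thrombus is the
  remaining material inside the wall.

Segmentation is strictly 2D per slice with in-plane 4-connectivity: the
per-cross-section workflow avoids 3D leaks through partial-volume bridges.
No denoising or pre-filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import VoxelImage, LabelVolume, MATERIAL_LABELS

__all__ = [
    "IntensityRange",
    "SegmentationCalibration",
    "TargetSpec",
    "AnalysisMode",
    "SliceQC",
    "SegmentationResult",
    "FourMaterialResult",
    "masking_wand",
    "include_border_layer",
    "propagate_seed",
    "segment_target",
    "segment_four_material",
    "global_threshold_masks",
    "auto_seed",
    "default_analysis_mode",
    "find_slice_span",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class IntensityRange:
    """Inclusive intensity band [lo, hi] in image units."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"need lo <= hi, got ({self.lo}, {self.hi})")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.lo) & (values <= self.hi)


@dataclass(frozen=True)
class SegmentationCalibration:
    """Operator calibration for one target material.

    ``core_range`` bounds the bright/dark target interior; ``border_range``
    is the "medium gray" partial-volume band whose pixels are annexed one
    layer at a time (``border_layers``, default 1) on the outside edge of
    the wand selection.  The gray band is an explicit input because real
    gray levels are scanner- and staining-dependent.
    """

    core_range: IntensityRange
    border_range: IntensityRange | None = None
    border_layers: int = 1
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.border_layers < 0:
            raise ValueError("border_layers must be >= 0")
        if self.connectivity != 4:
            raise ValueError("only in-plane 4-connectivity is supported")


@dataclass(frozen=True)
class TargetSpec:
    """One explicitly-segmented material within an analysis mode."""

    material: str
    calibration: SegmentationCalibration
    seed: tuple[int, int] | None = None  # (row, col) on the first analyzed slice


@dataclass(frozen=True)
class AnalysisMode:
    """Material-type-dependent segmentation recipe.

    ``material_type`` is one of ``PVA`` (radiopaque lumen),
    ``ePTFE`` (radiopaque thrombus) or ``collagen_ePTFE`` (four nested
    materials with the thrombus as the remainder).  ``targets`` are claimed
    in order; ``remainder_material`` (four-material mode only) names the
    material assigned to the unclaimed interior of the wall.
    """

    material_type: str
    targets: tuple[TargetSpec, ...]
    remainder_material: str | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("an analysis mode needs at least one target")
        if self.material_type == "collagen_ePTFE" and self.remainder_material is None:
            raise ValueError("four-material mode must name a remainder material")


@dataclass
class SliceQC:
    """Per-slice quality-control record of one target's traversal."""

    slice_index: int
    seed: tuple[int, int] | None
    n_pixels: int
    used_fallback: bool = False
    empty: bool = False


@dataclass
class SegmentationResult:
    """Per-slice mask stack for one target material."""

    masks: np.ndarray  # bool, full volume shape; False outside the analyzed range
    qc: list[SliceQC] = field(default_factory=list)

    @property
    def voxel_count(self) -> int:
        return int(self.masks.sum())


@dataclass
class FourMaterialResult:
    """Sequential four-material labeling output."""

    labels: LabelVolume
    flagged_slices: list[int] = field(default_factory=list)
    qc: dict[str, list[SliceQC]] = field(default_factory=dict)


def _check_seed(shape: tuple[int, int], seed) -> tuple[int, int]:
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < shape[0] and 0 <= c < shape[1]):
        raise ValueError(f"seed {seed} outside slice bounds {shape}")
    return r, c


def _wand2d(
    slice2d: np.ndarray,
    seed: tuple[int, int],
    rng: IntensityRange,
    available: np.ndarray | None = None,
) -> np.ndarray:
    """4-connected in-range component containing the seed (2D core)."""
    in_range = rng.contains(slice2d)
    if available is not None:
        in_range &= available
    r, c = seed
    if not in_range[r, c]:
        return np.zeros(slice2d.shape, dtype=bool)
    comp, _ = ndimage.label(in_range, structure=_CROSS)
    return comp == comp[r, c]


def masking_wand(
    image: VoxelImage,
    slice_index: int,
    seed: tuple[int, int],
    rng: IntensityRange,
) -> np.ndarray:
    """Masking-wand selection on one cross-sectional slice.

    Returns exactly the 4-connected component of pixels with
    ``lo <= I <= hi`` that contains the seed click; an empty mask if the
    seed's own intensity falls outside the range.
    """
    if not 0 <= slice_index < image.n_slices:
        raise ValueError(f"slice_index {slice_index} out of range")
    slice2d = image.data[slice_index]
    return _wand2d(slice2d, _check_seed(slice2d.shape, seed), rng)


def include_border_layer(
    mask: np.ndarray,
    slice2d: np.ndarray,
    border_range: IntensityRange,
    layers: int = 1,
    available: np.ndarray | None = None,
) -> np.ndarray:
    """Annex up to ``layers`` rings of border-band pixels onto a mask.

    Each pass adds the pixels 4-adjacent to the current mask whose
    intensity lies in ``border_range``; ``layers=0`` is the identity.  The
    result is always a superset of the input, and the operation is
    idempotent once no adjacent border-band pixels remain.
    """
    if mask.shape != slice2d.shape:
        raise ValueError("mask and slice shapes differ")
    out = mask.copy()
    in_border = border_range.contains(slice2d)
    if available is not None:
        in_border &= available
    for _ in range(layers):
        ring = ndimage.binary_dilation(out, structure=_CROSS) & ~out & in_border
        if not ring.any():
            break
        out |= ring
    return out


def propagate_seed(prev_mask: np.ndarray) -> tuple[int, int]:
    """Seed for the next slice: the in-mask pixel nearest the mask centroid.

    Guaranteed to lie inside the region even for crescents whose centroid
    falls in the hole.
    """
    coords = np.argwhere(prev_mask)
    if coords.size == 0:
        raise ValueError("cannot propagate a seed from an empty mask")
    centroid = coords.mean(axis=0)
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    r, c = coords[int(np.argmin(d2))]
    return int(r), int(c)


def auto_seed(
    slice2d: np.ndarray,
    core_range: IntensityRange,
    available: np.ndarray | None = None,
    exclude_border_components: bool = True,
) -> tuple[int, int] | None:
    """Automatic first click: centroid-nearest pixel of the largest in-range
    component, optionally skipping components that touch the image border
    (the surrounding bath shares the intensity of a dark lumen, but an
    operator never clicks outside the graft)."""
    in_range = core_range.contains(slice2d)
    if available is not None:
        in_range &= available
    comp, n = ndimage.label(in_range, structure=_CROSS)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    for idx in order:
        lab = idx + 1
        mask = comp == lab
        if exclude_border_components and (
            mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
        ):
            continue
        return propagate_seed(mask)
    return None


def find_slice_span(
    image: VoxelImage, core_range: IntensityRange, available: np.ndarray | None = None
) -> tuple[int, int]:
    """Half-open slice range containing any core-range pixel."""
    in_range = core_range.contains(image.data)
    if available is not None:
        in_range &= available
    hits = np.flatnonzero(in_range.any(axis=(1, 2)))
    if hits.size == 0:
        raise ValueError("no slice contains pixels in the core range")
    return int(hits[0]), int(hits[-1]) + 1


def _largest_component(in_range: np.ndarray) -> np.ndarray:
    comp, n = ndimage.label(in_range, structure=_CROSS)
    if n == 0:
        return np.zeros(in_range.shape, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    return comp == (int(np.argmax(sizes)) + 1)


def segment_target(
    image: VoxelImage,
    calibration: SegmentationCalibration,
    initial_seed: tuple[int, int],
    slice_range: tuple[int, int] | None = None,
    available: np.ndarray | None = None,
) -> SegmentationResult:
    """Traverse slices, growing the wand selection from a propagated seed.

    The first analyzed slice is segmented from ``initial_seed`` (an empty
    result there means the calibration is unusable and raises).  Each
    subsequent slice is seeded from the centroid of the previous non-empty
    mask; if the propagated seed lands out of range but in-range pixels
    exist, the largest in-range component is taken instead (an operator
    would re-click after an abrupt shape change).  Slices with no in-range
    pixels are recorded as empty — occlusion is a real outcome — and the
    traversal continues.
    """
    z0, z1 = slice_range if slice_range is not None else (0, image.n_slices)
    if not (0 <= z0 < z1 <= image.n_slices):
        raise ValueError(f"invalid slice range ({z0}, {z1})")
    masks = np.zeros(image.data.shape, dtype=bool)
    qc: list[SliceQC] = []
    prev_mask: np.ndarray | None = None
    for z in range(z0, z1):
        slice2d = image.data[z]
        avail2d = available[z] if available is not None else None
        fallback = False
        if prev_mask is None:
            seed = _check_seed(slice2d.shape, initial_seed)
        else:
            seed = propagate_seed(prev_mask)
        mask = _wand2d(slice2d, seed, calibration.core_range, avail2d)
        if not mask.any():
            in_range = calibration.core_range.contains(slice2d)
            if avail2d is not None:
                in_range &= avail2d
            if in_range.any():
                mask = _largest_component(in_range)
                fallback = True
                seed = propagate_seed(mask)
        if not mask.any():
            if prev_mask is None:
                raise ValueError(
                    f"first analyzed slice {z} yields an empty mask — "
                    "calibration unusable from this seed"
                )
            qc.append(SliceQC(z, None, 0, empty=True))
            continue
        if calibration.border_range is not None and calibration.border_layers > 0:
            mask = include_border_layer(
                mask, slice2d, calibration.border_range, calibration.border_layers, avail2d
            )
        masks[z] = mask
        prev_mask = mask
        qc.append(SliceQC(z, seed, int(mask.sum()), used_fallback=fallback))
    return SegmentationResult(masks, qc)


def global_threshold_masks(
    image: VoxelImage,
    rng: IntensityRange,
    slice_range: tuple[int, int] | None = None,
) -> SegmentationResult:
    """Global-threshold alternative to the per-slice wand.

    Selects every in-range voxel regardless of connectivity; provided for
    bright-thrombus samples where a single masking range may be applied to
    the whole stack.  The per-slice wand is the default elsewhere.
    """
    z0, z1 = slice_range if slice_range is not None else (0, image.n_slices)
    masks = np.zeros(image.data.shape, dtype=bool)
    masks[z0:z1] = rng.contains(image.data[z0:z1])
    qc = [
        SliceQC(z, None, int(masks[z].sum()), empty=not masks[z].any())
        for z in range(z0, z1)
    ]
    return SegmentationResult(masks, qc)


def segment_four_material(image: VoxelImage, mode: AnalysisMode) -> FourMaterialResult:
    """Sequential multi-material labeling with a remainder thrombus.

    Materials are claimed in the order given by ``mode.targets`` (lumen
    first, then the outermost heat-shrink tubing, then the graft wall); a
    voxel keeps the first label that claims it, so the output is a
    partition.  The thrombus is then the remaining material: per slice, the
    hole-filled interior of the wall ring minus every explicit claim.
    Slices where the wall does not close around a non-empty lumen are
    flagged in the result rather than failing the run.
    """
    if mode.remainder_material is None:
        raise ValueError("segment_four_material requires a remainder material")
    name_to_label = {name: lab for lab, name in MATERIAL_LABELS.items()}
    labels = np.zeros(image.data.shape, dtype=np.uint8)
    available = np.ones(image.data.shape, dtype=bool)
    qc: dict[str, list[SliceQC]] = {}
    target_masks: dict[str, np.ndarray] = {}

    # The graft's axial extent is found from the wall calibration: a dark
    # lumen shares its intensity with the surrounding bath, so only the wall
    # band reliably marks which slices contain the graft.
    wall_targets = [t for t in mode.targets if t.material == "wall"]
    if not wall_targets:
        raise ValueError("four-material mode must segment a 'wall' target")
    span = find_slice_span(image, wall_targets[0].calibration.core_range)

    for target in mode.targets:
        seed = target.seed
        if seed is None:
            seed = auto_seed(
                image.data[span[0]], target.calibration.core_range, available[span[0]]
            )
            if seed is None:
                raise ValueError(f"no usable seed for material {target.material!r}")
        result = segment_target(image, target.calibration, seed, span, available)
        labels[result.masks] = name_to_label[target.material]
        available &= ~result.masks
        target_masks[target.material] = result.masks
        qc[target.material] = result.qc

    wall = target_masks.get("wall")
    lumen = target_masks.get("lumen")
    if wall is None:
        raise ValueError("four-material mode must segment a 'wall' target")
    flagged: list[int] = []
    remainder_label = name_to_label[mode.remainder_material]
    for z in range(image.n_slices):
        wall_z = wall[z]
        lumen_z = lumen[z] if lumen is not None else np.zeros_like(wall_z)
        if not wall_z.any():
            if lumen_z.any():
                flagged.append(z)
            continue
        interior = ndimage.binary_fill_holes(wall_z, structure=_CROSS) & ~wall_z
        if not interior.any():
            if lumen_z.any():
                flagged.append(z)  # wall ring not closed around the lumen
            continue
        remainder = interior & (labels[z] == 0)
        labels[z][remainder] = remainder_label
    return FourMaterialResult(
        labels=LabelVolume(labels, image.spacing, dict(MATERIAL_LABELS)),
        flagged_slices=flagged,
        qc=qc,
    )


# ---------------------------------------------------------------------------
# default operator calibrations


def default_analysis_mode(
    material_type: str, intensities: dict[str, float] | None = None
) -> AnalysisMode:
    """Operator calibration derived from a mode's material intensity levels.

    The border band's outer edge sits at the half-occupancy gray level of
    the boundary between the target and the material it physically abuts
    (a partial-volume pixel is annexed exactly when the target occupies
    the majority of it), and the core bound retreats one eighth of the
    target contrast inside that edge.  This realizes the "core plus one
    layer of medium gray border pixels" rule with near-zero net area bias
    on a partial-volume skin.
    """
    from .phantom import DEFAULT_INTENSITIES  # intensity tables live with the modes

    mode_of = {
        "PVA": "lumen_opaque",
        "ePTFE": "thrombus_opaque",
        "collagen_ePTFE": "four_material",
    }
    if material_type not in mode_of:
        raise ValueError(f"material_type must be one of {sorted(mode_of)}")
    levels = dict(DEFAULT_INTENSITIES[mode_of[material_type]])
    if intensities:
        levels.update(intensities)

    def mid(a: str, b: str) -> float:
        return (levels[a] + levels[b]) / 2.0

    big = 10.0 * max(levels.values())

    if material_type == "PVA":
        # bright cast lumen; its skin meets the wall or a dark mural deposit
        edge = max(mid("lumen", "wall"), mid("lumen", "thrombus"))
        delta = levels["lumen"] - max(levels["wall"], levels["thrombus"])
        cal = SegmentationCalibration(
            core_range=IntensityRange(edge + delta / 8.0, big),
            border_range=IntensityRange(edge, edge + delta / 8.0),
            border_layers=1,
        )
        return AnalysisMode("PVA", (TargetSpec("lumen", cal),))

    if material_type == "ePTFE":
        # bright stained thrombus; its outer skin meets the graft wall
        edge = mid("thrombus", "wall")
        delta = levels["thrombus"] - levels["wall"]
        cal = SegmentationCalibration(
            core_range=IntensityRange(edge + delta / 8.0, big),
            border_range=IntensityRange(edge, edge + delta / 8.0),
            border_layers=1,
        )
        return AnalysisMode("ePTFE", (TargetSpec("thrombus", cal),))

    # collagen_ePTFE: dark lumen, bright shrink ring, mid-gray wall; the
    # thrombus is never wanded — it is the remainder inside the wall.
    # The dark lumen abuts the bright deposit, so its border band climbs to
    # that boundary's half-occupancy level.
    d_lw = levels["wall"] - levels["lumen"]
    lumen_core_hi = mid("lumen", "wall") - d_lw / 8.0
    lumen_cal = SegmentationCalibration(
        core_range=IntensityRange(-big, lumen_core_hi),
        border_range=IntensityRange(lumen_core_hi, mid("lumen", "thrombus")),
        border_layers=1,
    )
    d_sw = levels["shrink"] - levels["wall"]
    shrink_cal = SegmentationCalibration(
        core_range=IntensityRange(mid("shrink", "wall") + d_sw / 8.0, mid("shrink", "thrombus")),
        border_range=IntensityRange(mid("shrink", "wall"), mid("shrink", "wall") + d_sw / 8.0),
        border_layers=1,
    )
    wall_cal = SegmentationCalibration(
        core_range=IntensityRange(mid("wall", "lumen"), mid("wall", "thrombus")),
        border_range=None,
        border_layers=0,
    )
    return AnalysisMode(
        "collagen_ePTFE",
        (
            TargetSpec("lumen", lumen_cal),
            TargetSpec("shrink", shrink_cal),
            TargetSpec("wall", wall_cal),
        ),
        remainder_material="thrombus",
    )
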