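"""Voxel-wise lung aeration quantification from CT Hounsfield units.

Lung voxels are classified into the four standard aeration compartments

======================  =====================
compartment             HU range
======================  =====================
overdistended           [-1000, -900)
normally aerated        [-900, -500)
poorly aerated          [-500, -100)
atelectatic             [-100, 200]
======================  =====================

and gas volume / tissue mass are derived from the linear air–tissue mixture
model: a voxel at HU h contains a gas fraction ``-h/1000`` (clamped to
[0, 1]), a complementary tissue volume fraction, and tissue of density
``(h + 1000)/1000`` g/mL (clamped to [0, 1.2], so mildly hyperdense voxels
weigh more than water).  In-mask voxels outside the [-1000, 200] HU window
are reported as *excluded* and do not enter compartment fractions.

Segmental analysis cuts the mask's bounding extent along the dependent
(ventral->dorsal) axis into equal-thickness slabs, and splits left/right at
the mask midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "DEFAULT_BIN_EDGES",
    "CTVolume",
    "LungMask",
    "SegmentPartition",
    "AerationSummary",
    "classify_voxels",
    "quantify",
    "partition_segments",
    "summarize",
]

#: Compartment names in HU order (most to least aerated).
COMPARTMENTS = ("overdistended", "normally_aerated", "poorly_aerated", "atelectatic")

#: HU bin edges; intervals are lower-inclusive half-open except the last,
#: which includes its upper edge: [-1000,-900), [-900,-500), [-500,-100), [-100,200].
DEFAULT_BIN_EDGES = (-1000.0, -900.0, -500.0, -100.0, 200.0)

#: Segment names along the dependent axis, ventral first.
SEGMENTS = ("ventral", "medial", "dorsal")

_EXCLUDED = len(COMPARTMENTS)  # label for in-mask voxels outside the HU window
_OUTSIDE = -1  # label for voxels outside the lung mask

#: Tissue density clamp (g/mL) for HU above the water point.
MAX_TISSUE_DENSITY = 1.2


@dataclass(frozen=True)
class CTVolume:
    """A 3-D CT scalar field in (rescaled) Hounsfield units.

    Parameters
    ----------
    hu
        3-D array of Hounsfield units, slope/intercept already applied.
    spacing
        Voxel edge lengths in mm, one per axis.
    dependent_axis
        Index of the gravity-dependent axis.  Convention: increasing index
        along this axis runs ventral -> dorsal (supine subject).
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    dependent_axis: int = 2

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        if hu.ndim != 3:
            raise ValueError(f"hu must be 3-D, got shape {hu.shape}")
        if not np.all(np.isfinite(hu)):
            raise ValueError("hu contains non-finite values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.dependent_axis not in (0, 1, 2):
            raise ValueError(f"dependent_axis must be 0, 1 or 2, got {self.dependent_axis}")
        object.__setattr__(self, "hu", hu)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mm^3 = 1e-3 mL)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class LungMask:
    """Binary lung mask congruent with a :class:`CTVolume`."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        inside = np.asarray(self.inside, dtype=bool)
        if inside.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {inside.shape}")
        if not inside.any():
            raise ValueError("lung mask is empty")
        object.__setattr__(self, "inside", inside)

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())


@dataclass(frozen=True)
class SegmentPartition:
    """Per-voxel segment (ventral/medial/dorsal) and side (left/right) labels.

    ``segment`` holds 0..n_segments-1 ventral-first, ``side`` 0 (left) or 1
    (right); both are -1 outside the mask.
    """

    segment: np.ndarray
    side: np.ndarray
    segment_names: tuple[str, ...] = SEGMENTS

    def segment_mask(self, name: str) -> np.ndarray:
        return self.segment == self.segment_names.index(name)

    def side_mask(self, name: str) -> np.ndarray:
        return self.side == ("left", "right").index(name)


@dataclass(frozen=True)
class AerationSummary:
    """Aeration quantities for one scope (whole lung or a segment/side).

    Volumes are mL, fractions are percentages of the *included* (in-window)
    volume, ``total_lung_volume_l`` is the included volume in litres,
    ``tissue_mass_g`` in grams.
    """

    volume_ml: Mapping[str, float]
    fraction_pct: Mapping[str, float]
    excluded_volume_ml: float
    mask_volume_ml: float
    total_lung_volume_l: float
    gas_volume_ml: float
    tissue_volume_ml: float
    tissue_mass_g: float
    n_voxels: int
    by_segment: Mapping[str, "AerationSummary"] = field(default_factory=dict)
    by_side: Mapping[str, "AerationSummary"] = field(default_factory=dict)


def _check_congruent(ct: CTVolume, mask: LungMask) -> None:
    if ct.hu.shape != mask.inside.shape:
        raise ValueError(
            f"CT shape {ct.hu.shape} does not match mask shape {mask.inside.shape}"
        )


def classify_voxels(
    ct: CTVolume,
    mask: LungMask,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> np.ndarray:
    """Label every voxel with its aeration compartment.

    Returns an int array: 0..3 = compartments in :data:`COMPARTMENTS` order,
    4 = in-mask but outside the HU window, -1 = outside the mask.
    """
    _check_congruent(ct, mask)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) != len(COMPARTMENTS) + 1:
        raise ValueError(f"expected {len(COMPARTMENTS) + 1} bin edges, got {len(edges)}")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    labels = np.full(ct.hu.shape, _OUTSIDE, dtype=np.int8)
    hu = ct.hu[mask.inside]
    # right=False gives lower-inclusive half-open bins; fold the top edge in.
    idx = np.digitize(hu, edges, right=False) - 1
    idx[hu == edges[-1]] = len(COMPARTMENTS) - 1
    idx[(hu < edges[0]) | (hu > edges[-1])] = _EXCLUDED
    labels[mask.inside] = idx.astype(np.int8)
    return labels


def _quantify_region(ct: CTVolume, labels: np.ndarray, region: np.ndarray) -> AerationSummary:
    vox = ct.voxel_volume_ml
    lab = labels[region]
    hu = ct.hu[region]

    counts = np.array([(lab == i).sum() for i in range(len(COMPARTMENTS))], dtype=float)
    n_excluded = float((lab == _EXCLUDED).sum())
    included = lab != _EXCLUDED
    n_included = counts.sum()

    gas_frac = np.clip(-hu[included] / 1000.0, 0.0, 1.0)
    density = np.clip((hu[included] + 1000.0) / 1000.0, 0.0, MAX_TISSUE_DENSITY)

    volume_ml = {c: float(n * vox) for c, n in zip(COMPARTMENTS, counts)}
    if n_included > 0:
        fraction_pct = {c: float(100.0 * n / n_included) for c, n in zip(COMPARTMENTS, counts)}
    else:
        fraction_pct = {c: float("nan") for c in COMPARTMENTS}
    return AerationSummary(
        volume_ml=volume_ml,
        fraction_pct=fraction_pct,
        excluded_volume_ml=float(n_excluded * vox),
        mask_volume_ml=float((n_included + n_excluded) * vox),
        total_lung_volume_l=float(n_included * vox / 1000.0),
        gas_volume_ml=float(gas_frac.sum() * vox),
        tissue_volume_ml=float((1.0 - gas_frac).sum() * vox),
        tissue_mass_g=float(density.sum() * vox),
        n_voxels=int(n_included + n_excluded),
    )


def quantify(ct: CTVolume, mask: LungMask, labels: np.ndarray) -> AerationSummary:
    """Whole-lung aeration summary from precomputed compartment labels."""
    _check_congruent(ct, mask)
    if labels.shape != ct.hu.shape:
        raise ValueError("labels shape does not match the CT volume")
    return _quantify_region(ct, labels, mask.inside)


def partition_segments(ct: CTVolume, mask: LungMask, n_segments: int = 3) -> SegmentPartition:
    """Cut the mask into equal-thickness dorso-ventral slabs and left/right halves.

    The bounding extent of the mask along the dependent axis is divided into
    ``n_segments`` slabs of equal voxel thickness; when the depth is not
    divisible, the remainder voxels go to the ventral-most slab(s).  Sides
    are split at the midpoint of the mask's bounding extent along axis 0
    (the left-right axis).
    """
    _check_congruent(ct, mask)
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    names = SEGMENTS if n_segments == 3 else tuple(f"segment_{i}" for i in range(n_segments))

    dep = ct.dependent_axis
    idx_dep = np.nonzero(mask.inside.any(axis=tuple(a for a in range(3) if a != dep)))[0]
    lo, hi = int(idx_dep.min()), int(idx_dep.max())
    depth = hi - lo + 1
    if depth < n_segments:
        raise ValueError(
            f"mask extent along the dependent axis ({depth} voxels) is thinner "
            f"than n_segments={n_segments}"
        )
    base, rem = divmod(depth, n_segments)
    thickness = [base + (1 if i < rem else 0) for i in range(n_segments)]
    bounds = np.cumsum([lo] + thickness)  # slab i covers [bounds[i], bounds[i+1])

    coords_dep = np.arange(ct.hu.shape[dep])
    slab_of = np.searchsorted(bounds[1:], coords_dep, side="right")
    shape = [1, 1, 1]
    shape[dep] = -1
    segment = np.broadcast_to(slab_of.reshape(shape), ct.hu.shape).copy()
    segment[~mask.inside] = _OUTSIDE

    lr_axis = 0 if dep != 0 else 1
    idx_lr = np.nonzero(mask.inside.any(axis=tuple(a for a in range(3) if a != lr_axis)))[0]
    mid = (int(idx_lr.min()) + int(idx_lr.max()) + 1) / 2.0
    coords_lr = np.arange(ct.hu.shape[lr_axis])
    side_of = (coords_lr >= mid).astype(np.int8)
    shape = [1, 1, 1]
    shape[lr_axis] = -1
    side = np.broadcast_to(side_of.reshape(shape), ct.hu.shape).copy()
    side[~mask.inside] = _OUTSIDE

    return SegmentPartition(segment=segment, side=side, segment_names=names)


def summarize(
    ct: CTVolume,
    mask: LungMask,
    labels: np.ndarray | None = None,
    partition: SegmentPartition | None = None,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> AerationSummary:
    """Whole-lung summary with optional per-segment / per-side breakdown."""
    if labels is None:
        labels = classify_voxels(ct, mask, bin_edges)
    whole = quantify(ct, mask, labels)
    if partition is None:
        return whole
    by_segment = {
        name: _quantify_region(ct, labels, mask.inside & partition.segment_mask(name))
        for name in partition.segment_names
    }
    by_side = {
        name: _quantify_region(ct, labels, mask.inside & partition.side_mask(name))
        for name in ("left", "right")
    }
    return AerationSummary(
        volume_ml=whole.volume_ml,
        fraction_pct=whole.fraction_pct,
        excluded_volume_ml=whole.excluded_volume_ml,
        mask_volume_ml=whole.mask_volume_ml,
        total_lung_volume_l=whole.total_lung_volume_l,
        gas_volume_ml=whole.gas_volume_ml,
        tissue_volume_ml=whole.tissue_volume_ml,
        tissue_mass_g=whole.tissue_mass_g,
        n_voxels=whole.n_voxels,
        by_segment=by_segment,
        by_side=by_side,
    )
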