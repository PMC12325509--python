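"""Automatic lung segmentation and airway removal for thoracic CT.

The pipeline replaces an interactive workstation segmentation with a fully
deterministic algorithm (an externally supplied mask always bypasses it):

1. body mask — largest 26-connected component above ``body_threshold``;
2. candidate air — voxels at or below ``lung_upper_threshold`` whose
   26-connected component does not touch the volume border (this excludes
   the air surrounding the body) ;
3. component selection — keep components of at least
   ``min_component_volume`` mL, at most the two largest (a single component
   is accepted when the lungs merge through the airway tree);
4. morphological closing with a ``closing_radius``-mm ball to re-include
   vessels and partial-volume boundary voxels.

Airway removal seeds a 6-connected region growing at an automatically
detected trachea (a near-midline air column of roughly constant tubular
cross-section in the most cranial slices of the mask), grows through voxels
at or below ``lung_upper_threshold`` in breadth-first wavefronts, and halts
when a wavefront dilates far beyond the tubular baseline — the signature of
leaking into parenchyma.  The grown tree, dilated by
``airway_dilation_radius`` mm, is subtracted from the lung mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_ct import CTVolume, MaskVolume, LungDensError

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(LungDensError):
    pass


@dataclass
class SegmentationParams:
    """Tunable thresholds of the automatic segmentation (all HU / mm)."""

    lung_upper_threshold: float = -300.0   # air-like voxels
    body_threshold: float = -500.0         # soft tissue / body outline
    min_component_volume: float = 50.0     # mL, drops stomach gas etc.
    closing_radius: float = 2.0            # mm
    airway_dilation_radius: float = 2.0    # mm, margin around the grown tree
    trachea_seed: tuple[int, int, int] | None = None  # explicit (x,y,z) seed
    # wavefront guard: stop when a wave exceeds this multiple of the
    # median tubular wave size established in the trachea
    wavefront_guard_factor: float = 3.0

    def __post_init__(self):
        if self.lung_upper_threshold <= -1024:
            raise SegmentationError("lung_upper_threshold must exceed -1024 HU")
        if self.closing_radius < 0 or self.airway_dilation_radius < 0:
            raise SegmentationError("radii must be non-negative")
        if self.min_component_volume <= 0:
            raise SegmentationError("min_component_volume must be positive")


def _ball(radius_mm: float, spacing) -> np.ndarray | None:
    """Ellipsoidal structuring element approximating a ball of physical radius."""
    r = [max(0, int(round(radius_mm / s))) for s in spacing]
    if max(r) == 0:
        return None
    zz = [np.arange(-ri, ri + 1) * s for ri, s in zip(r, spacing)]
    X, Y, Z = np.meshgrid(*zz, indexing="ij")
    return (X / radius_mm) ** 2 + (Y / radius_mm) ** 2 + (Z / radius_mm) ** 2 <= 1.0 + 1e-9


def _border_touching_labels(labels: np.ndarray) -> set[int]:
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1],
             labels[:, :, 0], labels[:, :, -1]]
    out: set[int] = set()
    for f in faces:
        out.update(np.unique(f).tolist())
    out.discard(0)
    return out


def segment_lungs(vol: CTVolume, params: SegmentationParams | None = None) -> MaskVolume:
    """Extract the lungs (airways still included) from a thoracic CT volume."""
    params = params or SegmentationParams()
    hu = vol.voxels

    body_cand = hu > params.body_threshold
    if not body_cand.any():
        raise SegmentationError("no body found: no voxels above body threshold")
    body_labels, n_body = ndimage.label(body_cand, structure=_CONN26)
    body_sizes = np.bincount(body_labels.ravel())
    body = body_labels == (int(np.argmax(body_sizes[1:])) + 1)
    body_interior = ndimage.binary_fill_holes(body)

    air = (hu <= params.lung_upper_threshold) & body_interior
    labels, n = ndimage.label(air, structure=_CONN26)
    if n == 0:
        raise SegmentationError("no lung found: no candidate air voxels")

    border = _border_touching_labels(labels)
    sizes = np.bincount(labels.ravel())
    min_vox = params.min_component_volume * 1000.0 / vol.voxel_volume_mm3

    keep = [(sizes[lab], lab) for lab in range(1, n + 1)
            if lab not in border and sizes[lab] >= min_vox]
    if not keep:
        raise SegmentationError(
            "no lung found: no interior air component reaches the minimum volume")
    keep.sort(reverse=True)
    chosen = [lab for _, lab in keep[:2]]

    mask = np.isin(labels, chosen)
    ball = _ball(params.closing_radius, vol.spacing)
    if ball is not None:
        mask = ndimage.binary_closing(mask, structure=ball)
    return MaskVolume(mask, vol.spacing, vol.origin)


def mask_volume_ml(mask: MaskVolume) -> float:
    """Volume of the true voxels in millilitres."""
    dx, dy, dz = mask.spacing
    return float(np.count_nonzero(mask.flags)) * dx * dy * dz / 1000.0


def dice_coefficient(a: MaskVolume | np.ndarray, b: MaskVolume | np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)`` between two masks."""
    fa = a.flags if isinstance(a, MaskVolume) else np.asarray(a, bool)
    fb = b.flags if isinstance(b, MaskVolume) else np.asarray(b, bool)
    denom = fa.sum() + fb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(fa & fb) / denom


# ---------------------------------------------------------------------------
# trachea detection and airway removal
# ---------------------------------------------------------------------------

def _find_trachea_seed(mask: np.ndarray, spacing,
                       min_area_mm2: float = 15.0,
                       max_area_mm2: float = 600.0,
                       midline_tol_mm: float = 20.0,
                       persist_mm: float = 10.0,
                       max_growth_ratio: float = 1.5):
    """Locate a tubular near-midline air column in the most cranial slices.

    Scans downward from the top of the mask; a candidate must keep a
    cross-section inside ``[min_area, max_area]`` mm² that grows by at most
    ``max_growth_ratio`` per slice, sit within ``midline_tol_mm`` of the
    mask midline, and persist for at least ``persist_mm`` of slices.  Lung
    apex caps fail this: their area grows steeply slice-to-slice and their
    centroids sit far off the midline.  Returns the boolean seed slice
    component and its z index, or ``None``.
    """
    dx, dy, dz = spacing
    area_per_px = dx * dy
    nz = mask.shape[2]
    persist_slices = max(3, int(round(persist_mm / dz)))
    xs_mid = mask.any(axis=2).nonzero()[0]
    if xs_mid.size == 0:
        return None
    midline_x = 0.5 * (xs_mid.min() + xs_mid.max())

    top_zs = [z for z in range(nz - 1, -1, -1) if mask[:, :, z].any()]
    # only search the cranial third of the occupied extent
    top_zs = top_zs[: max(persist_slices * 3, len(top_zs) // 3)]
    for z0 in top_zs:
        sl_labels, n2 = ndimage.label(mask[:, :, z0])
        for lab in range(1, n2 + 1):
            comp = sl_labels == lab
            area = comp.sum() * area_per_px
            if not min_area_mm2 <= area <= max_area_mm2:
                continue
            cx = comp.nonzero()[0].mean()
            if abs(cx - midline_x) * dx > midline_tol_mm:
                continue
            # follow the column down and require tubular persistence
            ok = True
            prev, prev_area = comp, area
            for dzi in range(1, persist_slices):
                z = z0 - dzi
                if z < 0:
                    ok = False
                    break
                below = mask[:, :, z] & ndimage.binary_dilation(prev)
                lab2, m2 = ndimage.label(below)
                if m2 == 0:
                    ok = False
                    break
                # component overlapping the column from above
                areas2 = np.bincount(lab2.ravel())[1:] * area_per_px
                best = int(np.argmax(areas2)) + 1
                comp2 = lab2 == best
                a2 = comp2.sum() * area_per_px
                if not min_area_mm2 <= a2 <= max_area_mm2 * 1.5:
                    ok = False
                    break
                if a2 > max_growth_ratio * prev_area + 2 * area_per_px:
                    ok = False   # cross-section ballooning: not a tube
                    break
                prev, prev_area = comp2, a2
            if ok:
                return comp, z0
    return None


_FACE_OFFSETS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                          [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def _grow_airway(air: np.ndarray, seed_idx: np.ndarray, guard_factor: float) -> np.ndarray:
    """6-connected wavefront growth with a dilation guard.

    The reference wave size is the median of the first ten waves (the
    tubular trachea); a wave larger than ``guard_factor`` times the
    reference marks leakage into parenchyma and growth halts before adding
    it.
    """
    shape = air.shape
    visited = np.zeros(shape, dtype=bool)
    visited[tuple(seed_idx.T)] = True
    frontier = seed_idx
    wave_sizes = [len(seed_idx)]
    reference = None
    max_waves = int(sum(shape))
    for _ in range(max_waves):
        if len(frontier) == 0:
            break
        cand = (frontier[:, None, :] + _FACE_OFFSETS[None, :, :]).reshape(-1, 3)
        ok = np.all((cand >= 0) & (cand < np.array(shape)), axis=1)
        cand = cand[ok]
        ci = tuple(cand.T)
        new = air[ci] & ~visited[ci]
        cand = cand[new]
        if len(cand) == 0:
            break
        # deduplicate
        flat = np.ravel_multi_index(tuple(cand.T), shape)
        flat = np.unique(flat)
        cand = np.column_stack(np.unravel_index(flat, shape))
        if reference is None and len(wave_sizes) >= 10:
            reference = float(np.median(wave_sizes))
        if reference is not None and len(cand) > guard_factor * max(reference, 1.0):
            log.debug("airway growth stopped: wave %d > %.1f x reference %.1f",
                      len(cand), guard_factor, reference)
            break
        visited[tuple(cand.T)] = True
        frontier = cand
        wave_sizes.append(len(cand))
    return visited


def remove_airways(vol: CTVolume, lung_and_airway_mask: MaskVolume,
                   params: SegmentationParams | None = None) -> MaskVolume:
    """Subtract the airway tree from a lungs-plus-airways mask.

    If no trachea candidate is found the mask is returned unchanged with a
    logged warning rather than failing — a missing airway is a soft
    condition (it may simply lie outside the scanned range).
    """
    params = params or SegmentationParams()
    mask = lung_and_airway_mask.flags
    if not mask.any():
        raise SegmentationError("airway removal on an empty mask")

    if params.trachea_seed is not None:
        x, y, z = params.trachea_seed
        seed_idx = np.array([[x, y, z]])
        if not mask[x, y, z]:
            log.warning("explicit trachea seed lies outside the mask; returned unchanged")
            return MaskVolume(mask.copy(), lung_and_airway_mask.spacing,
                              lung_and_airway_mask.origin)
    else:
        found = _find_trachea_seed(mask, lung_and_airway_mask.spacing)
        if found is None:
            log.warning("no trachea candidate found; mask returned unchanged")
            return MaskVolume(mask.copy(), lung_and_airway_mask.spacing,
                              lung_and_airway_mask.origin)
        comp, z0 = found
        xs, ys = comp.nonzero()
        seed_idx = np.column_stack([xs, ys, np.full(xs.shape, z0)])

    air = vol.voxels <= params.lung_upper_threshold
    tree = _grow_airway(air, seed_idx, params.wavefront_guard_factor)
    ball = _ball(params.airway_dilation_radius, vol.spacing)
    if ball is not None:
        tree = ndimage.binary_dilation(tree, structure=ball)
    out = mask & ~tree
    log.info("airway removal: %d voxels removed", int(mask.sum() - out.sum()))
    return MaskVolume(out, lung_and_airway_mask.spacing, lung_and_airway_mask.origin)
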