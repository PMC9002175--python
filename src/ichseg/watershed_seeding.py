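"""Seed-point extraction by marker-controlled watershed preprocessing.

Each slice is treated as a topographic relief built from the *negated*
Gaussian-smoothed intensity, so hyperdense (bright) structures become
catchment basins with an interior minimum.  Shallow minima are removed by
h-minima suppression before flooding, which curbs the oversegmentation the
plain watershed transform suffers on noisy CT.  The resulting basin extrema
are proposed as region-growing seeds; a clinician (or the auto-selector)
then disposes among them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima, reconstruction
from skimage.segmentation import watershed

from .errors import NoHyperdenseSeedError, ValidationError
from .imaging_io import NormalizedVolume

#: defaults for the watershed preprocessing stage
DEFAULT_SMOOTHING_SIGMA = 1.5  # px, in-plane Gaussian
DEFAULT_H_MIN = 0.05           # normalized depth for h-minima suppression
DEFAULT_SEED_FLOOR = 0.55      # normalized hyperdensity floor (~50 HU)
DEFAULT_BONE_CUTOFF = 0.999    # window-saturated = bone
DEFAULT_MAX_SEEDS = 3
#: minimum number of supra-floor, sub-saturation pixels a basin must hold
#: to count as hyperdense — a single bright pixel is noise, a bleed is not
DEFAULT_MIN_HYPERDENSE_PX = 10


@dataclass(frozen=True)
class SeedCandidate:
    """A watershed basin summarized as a candidate growth origin.

    ``coordinate`` is the basin's extremal point: the brightest pixel of
    the basin on the original slice (ties broken toward the smallest
    (row, col) in lexicographic order).
    """

    coordinate: tuple[int, int, int]  # (slice, row, col)
    basin_label: int
    basin_min_value: float
    basin_mean_value: float
    basin_max_value: float
    basin_area_px: int

    def __post_init__(self):
        if self.basin_label < 1:
            raise ValidationError("basin_label must be >= 1")
        if self.basin_area_px < 1:
            raise ValidationError("basin_area_px must be >= 1")
        eps = 1e-9  # the mean of a constant basin can drift below its min
        if not (-eps <= self.basin_min_value <= self.basin_mean_value + eps
                and self.basin_mean_value <= self.basin_max_value + eps
                and self.basin_max_value <= 1.0 + eps):
            raise ValidationError("basin intensity summary out of order/bounds")


@dataclass(frozen=True)
class SeedPoint:
    """A voxel chosen as a region-growing origin."""

    coordinate: tuple[int, int, int]
    source: Literal["auto", "manual", "manual_snapped"] = "auto"


def watershed_slice(img: np.ndarray,
                    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
                    h_min: float = DEFAULT_H_MIN,
                    slice_index: int = 0):
    """Partition one normalized slice into watershed basins.

    Returns ``(labels, candidates)``: an int label image (labels >= 1,
    every pixel assigned — no watershed-line pixels are produced) and one
    :class:`SeedCandidate` per basin.

    The relief is ``-gaussian(img, smoothing_sigma)``; minima shallower
    than ``h_min`` are suppressed by grayscale reconstruction before the
    regional minima are taken as flood markers.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValidationError("watershed_slice expects a 2-D slice")
    if not np.all(np.isfinite(img)):
        raise ValidationError("slice contains non-finite pixels")
    if smoothing_sigma < 0 or not (0.0 <= h_min < 1.0):
        raise ValidationError("invalid smoothing_sigma or h_min")

    smoothed = ndi.gaussian_filter(img, smoothing_sigma) if smoothing_sigma > 0 else img
    relief = -smoothed
    if h_min > 0:
        # h-minima suppression: fill basins shallower than h_min
        relief = reconstruction(relief + h_min, relief, method="erosion")
    markers_mask = local_minima(relief, connectivity=2)
    markers, n_markers = ndi.label(markers_mask, structure=np.ones((3, 3), bool))
    if n_markers == 0:  # perfectly flat relief: one basin
        markers = np.ones(img.shape, dtype=np.int32)
    labels = watershed(relief, markers)

    candidates = []
    flat_img = img.ravel()
    flat_lab = labels.ravel()
    # group flat indices by basin label; indices stay in row-major order,
    # so the first argmax realizes the lexicographic (row, col) tie-break
    order = np.argsort(flat_lab, kind="stable")
    sorted_lab = flat_lab[order]
    unique_labels, starts = np.unique(sorted_lab, return_index=True)
    starts = list(starts) + [flat_lab.size]
    for i, lab in enumerate(unique_labels):
        if lab < 1:
            continue
        idx = np.sort(order[starts[i]:starts[i + 1]])
        vals = flat_img[idx]
        best = idx[int(np.argmax(vals))]
        r, c = np.unravel_index(best, img.shape)
        candidates.append(SeedCandidate(
            coordinate=(slice_index, int(r), int(c)),
            basin_label=int(lab),
            basin_min_value=float(vals.min()),
            basin_mean_value=float(vals.mean()),
            basin_max_value=float(vals.max()),
            basin_area_px=int(idx.size),
        ))
    return labels, candidates


def extract_seed_candidates(vol: NormalizedVolume,
                            smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
                            h_min: float = DEFAULT_H_MIN,
                            return_labels: bool = False):
    """Run the per-slice watershed over a volume and pool the candidates.

    Candidates are returned sorted by ``basin_mean_value`` descending
    (hyperdense basins first).  With ``return_labels=True`` the per-slice
    basin label volume is returned as well (needed for click snapping).
    """
    all_candidates: list[SeedCandidate] = []
    label_volume = np.zeros(vol.shape, dtype=np.int32)
    for z in range(vol.shape[0]):
        labels, cands = watershed_slice(vol.values[z], smoothing_sigma, h_min,
                                        slice_index=z)
        label_volume[z] = labels
        all_candidates.extend(cands)
    all_candidates.sort(key=lambda c: (-c.basin_mean_value, c.coordinate))
    if return_labels:
        return all_candidates, label_volume
    return all_candidates


def select_seeds(candidates: Sequence[SeedCandidate],
                 mode: Literal["auto", "manual"] = "auto",
                 clicks: Sequence[tuple[int, int, int]] | None = None,
                 k: int = DEFAULT_MAX_SEEDS,
                 seed_floor: float = DEFAULT_SEED_FLOOR,
                 bone_cutoff: float = DEFAULT_BONE_CUTOFF,
                 volume: NormalizedVolume | None = None,
                 labels: np.ndarray | None = None,
                 min_hyperdense_px: int = DEFAULT_MIN_HYPERDENSE_PX) -> list[SeedPoint]:
    """Choose growth origins from the watershed candidates.

    auto
        Admit candidates whose basin is hyperdense: it must hold at least
        ``min_hyperdense_px`` pixels above ``seed_floor`` (acute blood,
        ~>50 HU) yet below ``bone_cutoff`` (window-saturated bone is never
        a bleed) — a lone supra-floor pixel is indistinguishable from
        noise, so a count is required when the volume and basin labels are
        available.  The seed is the basin's brightest sub-saturation
        pixel.  Candidates are ranked by basin mean intensity, kept at
        most one per connected hyperdense cluster of the volume, and the
        top ``k`` are returned.
    manual
        Snap each click to the candidate whose basin contains it
        (``source="manual_snapped"``); a click inside no candidate basin
        is kept verbatim (``source="manual"``).
    """
    if mode == "manual":
        if not clicks:
            raise ValidationError("manual seed mode requires at least one click")
        by_slice_label = {}
        by_coord = {}
        for c in candidates:
            by_coord[c.coordinate] = c
            by_slice_label[(c.coordinate[0], c.basin_label)] = c
        seeds = []
        for click in clicks:
            click = tuple(int(x) for x in click)
            cand = by_coord.get(click)
            if cand is None and labels is not None:
                z, r, c_ = click
                if not (0 <= z < labels.shape[0] and 0 <= r < labels.shape[1]
                        and 0 <= c_ < labels.shape[2]):
                    raise ValidationError(f"click {click} outside volume")
                cand = by_slice_label.get((z, int(labels[z, r, c_])))
            if cand is not None:
                seeds.append(SeedPoint(cand.coordinate, source="manual_snapped"))
            else:
                seeds.append(SeedPoint(click, source="manual"))
        return seeds

    if mode != "auto":
        raise ValidationError(f"unknown seed mode {mode!r}")
    admitted: list[tuple[SeedCandidate, tuple[int, int, int]]] = []
    for c in candidates:
        if volume is not None and labels is not None:
            z = c.coordinate[0]
            basin = labels[z] == c.basin_label
            # mask out saturated pixels (skull); a bleed against the
            # inner table shares its basin with bone, so the admission
            # test and the seed anchor both use sub-saturation evidence
            vals = np.where(basin, volume.values[z], -1.0)
            vals[vals >= bone_cutoff] = -1.0
            if int((vals > seed_floor).sum()) < min_hyperdense_px:
                continue
            r, cc_ = np.unravel_index(int(np.argmax(vals)), vals.shape)
            admitted.append((c, (z, int(r), int(cc_))))
        elif seed_floor < c.basin_max_value < bone_cutoff:
            # summary-only fallback when basin labels are unavailable
            admitted.append((c, c.coordinate))
    if not admitted:
        raise NoHyperdenseSeedError(
            f"no hyperdense seed: no watershed basin peaks in "
            f"({seed_floor}, {bone_cutoff}) — likely no acute hemorrhage "
            f"under the current window/floor settings"
        )
    admitted.sort(key=lambda item: (-item[0].basin_mean_value, item[1]))
    if volume is not None:
        cluster_labels, _ = ndi.label(volume.values > seed_floor,
                                      structure=np.ones((3, 3, 3), bool))
        seen = set()
        unique = []
        for item in admitted:
            cl = int(cluster_labels[item[1]])
            if cl not in seen:
                seen.add(cl)
                unique.append(item)
        admitted = unique
    return [SeedPoint(coord, source="auto") for _, coord in admitted[:k]]
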