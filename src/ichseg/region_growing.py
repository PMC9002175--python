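"""Two-pass seeded region growing for hemorrhage segmentation (RG-WP core).

Pass 1 floods from each seed with the grayscale-difference criterion
``|f(seed) - f(neighbor)| <= tau`` (default tau 0.30, 4-connectivity) on the
normalized slice, then propagates to adjacent slices by re-seeding at the
centroid-nearest in-mask pixel of the previous slice.  Pass 2 refines the
threshold per slice by maximizing Otsu's between-class variance over a
region of interest around the first-pass mask and re-grows with the
one-sided rule ``intensity >= t*`` (hemorrhage is the bright class).

For bleeds abutting the skull, the brain parenchyma is extracted first
(also by region growing, exploiting the fact that bone saturates the
diagnostic window) and used as the growth domain.

Because the inclusion test compares each pixel against a *fixed* reference
intensity, a flood equals the connected component of the eligibility map
that contains the seed — the implementation computes exactly that, which
makes the result trivially independent of queue processing order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import (DegenerateHistogramError, EmptySegmentationError,
                     StageError, ValidationError)
from .imaging_io import CTVolume, NormalizedVolume, WindowSettings, apply_window
from .watershed_seeding import (DEFAULT_BONE_CUTOFF, DEFAULT_H_MIN,
                                DEFAULT_MAX_SEEDS, DEFAULT_SEED_FLOOR,
                                DEFAULT_SMOOTHING_SIGMA, SeedPoint,
                                extract_seed_candidates, select_seeds)

logger = logging.getLogger("ichseg")

DEFAULT_TAU = 0.30
DEFAULT_CONNECTIVITY = 4
DEFAULT_ROI_DILATION_PX = 5
DEFAULT_AIR_CUTOFF = 0.01


@dataclass(frozen=True)
class GrowthCriterion:
    """Similarity rule for pass-1 growing.

    ``reference`` is the intensity f(x, y) of the originating seed; when
    None it is looked up at the seed pixel.  A neighbor joins the region
    iff ``|reference - f(i, j)| <= tau``.
    """

    tau: float = DEFAULT_TAU
    connectivity: Literal[4, 8] = DEFAULT_CONNECTIVITY
    reference: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.tau <= 1.0):
            raise ValidationError(f"tau must be in [0, 1], got {self.tau}")
        if self.connectivity not in (4, 8):
            raise ValidationError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass
class SegmentationMask:
    """A binary 3-D mask aligned to a companion volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] | None = None
    provenance: Literal["first_pass", "second_pass", "parenchyma",
                        "ground_truth", "external"] = "external"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError("segmentation mask must be 3-D")
        uniq = np.unique(self.voxels)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValidationError("mask voxels must be 0/1")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def astype_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)


@dataclass
class GrowthResult:
    """Output of one growing pass."""

    mask: SegmentationMask
    tau_first: float
    tau_equivalent_second: float | None
    seeds_used: list[SeedPoint]
    per_slice_px: np.ndarray
    per_slice_threshold: dict[int, float | None] = field(default_factory=dict)


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def _component(eligible: np.ndarray, seed_rc: tuple[int, int],
               connectivity: int) -> np.ndarray:
    """Connected component of the eligibility map containing the seed."""
    if not eligible[seed_rc]:
        return np.zeros(eligible.shape, dtype=bool)
    lbl, _ = ndi.label(eligible, structure=_structure(connectivity))
    return lbl == lbl[seed_rc]


def _centroid_nearest(mask2d: np.ndarray) -> tuple[int, int]:
    """In-mask pixel nearest the mask centroid (ties -> lexicographic)."""
    coords = np.argwhere(mask2d)
    centroid = coords.mean(axis=0)
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    r, c = coords[int(np.argmin(d2))]
    return int(r), int(c)


def grow(img: np.ndarray, seeds_in_slice: Sequence[tuple[int, int]],
         criterion: GrowthCriterion,
         domain_mask: np.ndarray | None = None) -> np.ndarray:
    """Flood a single slice from the given seeds under Eq.-style criterion.

    Each seed carries its own reference intensity (the flood is the union
    of per-seed floods); the result is deterministic and independent of
    processing order.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValidationError("grow expects a 2-D slice")
    domain = np.ones(img.shape, bool) if domain_mask is None \
        else np.asarray(domain_mask, bool)
    out = np.zeros(img.shape, dtype=bool)
    for seed in seeds_in_slice:
        r, c = int(seed[0]), int(seed[1])
        if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
            raise ValidationError(f"seed {(r, c)} outside slice {img.shape}")
        if not domain[r, c]:
            raise ValidationError(f"seed {(r, c)} outside domain mask")
        ref = criterion.reference if criterion.reference is not None else img[r, c]
        # 1e-12 slack absorbs binary rounding of decimal intensities so
        # exact ties (|diff| == tau) are included as the criterion states
        eligible = (np.abs(img - ref) <= criterion.tau + 1e-12) & domain
        out |= _component(eligible, (r, c), criterion.connectivity)
    return out


def _propagate(values: np.ndarray, z0: int, seed_rc: tuple[int, int],
               eligible_for_slice, connectivity: int) -> dict[int, np.ndarray]:
    """Grow on the seed slice, then re-seed into adjacent slices.

    ``eligible_for_slice(z)`` returns the boolean eligibility map for
    slice z, or None when the pass does not extend to that slice.  The
    re-seed on each new slice is the centroid-nearest in-mask pixel of the
    previous slice's mask; propagation stops at the first empty result.
    """
    n_slices = values.shape[0]
    masks: dict[int, np.ndarray] = {}
    el0 = eligible_for_slice(z0)
    if el0 is None or not el0[seed_rc]:
        return masks
    masks[z0] = _component(el0, seed_rc, connectivity)
    for step in (1, -1):
        prev = masks[z0]
        z = z0 + step
        while 0 <= z < n_slices and prev.any():
            rc = _centroid_nearest(prev)
            el = eligible_for_slice(z)
            if el is None or not el[rc]:
                break
            m = _component(el, rc, connectivity)
            if not m.any():
                break
            masks[z] = masks.get(z, np.zeros(m.shape, bool)) | m
            prev = m
            z += step
    return masks


def _domain_slices(domain, shape) -> np.ndarray:
    if domain is None:
        return np.ones(shape, dtype=bool)
    if isinstance(domain, SegmentationMask):
        return domain.astype_bool()
    return np.asarray(domain, dtype=bool)


def first_pass(vol: NormalizedVolume, seeds: Sequence[SeedPoint],
               tau: float = DEFAULT_TAU,
               connectivity: int = DEFAULT_CONNECTIVITY,
               domain: SegmentationMask | np.ndarray | None = None) -> GrowthResult:
    """First region growing: flood with the empirical tolerance ``tau``.

    Each seed's reference intensity is carried unchanged to adjacent
    slices during propagation, so a slice whose re-seed pixel no longer
    resembles the original seed yields an empty mask and stops the walk.
    """
    if not seeds:
        raise ValidationError("first_pass requires at least one seed")
    GrowthCriterion(tau=tau, connectivity=connectivity)  # validate knobs
    dom = _domain_slices(domain, vol.shape)
    out = np.zeros(vol.shape, dtype=bool)
    for seed in seeds:
        z0, r0, c0 = seed.coordinate
        if not dom[z0, r0, c0]:
            raise ValidationError(f"seed {seed.coordinate} outside domain mask")
        ref = float(vol.values[z0, r0, c0])

        def eligible(z, _ref=ref):
            return (np.abs(vol.values[z] - _ref) <= tau + 1e-12) & dom[z]

        for z, m in _propagate(vol.values, z0, (r0, c0), eligible,
                               connectivity).items():
            out[z] |= m
    if not out.any():
        raise EmptySegmentationError("no pixel within tau of any seed")
    return GrowthResult(
        mask=SegmentationMask(out.astype(np.uint8), spacing=vol.spacing,
                              provenance="first_pass"),
        tau_first=tau, tau_equivalent_second=None,
        seeds_used=list(seeds),
        per_slice_px=out.sum(axis=(1, 2)).astype(int),
    )


def otsu_threshold(values: Sequence[float] | np.ndarray, bins: int = 256) -> float:
    """Between-class-variance-maximizing threshold over bin-edge candidates.

    Maximizes sigma_B^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2 with the
    background class strictly below t; ties break toward the smaller t.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateHistogramError("all intensities identical")
    edges = np.histogram_bin_edges(values, bins=bins)
    srt = np.sort(values)
    csum = np.concatenate([[0.0], np.cumsum(srt)])
    total, n = csum[-1], srt.size
    # class statistics computed exactly from the sample; candidate
    # thresholds are the interior bin edges (background strictly below t)
    counts = np.searchsorted(srt, edges[1:-1], side="left").astype(float)
    w0, w1 = counts, n - counts
    valid = (w0 > 0) & (w1 > 0)
    sigma_b2 = np.zeros(counts.shape)
    mu0 = np.divide(csum[counts.astype(int)], w0, where=valid,
                    out=np.zeros_like(w0))
    mu1 = np.divide(total - csum[counts.astype(int)], w1, where=valid,
                    out=np.zeros_like(w1))
    sigma_b2[valid] = (w0[valid] / n) * (w1[valid] / n) * \
        (mu0[valid] - mu1[valid]) ** 2
    best = int(np.argmax(sigma_b2))  # first max -> smallest t
    return float(edges[best + 1])


def second_pass(vol: NormalizedVolume, first: GrowthResult,
                roi_dilation_px: int = DEFAULT_ROI_DILATION_PX,
                connectivity: int = DEFAULT_CONNECTIVITY,
                domain: SegmentationMask | np.ndarray | None = None) -> GrowthResult:
    """Second region growing with per-slice Otsu-refined thresholds.

    For every slice touched by the first pass, the ROI is the bounding box
    of the first-pass mask dilated by ``roi_dilation_px``; the slice's t*
    maximizes the between-class variance of the ROI intensities, and the
    re-grow admits pixels with ``intensity >= t*`` (one-sided: hemorrhage
    is hyperdense).  A degenerate single-intensity ROI falls back to the
    first-pass mask for that slice.
    """
    first_mask = first.mask.astype_bool()
    if not first_mask.any():
        raise EmptySegmentationError("first-pass mask is empty")
    dom = _domain_slices(domain, vol.shape)

    thresholds: dict[int, float | None] = {}
    rois: dict[int, tuple[slice, slice]] = {}
    for z in range(vol.shape[0]):
        if not first_mask[z].any():
            continue
        rr, cc = np.nonzero(first_mask[z])
        d = roi_dilation_px
        roi = (slice(max(rr.min() - d, 0), min(rr.max() + d + 1, vol.shape[1])),
               slice(max(cc.min() - d, 0), min(cc.max() + d + 1, vol.shape[2])))
        rois[z] = roi
        roi_vals = vol.values[z][roi][dom[z][roi]] if domain is not None \
            else vol.values[z][roi]
        try:
            thresholds[z] = otsu_threshold(roi_vals)
        except DegenerateHistogramError:
            logger.warning("slice %d: degenerate ROI histogram; "
                           "falling back to first-pass mask", z)
            thresholds[z] = None

    def eligible(z):
        if z not in thresholds:
            return None
        if thresholds[z] is None:
            return first_mask[z]
        return (vol.values[z] >= thresholds[z]) & dom[z]

    out = np.zeros(vol.shape, dtype=bool)
    for seed in first.seeds_used:
        z0, r0, c0 = seed.coordinate
        for z, m in _propagate(vol.values, z0, (r0, c0), eligible,
                               connectivity).items():
            out[z] |= m
    for z, t in thresholds.items():
        if t is None:  # fallback contract: never less information than pass 1
            out[z] = first_mask[z]
    if not out.any():
        logger.warning("second pass empty; falling back to first-pass mask")
        out = first_mask.copy()

    seed0 = first.seeds_used[0].coordinate
    t0 = thresholds.get(seed0[0])
    tau_equiv = float(vol.values[seed0] - t0) if t0 is not None else None
    return GrowthResult(
        mask=SegmentationMask(out.astype(np.uint8), spacing=vol.spacing,
                              provenance="second_pass"),
        tau_first=first.tau_first,
        tau_equivalent_second=tau_equiv,
        seeds_used=list(first.seeds_used),
        per_slice_px=out.sum(axis=(1, 2)).astype(int),
        per_slice_threshold=thresholds,
    )


def extract_parenchyma(vol: NormalizedVolume,
                       brain_seed: SeedPoint | None = None,
                       bone_cutoff: float = DEFAULT_BONE_CUTOFF,
                       air_cutoff: float = DEFAULT_AIR_CUTOFF) -> SegmentationMask:
    """Extract the brain-parenchyma domain by region growing.

    Requires the default diagnostic window, under which bone saturates at
    1.0 and air at 0.0: the flood admits ``air_cutoff < value <
    bone_cutoff`` and starts from ``brain_seed`` (default: the most
    central non-saturated, non-air pixel of the middle slice).  Per-slice
    hole filling keeps interior hyperdense lesions inside the domain.
    """
    values = vol.values
    eligible = (values > air_cutoff) & (values < bone_cutoff)
    if brain_seed is None:
        z = values.shape[0] // 2
        rr, cc = np.nonzero(eligible[z])
        if rr.size == 0:
            raise ValidationError("middle slice has no parenchyma-range pixel")
        center = np.array([values.shape[1] / 2.0, values.shape[2] / 2.0])
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        i = int(np.argmin(d2))
        brain_seed = SeedPoint((z, int(rr[i]), int(cc[i])), source="auto")
    z, r, c = brain_seed.coordinate
    v = values[z, r, c]
    if v >= bone_cutoff:
        raise ValidationError(f"seed inside bone (value {v:.3f} >= {bone_cutoff})")
    if v <= air_cutoff:
        raise ValidationError(f"seed in air (value {v:.3f} <= {air_cutoff})")

    lbl, _ = ndi.label(eligible, structure=ndi.generate_binary_structure(3, 1))
    mask = lbl == lbl[z, r, c]
    for zz in range(mask.shape[0]):
        mask[zz] = ndi.binary_fill_holes(mask[zz])
    return SegmentationMask(mask.astype(np.uint8), spacing=vol.spacing,
                            provenance="parenchyma")


def _near_saturation(values: np.ndarray, seeds: Sequence[SeedPoint],
                     bone_cutoff: float, radius_px: int = 2) -> bool:
    """True when any seed lies within ``radius_px`` (in-plane Chebyshev)
    of a window-saturated voxel."""
    saturated = values >= bone_cutoff
    for seed in seeds:
        z, r, c = seed.coordinate
        r0, r1 = max(r - radius_px, 0), min(r + radius_px + 1, values.shape[1])
        c0, c1 = max(c - radius_px, 0), min(c + radius_px + 1, values.shape[2])
        if saturated[z, r0:r1, c0:c1].any():
            return True
    return False


def segment_hemorrhage(vol: CTVolume | NormalizedVolume,
                       seed_mode: Literal["auto", "manual"] = "auto",
                       clicks: Sequence[tuple[int, int, int]] | None = None,
                       window: WindowSettings | None = None,
                       tau: float = DEFAULT_TAU,
                       connectivity: int = DEFAULT_CONNECTIVITY,
                       smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
                       h_min: float = DEFAULT_H_MIN,
                       seed_floor: float = DEFAULT_SEED_FLOOR,
                       max_seeds: int = DEFAULT_MAX_SEEDS,
                       roi_dilation_px: int = DEFAULT_ROI_DILATION_PX,
                       skull_adjacent: bool = False,
                       bone_cutoff: float = DEFAULT_BONE_CUTOFF):
    """Run the full pipeline: window -> watershed seeds -> two-pass growing.

    Returns ``(GrowthResult, report)`` where the report is a
    JSON-serializable summary (volume in mL, seeds, thresholds, per-slice
    areas).  Stage failures are re-raised as :class:`StageError` carrying
    the stage name.
    """
    from .quantification import mask_volume_ml  # local import avoids a cycle

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    if isinstance(vol, NormalizedVolume):
        norm = vol
    else:
        norm = stage("apply_window", apply_window, vol, window)

    candidates, labels = stage("extract_seed_candidates", extract_seed_candidates,
                               norm, smoothing_sigma, h_min, True)
    seeds = stage("select_seeds", select_seeds, candidates, seed_mode,
                  clicks=clicks, k=max_seeds, seed_floor=seed_floor,
                  bone_cutoff=bone_cutoff, volume=norm, labels=labels)

    use_domain = skull_adjacent or _near_saturation(norm.values, seeds, bone_cutoff)
    domain = stage("extract_parenchyma", extract_parenchyma, norm,
                   bone_cutoff=bone_cutoff) if use_domain else None
    if domain is not None:
        inside = [s for s in seeds if domain.astype_bool()[s.coordinate]]
        if inside:
            seeds = inside

    first = stage("first_pass", first_pass, norm, seeds, tau=tau,
                  connectivity=connectivity, domain=domain)
    second = stage("second_pass", second_pass, norm, first,
                   roi_dilation_px=roi_dilation_px,
                   connectivity=connectivity, domain=domain)

    # a mask that swallowed saturated bone signals an undetected
    # skull-adjacent bleed: redo inside the parenchyma domain
    if domain is None and \
            (norm.values[second.mask.astype_bool()] >= bone_cutoff).any():
        logger.info("mask reached saturated bone; re-running with "
                    "parenchyma domain")
        return segment_hemorrhage(norm, seed_mode=seed_mode, clicks=clicks,
                                  tau=tau, connectivity=connectivity,
                                  smoothing_sigma=smoothing_sigma, h_min=h_min,
                                  seed_floor=seed_floor, max_seeds=max_seeds,
                                  roi_dilation_px=roi_dilation_px,
                                  skull_adjacent=True, bone_cutoff=bone_cutoff)

    volume_ml = stage("quantification", mask_volume_ml, second.mask)
    report = {
        "volume_ml": volume_ml,
        "seeds": [{"coordinate": list(s.coordinate), "source": s.source}
                  for s in second.seeds_used],
        "tau_first": second.tau_first,
        "tau_equivalent_second": second.tau_equivalent_second,
        "per_slice_threshold": {str(z): t for z, t
                                in sorted(second.per_slice_threshold.items())},
        "per_slice_px": [int(x) for x in second.per_slice_px],
        "parenchyma_domain": bool(use_domain),
        "connectivity": connectivity,
    }
    return second, report
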