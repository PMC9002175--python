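"""Synthetic head-CT phantoms with known hemorrhage ground truth.

A phantom is a stack of axial slices holding an elliptical skull ring
(2-voxel wall, 800 HU) around brain parenchyma (30 HU), surrounded by air
(-1000 HU), with zero or more hyperdense lesions (acute blood, 65 HU)
carved as ellipsoids — optionally radius-modulated by low-order angular
lobes to mimic irregular bleeds, for which the ABC/2 ellipsoid assumption
degrades.  I.i.d. Gaussian HU noise is added after the ground-truth mask
is recorded, so truth voxels are exactly blood before noise.

Default geometry mirrors a routine non-contrast head CT protocol:
256 x 256 in-plane at 0.726 x 0.644 mm, 12 slices of 7.2 mm.  The suite
generator draws lesion volumes log-uniformly in [1, 30] mL, the range of
clinically common supratentorial bleeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imaging_io import CTVolume
from .region_growing import SegmentationMask

DEFAULT_GRID = (12, 256, 256)
DEFAULT_SPACING = (7.2, 0.726, 0.644)
#: interior (brain) ellipse semi-axes as fractions of the grid half-size
SKULL_FRACTION = (0.84, 0.88)
SKULL_WALL_PX = 2


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic head CT."""

    grid: tuple[int, int, int] = DEFAULT_GRID
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    hu_air: float = -1000.0
    hu_brain: float = 30.0
    hu_blood: float = 65.0
    hu_bone: float = 800.0
    noise_sigma: float = 4.0
    lesion_shape: Literal["ellipsoid", "lobulated", "none"] = "ellipsoid"
    lesion_center: tuple[float, float, float] | None = None  # voxel coords
    semi_axes_mm: tuple[float, float, float] = (7.2, 15.0, 12.0)  # (z, r, c)
    lobes: int = 4
    lobe_amplitude: float = 0.25
    skull_adjacent: bool = False
    count: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.semi_axes_mm) <= 0:
            raise ValidationError("lesion semi-axes must be positive")
        if self.hu_blood <= self.hu_brain:
            raise ValidationError("blood must be hyperdense relative to brain")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not (0 <= self.lobe_amplitude <= 0.3):
            raise ValidationError("lobe_amplitude must be in [0, 0.3]")
        if self.count < 1:
            raise ValidationError("lesion count must be >= 1")


@dataclass
class Phantom:
    ct: CTVolume
    truth: SegmentationMask
    true_volume_ml: dict
    spec: PhantomSpec = field(repr=False, default=None)


def _skull_geometry(spec: PhantomSpec):
    _, nr, nc = spec.grid
    ar = SKULL_FRACTION[0] * nr / 2.0
    ac = SKULL_FRACTION[1] * nc / 2.0
    cr, cc = (nr - 1) / 2.0, (nc - 1) / 2.0
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    rho2_in = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2
    rho2_out = ((rows - cr) / (ar + SKULL_WALL_PX)) ** 2 + \
        ((cols - cc) / (ac + SKULL_WALL_PX)) ** 2
    interior = rho2_in < 1.0
    bone = (rho2_out < 1.0) & ~interior
    return interior, bone, (ar, ac), (cr, cc)


def _lesion_centers(spec: PhantomSpec, axes_px, skull_axes, skull_center):
    nz, nr, nc = spec.grid
    if spec.lesion_center is not None:
        base = tuple(float(x) for x in spec.lesion_center)
    else:
        base = (nz // 2, (nr - 1) / 2.0, (nc - 1) / 2.0)
    if spec.skull_adjacent:
        ar, ac = skull_axes
        cr, cc = skull_center
        # push the lesion against the inner table of the skull (cols axis)
        base = (base[0], base[1], cc + ac - axes_px[2] + 2.0)
    if spec.count == 1:
        return [base]
    offset = skull_axes[0] * 0.45
    centers = []
    for i in range(spec.count):
        sign = -1 if i % 2 == 0 else 1
        shift = sign * offset * (1 + i // 2)
        centers.append((base[0], base[1] + shift, base[2]))
    return centers


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize a phantom; deterministic for a given ``rng_seed``."""
    nz, nr, nc = spec.grid
    sz, sr, sc = spec.spacing
    interior, bone, skull_axes, skull_center = _skull_geometry(spec)

    hu = np.full(spec.grid, spec.hu_air, dtype=np.float64)
    hu[:, interior] = spec.hu_brain
    hu[:, bone] = spec.hu_bone

    rng = np.random.default_rng(spec.rng_seed)
    truth = np.zeros(spec.grid, dtype=bool)
    if spec.lesion_shape != "none":
        az, ar_mm, ac_mm = spec.semi_axes_mm
        axes_px = (az / sz, ar_mm / sr, ac_mm / sc)
        zz = np.arange(nz)[:, None, None] * sz
        rr = np.arange(nr)[None, :, None] * sr
        cc = np.arange(nc)[None, None, :] * sc
        for center in _lesion_centers(spec, axes_px, skull_axes, skull_center):
            dz = zz - center[0] * sz
            dr = rr - center[1] * sr
            dc = cc - center[2] * sc
            base = np.sqrt((dz / az) ** 2 + (dr / ar_mm) ** 2 + (dc / ac_mm) ** 2)
            if spec.lesion_shape == "ellipsoid":
                lesion = base <= 1.0
            else:  # lobulated: in-plane radius modulation by angular lobes
                phi = np.arctan2(dr, dc)
                mod = np.ones_like(base)
                phases = rng.uniform(0, 2 * np.pi, size=spec.lobes)
                for i in range(spec.lobes):
                    mod += (spec.lobe_amplitude / spec.lobes) * \
                        np.cos((i + 2) * phi + phases[i])
                lesion = base <= mod
            truth |= lesion

        outside = truth & ~interior[None, :, :]
        if outside.any():
            if not spec.skull_adjacent:
                raise ValidationError(
                    "lesion extends outside the brain interior; set "
                    "skull_adjacent=True to clip it against the skull"
                )
            truth &= interior[None, :, :]
        hu[truth] = spec.hu_blood

    if spec.noise_sigma > 0:
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape)

    voxel_ml = float(truth.sum()) * sz * sr * sc / 1000.0
    analytic_ml = None
    if spec.lesion_shape == "ellipsoid" and not spec.skull_adjacent:
        az, ar_mm, ac_mm = spec.semi_axes_mm
        analytic_ml = spec.count * 4.0 / 3.0 * math.pi * az * ar_mm * ac_mm / 1000.0
    return Phantom(
        ct=CTVolume(voxels=hu, spacing=spec.spacing),
        truth=SegmentationMask(truth.astype(np.uint8), spacing=spec.spacing,
                               provenance="ground_truth"),
        true_volume_ml={"voxel": voxel_ml, "analytic": analytic_ml},
        spec=spec,
    )


def make_suite(n: int, master_seed: int,
               profile: Literal["standard", "skull_adjacent", "multifocal",
                                "lobulated"] = "standard"):
    """Generate a cohort of ``n`` phantoms with known volumes.

    Lesion volumes are drawn log-uniformly in [1, 30] mL; aspect ratios
    and center jitter vary per case; per-case generator seeds derive from
    ``master_seed``.  Returns ``(phantoms, manifest)`` where the manifest
    is a DataFrame with one row per case (true voxel and analytic volumes
    in mL).
    """
    if n < 1:
        raise ValidationError("suite size must be >= 1")
    rng = np.random.default_rng(master_seed)
    nz, nr, nc = DEFAULT_GRID
    phantoms, rows = [], []
    for i in range(n):
        target_ml = float(np.exp(rng.uniform(np.log(1.0), np.log(30.0))))
        per_lesion = target_ml / (2 if profile == "multifocal" else 1)
        q = float(rng.uniform(0.7, 1.0))    # row/col aspect
        w = float(rng.uniform(0.5, 0.85))   # z/col aspect
        s = (3.0 * per_lesion * 1000.0 / (4.0 * math.pi * q * w)) ** (1.0 / 3.0)
        semi = (w * s, q * s, s)  # (z, r, c) mm
        center = (int(nz // 2 + rng.integers(-1, 2)),
                  (nr - 1) / 2.0 + float(rng.uniform(-8, 8)),
                  (nc - 1) / 2.0 + float(rng.uniform(-8, 8)))
        case_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = PhantomSpec(
            lesion_shape="lobulated" if profile == "lobulated" else "ellipsoid",
            lesion_center=center,
            semi_axes_mm=semi,
            lobes=int(rng.integers(3, 6)),
            lobe_amplitude=float(rng.uniform(0.2, 0.3)),
            skull_adjacent=(profile == "skull_adjacent"),
            count=2 if profile == "multifocal" else 1,
            rng_seed=case_seed,
        )
        ph = make_phantom(spec)
        # one calibration step: thick slices quantize the z extent, so the
        # voxelized volume can drift from the drawn target; rescale the
        # semi-axes once to bring it back
        realized = ph.true_volume_ml["voxel"]
        if realized > 0 and abs(realized - target_ml) / target_ml > 0.05:
            factor = min(max((target_ml / realized) ** (1.0 / 3.0), 0.8), 1.3)
            semi = tuple(x * factor for x in semi)
            spec = replace(spec, semi_axes_mm=semi)
            ph = make_phantom(spec)
        phantoms.append(ph)
        rows.append({
            "case_id": f"case_{i:03d}",
            "profile": profile,
            "rng_seed": case_seed,
            "target_volume_ml": target_ml,
            "true_volume_ml": ph.true_volume_ml["voxel"],
            "analytic_volume_ml": ph.true_volume_ml["analytic"],
            "semi_axes_mm": "x".join(f"{x:.2f}" for x in semi),
        })
    return phantoms, pd.DataFrame(rows)


def noiseless(spec: PhantomSpec) -> PhantomSpec:
    """Convenience: the same phantom without HU noise."""
    return replace(spec, noise_sigma=0.0)
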