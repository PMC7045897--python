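"""Synthetic dual-sequence phantom generator.

Produces paired channel-1 ("T1-like") / channel-2 ("T2-like") volumes of the
same physical scene on their own acquisition grids, plus a gold-standard
lesion mask drawn on the channel-2 grid.  The scene is built from
axis-aligned ellipsoidal lesions evaluated analytically at voxel centers, so
every geometric property (mask support, contrast, misalignment) is exactly
checkable.

The contrast structure mirrors the ambiguity the dual-sequence pipeline is
meant to resolve: part of each lesion is rendered at background level on
channel 1 (hypointense), while channel 2 shows the full lesion *and* bright
non-lesion confuser blobs.  Neither channel alone identifies the lesion
support; together they do.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .volume import Volume, write_nifti

__all__ = ["PhantomConfig", "PairedStudy", "generate_study", "generate_cohort", "write_study"]


@dataclass
class PhantomConfig:
    """Parameters of the synthetic paired-study generator.

    Spacings follow the acquisition geometry of dual-sequence head MRI:
    channel 1 coarser in-plane (0.93 mm) than channel 2 (0.48 mm), both with
    4 mm slices.  ``grid_shape`` is the channel-2 grid; the channel-1 grid is
    derived from the same physical extent at ``spacing_ch1``.
    """

    grid_shape: tuple[int, int, int] = (32, 128, 128)
    spacing_ch1: tuple[float, float, float] = (4.0, 0.93, 0.93)
    spacing_ch2: tuple[float, float, float] = (4.0, 0.48, 0.48)
    n_lesions: int = 1
    lesion_radius_range: tuple[float, float] = (5.0, 10.0)
    t1_hypointense_fraction: float = 0.5
    confuser_count: int = 3
    confuser_radius_range: tuple[float, float] = (4.0, 8.0)
    misregistration_offset: tuple[float, float, float] = (0.0, 2.0, 2.0)
    noise_sd: float = 0.02
    background_level: float = 0.2
    lesion_level_ch1: float = 0.8
    lesion_level_ch2: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spacing_ch1", "spacing_ch2"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"{name} entries must be strictly positive")
        for name in ("lesion_radius_range", "confuser_radius_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0:
                raise ValueError(f"{name} radii must be strictly positive")
            if lo > hi:
                raise ValueError(f"{name} lower bound exceeds upper bound")
        if not 0.0 <= self.t1_hypointense_fraction <= 1.0:
            raise ValueError("t1_hypointense_fraction must lie in [0, 1]")
        if self.n_lesions < 0 or self.confuser_count < 0:
            raise ValueError("n_lesions and confuser_count must be non-negative")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PairedStudy:
    """One patient's paired volumes plus gold-standard binary lesion mask."""

    t1w: Volume
    t2w: Volume
    gold: Volume
    patient_id: str

    def __post_init__(self) -> None:
        if not self.gold.is_binary():
            raise ValueError("gold mask must contain only values {0, 1}")


@dataclass
class _Ellipsoid:
    center: np.ndarray  # mm, (z, y, x)
    radii: np.ndarray   # mm, (z, y, x)

    def inside(self, zz: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        return (
            ((zz - self.center[0]) / self.radii[0]) ** 2
            + ((yy - self.center[1]) / self.radii[1]) ** 2
            + ((xx - self.center[2]) / self.radii[2]) ** 2
        ) <= 1.0


def _cap_height_for_fraction(frac: float) -> float:
    """Height h in [0, 2] of a unit-sphere cap holding `frac` of the volume.

    Cap volume fraction h^2 (3 - h) / 4 is monotone in h; solved by bisection.
    """
    if frac <= 0:
        return 0.0
    if frac >= 1:
        return 2.0
    lo, hi = 0.0, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mid * mid * (3 - mid) / 4.0 < frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _hypo_halfspace(lesion: _Ellipsoid, frac: float, rng: np.random.Generator):
    """Half-space cutting `frac` of the lesion volume, as (normal, offset).

    A point p is hypointense iff n . (p - c) > d.  The cut is computed in the
    unit-sphere coordinates of the ellipsoid (exact spherical-cap geometry),
    then mapped back, so the targeted volume fraction is analytic, not
    voxel-dependent.
    """
    n_sphere = rng.normal(size=3)
    n_sphere /= np.linalg.norm(n_sphere)
    h = _cap_height_for_fraction(frac)
    d_sphere = 1.0 - h  # cap {u . n > d} of a unit sphere has height 1 - d
    # sphere coords u = (p - c) / radii; u.n > d  <=>  (p - c) . (n / radii) > d
    n_phys = n_sphere / lesion.radii
    return n_phys, d_sphere


def _sample_fitting_ellipsoid(extent, radius_range, rng, kind: str) -> _Ellipsoid:
    lo, hi = radius_range
    radii = rng.uniform(lo, hi, size=3)
    axis_names = ("slices", "rows", "cols")
    for a in range(3):
        if 2 * radii[a] > extent[a]:
            raise ValueError(
                f"{kind} of radius {radii[a]:.2f} mm cannot fit along axis "
                f"'{axis_names[a]}' (physical extent {extent[a]:.2f} mm)"
            )
    center = np.array([rng.uniform(radii[a], extent[a] - radii[a]) for a in range(3)])
    return _Ellipsoid(center=center, radii=radii)


def _bbox_disjoint(a: _Ellipsoid, b: _Ellipsoid, margin: float = 1.0) -> bool:
    # disjoint bounding boxes along any axis guarantee disjoint ellipsoids
    return bool(np.any(np.abs(a.center - b.center) > a.radii + b.radii + margin))


def generate_study(config: PhantomConfig, patient_id: str | None = None) -> PairedStudy:
    """Generate one synthetic paired study.

    The scene (lesions + confusers) lives in a common physical frame.
    Channel 2 is sampled on ``grid_shape`` at ``spacing_ch2``; channel 1 on
    its own grid covering the same extent at ``spacing_ch1``, with the
    sampled coordinates shifted by ``misregistration_offset`` so the two
    channels are residually misaligned exactly as specified.  Identical
    seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    shape2 = tuple(int(s) for s in config.grid_shape)
    sp2 = np.asarray(config.spacing_ch2, dtype=float)
    extent = np.asarray(shape2) * sp2

    sp1 = np.asarray(config.spacing_ch1, dtype=float)
    shape1 = tuple(int(max(1, round(e / s))) for e, s in zip(extent, sp1))

    lesions = [
        _sample_fitting_ellipsoid(extent, config.lesion_radius_range, rng, "lesion")
        for _ in range(config.n_lesions)
    ]
    hypo_cuts = [
        _hypo_halfspace(les, config.t1_hypointense_fraction, rng) for les in lesions
    ]

    confusers: list[_Ellipsoid] = []
    for _ in range(config.confuser_count):
        for _attempt in range(200):
            cand = _sample_fitting_ellipsoid(
                extent, config.confuser_radius_range, rng, "confuser"
            )
            if all(_bbox_disjoint(cand, les) for les in lesions):
                confusers.append(cand)
                break
        else:
            raise RuntimeError("could not place a confuser disjoint from all lesions")

    def grid_coords(shape, spacing, offset=(0.0, 0.0, 0.0)):
        axes = [
            (np.arange(shape[a], dtype=float) + 0.5) * spacing[a] + offset[a]
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def render(zz, yy, xx, channel: int) -> np.ndarray:
        img = np.full(np.broadcast_shapes(zz.shape, yy.shape, xx.shape),
                      config.background_level, dtype=np.float64)
        for les, (n_phys, d) in zip(lesions, hypo_cuts):
            ins = les.inside(zz, yy, xx)
            if channel == 1:
                proj = (
                    n_phys[0] * (zz - les.center[0])
                    + n_phys[1] * (yy - les.center[1])
                    + n_phys[2] * (xx - les.center[2])
                )
                img[ins & (proj <= d)] = config.lesion_level_ch1
                # hypointense sub-region stays at background level
            else:
                img[ins] = config.lesion_level_ch2
        if channel == 2:
            for conf in confusers:
                img[conf.inside(zz, yy, xx)] = config.lesion_level_ch2
        return img

    zz2, yy2, xx2 = grid_coords(shape2, sp2)
    t2_vals = render(zz2, yy2, xx2, channel=2)
    gold_vals = np.zeros(shape2, dtype=np.uint8)
    for les in lesions:
        gold_vals |= les.inside(zz2, yy2, xx2).astype(np.uint8)

    off = np.asarray(config.misregistration_offset, dtype=float)
    zz1, yy1, xx1 = grid_coords(shape1, sp1, offset=off)
    t1_vals = render(zz1, yy1, xx1, channel=1)

    if config.noise_sd > 0:
        t1_vals = np.clip(t1_vals + rng.normal(0, config.noise_sd, shape1), 0, None)
        t2_vals = np.clip(t2_vals + rng.normal(0, config.noise_sd, shape2), 0, None)

    pid = patient_id if patient_id is not None else f"phantom-{config.seed:04d}"
    # origin is the physical center of voxel (0,0,0); content was sampled at
    # (i + 0.5) * spacing, so both channels declare the consistent geometry
    # and the only misalignment between them is misregistration_offset
    return PairedStudy(
        t1w=Volume(t1_vals, tuple(sp1), origin=tuple(0.5 * sp1)),
        t2w=Volume(t2_vals, tuple(sp2), origin=tuple(0.5 * sp2)),
        gold=Volume(gold_vals, tuple(sp2), origin=tuple(0.5 * sp2)),
        patient_id=pid,
    )


def generate_cohort(config: PhantomConfig, n_patients: int, base_seed: int | None = None):
    """Generate a list of studies with per-patient seeds ``base + i``."""
    base = config.seed if base_seed is None else base_seed
    cohort = []
    for i in range(n_patients):
        cfg_i = PhantomConfig(**{**asdict(config), "seed": base + i})
        cohort.append(generate_study(cfg_i, patient_id=f"phantom-{base + i:04d}"))
    return cohort


def write_study(study: PairedStudy, out_dir: str | Path) -> dict[str, str]:
    """Write one patient's NIfTI triplet; returns the file paths."""
    out = Path(out_dir) / study.patient_id
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "t1w": str(write_nifti(study.t1w, out / "t1w.nii.gz")),
        "t2w": str(write_nifti(study.t2w, out / "t2w.nii.gz")),
        "gold": str(write_nifti(study.gold, out / "gold.nii.gz")),
    }
    return paths
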