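"""Seeded 3D bone phantoms emulating dens (odontoid process) CT scans.

Each phantom embeds a vertical bone peg — a cortical shell (~1200 HU) around a
trabecular core (~300 HU) — in soft-tissue background (~40 HU). An optional
fracture is a thin planar cleft through the peg whose voxels drop to
background intensity, optionally with a rigid lateral displacement of the
fragment above the cleft. Partial-volume blurring along z and additive
Gaussian noise emulate the resolution and noise behaviour of clinical
cervical-spine CT (slice thickness 1-2 mm, in-plane 0.17-0.98 mm).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .io import Mask, Volume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_case",
    "generate_cohort",
    "study_base_spec",
    "easy_base_spec",
    "STUDY_PREVALENCE",
]

#: fracture prevalence of the emulated cohort: 79 fractures among 366 cases
STUDY_PREVALENCE = 79.0 / 366.0


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom case.

    Lengths are millimetres, intensities Hounsfield units. ``background_hu``
    is a (mean, sd) pair describing soft-tissue texture; ``noise_sd`` is
    global acquisition noise added last; ``z_blur_sd`` is a Gaussian sigma
    along z emulating partial-volume averaging from thick slices.
    """

    grid_size: int = 64
    voxel_spacing: tuple = (0.6, 0.6, 1.5)
    background_hu: tuple = (40.0, 10.0)
    cortical_hu: float = 1200.0
    trabecular_hu: float = 300.0
    dens_radius: float = 5.5
    dens_height: float = 18.0
    shell_thickness: float = 1.5
    fracture_present: bool = False
    fracture_width: float = 1.5
    fracture_displacement: float = 0.0
    fracture_angle: float = 0.0  # radians, tilt of the cleft plane from transverse
    noise_sd: float = 15.0
    z_blur_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 16:
            raise ParameterError(f"grid_size must be >= 16, got {self.grid_size}")
        if not (self.cortical_hu > self.trabecular_hu > self.background_hu[0]):
            raise ParameterError(
                "intensity ordering violated: need cortical_hu > trabecular_hu "
                f"> background mean, got {self.cortical_hu}, {self.trabecular_hu}, "
                f"{self.background_hu[0]}"
            )
        if self.fracture_present and not self.fracture_width > 0:
            raise ParameterError("fracture_width must be > 0 when fracture_present")
        for name in ("dens_radius", "dens_height", "shell_thickness"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class PhantomCase:
    """A generated case: volume, ground-truth dens mask, fracture mask, label."""

    volume: Volume
    dens_mask: Mask
    fracture_mask: Mask
    label: bool
    spec: PhantomSpec


def _margin_check(spec: PhantomSpec) -> None:
    # dens must fit inside the grid with a >= 2-voxel margin per axis
    sx, sy, sz = spec.voxel_spacing
    half_extent = (
        spec.grid_size * sx / 2.0,
        spec.grid_size * sy / 2.0,
        spec.grid_size * sz / 2.0,
    )
    if spec.dens_radius + 2 * sx > half_extent[0] or spec.dens_radius + 2 * sy > half_extent[1]:
        raise ParameterError(
            f"dens_radius {spec.dens_radius} mm does not fit in the grid "
            f"(in-plane half-extent {half_extent[0]:.1f}/{half_extent[1]:.1f} mm "
            "with 2-voxel margin)"
        )
    if spec.dens_height / 2.0 + 2 * sz > half_extent[2]:
        raise ParameterError(
            f"dens_height {spec.dens_height} mm does not fit in the grid "
            f"(z half-extent {half_extent[2]:.1f} mm with 2-voxel margin)"
        )


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case; identical spec (same seed) is bit-identical."""
    _margin_check(spec)
    n = spec.grid_size
    sx, sy, sz = spec.voxel_spacing
    rng = np.random.default_rng(spec.seed)

    ax = (np.arange(n) - (n - 1) / 2.0)
    x = (ax * sx)[:, None, None]
    y = (ax * sy)[None, :, None]
    z = (ax * sz)[None, None, :]
    r = np.sqrt(x**2 + y**2)

    inside = (r <= spec.dens_radius) & (np.abs(z) <= spec.dens_height / 2.0)
    core = (r <= spec.dens_radius - spec.shell_thickness) & (
        np.abs(z) <= spec.dens_height / 2.0 - spec.shell_thickness
    )
    core &= inside
    shell = inside & ~core

    bg_mean, bg_sd = spec.background_hu
    vol = np.full((n, n, n), bg_mean, dtype=np.float64)
    if bg_sd > 0:
        bg_tex = rng.normal(0.0, bg_sd, size=vol.shape)
        vol[~inside] += bg_tex[~inside]
    vol[core] = spec.trabecular_hu
    vol[shell] = spec.cortical_hu

    dens = inside.copy()
    frac = np.zeros_like(inside)
    if spec.fracture_present:
        a = spec.fracture_angle
        # cleft plane through the dens centre, normal tilted from z by `a`
        d = x * math.sin(a) + z * math.cos(a) + 0.0 * y
        cleft = (np.abs(d) <= spec.fracture_width / 2.0) & inside
        vol[cleft] = bg_mean
        frac = cleft
        shift = int(round(spec.fracture_displacement / sx))
        if shift != 0:
            fragment = inside & (d > spec.fracture_width / 2.0)
            idx = np.argwhere(fragment)
            moved = idx.copy()
            moved[:, 0] += shift
            keep = (moved[:, 0] >= 0) & (moved[:, 0] < n)
            src = idx[keep]
            dst = moved[keep]
            frag_vals = vol[src[:, 0], src[:, 1], src[:, 2]]
            vol[fragment] = bg_mean
            dens[fragment] = False
            vol[dst[:, 0], dst[:, 1], dst[:, 2]] = frag_vals
            dens[dst[:, 0], dst[:, 1], dst[:, 2]] = True

    if spec.z_blur_sd > 0:
        vol = ndimage.gaussian_filter1d(vol, sigma=spec.z_blur_sd / sz, axis=2, mode="nearest")
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)

    spacing = tuple(spec.voxel_spacing)
    label = bool(frac.any())
    return PhantomCase(
        volume=Volume(vol, spacing),
        dens_mask=Mask(dens.astype(np.uint8), spacing),
        fracture_mask=Mask(frac.astype(np.uint8), spacing),
        label=label,
        spec=spec,
    )


def _case_seed(cohort_seed: int, index: int) -> int:
    return int(np.random.SeedSequence((cohort_seed, index)).generate_state(1)[0] % (2**31))


def generate_cohort(
    n: int,
    fracture_prevalence: float = STUDY_PREVALENCE,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list:
    """Generate a cohort with exactly ``round(n * prevalence)`` fracture cases.

    Per-case specs jitter dens radius, cleft angle, cleft width, noise level
    and displacement around ``base_spec``; every case's randomness flows from
    a seed derived from (cohort seed, case index), so case content is
    independent of generation order.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not 0.0 <= fracture_prevalence <= 1.0:
        raise ParameterError(f"prevalence must be in [0, 1], got {fracture_prevalence}")
    base = base_spec if base_spec is not None else PhantomSpec()
    n_frac = int(math.floor(n * fracture_prevalence + 0.5))
    labels = np.zeros(n, dtype=bool)
    labels[:n_frac] = True
    np.random.default_rng(seed).shuffle(labels)

    cases = []
    for i in range(n):
        cseed = _case_seed(seed, i)
        jrng = np.random.default_rng(cseed)
        radius = base.dens_radius * jrng.uniform(0.9, 1.1)
        angle = math.radians(jrng.uniform(-30.0, 30.0))
        noise = base.noise_sd * jrng.uniform(0.8, 1.2)
        width = max(0.5, base.fracture_width + jrng.uniform(-0.5, 0.5))
        displaced = jrng.random() < 0.5
        displacement = jrng.uniform(1.0, 3.0) if displaced else 0.0
        spec = replace(
            base,
            dens_radius=radius,
            fracture_angle=angle,
            noise_sd=noise,
            fracture_present=bool(labels[i]),
            fracture_width=width,
            fracture_displacement=displacement if labels[i] else 0.0,
            seed=cseed,
        )
        cases.append(generate_case(spec))
    return cases


def study_base_spec(grid_size: int = 64) -> PhantomSpec:
    """Default study-like conditions: anisotropic voxels in the clinical
    range, realistic noise, 1-2 mm clefts."""
    return PhantomSpec(grid_size=grid_size)


def easy_base_spec(grid_size: int = 32) -> PhantomSpec:
    """A low-noise, wide-cleft, near-isotropic cohort preset used for
    pipeline sanity runs where the fracture signal should dominate."""
    return PhantomSpec(
        grid_size=grid_size,
        voxel_spacing=(1.0, 1.0, 1.5),
        background_hu=(40.0, 5.0),
        dens_radius=4.0,
        dens_height=12.0,
        shell_thickness=1.5,
        fracture_width=3.0,
        noise_sd=2.0,
        z_blur_sd=0.4,
    )
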