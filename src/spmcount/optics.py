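"""Interferometric scattering model for surface plasmon microscopy (SPM).

An SPM image of surface-bound nanoparticles is modelled as the interference
of two in-plane complex fields:

* a propagating surface-plasmon (SP) plane wave
  ``P(r) = E0 * exp(i * k_sp * (r . d))``, and
* one decaying scattered wave per particle,
  ``S_j(r) = A_j * exp(i * (k_sp * rho + phi_j)) * exp(-rho / L) / sqrt(rho)``
  with ``rho = |r - r0_j|``,

where ``k_sp = 2*pi / sp_wavelength`` is the SP wavenumber, ``L`` the 1/e
amplitude decay length of the scattered wave, and ``d`` the unit propagation
direction.  The detected intensity is ``I(r) = |P(r) + sum_j S_j(r)|**2``.
The cross term between the plane wave and a scattered wave produces the
characteristic parabolic fringe "tail" trailing each particle along ``+d``:
the interference phase ``k_sp * (rho - (r - r0) . d)`` is constant on
parabolas with focus at the particle.

Coordinates: row-major pixel grid, origin at the centre of pixel (0, 0),
``x`` increasing with column index and ``y`` with row index; particle
positions are continuous (sub-pixel), in microns.  The 1/sqrt(rho)
singularity at the particle centre is clamped at ``min_distance``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalParams",
    "ParticleSpec",
    "Scene",
    "plane_wave_field",
    "scattered_field",
    "render_scene",
    "sample_scene",
]


@dataclass(frozen=True)
class OpticalParams:
    """Geometry and field parameters of the SP imaging model.

    All lengths are in microns.  ``image_shape`` is (rows, cols).
    """

    sp_wavelength: float = 0.6
    decay_length: float = 10.0
    prop_direction: tuple[float, float] = (1.0, 0.0)
    background_amplitude: float = 1.0
    pixel_pitch: float = 0.1
    image_shape: tuple[int, int] = (64, 64)
    min_distance: float = 0.1

    def __post_init__(self) -> None:
        if self.sp_wavelength <= 0:
            raise ValueError(f"sp_wavelength must be > 0, got {self.sp_wavelength}")
        if self.decay_length <= 0:
            raise ValueError(f"decay_length must be > 0, got {self.decay_length}")
        if self.background_amplitude <= 0:
            raise ValueError("background_amplitude must be > 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.min_distance < self.pixel_pitch / 2:
            raise ValueError(
                f"min_distance {self.min_distance} must be >= pixel_pitch/2 "
                f"({self.pixel_pitch / 2})"
            )
        nrm = math.hypot(*self.prop_direction)
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError(f"prop_direction must be a unit vector, |d| = {nrm}")
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")

    @property
    def k_sp(self) -> float:
        """SP wavenumber 2*pi / sp_wavelength (rad/um)."""
        return 2.0 * math.pi / self.sp_wavelength

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (width_x, height_y) spanned by pixel centres, in um."""
        rows, cols = self.image_shape
        return ((cols - 1) * self.pixel_pitch, (rows - 1) * self.pixel_pitch)

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids (um) of pixel centres, each image_shape."""
        rows, cols = self.image_shape
        x = np.arange(cols, dtype=float) * self.pixel_pitch
        y = np.arange(rows, dtype=float) * self.pixel_pitch
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class ParticleSpec:
    """A single point scatterer: position (um), amplitude A >= 0, phase [0, 2pi)."""

    position: tuple[float, float]
    amplitude: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    def validate_inside(self, params: OpticalParams) -> None:
        w, h = params.extent
        x, y = self.position
        if not (0.0 <= x <= w and 0.0 <= y <= h):
            raise ValueError(
                f"particle position {self.position} outside image extent "
                f"[0, {w}] x [0, {h}]"
            )


@dataclass(frozen=True)
class Scene:
    """A fully specified clean image: optics + particle list + seed."""

    params: OpticalParams = field(default_factory=OpticalParams)
    particles: tuple[ParticleSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "particles", tuple(self.particles))
        for p in self.particles:
            p.validate_inside(self.params)

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def to_json(self) -> str:
        """Lossless JSON serialization (floats at full repr precision)."""
        d = {
            "params": {**dataclasses.asdict(self.params), "units": "um"},
            "particles": [dataclasses.asdict(p) for p in self.particles],
            "seed": self.seed,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "Scene":
        d = json.loads(s)
        pd = dict(d["params"])
        pd.pop("units", None)
        pd["prop_direction"] = tuple(pd["prop_direction"])
        pd["image_shape"] = tuple(pd["image_shape"])
        params = OpticalParams(**pd)
        particles = tuple(
            ParticleSpec(position=tuple(p["position"]), amplitude=p["amplitude"],
                         phase=p["phase"])
            for p in d["particles"]
        )
        return cls(params=params, particles=particles, seed=d["seed"])


def plane_wave_field(params: OpticalParams) -> np.ndarray:
    """Complex SP plane wave sampled at pixel centres.

    ``E(r) = E0 * exp(i * k_sp * (r . d))``; the phase is zero at the
    coordinate origin (centre of pixel (0, 0)).
    """
    x, y = params.pixel_coords()
    dx, dy = params.prop_direction
    phase = params.k_sp * (x * dx + y * dy)
    return params.background_amplitude * np.exp(1j * phase)


def scattered_field(params: OpticalParams, particle: ParticleSpec) -> np.ndarray:
    """Decaying in-plane scattered wave of one particle.

    ``S(r) = A * exp(i*(k_sp*rho' + phi)) * exp(-rho'/L) / sqrt(rho')`` with
    ``rho' = max(|r - r0|, min_distance)``; the clamp regularizes the point
    singularity (the model is never evaluated at the scatterer centre).
    """
    particle.validate_inside(params)
    x, y = params.pixel_coords()
    x0, y0 = particle.position
    rho = np.hypot(x - x0, y - y0)
    rho_c = np.maximum(rho, params.min_distance)
    envelope = np.exp(-rho_c / params.decay_length) / np.sqrt(rho_c)
    phase = params.k_sp * rho_c + particle.phase
    return particle.amplitude * envelope * np.exp(1j * phase)


def render_scene(scene: Scene) -> np.ndarray:
    """Clean intensity image ``I = |plane wave + sum of scattered waves|**2``.

    Superposition is linear in the complex fields; the modulus is taken once,
    at the end.  Returns a non-negative float array of shape ``image_shape``.
    """
    total = plane_wave_field(scene.params)
    for p in scene.particles:
        total = total + scattered_field(scene.params, p)
    return np.abs(total) ** 2


def sample_scene(
    n_particles: int,
    params: OpticalParams | None = None,
    position_margin: float = 4.0,
    amplitude_range: tuple[float, float] = (0.2, 1.0),
    rng_seed: int = 0,
) -> Scene:
    """Draw a random scene with ``n_particles`` i.i.d.-placed scatterers.

    Positions are uniform in the rectangle inset by ``position_margin``
    pixels from the image border, amplitudes uniform in ``amplitude_range``,
    phases uniform in [0, 2pi).  Deterministic given ``rng_seed``.
    """
    if params is None:
        params = OpticalParams()
    if n_particles < 0:
        raise ValueError(f"n_particles must be >= 0, got {n_particles}")
    lo, hi = amplitude_range
    if not (0 <= lo <= hi):
        raise ValueError(f"bad amplitude_range {amplitude_range}")
    rows, cols = params.image_shape
    if position_margin < 0 or 2 * position_margin >= min(rows - 1, cols - 1):
        raise ValueError(
            f"position_margin {position_margin} leaves no placement region "
            f"on a {rows}x{cols} grid"
        )
    m = position_margin * params.pixel_pitch
    w, h = params.extent
    rng = np.random.default_rng(rng_seed)
    particles = []
    for _ in range(n_particles):
        x = rng.uniform(m, w - m)
        y = rng.uniform(m, h - m)
        a = rng.uniform(lo, hi)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        particles.append(ParticleSpec(position=(x, y), amplitude=a, phase=phi))
    return Scene(params=params, particles=tuple(particles), seed=rng_seed)
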