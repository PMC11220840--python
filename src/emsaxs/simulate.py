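"""Simulated inputs: SAXS curves from structures and phantom density maps.

The validation method needs matched pairs of a density map and a solution
scattering curve.  Real cryo-EM map simulation with controlled resolution is
an open problem, so testing works the other way around: SAXS curves are
simulated exactly (Debye sum over an atomic or bead structure, Gaussian form
factor, per-atom contrasts) and density maps are built as *phantoms* —
geometric solids or Gaussian-smeared point depositions on a voxel grid.
Phantoms are internally consistent test fixtures, not EM simulators: they
carry no CTF, no detector model and no map-processing artefacts.

Simulated curves get per-point errors from an empirical error-magnitude
family (relative error growing with q plus a small baseline floor, scaled by
an exposure factor) and an optional Gaussian noise draw of that magnitude.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .map_io import DensityMap
from .scattering import FormFactorParams, debye_exact
from .structure_io import AtomicStructure, SAXSData

__all__ = [
    "NoiseModel",
    "PhantomSpec",
    "simulate_saxs",
    "simulate_saxs_from_intensity",
    "make_phantom_map",
    "phantom_structure",
    "phantom_truth_intensity",
    "sphere_form_factor",
]


@dataclasses.dataclass
class NoiseModel:
    """Empirical error-magnitude family for simulated SAXS curves.

    The 1-sigma error assigned to a point is

        sigma(q) = (alpha + beta * q**gamma) * (I(q) + floor * I(0)) / sqrt(exposure)

    i.e. a relative error that grows from ``alpha`` at low q as a power law
    in q, applied to the intensity plus a small baseline floor (so that
    sigma stays positive through form-factor minima, as a real buffer-
    subtracted measurement's does).  ``exposure`` scales overall counting
    statistics.  Defaults emulate a well-exposed synchrotron curve: ~0.5%
    relative error at low q rising to ~10% at q = 0.5 1/A.
    """

    alpha: float = 0.005
    beta: float = 0.3
    gamma: float = 1.5
    floor: float = 1e-3
    exposure: float = 1.0
    seed: int = 0

    def sigma(self, q: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=np.float64)
        intensity = np.asarray(intensity, dtype=np.float64)
        i0 = float(np.max(np.abs(intensity))) or 1.0
        rel = self.alpha + self.beta * q**self.gamma
        return rel * (np.abs(intensity) + self.floor * i0) / np.sqrt(self.exposure)


def simulate_saxs(
    structure: AtomicStructure,
    q_grid,
    noise: NoiseModel | None = NoiseModel(),
) -> SAXSData:
    """Simulate a SAXS curve from an atomic structure.

    The noiseless intensity is the exact Debye sum with the per-atom
    contrasts as weights and the shared Gaussian form factor.  With a
    :class:`NoiseModel`, per-point errors are computed from it and a Gaussian
    draw of that magnitude (reproducible through the model's seed) perturbs
    the curve; ``noise=None`` keeps the default error magnitudes but applies
    no perturbation.
    """
    if structure.contrast is None:
        raise ValueError("structure has no contrasts; call assign_contrasts first")
    q = np.asarray(q_grid, dtype=np.float64)
    truth = debye_exact(structure.positions, structure.contrast, q, FormFactorParams())
    return simulate_saxs_from_intensity(q, truth, noise, label=structure.label)


def simulate_saxs_from_intensity(
    q_grid,
    intensity,
    noise: NoiseModel | None = NoiseModel(),
    label: str = "",
) -> SAXSData:
    """Attach the error model (and optionally a noise draw) to a true curve."""
    q = np.asarray(q_grid, dtype=np.float64)
    truth = np.asarray(intensity, dtype=np.float64)
    model = noise or NoiseModel()
    sigma = model.sigma(q, truth)
    observed = truth
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        observed = truth + rng.normal(0.0, sigma)
    return SAXSData(q, observed, sigma, label=label)


@dataclasses.dataclass
class PhantomSpec:
    """Geometry of a phantom density map.

    ``kind`` is ``"ball"``, ``"two-ball"`` or ``"from-structure"``.  Lengths
    in Angstrom.  ``smear_sigma`` is the width of the isotropic Gaussian
    kernel applied after depositing the solid/structure on the grid;
    ``noise_level`` adds zero-mean Gaussian background per voxel.
    """

    kind: str = "ball"
    radius: float = 15.0
    separation: float = 0.0           # centre-centre distance for two-ball
    voxel_size: float = 2.0
    shape: tuple[int, int, int] = (32, 32, 32)
    smear_sigma: float = 2.0
    noise_level: float = 0.0
    structure: AtomicStructure | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ball", "two-ball", "from-structure"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind != "from-structure":
            extent = 2 * self.radius + (self.separation if self.kind == "two-ball" else 0)
            box = min(self.shape) * self.voxel_size
            if extent + 2 * self.smear_sigma > box:
                raise ValueError(
                    f"phantom extent {extent:.1f} A (+ smear margin) exceeds "
                    f"grid box {box:.1f} A"
                )

    def centers(self) -> np.ndarray:
        """World coordinates of the solid centres (grid centred at origin 0)."""
        c = (np.asarray(self.shape) - 1) * self.voxel_size / 2.0
        if self.kind == "two-ball":
            off = np.array([self.separation / 2.0, 0.0, 0.0])
            return np.array([c - off, c + off])
        return np.array([c])

    def volume(self) -> float:
        n_balls = 2 if self.kind == "two-ball" else 1
        return n_balls * 4.0 / 3.0 * np.pi * self.radius**3


def make_phantom_map(spec: PhantomSpec, seed: int | None = None) -> DensityMap:
    """Rasterize a phantom onto a voxel grid.

    Solids are deposited as density 1 inside the radius; ``from-structure``
    phantoms deposit each atom's contrast at its nearest voxel.  The result
    is smoothed with the requested Gaussian kernel and optional background noise
    is added (reproducible with ``seed``).
    """
    shape = tuple(spec.shape)
    vox = float(spec.voxel_size)
    grid = np.zeros(shape)
    coords = np.indices(shape).reshape(3, -1).T * vox
    if spec.kind == "from-structure":
        if spec.structure is None:
            raise ValueError("from-structure phantom requires a structure")
        weights = (
            spec.structure.contrast
            if spec.structure.contrast is not None
            else np.ones(len(spec.structure))
        )
        idx = np.rint(spec.structure.positions / vox).astype(np.int64)
        if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
            raise ValueError("structure does not fit inside the phantom grid")
        np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), weights)
    else:
        inside = np.zeros(coords.shape[0], dtype=bool)
        for center in spec.centers():
            inside |= np.linalg.norm(coords - center, axis=1) <= spec.radius
        grid = inside.reshape(shape).astype(np.float64)
    if spec.smear_sigma > 0:
        grid = gaussian_filter(grid, sigma=spec.smear_sigma / vox)
    if spec.noise_level > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, spec.noise_level, size=shape)
    return DensityMap(
        densities=grid,
        voxel_size=np.full(3, vox),
        origin=np.zeros(3),
        source_id=f"phantom-{spec.kind}",
    )


def phantom_structure(spec: PhantomSpec, contrast: float = 1.0) -> AtomicStructure:
    """Bead structure filling the phantom solid on the phantom's own grid.

    One unit-contrast bead per grid point inside the solid — the exact
    point-set counterpart of the unsmeared phantom map, which makes matched
    map/curve round trips possible.
    """
    if spec.kind == "from-structure":
        if spec.structure is None:
            raise ValueError("from-structure phantom requires a structure")
        return spec.structure
    coords = np.indices(spec.shape).reshape(3, -1).T * spec.voxel_size
    inside = np.zeros(coords.shape[0], dtype=bool)
    for center in spec.centers():
        inside |= np.linalg.norm(coords - center, axis=1) <= spec.radius
    return AtomicStructure.from_points(
        coords[inside], contrast=contrast, label=f"phantom-{spec.kind}"
    )


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized sphere form-factor intensity ``[3 (sin x - x cos x)/x^3]^2``."""
    x = np.asarray(q, dtype=np.float64) * radius
    amp = np.ones_like(x)
    big = np.abs(x) > 1e-2
    xb = x[big]
    amp[big] = 3.0 * (np.sin(xb) - xb * np.cos(xb)) / xb**3
    # series branch: sin x - x cos x = x^3/3 - x^5/30 + ..., avoids cancellation
    xs = x[~big]
    amp[~big] = 1.0 - xs**2 / 10.0
    return amp**2


def phantom_truth_intensity(spec: PhantomSpec, q_grid) -> np.ndarray:
    """Analytic scattering intensity of a solid phantom (oracle).

    Ball: ``V^2 * P_sphere(qR)``.  Two-ball: the orientationally averaged
    coherent sum of two identical spheres separated by d,
    ``2 V^2 P_sphere(qR) (1 + sinc(q d))``; at d = 0 this reduces to the
    single-sphere expression with amplitude 2V (intensity 4 V^2 P).
    """
    q = np.asarray(q_grid, dtype=np.float64)
    if spec.kind == "from-structure":
        raise ValueError("no analytic intensity for from-structure phantoms")
    v = 4.0 / 3.0 * np.pi * spec.radius**3
    p = sphere_form_factor(q, spec.radius)
    if spec.kind == "ball":
        return v**2 * p
    d = spec.separation
    return 2.0 * v**2 * p * (1.0 + np.sinc(q * d / np.pi))
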