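"""Dummy-atom model generation from a thresholded density map.

The map's own grid places the dummy atoms: every voxel whose density is at or
above the threshold ``d`` becomes one point scatterer at
``origin + index * voxel_size``.  Two weighting modes exist: *unity* (every
dummy atom weight 1) and *dynamic* (weight = voxel density).  For the
threshold scan the map is additionally partitioned into onion shells —
disjoint density bands whose union down to a level reproduces the excised
model exactly — which is what makes incremental histogram reuse possible.

A simulated hydration shell of dummy waters is placed one van-der-Waals
contact distance from the model surface; its scattering contribution is
scaled later by the fitted contrast factor ``c_w``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .map_io import DensityMap

__all__ = [
    "DummyModel",
    "OnionShells",
    "excise_model",
    "build_shells",
    "hydrate",
    "estimate_mass",
    "threshold_to_rms",
    "PROTEIN_MASS_DENSITY",
]

#: Average protein mass density, g/cm^3; the mass axis is approximate by
#: construction, so a standard constant suffices.
PROTEIN_MASS_DENSITY = 1.35

# 1 A^3 of protein at 1.35 g/cm^3, in Dalton (1.35e-24 g / 1.66054e-24 g/Da)
_DALTON_PER_A3 = PROTEIN_MASS_DENSITY / 1.66054


@dataclasses.dataclass
class DummyModel:
    """A threshold-selected weighted point set plus hydration waters."""

    threshold: float
    positions: np.ndarray          # (n, 3) Angstrom, on the source grid
    weights: np.ndarray            # (n,) all > 0; unity mode: all 1
    waters: np.ndarray             # (m, 3) Angstrom hydration dummy atoms
    stride: int = 1
    voxel_size: np.ndarray | None = None  # carried for surface detection
    source_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.waters = np.asarray(self.waters, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def is_empty(self) -> bool:
        return len(self) == 0


@dataclasses.dataclass
class OnionShells:
    """Disjoint density bands of a map, ordered from densest outwards.

    ``shell k`` holds the voxels with density in ``[levels[k], levels[k-1])``
    (shell 0: density >= levels[0]).  The union of shells 0..k equals the
    excised model at threshold ``levels[k]`` exactly.
    """

    levels: np.ndarray                     # strictly descending
    shell_positions: list[np.ndarray]      # per level, (m_k, 3)
    shell_weights: list[np.ndarray]        # per level, (m_k,)
    stride: int = 1
    voxel_size: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.levels)

    def cumulative_size(self, k: int) -> int:
        return int(sum(len(p) for p in self.shell_positions[: k + 1]))


def _selected(dmap: DensityMap, stride: int):
    """Strided voxel positions and densities of a map (flat arrays)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    dens = dmap.densities[::stride, ::stride, ::stride]
    idx = np.indices(dens.shape).reshape(3, -1).T * stride
    positions = dmap.voxel_to_world(idx)
    return positions, dens.reshape(-1)


def excise_model(
    dmap: DensityMap,
    threshold: float,
    weight_mode: str = "unity",
    stride: int = 1,
) -> DummyModel:
    """Cut a dummy-atom model out of a map at a density threshold.

    Density below the threshold is treated as noise and discarded.  With
    ``stride`` > 1 only every stride-th grid point per axis is considered
    (coarser sampling barely affects the low-resolution SAXS regime).  A
    threshold above the map maximum yields an *empty* model, not an error —
    the landscape scan must handle that case.
    """
    if weight_mode not in ("unity", "dynamic"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    positions, dens = _selected(dmap, stride)
    mask = dens >= threshold
    positions = positions[mask]
    weights = np.ones(mask.sum()) if weight_mode == "unity" else dens[mask].copy()
    return DummyModel(
        threshold=float(threshold),
        positions=positions,
        weights=weights,
        waters=np.empty((0, 3)),
        stride=stride,
        voxel_size=dmap.voxel_size * stride,
        source_id=dmap.source_id,
    )


def build_shells(
    dmap: DensityMap,
    levels: np.ndarray,
    weight_mode: str = "unity",
    stride: int = 1,
) -> OnionShells:
    """Partition a map into onion shells for a descending threshold scan."""
    levels = np.asarray(levels, dtype=np.float64)
    if len(levels) < 1 or np.any(np.diff(levels) >= 0):
        raise ValueError("levels must be strictly descending")
    if weight_mode not in ("unity", "dynamic"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    positions, dens = _selected(dmap, stride)
    shell_positions, shell_weights = [], []
    upper = np.inf
    for level in levels:
        mask = (dens >= level) & (dens < upper)
        shell_positions.append(positions[mask])
        shell_weights.append(
            np.ones(mask.sum()) if weight_mode == "unity" else dens[mask].copy()
        )
        upper = level
    return OnionShells(
        levels=levels,
        shell_positions=shell_positions,
        shell_weights=shell_weights,
        stride=stride,
        voxel_size=dmap.voxel_size * stride,
    )


def _surface_voxels(model: DummyModel) -> tuple[np.ndarray, float]:
    """Surface voxel positions and an estimated surface area (A^2).

    A voxel is on the surface when at least one of its six face neighbours is
    unselected.  Summing the exposed face areas overestimates the area of a
    smooth surface by a factor 3/2 (the staircase effect), so the estimate is
    2/3 of the exposed-face total.
    """
    if model.voxel_size is None:
        raise ValueError("model carries no grid spacing; cannot find surface")
    vox = np.asarray(model.voxel_size, dtype=float)
    ref = model.positions.min(axis=0)
    idx = np.rint((model.positions - ref) / vox).astype(np.int64)
    dims = idx.max(axis=0) + 3
    occ = np.zeros(dims, dtype=bool)
    occ[idx[:, 0] + 1, idx[:, 1] + 1, idx[:, 2] + 1] = True
    face_area = np.array(
        [vox[1] * vox[2], vox[0] * vox[2], vox[0] * vox[1]]
    )
    exposed_area = 0.0
    surface = np.zeros(dims, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            neighbour = np.roll(occ, shift, axis=axis)
            exposed = occ & ~neighbour
            surface |= exposed
            exposed_area += float(exposed.sum()) * face_area[axis]
    sidx = np.argwhere(surface) - 1
    positions = ref + sidx * vox
    return positions, exposed_area * (2.0 / 3.0)


def hydrate(
    model: DummyModel,
    seed,
    shell_distance: float = 3.0,
    target_density: float = 0.2,
    min_water_spacing: float = 2.8,
    placement_tolerance: float = 2.8,
    candidates_per_voxel: int = 100,
) -> DummyModel:
    """Simulate a hydration shell of dummy waters around a model.

    Candidate sites are drawn at random directions around each surface voxel
    at radii in ``[shell_distance, shell_distance + placement_tolerance]``;
    sites closer than ``shell_distance`` to *any* dummy atom (interior
    placements) or than ``min_water_spacing`` to an accepted water are
    rejected, and placement stops when the target count
    ``target_density * estimated surface area`` is reached.  The same seed
    always reproduces the same waters.

    Parameters use Angstrom: the default 3.0 A shell distance is a typical
    carbon/water-oxygen van-der-Waals contact; 2.8 A is the water-water
    contact distance, used both as the minimum spacing and as the default
    radial thickness of the shell (one molecular layer); 0.2 waters/A^2
    roughly matches a monolayer's surface density.
    """
    if model.is_empty:
        raise ValueError("cannot hydrate an empty model")
    rng = np.random.default_rng(seed)
    surface, area = _surface_voxels(model)
    n_target = int(round(target_density * area))
    if n_target == 0 or len(surface) == 0:
        return dataclasses.replace(model, waters=np.empty((0, 3)))

    n_cand = len(surface) * candidates_per_voxel
    directions = rng.normal(size=(n_cand, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = rng.uniform(shell_distance, shell_distance + placement_tolerance, n_cand)
    candidates = np.repeat(surface, candidates_per_voxel, axis=0)
    candidates = candidates + directions * radii[:, None]

    # no interior placement: nearest dummy atom must be >= shell_distance away
    tree = cKDTree(model.positions)
    dmin, _ = tree.query(candidates, k=1)
    candidates = candidates[dmin >= shell_distance - 1e-9]
    rng.shuffle(candidates, axis=0)

    # greedy acceptance with a cell list enforcing water-water spacing
    cell = min_water_spacing
    occupied: dict[tuple[int, int, int], list[np.ndarray]] = {}
    accepted: list[np.ndarray] = []
    spacing2 = min_water_spacing**2
    for point in candidates:
        key = tuple((point // cell).astype(np.int64))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for other in occupied.get(
                        (key[0] + dx, key[1] + dy, key[2] + dz), ()
                    ):
                        diff = point - other
                        if diff @ diff < spacing2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(point)
            occupied.setdefault(key, []).append(point)
            if len(accepted) >= n_target:
                break
    waters = np.array(accepted).reshape(-1, 3)
    return dataclasses.replace(model, waters=waters)


def estimate_mass(model: DummyModel, dmap: DensityMap) -> float:
    """Mass of a model in kDa from its voxel volume.

    Counts all voxels at or above the model's threshold at stride 1 (the
    scattering stride does not change the physical volume) and converts the
    volume to mass with the average protein density.  The mapping from
    threshold to mass is one-to-one but carries significant uncertainty; it
    serves to label landscape minima, not for absolute comparisons.
    """
    if model.is_empty:
        return 0.0
    count = int(np.count_nonzero(dmap.densities >= model.threshold))
    return count * dmap.voxel_volume * _DALTON_PER_A3 / 1000.0


def threshold_to_rms(dmap: DensityMap, threshold: float) -> float:
    """Express a threshold in RMS units (the PyMOL/Chimera contour scale)."""
    rms = dmap.density_rms
    if rms <= 0:
        raise ValueError("map RMS is zero; cannot express threshold in RMS units")
    return float(threshold) / rms
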