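"""Reading, writing and thresholding of EM density maps (MRC2014/CCP4).

An EM map is a 3-D grid of density values with geometry metadata that maps
grid indices to Cartesian coordinates in Angstrom.  Files may store the grid
with any axis permutation (MAPC/MAPR/MAPS); on read the data are always
canonicalised so that ``densities[ix, iy, iz]`` indexes the crystallographic
x, y and z axes, with x varying fastest in file order.

The file-level parsing is delegated to :mod:`gemmi`; this module adds the
geometry conventions used throughout the package:

* a voxel's dummy atom sits at the grid point ``origin + index * voxel_size``
  (0-based indices, no half-voxel centre offset);
* the map origin is taken from the ORIGIN header record, falling back to
  ``NXSTART * voxel_size`` when ORIGIN is all-zero (the MRC2014
  recommendation); the precedence can be overridden;
* the RMS density is always recomputed from the data; a header RMS that
  disagrees triggers a warning but is not trusted.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "MapFormatError",
    "read_map",
    "write_map",
    "density_levels",
]


class MapFormatError(ValueError):
    """Raised when a file is not a readable MRC/CCP4 density map."""


@dataclasses.dataclass
class DensityMap:
    """A voxel grid of EM density with geometry metadata.

    Parameters
    ----------
    densities:
        Array of shape ``(nx, ny, nz)`` in canonical axis order, i.e.
        ``densities[ix, iy, iz]`` is the density at world coordinate
        ``origin + (ix, iy, iz) * voxel_size``.
    voxel_size:
        Grid spacing along each cell axis, Angstrom.  All components > 0.
    origin:
        World position of voxel ``(0, 0, 0)``, Angstrom.
    axis_order:
        The MAPC/MAPR/MAPS permutation of the *source file*.  Purely
        informational: the stored data are always canonical ``(1, 2, 3)``.
    source_id:
        Free-text label (file name, EMDB id, phantom description ...).
    """

    densities: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    axis_order: tuple[int, int, int] = (1, 2, 3)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=np.float64)
        if self.densities.ndim != 3:
            raise ValueError("densities must be a 3-D array")
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.voxel_size.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("voxel_size and origin must be length-3")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be positive")
        if sorted(self.axis_order) != [1, 2, 3]:
            raise ValueError(f"invalid axis order {self.axis_order!r}")

    @property
    def dims(self) -> tuple[int, int, int]:
        """Grid dimensions ``(nx, ny, nz)``."""
        return self.densities.shape

    @property
    def density_rms(self) -> float:
        """Root-mean-square of all voxel values (recomputed, not cached)."""
        return float(np.sqrt(np.mean(self.densities**2)))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, cubic Angstrom."""
        return float(np.prod(self.voxel_size))

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (Angstrom) of integer voxel indices ``(n, 3)``."""
        return self.origin + np.asarray(indices, dtype=np.float64) * self.voxel_size


def read_map(path, prefer_origin_record: bool = True) -> DensityMap:
    """Read an MRC2014/CCP4 density map (optionally gzip-compressed).

    The grid is canonicalised to x-fastest order regardless of the file's
    MAPC/MAPR/MAPS permutation.  The voxel size is ``CELLA / (MX, MY, MZ)``.

    Parameters
    ----------
    path:
        ``.mrc`` / ``.map`` file, or a ``.gz`` compressed one.
    prefer_origin_record:
        If True (default, the MRC2014 recommendation) a non-zero ORIGIN
        record wins over NXSTART; set False to always use NXSTART.

    Raises
    ------
    MapFormatError
        Wrong magic word, unsupported data mode, or header/data mismatch.
    FileNotFoundError
        Missing file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"map not found: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except RuntimeError as exc:
        raise MapFormatError(f"{path}: {exc}") from exc

    axis_order = tuple(ccp4.header_i32(w) for w in (17, 18, 19))
    if sorted(axis_order) != [1, 2, 3]:
        raise MapFormatError(f"{path}: invalid MAPC/MAPR/MAPS {axis_order}")
    start_crs = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
    mxyz = np.array([ccp4.header_i32(w) for w in (8, 9, 10)], dtype=float)
    cella = np.array([ccp4.header_float(w) for w in (11, 12, 13)])
    origin_rec = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    header_rms = ccp4.header_float(55)
    if np.any(mxyz <= 0) or np.any(cella <= 0):
        raise MapFormatError(f"{path}: non-positive cell or sampling in header")
    voxel_size = cella / mxyz

    # Reorder the data so the crystallographic x axis varies fastest.
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    densities = np.array(ccp4.grid, copy=True)

    # NXSTART/NYSTART/NZSTART are stored per file axis; permute to x, y, z.
    start_xyz = np.empty(3)
    for file_axis, cryst_axis in enumerate(axis_order):
        start_xyz[cryst_axis - 1] = start_crs[file_axis]
    if prefer_origin_record and np.any(origin_rec != 0.0):
        origin = origin_rec
    else:
        origin = start_xyz * voxel_size

    dmap = DensityMap(
        densities=densities,
        voxel_size=voxel_size,
        origin=origin,
        axis_order=axis_order,  # type: ignore[arg-type]
        source_id=path.name,
    )
    if header_rms > 0 and not np.isclose(header_rms, dmap.density_rms, rtol=1e-4):
        warnings.warn(
            f"{path.name}: header RMS {header_rms:g} disagrees with recomputed "
            f"RMS {dmap.density_rms:g}; the recomputed value is used",
            stacklevel=2,
        )
    return dmap


def write_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC2014 mode 2 (float32), canonical axis order.

    ``read_map(write_map(m))`` is the identity on dims, origin, voxel size
    and densities at float32 precision.
    """
    nx, ny, nz = dmap.dims
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid)[...] = dmap.densities.astype(np.float32)
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * dmap.voxel_size[0],
            ny * dmap.voxel_size[1],
            nz * dmap.voxel_size[2],
            90.0,
            90.0,
            90.0,
        )
    )
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.set_header_float(55, dmap.density_rms)
    ccp4.write_ccp4_map(str(path))


def density_levels(
    dmap: DensityMap,
    n_levels: int,
    min_level: float | None = None,
    max_level: float | None = None,
) -> np.ndarray:
    """Equidistant threshold levels in strictly descending order.

    The threshold scan runs from the highest level towards the lowest, so the
    first element is ``max_level`` and the last is ``min_level``.

    Automatic bounds when not given: ``max_level`` is the maximum voxel
    density; ``min_level`` is 0 for maps without negative values, otherwise
    one RMS (negative densities in an EM map are noise, so scanning below the
    noise floor is pointless).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if max_level is None:
        max_level = float(dmap.densities.max())
    if min_level is None:
        min_level = 0.0 if dmap.densities.min() >= 0 else dmap.density_rms
    if not min_level < max_level:
        raise ValueError(f"min_level {min_level} must be < max_level {max_level}")
    return np.linspace(max_level, min_level, n_levels)
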