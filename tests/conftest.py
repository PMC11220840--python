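"""Shared fixtures: hand-rolled MRC writer (independent oracle) and phantoms."""

from __future__ import annotations

import struct

import numpy as np
import pytest


def write_raw_mrc(
    path,
    densities: np.ndarray,
    axis_order=(1, 2, 3),
    voxel_size=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    nxstart=(0, 0, 0),
    mode: int = 2,
    magic: bytes = b"MAP ",
    rms: float | None = None,
) -> None:
    """Write an MRC2014 file by direct header arithmetic.

    Completely independent of the package's map I/O: the 1024-byte header is
    assembled word by word and the data block is permuted by hand according
    to ``axis_order`` (MAPC/MAPR/MAPS).  ``densities`` is given in canonical
    (x, y, z) index order; ``nxstart`` is given per *file* axis.
    """
    densities = np.asarray(densities, dtype=np.float64)
    nx, ny, nz = densities.shape
    dims_xyz = (nx, ny, nz)
    # file array F[s, r, c] where c/r/s are the crystallographic axes named
    # by axis_order; build by moving canonical axes into file order
    perm = [axis_order[2] - 1, axis_order[1] - 1, axis_order[0] - 1]
    F = np.transpose(densities, perm).astype("<f4")
    counts_crs = (dims_xyz[axis_order[0] - 1],
                  dims_xyz[axis_order[1] - 1],
                  dims_xyz[axis_order[2] - 1])

    header = np.zeros(256, dtype="<i4")
    fh = header.view("<f4")
    header[0:3] = counts_crs
    header[3] = mode
    header[4:7] = nxstart
    header[7:10] = dims_xyz
    fh[10:13] = np.array(dims_xyz) * np.asarray(voxel_size)
    fh[13:16] = (90.0, 90.0, 90.0)
    header[16:19] = axis_order
    fh[19] = densities.min()
    fh[20] = densities.max()
    fh[21] = densities.mean()
    header[22] = 1  # ISPG
    fh[49:52] = origin
    header[52] = struct.unpack("<i", magic)[0]
    header[53] = struct.unpack("<i", b"\x44\x41\x00\x00")[0]  # little-endian MACHST
    fh[54] = float(np.sqrt(np.mean(densities**2))) if rms is None else rms
    with open(path, "wb") as fh_out:
        fh_out.write(header.tobytes())
        if mode == 2:
            fh_out.write(F.tobytes())
        elif mode == 0:
            fh_out.write(F.astype("<i1").tobytes())
        elif mode == 1:
            fh_out.write(F.astype("<i2").tobytes())
        else:
            fh_out.write(F.tobytes())


@pytest.fixture
def raw_mrc_writer():
    return write_raw_mrc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pdb(tmp_path):
    """A hand-written three-residue PDB fragment."""
    text = """\
HEADER    TOY
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00 10.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      7  CA  GLY A   2       3.985   2.835   0.000  1.00 10.00           C
ATOM      8  C   GLY A   2       5.498   2.705   0.000  1.00 10.00           C
ATOM      9  O   GLY A   2       6.062   1.610   0.000  1.00 10.00           O
ATOM     10  N   SER A   3       6.158   3.853   0.000  1.00 10.00           N
ATOM     11  CA  SER A   3       7.613   3.905   0.000  1.00 10.00           C
ATOM     12  CB  SER A   3       8.127   5.340   0.000  1.00 10.00           C
ATOM     13  OG  SER A   3       9.544   5.355   0.000  1.00 10.00           O
TER
HETATM   14  O   HOH A 101      10.000  10.000  10.000  1.00 20.00           O
END
"""
    path = tmp_path / "toy.pdb"
    path.write_text(text)
    return path
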