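"""Atomic structures, SAXS curves, and dummy-model export.

Covers the file formats around the core method: PDB structures (input for
SAXS simulation), three-column SAXS ``.dat`` curves in the ATSAS/GNOM
dialect, and PDB export of dummy-atom models for visualization.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import TYPE_CHECKING

import gemmi
import numpy as np

from .chemistry import lookup_atom

if TYPE_CHECKING:  # pragma: no cover
    from .model_generation import DummyModel

__all__ = [
    "AtomicStructure",
    "SAXSData",
    "StructureError",
    "SAXSFormatError",
    "read_pdb",
    "assign_contrasts",
    "read_saxs",
    "write_saxs",
    "write_model_pdb",
]

DEFAULT_SOLVENT_E_DENSITY = 0.334  # e/A^3, pure water


class StructureError(ValueError):
    """Raised for unusable atomic-structure input."""


class SAXSFormatError(ValueError):
    """Raised for malformed SAXS data files."""


@dataclasses.dataclass
class AtomicStructure:
    """A flat list of heavy atoms with scattering bookkeeping.

    ``z_eff`` counts the atom's electrons plus those of its bonded hydrogens;
    ``v_excl`` is the excluded solvent volume per atom (A^3).  ``contrast``
    stays ``None`` until :func:`assign_contrasts` fills in
    ``z_eff - rho_solvent * v_excl`` (electrons; may be negative).
    """

    elements: list[str]
    residues: list[str]
    atom_names: list[str]
    positions: np.ndarray            # (n, 3) Angstrom
    z_eff: np.ndarray                # (n,)
    v_excl: np.ndarray               # (n,)
    contrast: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.z_eff = np.asarray(self.z_eff, dtype=np.float64)
        self.v_excl = np.asarray(self.v_excl, dtype=np.float64)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def from_points(cls, positions, contrast=1.0, label="") -> "AtomicStructure":
        """Build a bead structure with explicit contrasts (phantoms, tests)."""
        positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
        n = positions.shape[0]
        contrast = np.broadcast_to(np.asarray(contrast, dtype=np.float64), (n,)).copy()
        return cls(
            elements=["C"] * n,
            residues=["DUM"] * n,
            atom_names=["C"] * n,
            positions=positions,
            z_eff=contrast.copy(),
            v_excl=np.zeros(n),
            contrast=contrast,
            label=label,
        )


def read_pdb(
    path,
    strip_waters: bool = True,
    strip_hydrogens: bool = True,
    skip_unknown: bool = False,
) -> AtomicStructure:
    """Read ATOM/HETATM records from a PDB file.

    Alternate locations are resolved by keeping the highest-occupancy altloc
    of each atom.  Z_eff and V_excl are resolved from the bundled residue
    table (element-level fallback with a warning).

    Raises
    ------
    StructureError
        No atoms remain after filtering.
    KeyError
        Unknown element and ``skip_unknown`` is False.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure not found: {path}")
    structure = gemmi.read_structure(str(path))
    elements: list[str] = []
    residues: list[str] = []
    names: list[str] = []
    positions: list[tuple[float, float, float]] = []
    z_eff: list[float] = []
    v_excl: list[float] = []
    model = structure[0] if len(structure) else None
    if model is None:
        raise StructureError(f"{path}: no models")
    for chain in model:
        for residue in chain:
            if strip_waters and residue.name.strip() in ("HOH", "WAT", "DOD"):
                continue
            # keep the highest-occupancy altloc per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if strip_hydrogens and atom.element.name in ("H", "D"):
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                element = atom.element.name.upper()
                try:
                    z, v = lookup_atom(element, residue.name, name)
                except KeyError:
                    if skip_unknown:
                        continue
                    raise
                elements.append(element)
                residues.append(residue.name)
                names.append(name)
                positions.append((atom.pos.x, atom.pos.y, atom.pos.z))
                z_eff.append(z)
                v_excl.append(v)
    if not positions:
        raise StructureError(f"{path}: no usable atoms after filtering")
    return AtomicStructure(
        elements=elements,
        residues=residues,
        atom_names=names,
        positions=np.array(positions),
        z_eff=np.array(z_eff),
        v_excl=np.array(v_excl),
        label=path.name,
    )


def assign_contrasts(
    structure: AtomicStructure,
    solvent_e_density: float = DEFAULT_SOLVENT_E_DENSITY,
) -> AtomicStructure:
    """Assign per-atom contrast ``Z_eff - rho_solvent * V_excl`` in place.

    The contrast is the excess scattering length of the atom over the solvent
    it displaces; it may legitimately be negative.  Returns the structure for
    chaining.
    """
    structure.contrast = structure.z_eff - solvent_e_density * structure.v_excl
    return structure


@dataclasses.dataclass
class SAXSData:
    """A 1-D SAXS curve: scattering vector q (1/A), intensity, 1-sigma errors."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise SAXSFormatError("q, intensity and sigma must have equal length")
        if len(self.q) and (np.any(np.diff(self.q) <= 0) or self.q[0] <= 0):
            raise SAXSFormatError("q must be strictly increasing and positive")
        if np.any(self.sigma <= 0):
            raise SAXSFormatError("all sigma must be positive")

    def __len__(self) -> int:
        return len(self.q)

    def truncate(self, qmin: float | None = None, qmax: float | None = None) -> "SAXSData":
        mask = np.ones(len(self.q), dtype=bool)
        if qmin is not None:
            mask &= self.q >= qmin
        if qmax is not None:
            mask &= self.q <= qmax
        return SAXSData(self.q[mask], self.intensity[mask], self.sigma[mask], self.label)

    def rebin(self, n_bins: int) -> "SAXSData":
        """Logarithmic rebinning for oversampled high-q data.

        Within each log-spaced q bin the intensity is averaged and the errors
        are combined as ``sigma_bin = sqrt(sum sigma^2) / n``; the bin's q is
        the mean of its members.  Returns at most ``n_bins`` points.
        """
        if n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if n_bins >= len(self.q):
            return self
        edges = np.geomspace(self.q[0], self.q[-1] * (1 + 1e-12), n_bins + 1)
        idx = np.clip(np.digitize(self.q, edges) - 1, 0, n_bins - 1)
        qs, Is, sigmas = [], [], []
        for k in range(n_bins):
            sel = idx == k
            n = int(sel.sum())
            if n == 0:
                continue
            qs.append(self.q[sel].mean())
            Is.append(self.intensity[sel].mean())
            sigmas.append(math.sqrt(float(np.sum(self.sigma[sel] ** 2))) / n)
        return SAXSData(np.array(qs), np.array(Is), np.array(sigmas), self.label)


def read_saxs(
    path,
    qmin: float | None = None,
    qmax: float | None = None,
    rebin: int | None = None,
    drop_bad_points: bool = False,
) -> SAXSData:
    """Read a whitespace-separated three-column ``q I sigma`` file.

    Header and footer lines ('#' comments or any non-numeric text, as written
    by GNOM/ATSAS tools) are tolerated.  Optional q-range truncation and
    logarithmic rebinning are applied after parsing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SAXS data not found: {path}")
    rows: list[tuple[float, float, float]] = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            if rows:
                raise SAXSFormatError(f"{path}: data line with <3 columns: {line!r}")
            continue  # header text
        try:
            q, inten, sig = (float(parts[0]), float(parts[1]), float(parts[2]))
        except ValueError:
            if rows:
                break  # footer text after the data block
            continue
        rows.append((q, inten, sig))
    if not rows:
        raise SAXSFormatError(f"{path}: no numeric three-column data found")
    arr = np.array(rows)
    if drop_bad_points:
        arr = arr[(arr[:, 2] > 0) & (arr[:, 0] > 0)]
    try:
        data = SAXSData(arr[:, 0], arr[:, 1], arr[:, 2], label=path.name)
    except SAXSFormatError as exc:
        raise SAXSFormatError(f"{path}: {exc}") from exc
    data = data.truncate(qmin, qmax)
    if rebin is not None:
        data = data.rebin(rebin)
    return data


def write_saxs(data: SAXSData, path) -> None:
    """Write a SAXS curve as three columns with a one-line header."""
    header = f"q(1/A) I sigma  [{data.label}]"
    np.savetxt(
        path,
        np.column_stack([data.q, data.intensity, data.sigma]),
        header=header,
        fmt="%.8e",
    )


def write_model_pdb(model: "DummyModel", path) -> None:
    """Write a dummy model as a PDB file for visualization.

    Map-derived dummy atoms become HETATM carbon records in chain A with the
    dummy weight in the B-factor column; hydration waters become HOH oxygens
    in chain B.  Models beyond the classic 99 999-serial limit are written
    with gemmi's hybrid-36-style numbering.
    """
    model_positions = np.asarray(model.positions, dtype=float).reshape(-1, 3)
    if model_positions.shape[0] == 0:
        raise ValueError("cannot write an empty dummy model")
    structure = gemmi.Structure()
    structure.name = model.source_id or "dummy-model"
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain("A")
    weights = np.asarray(model.weights, dtype=float)
    for i, (pos, w) in enumerate(zip(model_positions, weights)):
        residue = gemmi.Residue()
        residue.name = "DUM"
        residue.seqid = gemmi.SeqId(i % 9999 + 1, " ")
        residue.het_flag = "H"
        atom = gemmi.Atom()
        atom.name = "C"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        atom.b_iso = float(w)
        residue.add_atom(atom)
        chain.add_residue(residue)
    gmodel.add_chain(chain)
    waters = np.asarray(model.waters, dtype=float).reshape(-1, 3)
    if waters.shape[0]:
        wchain = gemmi.Chain("B")
        for i, pos in enumerate(waters):
            residue = gemmi.Residue()
            residue.name = "HOH"
            residue.seqid = gemmi.SeqId(i % 9999 + 1, " ")
            residue.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = "O"
            atom.element = gemmi.Element("O")
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            atom.b_iso = 0.0
            residue.add_atom(atom)
            wchain.add_residue(residue)
        gmodel.add_chain(wchain)
    structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))
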