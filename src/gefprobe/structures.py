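"""Structure and ensemble data model, PDB I/O, and atom selection.

The atomic containers here are deliberately small: an :class:`Atom` carries
the PDB fields the downstream analyses need (coordinates, naming, numbering,
element), a :class:`Structure` is an ordered atom list, and an
:class:`Ensemble` is a topology plus a stack of coordinate frames sharing it.
Residue numbers are always the author numbering of the input file; no
renumbering is ever performed, so region definitions like "residues 62-78"
are interpreted file-locally.

Multi-model PDB reading/writing is implemented here directly (fixed-column
ATOM/HETATM records, MODEL/ENDMDL blocks) rather than delegated, so that
plain-text ensembles round-trip exactly at the format's 0.001 A precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: van der Waals radii in Angstrom. Unknown elements fall back to carbon's
#: 1.70 A with a logged warning; the table is overridable at call sites that
#: take a ``radii`` argument.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
}

FALLBACK_VDW_RADIUS = 1.70


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


class TopologyMismatchError(ValueError):
    """Raised when models/frames disagree in atom count or order."""


@dataclass(frozen=True)
class Atom:
    """One atom record.

    Attributes
    ----------
    serial : int
        PDB serial number.
    name : str
        Atom name, stripped (e.g. ``"CA"``).
    element : str
        Element symbol, upper-case; resolved from columns 77-78 or, failing
        that, guessed from the atom name.
    residue_name : str
        Three-letter residue code.
    chain_id : str
        Single-character chain identifier.
    residue_number : int
        Author residue number.
    coords : numpy.ndarray
        Cartesian coordinates, shape (3,), Angstrom.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    coords: np.ndarray

    def vdw_radius(self, radii: dict[str, float] | None = None) -> float:
        table = VDW_RADII if radii is None else radii
        r = table.get(self.element.upper())
        if r is None:
            logger.warning(
                "unknown element %r for atom %s/%s%d; using fallback vdW radius %.2f A",
                self.element, self.name, self.chain_id, self.residue_number,
                FALLBACK_VDW_RADIUS,
            )
            return FALLBACK_VDW_RADIUS
        return r


@dataclass
class Structure:
    """An ordered collection of atoms with a free-text label."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        keys = [(a.chain_id, a.residue_number, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple] = set()
            for k in keys:
                if k in seen:
                    raise PDBFormatError(
                        f"duplicate atom (chain, resnum, name) = {k} in structure"
                    )
                seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise TopologyMismatchError(
                f"coordinate array {coords.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, label=self.label if label is None else label)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_number) keys, first-occurrence order."""
        seen: set[tuple[str, int]] = set()
        out: list[tuple[str, int]] = []
        for a in self.atoms:
            k = (a.chain_id, a.residue_number)
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out


@dataclass
class Ensemble:
    """A stack of conformations sharing one topology.

    ``topology`` supplies atom metadata (frame 0's); ``frames`` is a list of
    (n_atoms, 3) arrays in Angstrom; ``species_label`` tags the molecular
    species (e.g. "WT", "pSer", "pThr", "pSer/pThr").
    """

    topology: Structure
    frames: list[np.ndarray]
    species_label: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise TopologyMismatchError("an ensemble needs at least one frame")
        n = len(self.topology)
        clean = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise TopologyMismatchError(
                    f"frame {i} has shape {f.shape}, topology has {n} atoms"
                )
            clean.append(f)
        self.frames = clean

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selection by chain, inclusive residue range and atom names.

    ``residue_range`` uses author numbering; ``atom_names=("CA",)`` restricts
    to alpha carbons. Any field left ``None`` matches everything.
    """

    chain_id: str | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise ValueError(f"residue_range start {lo} > end {hi}")

    @classmethod
    def parse(cls, text: str, atom_names: tuple[str, ...] | None = None) -> "SelectionSpec":
        """Parse ``"A:62-78"`` / ``"A"`` / ``"62-78"`` shorthand."""
        chain: str | None = None
        rng: tuple[int, int] | None = None
        body = text.strip()
        if ":" in body:
            chain_part, body = body.split(":", 1)
            chain = chain_part or None
        elif body and not body[0].isdigit():
            chain, body = body, ""
        if body:
            lo_s, sep, hi_s = body.partition("-")
            rng = (int(lo_s), int(hi_s)) if sep else (int(body), int(body))
        return cls(chain_id=chain, residue_range=rng, atom_names=atom_names)


CA_ONLY = ("CA",)


def select_atoms(s: Structure, spec: SelectionSpec) -> list[int]:
    """Indices of atoms matching ``spec``, in structure order. May be empty."""
    out: list[int] = []
    names = None if spec.atom_names is None else {n.upper() for n in spec.atom_names}
    for i, a in enumerate(s.atoms):
        if spec.chain_id is not None and a.chain_id != spec.chain_id:
            continue
        if spec.residue_range is not None:
            lo, hi = spec.residue_range
            if not (lo <= a.residue_number <= hi):
                continue
        if names is not None and a.name.upper() not in names:
            continue
        out.append(i)
    if not out:
        logger.info("selection %r matched no atoms in %r", spec, s.label)
    return out


# ---------------------------------------------------------------------------
# PDB parsing

def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    # Two-character elements in protein PDB files start in column 13; for the
    # common case strip leading digits and take the first letter.
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in VDW_RADII and stripped[:2].isalpha():
        # e.g. FE, ZN, MG, CL
        if stripped[:2].upper() not in {"CA", "CB", "CG", "CD", "CE", "CZ", "CH",
                                        "ND", "NE", "NH", "NZ", "OD", "OE", "OG",
                                        "OH", "SD", "SG", "HA", "HB", "HG", "HD"}:
            return stripped[:2].upper()
    return stripped[0].upper() if stripped else "C"


def _parse_atom_line(line: str, keep_altlocs: set[tuple] | None = None) -> Atom | None:
    altloc = line[16] if len(line) > 16 else " "
    icode = line[26] if len(line) > 26 else " "
    if icode not in (" ", ""):
        raise PDBFormatError(
            f"insertion codes are not supported (found {icode!r}): {line.rstrip()!r}"
        )
    name = line[12:16].strip()
    resname = line[17:20].strip()
    chain = line[21] if len(line) > 21 else " "
    resnum = int(line[22:26])
    if altloc not in (" ", ""):
        key = (chain, resnum, name)
        if keep_altlocs is not None:
            if key in keep_altlocs:
                return None  # keep first altloc only
            keep_altlocs.add(key)
    x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
    coords = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise PDBFormatError(f"non-finite coordinates: {line.rstrip()!r}")
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    return Atom(
        serial=int(line[6:11]),
        name=name,
        element=element,
        residue_name=resname,
        chain_id=chain,
        residue_number=resnum,
        coords=coords,
    )


def _parse_models(path: str | Path) -> list[list[Atom]]:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:
        raise IOError(f"cannot read PDB file {path}: {e}") from e
    models: list[list[Atom]] = []
    current: list[Atom] = []
    altlocs: set[tuple] = set()
    in_model = False
    for line in text.splitlines():
        rec = line[:6]
        if rec.startswith("MODEL"):
            if current:
                models.append(current)
            current = []
            altlocs = set()
            in_model = True
        elif rec.startswith("ENDMDL"):
            models.append(current)
            current = []
            altlocs = set()
            in_model = False
        elif rec.startswith(("ATOM  ", "HETATM")):
            atom = _parse_atom_line(line, altlocs)
            if atom is not None:
                current.append(atom)
    if current:
        models.append(current)
    if not models or all(len(m) == 0 for m in models):
        raise PDBFormatError(f"no ATOM/HETATM records found in {path}")
    return [m for m in models if m]


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Read one model of a PDB file.

    ``model_index`` selects among MODEL blocks (0-based, default first).
    """
    models = _parse_models(path)
    if not (0 <= model_index < len(models)):
        raise IndexError(
            f"model_index {model_index} out of range for {len(models)} model(s) in {path}"
        )
    return Structure(atoms=models[model_index], label=str(Path(path).stem))


def read_ensemble(paths: str | Path | Sequence[str | Path],
                  species_label: str = "") -> Ensemble:
    """Read a multi-model PDB file (or several) as an ensemble.

    One frame per model; files are concatenated in argument order. All models
    must share atom count and order.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    topology: Structure | None = None
    frames: list[np.ndarray] = []
    ref_names: list[tuple] | None = None
    for p in paths:
        for model in _parse_models(p):
            names = [(a.chain_id, a.residue_number, a.name) for a in model]
            if topology is None:
                topology = Structure(atoms=model, label=str(Path(p).stem))
                ref_names = names
            elif names != ref_names:
                raise TopologyMismatchError(
                    f"model in {p} has {len(model)} atoms / different order than "
                    f"topology ({len(topology)} atoms)"
                )
            frames.append(np.array([a.coords for a in model], dtype=float))
    assert topology is not None
    return Ensemble(topology=topology, frames=frames,
                    species_label=species_label or topology.label)


def _format_atom_line(a: Atom) -> str:
    name = a.name
    # PDB alignment: 1-3 char names start in column 14 unless 4 chars
    if len(name) < 4 and not name[:1].isdigit():
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"ATOM  {a.serial:5d} {name_field} {a.residue_name:<3s} {a.chain_id}"
        f"{a.residue_number:4d}    "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
    )


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a single-model PDB file."""
    with open(path, "w") as fh:
        for a in s.atoms:
            fh.write(_format_atom_line(a))
        fh.write("END\n")


def write_ensemble(e: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file."""
    with open(path, "w") as fh:
        for i, frame in enumerate(e.frames):
            fh.write(f"MODEL     {i + 1:4d}\n")
            for a, xyz in zip(e.topology.atoms, frame):
                fh.write(_format_atom_line(replace(a, coords=xyz)))
            fh.write("ENDMDL\n")
        fh.write("END\n")
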