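"""Structures, trajectories, selections and section extraction.

The in-memory containers are deliberately thin: a :class:`Structure` is a
set of parallel numpy arrays (one entry per atom) plus coordinates, and a
:class:`Trajectory` is a topology plus a ``(n_frames, n_atoms, 3)`` coordinate
array in Å.  Multi-model PDB is the native on-disk format (parsed and written
through biotite); every interface uses PDB residue numbers (1-based).
Internal 0-based indices are never exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile


class PDBParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a named selection is empty where atoms are required."""


# Standard atomic masses (amu).  Unknown elements are a hard error rather
# than silently mass-1: centre-of-mass descriptors depend on them.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "NA": 22.990, "MG": 24.305, "CL": 35.45,
    "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845, "ZN": 65.38,
    "BR": 79.904, "I": 126.904, "F": 18.998,
}

# Deoxyribose / abasic-sugar atoms.  O1' is the hemiacetal hydroxyl retained
# on a deoxyribo-type abasic (AP) site and counts as sugar, not base.
SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "C5'",
                         "O4'", "O3'", "O5'", "O2'", "O1'"})
PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3"})

# Residue-name dialects for the two abasic-site chemistries.  PDB and
# force-field conventions differ; both map onto a canonical name.
AP_ALIASES = frozenset({"AP", "AB", "3DR"})
THF_ALIASES = frozenset({"THF", "F", "ORP"})


def canonical_lesion_name(res_name: str) -> str | None:
    """Canonical lesion name ("AP"/"THF") for a residue name, else None."""
    if res_name in AP_ALIASES:
        return "AP"
    if res_name in THF_ALIASES:
        return "THF"
    return None


def mass_of(element: str, *, context: str = "") -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise PDBParseError(
            f"unknown element {element!r} with no mass{context}"
        ) from None


@dataclass
class AtomRecord:
    """A single atom; a row view onto :class:`Structure`."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    mass: float
    occupancy: float
    bfactor: float
    coord: np.ndarray


@dataclass
class Structure:
    """An ordered set of atoms with coordinates in Å."""

    serial: np.ndarray
    name: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    res_id: np.ndarray
    element: np.ndarray
    mass: np.ndarray
    coords: np.ndarray
    occupancy: np.ndarray = None
    bfactor: np.ndarray = None

    def __post_init__(self) -> None:
        n = len(self.name)
        if self.occupancy is None:
            self.occupancy = np.ones(n)
        if self.bfactor is None:
            self.bfactor = np.zeros(n)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            int(self.serial[i]), str(self.name[i]), str(self.res_name[i]),
            str(self.chain_id[i]), int(self.res_id[i]), str(self.element[i]),
            float(self.mass[i]), float(self.occupancy[i]),
            float(self.bfactor[i]), self.coords[i],
        )

    @property
    def chains(self) -> dict[str, list[int]]:
        """Mapping chain id -> ordered residue numbers (file order)."""
        out: dict[str, list[int]] = {}
        for c, r in zip(self.chain_id, self.res_id):
            lst = out.setdefault(str(c), [])
            if not lst or lst[-1] != int(r):
                lst.append(int(r))
        return out

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            self.serial[idx], self.name[idx], self.res_name[idx],
            self.chain_id[idx], self.res_id[idx], self.element[idx],
            self.mass[idx], self.coords[idx],
            self.occupancy[idx], self.bfactor[idx],
        )

    def copy(self) -> "Structure":
        return Structure(
            self.serial.copy(), self.name.copy(), self.res_name.copy(),
            self.chain_id.copy(), self.res_id.copy(), self.element.copy(),
            self.mass.copy(), self.coords.copy(),
            self.occupancy.copy(), self.bfactor.copy(),
        )

    def residue_atom_indices(self, chain: str, residue_number: int) -> np.ndarray:
        return np.flatnonzero(
            (self.chain_id == chain) & (self.res_id == residue_number)
        )


@dataclass
class Trajectory:
    """A topology plus per-frame coordinate sets (Å)."""

    topology: Structure
    frames: np.ndarray
    frame_stride_ps: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.n_frames < 1:
            raise ValueError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def subset(self, indices: np.ndarray) -> "Trajectory":
        idx = np.asarray(indices, dtype=int)
        return Trajectory(self.topology.subset(idx), self.frames[:, idx],
                          self.frame_stride_ps)

    def frame_structure(self, i: int) -> Structure:
        s = self.topology.copy()
        s.coords = self.frames[i].copy()
        return s


@dataclass(frozen=True)
class StrandRange:
    """A contiguous run of residues on one strand."""

    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("strand range end before start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def trimmed(self, trim: int) -> "StrandRange":
        return StrandRange(self.chain, self.start + trim, self.end - trim)


@dataclass(frozen=True)
class SiteSpec:
    """A damaged site and the duplex section that embeds it.

    ``lesion`` and ``facing`` are (chain, residue_number) pairs on opposite
    strands; ``orphan``/``orphan_partner`` describe the unpaired base left by
    an ejected lesion and its would-be Watson–Crick partner.  ``section`` is
    the pair of strand ranges (same length) delimiting the analysis window,
    typically 15 bp trimmed to 13 bp before analysis.
    """

    lesion: tuple[str, int]
    facing: tuple[str, int]
    section: tuple[StrandRange, StrandRange]
    orphan: tuple[str, int] | None = None
    orphan_partner: tuple[str, int] | None = None
    label: str = "site"
    replicate: str = "MD1"

    def __post_init__(self) -> None:
        a, b = self.section
        if a.length != b.length:
            raise ValueError("section strand ranges must have equal length")
        if self.lesion[0] == self.facing[0]:
            raise ValueError("lesion and facing must lie on opposite strands")

    @property
    def n_bp(self) -> int:
        return self.section[0].length


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    # PDB convention: for standard biomolecular atoms the element is the
    # first alphabetic character of the stripped name (C1', NZ, OP1, ...).
    stripped = atom_name.strip().lstrip("0123456789")
    head = "".join(ch for ch in stripped if ch.isalpha())
    return head[:1].upper()


def _structure_from_atom_array(arr: bst.AtomArray, path: str) -> Structure:
    n = arr.array_length()
    elements = np.array([e.strip() for e in arr.element], dtype=object)
    names = np.array([a.strip() for a in arr.atom_name], dtype=object)
    for i in range(n):
        if not elements[i]:
            elements[i] = _infer_element(names[i])
    masses = np.array([
        mass_of(elements[i], context=f" for atom {names[i]} "
                f"(serial {int(arr.atom_id[i]) if 'atom_id' in arr.get_annotation_categories() else i + 1}) in {path}")
        for i in range(n)
    ])
    serial = (arr.atom_id.astype(int)
              if "atom_id" in arr.get_annotation_categories()
              else np.arange(1, n + 1))
    occ = (arr.occupancy.astype(float)
           if "occupancy" in arr.get_annotation_categories() else np.ones(n))
    bf = (arr.b_factor.astype(float)
          if "b_factor" in arr.get_annotation_categories() else np.zeros(n))
    return Structure(
        serial, names, np.array(list(arr.res_name), dtype=object),
        np.array(list(arr.chain_id), dtype=object), arr.res_id.astype(int),
        elements, masses, np.asarray(arr.coord, dtype=float), occ, bf,
    )


def _atom_array_from_structure(struct: Structure) -> bst.AtomArray:
    n = struct.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(struct.coords, dtype=np.float32)
    arr.chain_id = struct.chain_id.astype("U4")
    arr.res_id = struct.res_id.astype(int)
    arr.res_name = struct.res_name.astype("U5")
    arr.atom_name = struct.name.astype("U6")
    arr.element = struct.element.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("atom_id", struct.serial.astype(int))
    arr.set_annotation("occupancy", struct.occupancy.astype(float))
    arr.set_annotation("b_factor", struct.bfactor.astype(float))
    return arr


def read_structure(path: str | Path) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`."""
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises several error types
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if n_models == 0:
        raise PDBParseError(f"no atom records found in {path}")
    try:
        arr = pdb.get_structure(
            model=1, extra_fields=["atom_id", "occupancy", "b_factor"]
        )
    except Exception as exc:
        raise PDBParseError(f"cannot parse coordinates in {path}: {exc}") from exc
    return _structure_from_atom_array(arr, str(path))


def read_trajectory(path: str | Path, topology: Structure | None = None,
                    frame_stride_ps: float | None = None) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Every model must have the same atom count as ``topology`` (the first
    model, when no topology is given); a mismatch is reported with the
    offending 0-based frame index.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if n_models == 0:
        raise PDBParseError(f"no atom records found in {path}")
    frames = []
    topo = topology
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(
            model=m, extra_fields=["atom_id", "occupancy", "b_factor"]
        )
        if topo is None:
            topo = _structure_from_atom_array(arr, str(path))
        if arr.array_length() != topo.n_atoms:
            raise PDBParseError(
                f"atom count mismatch in {path} at frame index {m - 1}: "
                f"{arr.array_length()} atoms vs topology {topo.n_atoms}"
            )
        frames.append(np.asarray(arr.coord, dtype=float))
    return Trajectory(topo, np.stack(frames), frame_stride_ps)


def write_structure(struct: Structure, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_structure(struct))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    n = traj.topology.n_atoms
    stack = bst.AtomArrayStack(traj.n_frames, n)
    template = _atom_array_from_structure(traj.topology)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj.frames.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select_atoms(
    structure: Structure,
    *,
    chain: str | Sequence[str] | None = None,
    residue_number: int | Sequence[int] | None = None,
    residue_name: str | Sequence[str] | None = None,
    atom_name: str | Sequence[str] | None = None,
    heavy_only: bool = False,
    base_only: bool = False,
    required: str | None = None,
) -> np.ndarray:
    """Deterministic, order-stable atom index selection.

    ``base_only`` keeps nucleobase heavy atoms only: sugar atoms
    (C1'–C5', O2'–O5', and the abasic O1'), phosphate atoms (P, OP1, OP2,
    OP3) and all hydrogens are excluded.  If ``required`` names the
    selection, an empty result raises :class:`SelectionError`.
    """
    mask = np.ones(structure.n_atoms, dtype=bool)

    def _as_set(v):
        if isinstance(v, (str, int)):
            return {v}
        return set(v)

    if chain is not None:
        allowed = _as_set(chain)
        mask &= np.array([c in allowed for c in structure.chain_id])
    if residue_number is not None:
        allowed = _as_set(residue_number)
        mask &= np.array([int(r) in allowed for r in structure.res_id])
    if residue_name is not None:
        allowed = _as_set(residue_name)
        mask &= np.array([r in allowed for r in structure.res_name])
    if atom_name is not None:
        allowed = _as_set(atom_name)
        mask &= np.array([a in allowed for a in structure.name])
    if heavy_only or base_only:
        mask &= np.array([e.upper() not in ("H", "D")
                          for e in structure.element])
    if base_only:
        mask &= np.array([a not in SUGAR_ATOMS and a not in PHOSPHATE_ATOMS
                          for a in structure.name])
    idx = np.flatnonzero(mask)
    if required is not None and idx.size == 0:
        raise SelectionError(f"selection {required!r} matched no atoms")
    return idx


def extract_section(traj: Trajectory, spec: SiteSpec, trim: int = 0) -> Trajectory:
    """Restrict a trajectory to the duplex section of ``spec``.

    ``trim`` removes that many base pairs at *each* end of the section on
    both strands; the study convention analyses 15-bp sections trimmed to
    13 bp to avoid edge effects.  Atom ordering is preserved.
    Trimming composes: trim=a then trim=b equals trim=a+b.
    """
    if trim < 0:
        raise ValueError("trim must be non-negative")
    n_bp = spec.n_bp
    if 2 * trim >= n_bp:
        raise ValueError(
            f"trim={trim} removes the whole {n_bp}-bp section"
        )
    keep = np.zeros(traj.topology.n_atoms, dtype=bool)
    for rng in spec.section:
        t = rng.trimmed(trim)
        keep |= (
            (traj.topology.chain_id == t.chain)
            & (traj.topology.res_id >= t.start)
            & (traj.topology.res_id <= t.end)
        )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise SelectionError("section selection matched no atoms")
    return traj.subset(idx)


def trim_site_spec(spec: SiteSpec, trim: int) -> SiteSpec:
    """The SiteSpec describing the trimmed section (bounds shrunk by trim)."""
    a, b = spec.section
    return replace(spec, section=(a.trimmed(trim), b.trimmed(trim)))
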