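"""Structural I/O and the internal topology / ensemble model.

The package operates on three light containers:

* :class:`Topology` — per-atom metadata (name, element, residue, chain) with
  1-based author residue numbering, as found in PDB files.
* :class:`Ensemble` — a stack of coordinate frames (frames x atoms x 3, in
  Angstrom) tied to a topology, with per-frame times in nanoseconds.
* :class:`Selection` — an ordered list of 0-based atom indices plus the
  expression that produced it.

File reading and writing (PDB, DCD, XTC) is delegated to MDAnalysis; the
selection grammar is MDAnalysis's, so ``name CA and resid 59-76`` works the
way practitioners expect.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

__all__ = [
    "Topology",
    "Ensemble",
    "Selection",
    "TopologyParseError",
    "load_topology",
    "load_trajectory",
    "select",
    "write_trajectory",
    "write_pdb",
    "load_atom_parameters",
]


class TopologyParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


# minimal element table for name-based inference (PDB columns often lack
# element entries in toy/synthetic files)
_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "SE", "CU"}


def _infer_element(atom_name: str, resname: str = "") -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    # CA is calcium only when it is an ion residue, otherwise an alpha carbon
    if two in _TWO_LETTER and not (two == "CA" and resname.upper() not in ("CA", "CAL")):
        return stripped[0].upper() + stripped[1].lower()
    return stripped[0].upper()


@dataclass
class Topology:
    """Per-atom structural metadata with 1-based author residue numbers."""

    names: np.ndarray          # str, atom names
    elements: np.ndarray       # str
    resnames: np.ndarray       # str
    resids: np.ndarray         # int, 1-based author numbering
    chainids: np.ndarray       # str
    source: str = ""
    groups: dict = field(default_factory=dict)  # named Selections
    _universe: "mda.Universe | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.names)
        for arr_name in ("elements", "resnames", "resids", "chainids"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"topology field {arr_name!r} length mismatch")
        if any(str(x).strip() == "" for x in self.names):
            raise TopologyParseError("topology contains an atom with an empty name")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_label(self, atom_index: int) -> str:
        return f"{self.resnames[atom_index]}{self.resids[atom_index]}"

    def build_universe(self) -> "mda.Universe":
        """Construct a fresh MDAnalysis universe carrying this topology."""
        resid_chain = list(dict.fromkeys(
            zip(self.resids.tolist(), self.chainids.tolist())))
        res_index_of = {rc: i for i, rc in enumerate(resid_chain)}
        atom_resindex = np.array(
            [res_index_of[(int(r), c)] for r, c in zip(self.resids, self.chainids)]
        )
        u = mda.Universe.empty(
            self.n_atoms,
            n_residues=len(resid_chain),
            atom_resindex=atom_resindex,
            residue_segindex=np.zeros(len(resid_chain), dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(x) for x in self.names])
        u.add_TopologyAttr("elements", [str(x) for x in self.elements])
        u.add_TopologyAttr("chainIDs", [str(x) for x in self.chainids])
        u.add_TopologyAttr("resids", [rc[0] for rc in resid_chain])
        first_atom = {}
        for i, rc in enumerate(zip(self.resids.tolist(), self.chainids.tolist())):
            first_atom.setdefault(rc, i)
        u.add_TopologyAttr(
            "resnames", [str(self.resnames[first_atom[rc]]) for rc in resid_chain])
        return u

    def selection_universe(self) -> "mda.Universe":
        """A cached MDAnalysis universe used to evaluate selections."""
        if self._universe is None:
            self._universe = self.build_universe()
        return self._universe


@dataclass
class Ensemble:
    """Coordinate frames (Angstrom) plus frame times (ns) for one system."""

    coordinates: np.ndarray    # (n_frames, n_atoms, 3), float64, Angstrom
    frame_times: np.ndarray    # (n_frames,), ns, strictly increasing
    topology: Topology
    system_label: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"ensemble has {self.coordinates.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}")
        if len(self.frame_times) != self.coordinates.shape[0]:
            raise ValueError("frame_times length must equal number of frames")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def subset(self, selection: "Selection") -> np.ndarray:
        """Coordinates of the selected atoms, shape (frames, k, 3)."""
        return self.coordinates[:, selection.indices, :]

    def copy(self) -> "Ensemble":
        return Ensemble(self.coordinates.copy(), self.frame_times.copy(),
                        self.topology, self.system_label)


@dataclass(frozen=True)
class Selection:
    """An ordered, duplicate-free list of 0-based atom indices."""

    indices: tuple
    expression: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def union(self, other: "Selection") -> "Selection":
        seen = dict.fromkeys(self.indices)
        seen.update(dict.fromkeys(other.indices))
        return Selection(tuple(seen), f"({self.expression}) or ({other.expression})")

    def intersection(self, other: "Selection") -> "Selection":
        other_set = set(other.indices)
        return Selection(tuple(i for i in self.indices if i in other_set),
                         f"({self.expression}) and ({other.expression})")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _validate_pdb_records(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise TopologyParseError(
                        f"{path}: line {lineno}: record too short for coordinates")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    raise TopologyParseError(
                        f"{path}: line {lineno}: unparsable coordinate fields") from None


def load_topology(path: str | Path) -> Topology:
    """Read ATOM/HETATM records of MODEL 1 of a PDB file into a :class:`Topology`.

    Residue numbers are taken from the author field unchanged.  For atoms with
    alternate locations only the highest-occupancy altloc is kept.  Multi-model
    files trigger a warning and only the first model is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_records(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        if hasattr(u, "trajectory") and len(u.trajectory) > 1:
            warnings.simplefilter("default")
            warnings.warn(f"{path.name}: multi-model PDB; only MODEL 1 is used")
    atoms = u.atoms
    names = np.array([a.name for a in atoms], dtype=object)
    resnames = np.array([a.resname for a in atoms], dtype=object)
    resids = np.array([a.resid for a in atoms], dtype=int)
    try:
        chainids = np.array([a.chainID for a in atoms], dtype=object)
    except (AttributeError, mda.exceptions.NoDataError):
        chainids = np.array(["A"] * len(atoms), dtype=object)
    try:
        elements = np.array(
            [str(a.element) if str(a.element).strip() else
             _infer_element(a.name, a.resname) for a in atoms], dtype=object)
    except (AttributeError, mda.exceptions.NoDataError):
        elements = np.array(
            [_infer_element(n, r) for n, r in zip(names, resnames)], dtype=object)

    # altloc filter: for duplicated (chain, resid, name) keep highest occupancy
    keep = np.ones(len(atoms), dtype=bool)
    try:
        altlocs = np.array([a.altLoc for a in atoms], dtype=object)
        occupancies = np.array([a.occupancy for a in atoms], dtype=float)
    except (AttributeError, mda.exceptions.NoDataError):
        altlocs = np.array([""] * len(atoms), dtype=object)
        occupancies = np.ones(len(atoms))
    if any(str(a).strip() for a in altlocs):
        groups: dict = {}
        for i in range(len(atoms)):
            groups.setdefault((chainids[i], resids[i], names[i]), []).append(i)
        for members in groups.values():
            if len(members) > 1:
                best = max(members, key=lambda i: occupancies[i])
                for i in members:
                    keep[i] = i == best

    return Topology(names[keep], elements[keep], resnames[keep], resids[keep],
                    chainids[keep], source=str(path))


def load_trajectory(topology: Topology, paths: Sequence[str | Path],
                    frame_time_step: float) -> Ensemble:
    """Concatenate DCD/XTC files (in the given order) into an :class:`Ensemble`.

    ``frame_time_step`` is the saving interval in nanoseconds; it must be
    supplied by the user because trajectory files do not carry reliable time
    metadata.
    """
    if frame_time_step <= 0:
        raise ValueError("frame_time_step must be positive (ns)")
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no trajectory files given")
    chunks = []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if topology.source:
                u = mda.Universe(topology.source, str(p))
            else:
                u = mda.Universe.empty(topology.n_atoms, trajectory=True)
                u.load_new(str(p))
        if u.atoms.n_atoms != topology.n_atoms:
            raise ValueError(
                f"{p.name}: trajectory has {u.atoms.n_atoms} atoms, topology has "
                f"{topology.n_atoms}")
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
        if coords.shape[0] == 0:
            raise ValueError(f"{p.name}: trajectory contains zero frames")
        chunks.append(coords)
    coordinates = np.concatenate(chunks, axis=0)
    n = coordinates.shape[0]
    frame_times = frame_time_step * np.arange(1, n + 1)
    return Ensemble(coordinates, frame_times, topology)


_RANGE_DASH = None


def _normalize_expression(expression: str) -> str:
    # allow "resid 59-76" alongside MDAnalysis's "resid 59:76"
    import re
    return re.sub(r"(?<=\d)\s*-\s*(?=\d)", ":", expression)


def select(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression against a topology.

    The grammar is MDAnalysis's selection language (``name``, ``resid``
    ranges, ``resname``, ``chainID``, ``element`` and boolean and/or/not);
    dash ranges such as ``resid 59-76`` are accepted.  An empty result is
    allowed but triggers a warning.
    """
    u = topology.selection_universe()
    try:
        group = u.select_atoms(_normalize_expression(expression))
    except Exception as exc:  # MDAnalysis raises SelectionError subclasses
        raise ValueError(f"selection syntax error in {expression!r}: {exc}") from exc
    indices = tuple(int(i) for i in group.ix)
    if not indices:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return Selection(indices, expression)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _memory_universe(ensemble: Ensemble) -> "mda.Universe":
    u = ensemble.topology.build_universe()
    u.load_new(ensemble.coordinates.astype(np.float64), format=MemoryReader)
    return u


def write_trajectory(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble's coordinates as DCD or XTC (by file extension)."""
    u = _memory_universe(ensemble)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=ensemble.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_pdb(ensemble: Ensemble, frame: int, path: str | Path) -> None:
    """Write a single frame as a PDB snapshot."""
    u = _memory_universe(ensemble)
    u.trajectory[frame]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def load_atom_parameters(path: str | Path) -> pd.DataFrame:
    """Read a delimited per-atom parameter table.

    Expected columns: ``atom_index`` (0-based), ``charge`` (e), ``sigma``
    (Angstrom) and ``epsilon`` (kcal/mol).  Both comma- and
    whitespace-delimited files are accepted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
        if df.shape[1] == 1:
            raise ValueError
    except ValueError:
        df = pd.read_csv(path, sep=r"\s+")
    required = {"atom_index", "charge", "sigma", "epsilon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    if (df["epsilon"] < 0).any() or (df["sigma"] <= 0).any():
        raise ValueError("parameter table violates epsilon >= 0 / sigma > 0")
    return df.set_index("atom_index")
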