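"""Structures, trajectories and atom selections.

Coordinates are in Å throughout. Residue numbering is the author numbering
taken verbatim from the file and never renumbered, because published residue
identities (e.g. Glu37, Asp64 of the BZR basic region, Glu304 of the MBP
chaperone) refer to author numbers.

PDB reading and writing is delegated to :mod:`gemmi`; this module keeps a
deliberately small in-memory representation (a flat list of
:class:`AtomRecord`) that the geometry and interaction analyses operate on.
Multi-model PDB files double as the trajectory exchange format; a
whitespace-delimited per-frame XYZ table is supported for synthetic fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Trajectory",
    "Selection",
    "SelectionError",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "select",
    "extract_assembly",
    "strip_waters",
    "read_frame_table",
    "write_frame_table",
]

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
NUCLEOTIDES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U", "DI"}


class PDBFormatError(ValueError):
    """Raised for unreadable or malformed structure files."""


class SelectionError(ValueError):
    """Raised for selection expressions referencing unsupported fields."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model: identity, position and displacement parameter."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: np.ndarray  # shape (3,), Å
    b_factor: float = 0.0
    element: str = ""
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coordinates, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(
                f"atom {self.chain_id}/{self.residue_number}/{self.name}: "
                "coordinates must be a finite 3-vector"
            )
        object.__setattr__(self, "coordinates", xyz)

    @property
    def residue_label(self) -> str:
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}"

    @property
    def atom_id(self) -> tuple[str, int, str]:
        """(chain, residue number, atom name) — unique within a model."""
        return (self.chain_id, self.residue_number, self.name)


@dataclass
class StructureModel:
    """An ordered list of atoms: one crystal model or one trajectory frame."""

    atoms: list[AtomRecord]
    model_id: int = 1
    source_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.coordinates for a in self.atoms])

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def with_coordinates(self, coords: np.ndarray, model_id: int | None = None) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, coordinates=c) for a, c in zip(self.atoms, coords)]
        return StructureModel(
            atoms=atoms,
            model_id=self.model_id if model_id is None else model_id,
            source_id=self.source_id,
            metadata=dict(self.metadata),
        )

    def atom_index(self, chain_id: str, residue_number: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.residue_number == residue_number and a.name == name:
                return i
        raise KeyError(f"no atom {chain_id}/{residue_number}/{name} in model")


@dataclass
class Trajectory:
    """Frames sharing one atom topology, with a frame interval in ps."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 10.0  # ps, mirroring typical MD snapshot spacing
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"every frame must have {len(self.topology)} atom coordinates, "
                f"got {self.frames.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_model(self, i: int) -> StructureModel:
        return self.topology.with_coordinates(self.frames[i], model_id=i + 1)

    def __iter__(self):
        return (self.frames[i] for i in range(self.n_frames))


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the expression plus ordered atom indices."""

    expression: str
    resolved_indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.resolved_indices)

    def coordinates(self, model_or_frame) -> np.ndarray:
        if isinstance(model_or_frame, StructureModel):
            coords = model_or_frame.coordinates
        else:
            coords = np.asarray(model_or_frame, dtype=float)
        return coords[list(self.resolved_indices)]

    def atoms(self, model: StructureModel) -> list[AtomRecord]:
        return [model.atoms[i] for i in self.resolved_indices]


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> altloc 'A'.

    Crystal structures frequently contain alternate conformations; downstream
    geometry needs a single deterministic conformer per atom.
    """
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        if atom.occ > prev.occ:
            by_name[atom.name] = atom
        elif atom.occ == prev.occ:
            # tie: prefer blank altloc, then 'A', then lexical order
            def rank(a: gemmi.Atom) -> tuple:
                alt = a.altloc if a.altloc else "A"
                return (0 if alt == "A" else 1, alt)
            if rank(atom) < rank(prev):
                by_name[atom.name] = atom
    # preserve original atom order
    kept = set(id(a) for a in by_name.values())
    return [a for a in residue if id(a) in kept]


def read_pdb(path: str | Path, keep_waters: bool = True) -> list[StructureModel]:
    """Read a PDB file into one :class:`StructureModel` per MODEL record.

    HETATM records (including waters, needed for water-mediated hydrogen-bond
    analysis) are retained unless ``keep_waters`` is False, in which case
    water residues are stripped. Alternate locations are resolved to the
    highest-occupancy conformer (ties to altloc "A").
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise PDBFormatError(f"{path}: empty file")
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models found")
    _validate_coordinate_fields(path)
    models: list[StructureModel] = []
    for mi, gmodel in enumerate(st, start=1):
        atoms: list[AtomRecord] = []
        serial = 0
        for chain in gmodel:
            for residue in chain:
                if not keep_waters and residue.name in WATER_NAMES:
                    continue
                is_het = residue.het_flag == "H"
                for atom in _resolve_altlocs(residue):
                    serial += 1
                    atoms.append(
                        AtomRecord(
                            serial=serial,
                            name=atom.name,
                            residue_name=residue.name,
                            chain_id=chain.name,
                            residue_number=residue.seqid.num,
                            coordinates=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                            b_factor=atom.b_iso,
                            element=atom.element.name.upper(),
                            is_hetatm=is_het,
                        )
                    )
        if not atoms:
            raise PDBFormatError(f"{path}: model {mi} contains no atoms")
        models.append(StructureModel(atoms=atoms, model_id=mi, source_id=path.stem))
    return models


_COORD_RE = re.compile(r"^(ATOM|HETATM)")


def _validate_coordinate_fields(path: Path) -> None:
    """Fail with a line number on malformed fixed-width coordinate fields.

    gemmi is lenient about some malformed records; published analyses should
    not silently ingest them.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not _COORD_RE.match(line):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(
                    f"{path}:{lineno}: truncated coordinate record"
                )
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise PDBFormatError(
                        f"{path}:{lineno}: malformed coordinate field {fld!r}"
                    ) from None


def write_pdb(models: Sequence[StructureModel] | StructureModel, path: str | Path) -> None:
    """Write models as a (multi-model) fixed-width PDB file via gemmi.

    More than one model produces MODEL/ENDMDL wrapping. Coordinates with
    magnitude ≥ 10000 Å cannot be represented in the %8.3f field and raise.
    """
    if isinstance(models, StructureModel):
        models = [models]
    if len(models) == 0:
        raise ValueError("empty model list")
    for m in models:
        if np.any(np.abs(m.coordinates) >= 10000.0):
            raise ValueError("coordinate magnitude >= 10000 Å not representable in PDB fields")
    st = gemmi.Structure()
    st.name = models[0].source_id or "bzrmd"
    for mi, model in enumerate(models, start=1):
        gmodel = gemmi.Model(mi)
        chain_map: dict[str, gemmi.Chain] = {}
        for a in model.atoms:
            chain = chain_map.get(a.chain_id)
            if chain is None:
                chain = gemmi.Chain(a.chain_id)
                chain_map[a.chain_id] = chain
                gmodel.add_chain(chain)
                chain = gmodel[-1]
                chain_map[a.chain_id] = chain
            if (len(chain) == 0
                    or chain[-1].seqid.num != a.residue_number
                    or chain[-1].name != a.residue_name):
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                res.het_flag = "H" if a.is_hetatm else "A"
                chain.add_residue(res)
            res = chain[-1]
            atom = gemmi.Atom()
            atom.name = a.name
            atom.pos = gemmi.Position(*a.coordinates)
            atom.b_iso = a.b_factor
            atom.occ = 1.0
            if a.element:
                atom.element = gemmi.Element(a.element)
            res.add_atom(atom)
        st.add_model(gmodel)
    st.setup_entities()
    doc_path = str(Path(path))
    st.write_pdb(doc_path)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_FIELD_KEYWORDS = {"chain", "name", "resname", "resid"}
_BARE_KEYWORDS = {"protein", "nucleic", "water", "all", "hetatm", "backbone"}


def _parse_resid_spec(spec: str) -> Callable[[int], bool]:
    ranges: list[tuple[int, int]] = []
    for p in spec.split(","):
        m = re.fullmatch(r"(-?\d+)-(-?\d+)", p)
        if m:
            ranges.append((int(m.group(1)), int(m.group(2))))
        elif re.fullmatch(r"-?\d+", p):
            n = int(p)
            ranges.append((n, n))
        else:
            raise SelectionError(f"bad resid specifier {p!r}")
    return lambda n: any(lo <= n <= hi for lo, hi in ranges)


def _atom_predicate(tokens: list[str], pos: int) -> tuple[Callable[[AtomRecord], bool], int]:
    tok = tokens[pos].lower()
    if tok == "(":
        pred, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise SelectionError("unbalanced parenthesis in selection")
        return pred, pos + 1
    if tok == "not":
        inner, pos = _atom_predicate(tokens, pos + 1)
        return (lambda a: not inner(a)), pos
    if tok in _BARE_KEYWORDS:
        if tok == "protein":
            return (lambda a: a.residue_name in AMINO_ACIDS), pos + 1
        if tok == "nucleic":
            return (lambda a: a.residue_name in NUCLEOTIDES), pos + 1
        if tok == "water":
            return (lambda a: a.residue_name in WATER_NAMES), pos + 1
        if tok == "hetatm":
            return (lambda a: a.is_hetatm), pos + 1
        if tok == "backbone":
            bb = {"N", "CA", "C", "O", "P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"}
            return (lambda a: a.name in bb), pos + 1
        return (lambda a: True), pos + 1
    if tok in _FIELD_KEYWORDS:
        if pos + 1 >= len(tokens):
            raise SelectionError(f"field {tok!r} needs a value")
        value = tokens[pos + 1]
        if tok == "chain":
            ids = set(value.split(","))
            return (lambda a: a.chain_id in ids), pos + 2
        if tok == "name":
            names = set(v.upper() for v in value.split(","))
            return (lambda a: a.name.upper() in names), pos + 2
        if tok == "resname":
            names = set(v.upper() for v in value.split(","))
            return (lambda a: a.residue_name.upper() in names), pos + 2
        if tok == "resid":
            in_range = _parse_resid_spec(value)
            return (lambda a: in_range(a.residue_number)), pos + 2
    raise SelectionError(
        f"unknown selection field {tokens[pos]!r}; supported: "
        f"{sorted(_FIELD_KEYWORDS | _BARE_KEYWORDS)}, and/or/not, parentheses"
    )


def _parse_and(tokens: list[str], pos: int):
    left, pos = _atom_predicate(tokens, pos)
    while pos < len(tokens) and tokens[pos].lower() == "and":
        right, pos = _atom_predicate(tokens, pos + 1)
        l, r = left, right
        left = lambda a, l=l, r=r: l(a) and r(a)
    return left, pos


def _parse_or(tokens: list[str], pos: int):
    left, pos = _parse_and(tokens, pos)
    while pos < len(tokens) and tokens[pos].lower() == "or":
        right, pos = _parse_and(tokens, pos + 1)
        l, r = left, right
        left = lambda a, l=l, r=r: l(a) or r(a)
    return left, pos


def compile_selection(expression: str) -> Callable[[AtomRecord], bool]:
    """Compile a selection expression to an atom predicate.

    Grammar: ``chain C``, ``name CA,P``, ``resname DA,DG``, ``resid 21-88``,
    bare keywords ``protein | nucleic | water | hetatm | backbone | all``,
    combined with ``and``, ``or``, ``not`` and parentheses.
    """
    tokens = _TOKEN_RE.findall(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    pred, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise SelectionError(f"trailing tokens in selection: {tokens[pos:]!r}")
    return pred


def select(model: StructureModel, expression: str) -> Selection:
    """Resolve ``expression`` against ``model`` in file order (deterministic)."""
    pred = compile_selection(expression)
    idx = tuple(i for i, a in enumerate(model.atoms) if pred(a))
    return Selection(expression=expression, resolved_indices=idx)


def extract_assembly(model: StructureModel, chain_ids: Iterable[str]) -> StructureModel:
    """New model containing exactly ``chain_ids``, original atom order kept."""
    wanted = set(chain_ids)
    present = set(model.chain_ids)
    missing = wanted - present
    if missing:
        raise KeyError(
            f"chains {sorted(missing)} not in model; available: {sorted(present)}"
        )
    atoms = [a for a in model.atoms if a.chain_id in wanted]
    return StructureModel(
        atoms=atoms,
        model_id=model.model_id,
        source_id=model.source_id,
        metadata=dict(model.metadata),
    )


def strip_waters(model: StructureModel) -> StructureModel:
    atoms = [a for a in model.atoms if a.residue_name not in WATER_NAMES]
    return StructureModel(atoms, model.model_id, model.source_id, dict(model.metadata))


# ---------------------------------------------------------------------------
# Plain-text XYZ frame table (synthetic-fixture exchange format)
# ---------------------------------------------------------------------------

def write_frame_table(traj: Trajectory, path: str | Path) -> None:
    """Write frames as ``natoms frame_interval_ps`` header + one row per atom per frame."""
    n_atoms = len(traj.topology)
    with open(path, "w") as fh:
        fh.write(f"{n_atoms} {traj.frame_interval:g}\n")
        for frame in traj.frames:
            for xyz in frame:
                fh.write(f"{xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f}\n")


def read_frame_table(path: str | Path, topology: StructureModel) -> Trajectory:
    """Read the whitespace frame table written by :func:`write_frame_table`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise PDBFormatError(f"{path}: frame-table header must be 'natoms interval'")
        n_atoms, interval = int(header[0]), float(header[1])
        if n_atoms != len(topology):
            raise ValueError(
                f"frame table atom count {n_atoms} != topology {len(topology)}"
            )
        data = np.loadtxt(fh, dtype=float)
    data = np.atleast_2d(data)
    if data.shape[0] % n_atoms != 0 or data.shape[1] != 3:
        raise PDBFormatError(f"{path}: row count not a multiple of natoms")
    frames = data.reshape(-1, n_atoms, 3)
    return Trajectory(topology=topology, frames=frames, frame_interval=interval)
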