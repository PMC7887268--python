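"""Contact detection and occupancy analysis.

Detects hydrogen bonds, salt bridges, van der Waals contacts and
water-mediated bridges between two atom groups of one model, computes
per-pair hydrogen-bond occupancy over a trajectory, and dissects
chaperone–cargo (crystal-packing) interfaces with a per-chain B-factor
summary.

Geometric criteria are declared conventions, chosen from standard practice:
donor–acceptor ≤ 3.5 Å (with a D–H···A angle test only when hydrogens are
present — crystal structures lack them), charged-group N···O ≤ 4.0 Å for
salt bridges, and fixed van der Waals radii with a 0.4 Å tolerance. All are
overridable at call sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import (
    AMINO_ACIDS,
    NUCLEOTIDES,
    WATER_NAMES,
    AtomRecord,
    Selection,
    StructureModel,
    Trajectory,
)

__all__ = [
    "HBondCriteria",
    "ContactEvent",
    "OccupancyTable",
    "find_hbonds",
    "find_salt_bridges",
    "find_vdw_contacts",
    "find_water_bridges",
    "hbond_occupancy",
    "interface_contacts",
    "InterfaceReport",
    "VDW_RADII",
]

# ---------------------------------------------------------------------------
# Donor / acceptor role tables (N/O heavy atoms; hydrogens optional)
# ---------------------------------------------------------------------------

_BACKBONE_DONOR = {"N"}  # amide N; Pro excluded below
_BACKBONE_ACCEPTOR = {"O", "OXT"}

_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "TRP": {"NE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

# deoxynucleotide base donors/acceptors plus backbone phosphate and sugar
_NUC_DONORS: dict[str, set[str]] = {
    "DA": {"N6"},
    "DC": {"N4"},
    "DG": {"N1", "N2"},
    "DT": {"N3"},
}
_NUC_ACCEPTORS: dict[str, set[str]] = {
    "DA": {"N1", "N3", "N7"},
    "DC": {"O2", "N3"},
    "DG": {"O6", "N7", "N3"},
    "DT": {"O2", "O4"},
}
_NUC_BACKBONE_ACCEPTORS = {"OP1", "OP2", "O1P", "O2P", "O3'", "O5'", "O4'"}

# charged-group atoms for salt bridges
_BASIC_ATOMS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_PHOSPHATE_OXYGENS = {"OP1", "OP2", "O1P", "O2P"}

VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}


def is_donor(atom: AtomRecord) -> bool:
    rn, an = atom.residue_name.upper(), atom.name.upper()
    if rn in WATER_NAMES:
        return an.startswith("O")
    if rn in AMINO_ACIDS:
        if an in _BACKBONE_DONOR and rn != "PRO":
            return True
        return an in _SIDECHAIN_DONORS.get(rn, ())
    if rn in NUCLEOTIDES:
        return an in _NUC_DONORS.get(rn, ())
    # unknown residue: fall back on element identity
    return atom.element in {"N"}


def is_acceptor(atom: AtomRecord) -> bool:
    rn, an = atom.residue_name.upper(), atom.name.upper()
    if rn in WATER_NAMES:
        return an.startswith("O")
    if rn in AMINO_ACIDS:
        return an in _BACKBONE_ACCEPTOR or an in _SIDECHAIN_ACCEPTORS.get(rn, ())
    if rn in NUCLEOTIDES:
        return an in _NUC_BACKBONE_ACCEPTORS or an in _NUC_ACCEPTORS.get(rn, ())
    return atom.element in {"O"}


def _is_basic_atom(atom: AtomRecord) -> bool:
    return atom.name.upper() in _BASIC_ATOMS.get(atom.residue_name.upper(), ())


def _is_acidic_atom(atom: AtomRecord) -> bool:
    rn, an = atom.residue_name.upper(), atom.name.upper()
    if an in _ACIDIC_ATOMS.get(rn, ()):
        return True
    return rn in NUCLEOTIDES and an in _PHOSPHATE_OXYGENS


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    The angle test applies only when explicit hydrogens exist on the donor;
    heavy-atom-only models are judged on the donor–acceptor distance alone.
    """

    max_donor_acceptor_distance: float = 3.5  # Å
    min_dha_angle: float = 120.0  # degrees

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 <= self.min_dha_angle <= 180.0:
            raise ValueError("DHA angle must lie in [0, 180] degrees")


@dataclass(frozen=True)
class ContactEvent:
    """One classified interatomic interaction."""

    kind: str  # hbond | salt_bridge | vdw | water_bridge
    atom_a: tuple[str, str, str]  # (chain, residue label e.g. "GLU304", atom name)
    atom_b: tuple[str, str, str]
    distance: float  # Å; for water bridges, the longer of the two legs
    bridging_water: tuple[str, str] | None = None  # (chain, residue label)

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if self.kind == "water_bridge" and self.bridging_water is None:
            raise ValueError("water_bridge events must record the bridging water")


def _atom_label(atom: AtomRecord) -> tuple[str, str, str]:
    return (atom.chain_id, f"{atom.residue_name}{atom.residue_number}", atom.name)


def _check_disjoint(model: StructureModel, group_a: Selection, group_b: Selection) -> None:
    overlap = set(group_a.resolved_indices) & set(group_b.resolved_indices)
    if overlap:
        raise ValueError(f"groups overlap on {len(overlap)} atoms; they must be disjoint")


def _cross_pairs(
    model: StructureModel, group_a: Selection, group_b: Selection, cutoff: float
) -> Iterable[tuple[int, int, float]]:
    """(index_a, index_b, distance) for cross-group pairs within cutoff."""
    ia = list(group_a.resolved_indices)
    ib = list(group_b.resolved_indices)
    if not ia or not ib:
        return []
    coords = model.coordinates
    tree_b = cKDTree(coords[ib])
    out: list[tuple[int, int, float]] = []
    for a_pos, a_idx in enumerate(ia):
        for b_pos in tree_b.query_ball_point(coords[a_idx], cutoff):
            b_idx = ib[b_pos]
            d = float(np.linalg.norm(coords[a_idx] - coords[b_idx]))
            out.append((a_idx, b_idx, d))
    return out


def _donor_hydrogens(model: StructureModel, donor_idx: int) -> list[int]:
    """Hydrogens covalently attached to the donor (within 1.25 Å, same residue)."""
    donor = model.atoms[donor_idx]
    out = []
    for i, a in enumerate(model.atoms):
        if a.element != "H":
            continue
        if a.chain_id != donor.chain_id or a.residue_number != donor.residue_number:
            continue
        if np.linalg.norm(a.coordinates - donor.coordinates) <= 1.25:
            out.append(i)
    return out


def _dha_satisfied(
    model: StructureModel, donor_idx: int, acceptor_idx: int, criteria: HBondCriteria
) -> bool:
    hydrogens = _donor_hydrogens(model, donor_idx)
    if not hydrogens:
        return True  # heavy-atom model: distance criterion only
    d = model.atoms[donor_idx].coordinates
    a = model.atoms[acceptor_idx].coordinates
    for h_idx in hydrogens:
        h = model.atoms[h_idx].coordinates
        v1 = d - h
        v2 = a - h
        cosine = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angle = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
        if angle >= criteria.min_dha_angle:
            return True
    return False


def find_hbonds(
    model: StructureModel,
    criteria: HBondCriteria | None = None,
    group_a: Selection | None = None,
    group_b: Selection | None = None,
) -> list[ContactEvent]:
    """Hydrogen bonds between two disjoint atom groups.

    Every cross-group (donor, acceptor) pair of N/O heavy atoms with standard
    donor/acceptor roles — amino acids, deoxynucleotides, water — satisfying
    the criteria is reported. The result is symmetric in group order.
    """
    criteria = criteria or HBondCriteria()
    _check_disjoint(model, group_a, group_b)
    events: list[ContactEvent] = []
    seen: set[frozenset[int]] = set()
    for ai, bi, dist in _cross_pairs(model, group_a, group_b, criteria.max_donor_acceptor_distance):
        a, b = model.atoms[ai], model.atoms[bi]
        pair_roles = (
            (is_donor(a) and is_acceptor(b) and _dha_satisfied(model, ai, bi, criteria))
            or (is_donor(b) and is_acceptor(a) and _dha_satisfied(model, bi, ai, criteria))
        )
        key = frozenset((ai, bi))
        if pair_roles and key not in seen:
            seen.add(key)
            events.append(ContactEvent("hbond", _atom_label(a), _atom_label(b), dist))
    events.sort(key=lambda e: (e.atom_a, e.atom_b))
    return events


def find_salt_bridges(
    model: StructureModel,
    group_a: Selection,
    group_b: Selection,
    max_distance: float = 4.0,
) -> list[ContactEvent]:
    """Charged-group contacts: Arg/Lys/His nitrogens vs Asp/Glu/phosphate oxygens."""
    _check_disjoint(model, group_a, group_b)
    events: list[ContactEvent] = []
    for ai, bi, dist in _cross_pairs(model, group_a, group_b, max_distance):
        a, b = model.atoms[ai], model.atoms[bi]
        if (_is_basic_atom(a) and _is_acidic_atom(b)) or (_is_basic_atom(b) and _is_acidic_atom(a)):
            events.append(ContactEvent("salt_bridge", _atom_label(a), _atom_label(b), dist))
    events.sort(key=lambda e: (e.atom_a, e.atom_b))
    return events


def find_vdw_contacts(
    model: StructureModel,
    group_a: Selection,
    group_b: Selection,
    tolerance: float = 0.4,
    radii: dict[str, float] | None = None,
) -> list[ContactEvent]:
    """Heavy-atom pairs with distance ≤ r_vdw(a) + r_vdw(b) + tolerance."""
    _check_disjoint(model, group_a, group_b)
    radii = radii or VDW_RADII
    unknown = sorted(
        {
            model.atoms[i].element or "?"
            for sel in (group_a, group_b)
            for i in sel.resolved_indices
            if (model.atoms[i].element or "?") not in radii
        }
    )
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {unknown}")
    max_cut = 2 * max(radii.values()) + tolerance
    events: list[ContactEvent] = []
    for ai, bi, dist in _cross_pairs(model, group_a, group_b, max_cut):
        a, b = model.atoms[ai], model.atoms[bi]
        if a.element == "H" or b.element == "H":
            continue
        if dist <= radii[a.element] + radii[b.element] + tolerance:
            events.append(ContactEvent("vdw", _atom_label(a), _atom_label(b), dist))
    events.sort(key=lambda e: (e.atom_a, e.atom_b))
    return events


def find_water_bridges(
    model: StructureModel,
    group_a: Selection,
    group_b: Selection,
    criteria: HBondCriteria | None = None,
) -> list[ContactEvent]:
    """Water molecules hydrogen-bonding one atom in each group simultaneously.

    The hydrogen-bond criteria are applied to both legs; the event records the
    two bridged atoms, the longer leg distance, and the bridging water.
    """
    criteria = criteria or HBondCriteria()
    _check_disjoint(model, group_a, group_b)
    water_idx = [
        i for i, a in enumerate(model.atoms)
        if a.residue_name in WATER_NAMES and a.element == "O"
    ]
    if not water_idx:
        return []
    coords = model.coordinates
    cutoff = criteria.max_donor_acceptor_distance
    events: list[ContactEvent] = []
    for wi in water_idx:
        w = model.atoms[wi]
        legs_a = []
        legs_b = []
        for sel, legs in ((group_a, legs_a), (group_b, legs_b)):
            for i in sel.resolved_indices:
                a = model.atoms[i]
                if not (is_donor(a) or is_acceptor(a)):
                    continue
                d = float(np.linalg.norm(coords[i] - coords[wi]))
                if d <= cutoff:
                    legs.append((i, d))
        for ai, da in legs_a:
            for bi, db in legs_b:
                events.append(
                    ContactEvent(
                        "water_bridge",
                        _atom_label(model.atoms[ai]),
                        _atom_label(model.atoms[bi]),
                        max(da, db),
                        bridging_water=(w.chain_id, f"{w.residue_name}{w.residue_number}"),
                    )
                )
    events.sort(key=lambda e: (e.atom_a, e.atom_b))
    return events


# ---------------------------------------------------------------------------
# Occupancy over trajectories
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    """Per-pair fraction of frames in which a hydrogen bond holds.

    ``table`` columns: pair, chain, run, fraction, n_frames — mirroring the
    per-chain / per-run layout of replicated MD occupancy matrices.
    """

    table: pd.DataFrame
    n_frames: int

    def fraction(self, pair: str, chain: str = "", run: str = "") -> float:
        df = self.table
        mask = df["pair"] == pair
        if chain:
            mask &= df["chain"] == chain
        if run:
            mask &= df["run"] == run
        sub = df[mask]
        if sub.empty:
            raise KeyError(f"no occupancy row for pair={pair!r} chain={chain!r} run={run!r}")
        return float(sub["fraction"].iloc[0])


def hbond_occupancy(
    traj: Trajectory,
    pairs: Sequence[tuple[tuple[str, int, str], tuple[str, int, str]]],
    criteria: HBondCriteria | None = None,
    run_label: str = "run1",
    pair_labels: Sequence[str] | None = None,
) -> OccupancyTable:
    """Fraction of frames in which each (donor, acceptor) pair is bonded.

    Atom ids are (chain, residue number, atom name) on the trajectory
    topology. The donor's chain labels the row, so symmetric pairs on the two
    protomers of a dimer report per-chain occupancies.
    """
    criteria = criteria or HBondCriteria()
    top = traj.topology
    resolved: list[tuple[int, int]] = []
    for don, acc in pairs:
        try:
            di = top.atom_index(*don)
            ai = top.atom_index(*acc)
        except KeyError as exc:
            raise KeyError(f"occupancy pair {don} -> {acc}: {exc}") from exc
        resolved.append((di, ai))
    if pair_labels is None:
        pair_labels = [
            f"{don[0]}/{don[2]}{don[1]}-{acc[0]}/{acc[2]}{acc[1]}" for don, acc in pairs
        ]
    rows = []
    cutoff = criteria.max_donor_acceptor_distance
    for (di, ai), (don, _), label in zip(resolved, pairs, pair_labels):
        dist = np.linalg.norm(traj.frames[:, di, :] - traj.frames[:, ai, :], axis=1)
        n_on = int(np.count_nonzero(dist <= cutoff))
        rows.append(
            {
                "pair": label,
                "chain": don[0],
                "run": run_label,
                "fraction": n_on / traj.n_frames,
                "n_frames": traj.n_frames,
            }
        )
    return OccupancyTable(table=pd.DataFrame(rows), n_frames=traj.n_frames)


# ---------------------------------------------------------------------------
# Interface (crystal-packing) dissection
# ---------------------------------------------------------------------------

@dataclass
class InterfaceReport:
    """Classified chaperone–cargo contacts grouped by cargo residue.

    Each atom pair appears under exactly one kind with precedence
    salt_bridge > hbond > vdw. ``b_factors`` holds per-chain mean B-factors,
    supporting mobility comparisons between crystallographic assemblies.
    """

    events: list[ContactEvent]
    by_cargo_residue: dict[str, list[ContactEvent]]
    b_factors: pd.DataFrame  # columns: chain, mean_b_factor, n_atoms

    @property
    def n_events(self) -> int:
        return len(self.events)

    def counts(self) -> dict[str, int]:
        out = {"salt_bridge": 0, "hbond": 0, "vdw": 0}
        for e in self.events:
            out[e.kind] += 1
        return out


def interface_contacts(
    model: StructureModel,
    cargo_chains: Iterable[str],
    chaperone_chains: Iterable[str],
    criteria: HBondCriteria | None = None,
    salt_bridge_cutoff: float = 4.0,
    vdw_tolerance: float = 0.4,
) -> InterfaceReport:
    """Dissect all contacts between a cargo chain group and a chaperone group."""
    cargo = set(cargo_chains)
    chap = set(chaperone_chains)
    if cargo & chap:
        raise ValueError(f"cargo and chaperone chain sets overlap: {sorted(cargo & chap)}")
    for name, chains in (("cargo", cargo), ("chaperone", chap)):
        missing = chains - set(model.chain_ids)
        if missing:
            raise KeyError(f"{name} chains {sorted(missing)} absent from model")
    from .structure import select  # local import avoids cycle at module load

    sel_cargo = select(model, "chain " + ",".join(sorted(cargo)))
    sel_chap = select(model, "chain " + ",".join(sorted(chap)))
    salt = find_salt_bridges(model, sel_cargo, sel_chap, salt_bridge_cutoff)
    hbonds = find_hbonds(model, criteria, sel_cargo, sel_chap)
    vdw = find_vdw_contacts(model, sel_cargo, sel_chap, vdw_tolerance)
    # precedence salt_bridge > hbond > vdw: each pair reported once
    taken: set[frozenset[tuple[str, str, str]]] = set()
    events: list[ContactEvent] = []
    for bucket in (salt, hbonds, vdw):
        for e in bucket:
            key = frozenset((e.atom_a, e.atom_b))
            if key not in taken:
                taken.add(key)
                events.append(e)
    by_residue: dict[str, list[ContactEvent]] = {}
    for e in events:
        cargo_atom = e.atom_a if e.atom_a[0] in cargo else e.atom_b
        label = f"{cargo_atom[0]}/{cargo_atom[1]}"
        by_residue.setdefault(label, []).append(e)
    rows = []
    for chain in model.chain_ids:
        bs = [a.b_factor for a in model.atoms if a.chain_id == chain]
        rows.append({"chain": chain, "mean_b_factor": float(np.mean(bs)), "n_atoms": len(bs)})
    return InterfaceReport(
        events=events,
        by_cargo_residue=by_residue,
        b_factors=pd.DataFrame(rows),
    )
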