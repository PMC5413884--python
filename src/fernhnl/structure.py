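"""Active-site geometry from protein–ligand complex coordinates.

A minimal structure model (atoms with fixed-column PDB provenance) supports
three desk-scale analyses of a ligand-bound enzyme:

* ligand contacts — every protein residue with a heavy atom within a cutoff
  of any ligand heavy atom, with per-residue minimum distances (hydrophobic
  pocket composition);
* polar distances — minimum heavy-atom distance between two atom selections
  (hydrogen bonds are reported on heavy-atom distance with a 3.6 A ceiling,
  since crystal structures at typical resolution lack reliable hydrogens);
* water chains — a greedy nearest-neighbour walk over water oxygens starting
  at the active site, a documented simplification of volumetric tunnel
  analysis that captures an aligned water channel leaving the site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "ResidueContact",
    "PolarContact",
    "ContactReport",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "ligand_contacts",
    "polar_distance",
    "water_chain",
]

WATER_RESNAMES = {"HOH", "WAT", "H2O"}

#: heavy-atom distance ceiling for calling a polar contact a hydrogen bond
HBOND_CEILING = 3.6


@dataclass(frozen=True)
class Atom:
    record: str  # ATOM or HETATM
    serial: int
    name: str
    resname: str
    chain: str
    resnum: int
    x: float
    y: float
    z: float
    element: str
    altloc: str = ""

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class StructureModel:
    atoms: list[Atom]
    resolution: float | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates on atom serial {a.serial}")

    @property
    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.record == "ATOM" and not a.is_water]

    @property
    def het_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.record == "HETATM" and not a.is_water]

    @property
    def waters(self) -> list[Atom]:
        """Water oxygen atoms."""
        return [a for a in self.atoms if a.is_water and a.element.upper() == "O"]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transformed copy (geometry reports must be invariant)."""
        rot = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        new = []
        for a in self.atoms:
            x, y, z = rot @ a.pos + tr
            new.append(
                Atom(a.record, a.serial, a.name, a.resname, a.chain, a.resnum,
                     float(x), float(y), float(z), a.element, a.altloc)
            )
        return StructureModel(new, resolution=self.resolution, identifier=self.identifier)


def _validate_pdb_text(path: Path) -> None:
    """Light fixed-column sanity check so malformed coordinate lines are
    reported with their line number (the backing parser is lenient)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}:{lineno}: coordinate record shorter than 54 columns")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed x/y/z columns in coordinate record"
                ) from None


def read_pdb(path: str | Path) -> StructureModel:
    """Parse a fixed-column PDB file into a StructureModel.

    ATOM and HETATM records are read (first model only), the REMARK 2 stated
    resolution is captured when present, the first alternate location of each
    atom is kept, and waters are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    resolution = float(st.resolution) if st.resolution else None
    atoms: list[Atom] = []
    seen: set[tuple] = set()
    model = st[0]
    for chain in model:
        for res in chain:
            record = "HETATM" if res.het_flag == "H" else "ATOM"
            for at in res:
                key = (chain.name, res.seqid.num, res.name, at.name)
                if key in seen:  # keep first altloc only
                    continue
                seen.add(key)
                atoms.append(
                    Atom(
                        record=record,
                        serial=at.serial,
                        name=at.name,
                        resname=res.name,
                        chain=chain.name,
                        resnum=res.seqid.num,
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                        element=at.element.name,
                        altloc=at.altloc if at.altloc != "\x00" else "",
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return StructureModel(atoms, resolution=resolution, identifier=st.name or path.stem)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as fixed-column PDB text (3-decimal coordinates)."""
    with open(path, "w") as fh:
        if model.resolution is not None:
            fh.write(f"REMARK   2 RESOLUTION. {model.resolution:7.2f} ANGSTROMS.\n")
        for a in model.atoms:
            fh.write(
                f"{a.record:<6}{a.serial:>5} {a.name:^4}{a.altloc or ' '}"
                f"{a.resname:>3} {a.chain:1}{a.resnum:>4}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2}\n"
            )
        fh.write("END\n")


def select_atoms(
    model: StructureModel,
    chain: str | None = None,
    resname: str | None = None,
    resnum: int | None = None,
    names: Iterable[str] | None = None,
    record: str | None = None,
) -> list[Atom]:
    """Atoms matching every given criterion (None = wildcard)."""
    name_set = {n.upper() for n in names} if names is not None else None
    out = []
    for a in model.atoms:
        if chain is not None and a.chain != chain:
            continue
        if resname is not None and a.resname != resname:
            continue
        if resnum is not None and a.resnum != resnum:
            continue
        if name_set is not None and a.name.upper() not in name_set:
            continue
        if record is not None and a.record != record:
            continue
        out.append(a)
    return out


@dataclass(frozen=True)
class ResidueContact:
    chain: str
    resnum: int
    resname: str
    min_distance: float


@dataclass(frozen=True)
class PolarContact:
    ligand_atom: str
    residue: str  # e.g. "A/ARG 69/NH1"
    distance: float


@dataclass
class ContactReport:
    ligand: str
    residues: list[ResidueContact]
    polar: list[PolarContact]


_POLAR_ELEMENTS = {"N", "O"}


def ligand_contacts(
    model: StructureModel,
    ligand_resname: str,
    cutoff: float = 4.0,
    chain: str | None = None,
) -> ContactReport:
    """Protein residues with any heavy atom within ``cutoff`` of any ligand
    heavy atom, sorted by ascending minimum distance, with a sublist of polar
    (N/O–N/O) pairs within the hydrogen-bond ceiling."""
    lig = [
        a
        for a in select_atoms(model, resname=ligand_resname, chain=chain)
        if a.is_heavy
    ]
    if not lig:
        available = sorted({a.resname for a in model.het_atoms})
        raise ValueError(
            f"ligand {ligand_resname!r} not found; available het groups: {available}"
        )
    prot = [a for a in model.protein_atoms if a.is_heavy]
    per_res: dict[tuple[str, int, str], float] = {}
    polar: list[PolarContact] = []
    if prot and cutoff > 0:
        lig_xyz = np.array([a.pos for a in lig])
        prot_xyz = np.array([a.pos for a in prot])
        d = np.linalg.norm(prot_xyz[:, None, :] - lig_xyz[None, :, :], axis=2)
        for i, pa in enumerate(prot):
            dmin = float(d[i].min())
            if dmin <= cutoff:
                key = (pa.chain, pa.resnum, pa.resname)
                per_res[key] = min(per_res.get(key, math.inf), dmin)
            for j, la in enumerate(lig):
                dij = float(d[i, j])
                if (
                    dij <= min(cutoff, HBOND_CEILING)
                    and pa.element.upper() in _POLAR_ELEMENTS
                    and la.element.upper() in _POLAR_ELEMENTS
                ):
                    polar.append(
                        PolarContact(
                            ligand_atom=la.name,
                            residue=f"{pa.chain}/{pa.resname} {pa.resnum}/{pa.name}",
                            distance=round(dij, 2),
                        )
                    )
    residues = sorted(
        (ResidueContact(c, n, r, round(dm, 2)) for (c, n, r), dm in per_res.items()),
        key=lambda rc: rc.min_distance,
    )
    polar.sort(key=lambda p: p.distance)
    return ContactReport(ligand=ligand_resname, residues=residues, polar=polar)


def polar_distance(
    model: StructureModel,
    selection_a: dict,
    selection_b: dict,
) -> float:
    """Minimum pairwise distance (A) between two atom selections.

    Selections are keyword dicts for :func:`select_atoms`, e.g. a nitrile N
    versus the guanidinium atoms {NE, NH1, NH2} of an arginine.
    """
    atoms_a = select_atoms(model, **selection_a)
    atoms_b = select_atoms(model, **selection_b)
    if not atoms_a:
        raise ValueError(f"selection A matched no atoms: {selection_a}")
    if not atoms_b:
        raise ValueError(f"selection B matched no atoms: {selection_b}")
    xa = np.array([a.pos for a in atoms_a])
    xb = np.array([b.pos for b in atoms_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return float(d.min())


def water_chain(
    model: StructureModel,
    start_selection: dict,
    max_step: float = 3.5,
    surface_neighbor_count: int = 0,
) -> list[Atom]:
    """Greedy chain of water oxygens leading away from the active site.

    The chain starts at the water nearest the start selection (within
    ``max_step``) and repeatedly extends to the nearest unvisited water within
    ``max_step`` of the current one; ties are broken by lower serial number.
    With ``surface_neighbor_count`` > 0 the walk additionally terminates once
    the current water is solvent-exposed (fewer than that many protein heavy
    atoms within 5 A). Returns the ordered chain; empty when no water lies
    within ``max_step`` of the start selection.
    """
    waters = model.waters
    if not waters:
        return []
    start_atoms = select_atoms(model, **start_selection)
    if not start_atoms:
        raise ValueError(f"start selection matched no atoms: {start_selection}")
    sx = np.array([a.pos for a in start_atoms])
    wx = np.array([w.pos for w in waters])
    d0 = np.linalg.norm(wx[:, None, :] - sx[None, :, :], axis=2).min(axis=1)
    order = sorted(range(len(waters)), key=lambda i: (d0[i], waters[i].serial))
    if d0[order[0]] > max_step:
        return []
    prot_xyz = (
        np.array([a.pos for a in model.protein_atoms if a.is_heavy])
        if model.protein_atoms
        else np.empty((0, 3))
    )

    def exposed(idx: int) -> bool:
        if surface_neighbor_count <= 0:
            return False
        if prot_xyz.shape[0] == 0:
            return True
        n_near = int(
            (np.linalg.norm(prot_xyz - wx[idx], axis=1) <= 5.0).sum()
        )
        return n_near < surface_neighbor_count

    chain = [order[0]]
    visited = {order[0]}
    while not exposed(chain[-1]):
        cur = wx[chain[-1]]
        candidates = [
            (float(np.linalg.norm(wx[i] - cur)), waters[i].serial, i)
            for i in range(len(waters))
            if i not in visited
        ]
        candidates = [c for c in candidates if c[0] <= max_step]
        if not candidates:
            break
        _, _, nxt = min(candidates)
        chain.append(nxt)
        visited.add(nxt)
    return [waters[i] for i in chain]
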