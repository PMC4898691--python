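"""Structure-derived active-site geometry.

Measurements that characterize a flavoenzyme active site from coordinates:
atom-atom distances (e.g. the chloride oxygen-surrogate to the flavin C4a),
minimum heavy-atom contacts between residues (hydrogen bonds are quoted as
heavy-atom distances, no angle criterion), the isoalloxazine butterfly bend
(angle between the least-squares planes of the pyrimidine and dimethylbenzene
rings, hinged at the N5-N10 axis) and Kabsch superposition for structure
overlays.  PDB-format input is parsed with gemmi; only ATOM/HETATM content is
retained and alternate locations other than '' / 'A' are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "RingSpec",
    "FAD_RING_SPEC",
    "read_structure",
    "write_pdb",
    "atom_distance",
    "min_contact",
    "ring_plane_angle",
    "superpose",
]

# PDB chemical-dictionary versions disagree on flavin junction-atom names.
_ATOM_ALIASES: dict[str, tuple[str, ...]] = {
    "C4A": ("C4A", "C4X"), "C4X": ("C4X", "C4A"),
    "C5A": ("C5A", "C5X"), "C5X": ("C5X", "C5A"),
    "C10": ("C10", "C10A"), "C10A": ("C10A", "C10"),
}


@dataclass(frozen=True)
class AtomRecord:
    name: str
    res_name: str
    res_num: int
    chain: str
    element: str
    xyz: np.ndarray  # Angstrom
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be three finite numbers")
        if not self.element:
            raise ValueError("element must be nonempty")
        object.__setattr__(self, "xyz", xyz)


class StructureModel:
    """A flat list of atoms with (chain, residue number, atom name) lookup."""

    def __init__(self, atoms: Sequence[AtomRecord]) -> None:
        self.atoms = list(atoms)
        self._index: dict[tuple[str, int, str], AtomRecord] = {}
        for a in self.atoms:
            self._index.setdefault((a.chain, a.res_num, a.name), a)

    def __len__(self) -> int:
        return len(self.atoms)

    def find_atom(self, chain: str, res_num: int, name: str) -> AtomRecord:
        """Atom lookup with flavin-naming aliases (C4A/C4X etc.)."""
        for candidate in _ATOM_ALIASES.get(name.upper(), (name,)):
            atom = self._index.get((chain, res_num, candidate.upper()))
            if atom is not None:
                return atom
        raise KeyError(f"no atom {chain}:{res_num}:{name}")

    def residue_atoms(self, chain: str, res_num: int) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain == chain and a.res_num == res_num]

    def select(self, selection: str) -> AtomRecord:
        """Resolve a ``chain:resnum:atomname`` selection string to one atom."""
        parts = selection.split(":")
        if len(parts) != 3:
            raise ValueError(f"selection {selection!r} must be chain:resnum:atomname")
        return self.find_atom(parts[0], int(parts[1]), parts[2])

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        return StructureModel([
            AtomRecord(a.name, a.res_name, a.res_num, a.chain, a.element,
                       rot @ a.xyz + tr, a.is_hetatm)
            for a in self.atoms])


@dataclass(frozen=True)
class RingSpec:
    """Atom names of the two flavin wing rings and the hinge axis.

    Each ring entry is a tuple of acceptable names for one atom (dictionary
    versions differ); the first name found in the model is used.
    """

    ring1: tuple[tuple[str, ...], ...]
    ring2: tuple[tuple[str, ...], ...]
    hinge: tuple[str, str] = ("N5", "N10")

    def __post_init__(self) -> None:
        if len(self.ring1) < 3 or len(self.ring2) < 3:
            raise ValueError("each ring needs at least 3 atoms")


#: Isoalloxazine rings in PDB FAD naming: pyrimidine wing vs dimethylbenzene wing.
FAD_RING_SPEC = RingSpec(
    ring1=(("N1",), ("C2",), ("N3",), ("C4",), ("C4X", "C4A"), ("C10", "C10A")),
    ring2=(("C5X", "C5A"), ("C6",), ("C7",), ("C8",), ("C9",), ("C9A",)),
)


def read_structure(pdb_text: str) -> StructureModel:
    """Parse PDB-format text (ATOM/HETATM; altloc '' or 'A'; waters kept).

    Malformed records are skipped with a warning; zero parsed atoms is an
    error.
    """
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError):
        kept, dropped = [], 0
        for line in pdb_text.splitlines():
            if line.startswith(("ATOM", "HETATM")):
                if len(line) >= 54:
                    kept.append(line)
                else:
                    dropped += 1
        if dropped:
            warnings.warn(f"skipped {dropped} malformed ATOM/HETATM records")
        if not kept:
            raise ValueError("no ATOM/HETATM records parsed")
        structure = gemmi.read_pdb_string("\n".join(kept) + "\n")
    atoms: list[AtomRecord] = []
    if len(structure) == 0:
        raise ValueError("no ATOM/HETATM records parsed")
    model = structure[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                atoms.append(AtomRecord(
                    name=atom.name.upper(),
                    res_name=residue.name,
                    res_num=residue.seqid.num,
                    chain=chain.name,
                    element=atom.element.name or atom.name[0],
                    xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    is_hetatm=residue.het_flag == "H"))
    if not atoms:
        raise ValueError("no ATOM/HETATM records parsed")
    return StructureModel(atoms)


def write_pdb(model: StructureModel) -> str:
    """Serialize a model to minimal PDB-format text (round-trips coordinates)."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        record = "HETATM" if a.is_hetatm else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{i:5d} {name:<4s} {a.res_name:<3s} {a.chain:1s}"
            f"{a.res_num:4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}")
    return "\n".join(lines + ["END"]) + "\n"


def atom_distance(model: StructureModel, sel_a: str, sel_b: str) -> float:
    """Euclidean distance (Angstrom) between two single-atom selections."""
    a = model.select(sel_a)
    b = model.select(sel_b)
    return float(np.linalg.norm(a.xyz - b.xyz))


def min_contact(model: StructureModel, residue_a: tuple[str, int],
                residue_b: tuple[str, int],
                atom_filter: Callable[[AtomRecord], bool] | None = None
                ) -> tuple[float, tuple[AtomRecord, AtomRecord]]:
    """Minimum pairwise distance between two residues' (filtered) atoms.

    ``atom_filter`` defaults to polar heavy atoms (N, O) — the convention for
    quoting hydrogen bonds and salt bridges as heavy-atom distances.
    """
    if atom_filter is None:
        atom_filter = lambda a: a.element in ("N", "O")
    set_a = [a for a in model.residue_atoms(*residue_a) if atom_filter(a)]
    set_b = [a for a in model.residue_atoms(*residue_b) if atom_filter(a)]
    if not set_a or not set_b:
        raise ValueError("atom filter left an empty selection")
    best = None
    for a in set_a:
        for b in set_b:
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if best is None or d < best[0]:
                best = (d, (a, b))
    return best


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered)
    if svals[1] < 1e-8:
        raise ValueError("ring atoms are collinear; no plane defined")
    return vt[2]


def _ring_coords(model: StructureModel, chain: str, res_num: int,
                 ring: tuple[tuple[str, ...], ...]) -> np.ndarray:
    coords = []
    for names in ring:
        atom = None
        for n in names:
            try:
                atom = model.find_atom(chain, res_num, n)
                break
            except KeyError:
                continue
        if atom is None:
            raise KeyError(f"ring atom {'/'.join(names)} missing in {chain}:{res_num}")
        coords.append(atom.xyz)
    return np.array(coords)


def ring_plane_angle(model: StructureModel, chain: str, res_num: int,
                     ring_spec: RingSpec = FAD_RING_SPEC) -> float:
    """Butterfly-bend angle (deg, in [0, 90]) between the two wing-ring planes."""
    n1 = _plane_normal(_ring_coords(model, chain, res_num, ring_spec.ring1))
    n2 = _plane_normal(_ring_coords(model, chain, res_num, ring_spec.ring2))
    cosang = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def superpose(model_mobile: StructureModel, model_ref: StructureModel,
              atom_pairs: Sequence[tuple[str, str]]
              ) -> tuple[float, StructureModel]:
    """Least-squares rigid superposition (Kabsch, no reflection).

    ``atom_pairs`` are (mobile selection, reference selection) strings; at
    least 3 non-collinear pairs are required.  Returns the RMSD over the
    paired atoms and the transformed mobile model.
    """
    if len(atom_pairs) < 3:
        raise ValueError("need at least 3 atom pairs")
    p = np.array([model_mobile.select(m).xyz for m, _ in atom_pairs])
    q = np.array([model_ref.select(r).xyz for _, r in atom_pairs])
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    if np.linalg.matrix_rank(p0, tol=1e-8) < 2:
        raise ValueError("paired atoms are collinear")
    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (rot @ p0.T).T + qc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    translation = qc - rot @ pc
    return rmsd, model_mobile.transformed(rot, translation)
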