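"""Cα superposition and RMSD between receptor models.

Two coordinate sets are paired by (chain, residue number, atom name) within a
selection (Cα by default), superposed by the closed-form least-squares
rotation (Kabsch algorithm, SVD with reflection correction) and the RMSD over
the paired atoms is reported. No outlier trimming is applied: the RMSD is the
plain root-mean-square paired distance after optimal superposition.

Coordinate files (PDB or mmCIF) are read through gemmi; alternate locations
keep the highest-occupancy conformer and hydrogens are always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

__all__ = [
    "CoordinateSet",
    "SuperpositionResult",
    "superpose_rmsd",
    "kabsch",
    "read_structure",
]


class PairingError(ValueError):
    """Fewer than 3 atoms could be paired between the two coordinate sets."""


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float


@dataclass
class CoordinateSet:
    """A labelled list of atoms with unique (chain, residue number, atom name) keys."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        keys = [(a.chain, a.residue_number, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError(f"{self.label}: duplicate atom keys")
        for a in self.atoms:
            if not all(np.isfinite([a.x, a.y, a.z])):
                raise ValueError(f"{self.label}: non-finite coordinates")

    def select(self, atom_name: str | None = "CA", chain: str | None = None) -> "CoordinateSet":
        atoms = [
            a
            for a in self.atoms
            if (atom_name is None or a.atom_name == atom_name)
            and (chain is None or a.chain == chain)
        ]
        return CoordinateSet(atoms, self.label)

    @property
    def chains(self) -> list[str]:
        seen = dict.fromkeys(a.chain for a in self.atoms)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition of b onto a and the resulting RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation/translation mapping q onto p, and the RMSD.

    Closed-form solution via SVD of the covariance matrix, with the sign of
    the smallest singular vector flipped when the optimum would otherwise be
    a reflection.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = q0.T @ p0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    rot = vt.T @ s @ u.T
    q_fit = (rot @ q0.T).T + pc
    rmsd = float(np.sqrt(np.mean(np.sum((q_fit - (p0 + pc)) ** 2, axis=1))))
    trans = pc - rot @ qc
    return rot, trans, rmsd


def superpose_rmsd(
    a: CoordinateSet,
    b: CoordinateSet,
    atom_name: str | None = "CA",
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> SuperpositionResult:
    """Pair atoms by residue number, superpose, and report RMSD.

    Atoms are taken from one chain of each set (the first chain by default)
    restricted to ``atom_name``, and paired on residue number intersection.
    Raises :class:`PairingError` (listing the unmatched residues) if fewer
    than 3 atoms pair up.
    """
    sel_a = a.select(atom_name)
    sel_b = b.select(atom_name)
    ca = chain_a or (sel_a.chains[0] if sel_a.chains else "")
    cb = chain_b or (sel_b.chains[0] if sel_b.chains else "")
    sel_a = sel_a.select(atom_name, ca)
    sel_b = sel_b.select(atom_name, cb)
    map_a = {x.residue_number: x for x in sel_a.atoms}
    map_b = {x.residue_number: x for x in sel_b.atoms}
    common = sorted(set(map_a) & set(map_b))
    if len(common) < 3:
        unmatched = sorted(set(map_a) ^ set(map_b))
        raise PairingError(
            f"only {len(common)} paired atoms between {a.label!r} and {b.label!r}; "
            f"unmatched residues: {unmatched[:20]}"
        )
    p = np.array([[map_a[r].x, map_a[r].y, map_a[r].z] for r in common])
    q = np.array([[map_b[r].x, map_b[r].y, map_b[r].z] for r in common])
    rot, trans, rmsd = kabsch(p, q)
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(common))


def read_structure(path, label: str | None = None) -> CoordinateSet:
    """Read a PDB or mmCIF file into a :class:`CoordinateSet`.

    Keeps the first model only; for alternate locations the highest-occupancy
    conformer is kept; hydrogens are excluded.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_hydrogens()
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            best: dict[str, "gemmi.Atom"] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    return CoordinateSet(atoms, label or Path(str(path)).stem)
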