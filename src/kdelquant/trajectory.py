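"""Collective-variable, hydrogen-bond occupancy and RMSF analysis of trajectories.

The engagement of a retrieval signal with the receptor binding pocket is
followed along a scalar collective variable (CV): the distance between the
peptide's N-terminal nitrogen and the centroid of the Cα atoms of five
binding-pocket residues (9, 44, 64, 124 and 162). Hydrogen bonds between the
signal's carboxylate groups and the receptor's arginine ladder (R5, R47,
R169) are detected per frame with a geometric criterion and their occupancy
is binned along the CV, producing handover profiles. Positional flexibility
is summarised as per-atom RMSF after iterative superposition onto the mean
structure.

Internal length unit is Å; the CV is reported in nm to match convention for
umbrella-sampling window layouts (default bins: 0.1 nm steps from 1.8 to
3.3 nm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .structure import kabsch

__all__ = [
    "Trajectory",
    "CollectiveVariable",
    "HBondDefinition",
    "OccupancyProfile",
    "RmsfProfile",
    "binding_pocket_cv",
    "hbond_occupancy_vs_cv",
    "rmsf",
    "DEFAULT_POCKET_RESIDUES",
    "DEFAULT_CV_BIN_EDGES_NM",
]

#: receptor residues whose Cα centroid defines the binding-pocket centre
DEFAULT_POCKET_RESIDUES = (9, 44, 64, 124, 162)

#: default CV bin edges in nm: 0.1 nm steps spanning the 1.8-3.3 nm window layout
DEFAULT_CV_BIN_EDGES_NM = np.round(np.arange(1.8, 3.3001, 0.1), 10)

ANGSTROM_PER_NM = 10.0


class SelectorError(KeyError):
    """A requested atom could not be resolved in the topology."""


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed topology.

    ``topology`` is a DataFrame with columns segment ('receptor'/'peptide'),
    residue_number, residue_name, atom_name; ``frames`` has shape (F, N, 3)
    in Å. ``frame_spacing`` is carried as metadata only.
    """

    topology: pd.DataFrame
    frames: np.ndarray
    frame_spacing: float = 1.0
    frame_spacing_unit: str = "frame"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError("topology and frames disagree on atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def atom_index(
        self, segment: str, residue_number: int, atom_name: str
    ) -> int:
        t = self.topology
        mask = (
            (t["segment"] == segment)
            & (t["residue_number"] == residue_number)
            & (t["atom_name"] == atom_name)
        )
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) != 1:
            raise SelectorError(
                f"atom ({segment}, residue {residue_number}, {atom_name!r}): "
                f"{len(idx)} matches"
            )
        return int(idx[0])

    def select_indices(self, segment: str | None = None, atom_name: str | None = None) -> np.ndarray:
        t = self.topology
        mask = np.ones(len(t), dtype=bool)
        if segment is not None:
            mask &= (t["segment"] == segment).to_numpy()
        if atom_name is not None:
            mask &= (t["atom_name"] == atom_name).to_numpy()
        return np.flatnonzero(mask)

    # -------------------------------------------------------------- file I/O

    def to_multimodel_pdb(self, path) -> None:
        """Write as a multi-MODEL PDB file (one MODEL per frame)."""
        chain_of = {"receptor": "A", "peptide": "B"}
        with open(path, "w") as fh:
            for f in range(self.n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                serial = 1
                for i, row in enumerate(self.topology.itertuples(index=False)):
                    x, y, z = self.frames[f, i]
                    name = row.atom_name
                    pdb_name = f" {name:<3s}" if len(name) < 4 else name
                    element = name[0]
                    fh.write(
                        f"ATOM  {serial:5d} {pdb_name:<4s}{row.residue_name:>4s} "
                        f"{chain_of.get(row.segment, 'C')}{row.residue_number:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {element:>2s}\n"
                    )
                    serial += 1
                fh.write("ENDMDL\n")
            fh.write("END\n")

    @classmethod
    def from_multimodel_pdb(cls, path) -> "Trajectory":
        """Read a multi-MODEL PDB written by :meth:`to_multimodel_pdb`."""
        segment_of = {"A": "receptor", "B": "peptide"}
        frames: list[list[list[float]]] = []
        topo_rows: list[dict] = []
        current: list[list[float]] | None = None
        first_model = True
        with open(path) as fh:
            for line in fh:
                if line.startswith("MODEL"):
                    current = []
                elif line.startswith("ENDMDL"):
                    frames.append(current)
                    current = None
                    first_model = False
                elif line.startswith(("ATOM", "HETATM")) and current is not None:
                    if first_model:
                        topo_rows.append(
                            {
                                "segment": segment_of.get(line[21], "other"),
                                "residue_number": int(line[22:26]),
                                "residue_name": line[17:21].strip(),
                                "atom_name": line[12:16].strip(),
                            }
                        )
                    current.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
        if not frames:
            raise ValueError(f"{path}: no MODEL records found")
        return cls(topology=pd.DataFrame(topo_rows), frames=np.array(frames))


@dataclass
class CollectiveVariable:
    """Per-frame CV values in nm, with the defining selections."""

    values: np.ndarray
    probe: tuple[str, int, str]
    pocket_residues: tuple[int, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("CV values must be >= 0")


def binding_pocket_cv(
    traj: Trajectory,
    probe: tuple[str, int, str] | None = None,
    pocket_residues: Sequence[int] = DEFAULT_POCKET_RESIDUES,
) -> CollectiveVariable:
    """Distance (nm) from the peptide N-terminal N atom to the pocket centroid.

    The pocket centre is the unweighted centroid of the Cα atoms of
    ``pocket_residues`` on the receptor. ``probe`` defaults to the N atom of
    the peptide's first (lowest-numbered) residue.
    """
    if probe is None:
        pep = traj.topology[traj.topology["segment"] == "peptide"]
        if pep.empty:
            raise SelectorError("no peptide segment in topology")
        probe = ("peptide", int(pep["residue_number"].min()), "N")
    probe_idx = traj.atom_index(*probe)
    ca_idx = [traj.atom_index("receptor", r, "CA") for r in pocket_residues]
    centroid = traj.frames[:, ca_idx, :].mean(axis=1)
    d = np.linalg.norm(traj.frames[:, probe_idx, :] - centroid, axis=1)
    return CollectiveVariable(
        values=d / ANGSTROM_PER_NM,
        probe=probe,
        pocket_residues=tuple(pocket_residues),
    )


@dataclass(frozen=True)
class HBondDefinition:
    """Geometric hydrogen-bond criterion between donor/hydrogen/acceptor atoms.

    Selectors are (segment, residue_number, atom_name) triples. ``hydrogen``
    may be None, in which case a tighter distance-only criterion
    (``d_cut_no_h``) is applied and the profile is flagged.
    """

    name: str
    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    hydrogen: tuple[str, int, str] | None = None
    d_cut: float = 3.5
    angle_cut: float = 150.0
    d_cut_no_h: float = 3.0

    def __post_init__(self) -> None:
        if self.d_cut <= 0 or self.d_cut_no_h <= 0:
            raise ValueError("distance cutoffs must be > 0")
        if not 0 < self.angle_cut <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass
class OccupancyProfile:
    """Per-bond hydrogen-bond occupancy binned along the CV.

    ``occupancy`` maps bond name -> length-(n_bins) array in [0, 1], with NaN
    for bins containing no frames (reported missing, not zero).
    """

    cv_bin_edges: np.ndarray
    occupancy: dict[str, np.ndarray]
    frame_counts: np.ndarray
    distance_only: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        mid = 0.5 * (self.cv_bin_edges[:-1] + self.cv_bin_edges[1:])
        data = {"cv_mid_nm": mid, "n_frames": self.frame_counts}
        data.update(self.occupancy)
        return pd.DataFrame(data)


def _bond_present(traj: Trajectory, bond: HBondDefinition) -> np.ndarray:
    d_idx = traj.atom_index(*bond.donor)
    a_idx = traj.atom_index(*bond.acceptor)
    d = traj.frames[:, d_idx, :]
    a = traj.frames[:, a_idx, :]
    da = np.linalg.norm(d - a, axis=1)
    if bond.hydrogen is None:
        return da <= bond.d_cut_no_h
    h_idx = traj.atom_index(*bond.hydrogen)
    h = traj.frames[:, h_idx, :]
    v1 = d - h
    v2 = a - h
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (da <= bond.d_cut) & (angle >= bond.angle_cut)


def hbond_occupancy_vs_cv(
    traj: Trajectory,
    bonds: Sequence[HBondDefinition],
    cv: CollectiveVariable,
    bin_edges_nm: np.ndarray = DEFAULT_CV_BIN_EDGES_NM,
) -> OccupancyProfile:
    """Occupancy of each hydrogen bond per CV bin.

    A bond is present in a frame iff the donor-acceptor distance is within
    ``d_cut`` and the D-H···A angle is at least ``angle_cut`` (or, lacking a
    hydrogen, distance within ``d_cut_no_h``). Occupancy in a bin is the
    fraction of that bin's frames where the bond is present; empty bins are
    NaN. Frames outside the bin range are excluded from the counts.
    """
    if len(cv.values) != traj.n_frames:
        raise ValueError("CV length must equal the number of frames")
    edges = np.asarray(bin_edges_nm, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be increasing with >= 2 values")
    # right-inclusive final bin so the ramp endpoint is counted
    idx = np.digitize(cv.values, edges) - 1
    idx[np.isclose(cv.values, edges[-1])] = len(edges) - 2
    in_range = (idx >= 0) & (idx < len(edges) - 1)
    counts = np.bincount(idx[in_range], minlength=len(edges) - 1)
    occupancy: dict[str, np.ndarray] = {}
    distance_only = []
    for bond in bonds:
        present = _bond_present(traj, bond)
        if bond.hydrogen is None:
            distance_only.append(bond.name)
        hits = np.bincount(
            idx[in_range], weights=present[in_range].astype(float), minlength=len(edges) - 1
        )
        with np.errstate(invalid="ignore"):
            occ = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
        occupancy[bond.name] = occ
    return OccupancyProfile(
        cv_bin_edges=edges,
        occupancy=occupancy,
        frame_counts=counts,
        distance_only=tuple(distance_only),
    )


@dataclass
class RmsfProfile:
    """Per-atom RMSF (Å) after superposition, with the selections used."""

    atom_indices: np.ndarray
    rmsf: np.ndarray
    alignment_selection: str

    def __post_init__(self) -> None:
        if (np.asarray(self.rmsf) < 0).any():
            raise ValueError("RMSF must be >= 0")

    def by_residue(self, topology: pd.DataFrame) -> pd.DataFrame:
        sub = topology.iloc[self.atom_indices].copy()
        sub["rmsf"] = self.rmsf
        return (
            sub.groupby(["segment", "residue_number"], sort=True)["rmsf"]
            .mean()
            .reset_index()
        )


def rmsf(
    traj: Trajectory,
    align_segment: str | None = "receptor",
    align_atom_name: str | None = "CA",
    report_segment: str | None = None,
    report_atom_name: str | None = None,
) -> RmsfProfile:
    """Per-atom RMSF after removing rigid-body motion.

    Frames are superposed onto the mean structure over the alignment
    selection; the mean is recomputed and the superposition iterated once
    more. RMSF_i = sqrt(mean_t |r_i(t) − <r_i>|²) over the report selection
    (all atoms by default).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    align_idx = traj.select_indices(align_segment, align_atom_name)
    if len(align_idx) < 3:
        raise SelectorError("alignment selection needs >= 3 atoms")
    frames = traj.frames.copy()
    for _ in range(2):  # align to mean, then re-align to the updated mean
        ref = frames[:, align_idx, :].mean(axis=0)
        for f in range(frames.shape[0]):
            rot, trans, _ = kabsch(ref, frames[f, align_idx, :])
            frames[f] = (rot @ frames[f].T).T + trans
    report_idx = traj.select_indices(report_segment, report_atom_name)
    mean_pos = frames[:, report_idx, :].mean(axis=0)
    disp2 = np.sum((frames[:, report_idx, :] - mean_pos) ** 2, axis=2)
    values = np.sqrt(disp2.mean(axis=0))
    sel = f"segment={align_segment},atom={align_atom_name}"
    return RmsfProfile(atom_indices=report_idx, rmsf=values, alignment_selection=sel)
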