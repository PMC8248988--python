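"""Seeded synthetic-data generators with machine-readable ground truth.

Every pipeline stage has a generator that emulates its real input — an
ER-proteome-like table with planted retrieval-signal frequencies and
log-normal abundances, 4PL dose-response plates with multiplicative noise,
replicate alchemical-leg tables with an exactly known planted cycle value and
pKa shifts, two-condition per-cell Golgi/total intensity tables with stated
effect sizes, and toy receptor/peptide trajectories with planted CV ramps,
hydrogen-bond occupancies and positional jitter.

Each generator derives its own pseudorandom stream from the master seed by
stable hashing of the generator name, so adding or reordering calls never
changes another generator's output, and returns a truth manifest recording
every planted parameter (written as JSON next to the data files when an
output directory is given).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import thermo
from .proteomics import AMINO_ACIDS, ProteinRecord
from .trajectory import (
    DEFAULT_CV_BIN_EDGES_NM,
    HBondDefinition,
    Trajectory,
)

__all__ = [
    "GeneratorConfig",
    "gen_proteome",
    "gen_binding_curves",
    "gen_alchemical_legs",
    "gen_cell_table",
    "gen_trajectory",
    "generate_all",
]


@dataclass
class GeneratorConfig:
    """Master seed plus the planted parameters of every generator.

    Defaults are the study conditions the generators emulate: roughly equal
    K/H/R variant frequencies with the summed KDEL abundance 5.5-fold that of
    HDEL; 8-point titrations with 5% multiplicative noise; three replicate
    alchemical legs per transformation with a planted KDEL→HDEL binding
    preference of −1.8 kcal/mol and a planted site pKa of 8.9 for the
    histidine; 40 cells per condition with a −0.4 ligand-induced drop in
    Golgi fraction; 300-frame trajectories spanning the 1.8-3.3 nm CV window.
    """

    seed: int = 0

    # proteome
    n_proteins: int = 300
    variant_frequencies: dict = field(
        default_factory=lambda: {"K": 0.25, "H": 0.25, "R": 0.25}
    )
    abundance_mu: float = 0.0  # log-space mean of µM abundances
    abundance_sigma: float = 1.5
    abundance_unit: str = "uM"
    abundance_ratio_k_h: float | None = 5.5
    min_length: int = 30
    max_length: int = 80

    # binding curves
    n_curves: int = 100
    n_points: int = 8
    x_min_uM: float = 1e-3
    x_max_uM: float = 100.0
    top_range: tuple = (0.8, 1.2)
    bottom_range: tuple = (0.0, 0.1)
    hill_range: tuple = (0.8, 1.5)
    midpoint_range_uM: tuple = (0.05, 20.0)
    noise_sd: float = 0.05  # multiplicative log-normal sd
    hot_conc_uM: float = 0.01
    hot_kd_uM: float = 0.24

    # alchemical legs
    n_replicates: int = 3
    leg_sd: float = 0.5
    temperature: float = 310.0
    target_ddg_bind: float = -1.8
    target_pka_his: float = 8.9
    target_pka_lys: float = 10.2
    # chosen so the calibrated effective deprotonation free energies are O(RT),
    # i.e. genuinely mixed protonation ensembles in solution
    solution_leg_truths: dict = field(
        default_factory=lambda: {
            "LYS2LYN": -2.0,
            "LYS2HIP": -35.0,
            "HIP2HID": 1.8,
            "HIP2HIE": 2.2,
        }
    )

    # per-cell table
    n_cells: int = 40
    condition_means: dict = field(
        default_factory=lambda: {"no_ligand": 0.55, "KDEL": 0.15}
    )
    beta_concentration: float = 50.0
    total_intensity_mu: float = 10.0  # log-space
    total_intensity_sigma: float = 0.3

    # trajectory
    n_frames: int = 300
    cv_start_nm: float = 1.8
    cv_end_nm: float = 3.3
    jitter_sd: float = 0.5  # Å, on the flexible side-chain atom
    occupancy_profiles: dict | None = None  # bond name -> per-bin occupancy

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if sum(self.variant_frequencies.values()) > 1 + 1e-12:
            raise ValueError("variant frequencies must sum to <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for mean in self.condition_means.values():
            if not 0 < mean < 1:
                raise ValueError("condition means must lie in (0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    def rng(self, name: str) -> np.random.Generator:
        """Independent stream for one generator, derived by stable name hash."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(zlib.crc32(name.encode()),))
        )


def _write_manifest(manifest: dict, out_dir, name: str) -> None:
    path = Path(out_dir) / f"{name}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float) + "\n")


# ------------------------------------------------------------------ proteome


def gen_proteome(cfg: GeneratorConfig, out_dir=None):
    """Synthetic ER-proteome: sequences with planted C-terminal signals.

    Canonical x-D-E-L tails are planted with the configured variant
    frequencies; the remainder get random non-canonical tails. Abundances are
    log-normal, then rescaled per variant so that the summed KDEL abundance is
    exactly ``abundance_ratio_k_h`` times the summed HDEL abundance (when both
    classes are non-empty). Returns (records, manifest); writes
    ``proteome.fasta``, ``abundance.tsv`` and the manifest if ``out_dir``.
    """
    rng = cfg.rng("proteome")
    variants = list(cfg.variant_frequencies)
    probs = np.array([cfg.variant_frequencies[v] for v in variants])
    p_other = 1.0 - probs.sum()
    choices = rng.choice(
        variants + ["__other__"],
        size=cfg.n_proteins,
        p=np.append(probs, p_other),
    )
    aa = np.array(list(AMINO_ACIDS))
    records = []
    labels = []
    for i, label in enumerate(choices):
        n = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        body = "".join(rng.choice(aa, size=n - 4))
        if label == "__other__":
            while True:
                tail = "".join(rng.choice(aa, size=4))
                if tail[1:] != "DEL":
                    break
        else:
            tail = label + "DEL"
        abundance = float(rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma))
        records.append(
            ProteinRecord(
                id=f"SYN{i:04d}",
                sequence=body + tail,
                abundance=abundance,
                unit=cfg.abundance_unit,
                source="synthetic",
            )
        )
        labels.append(label)
    labels = np.array(labels)

    if cfg.abundance_ratio_k_h is not None and {"K", "H"} <= set(variants):
        sum_k = sum(r.abundance for r, l in zip(records, labels) if l == "K")
        sum_h = sum(r.abundance for r, l in zip(records, labels) if l == "H")
        if sum_k > 0 and sum_h > 0:
            scale = cfg.abundance_ratio_k_h * sum_h / sum_k
            records = [
                ProteinRecord(r.id, r.sequence, r.abundance * scale, r.unit, r.source)
                if l == "K"
                else r
                for r, l in zip(records, labels)
            ]

    planted_counts = {v: int((labels == v).sum()) for v in variants}
    planted_counts["non_canonical"] = int((labels == "__other__").sum())
    planted_totals = {
        v: float(sum(r.abundance for r, l in zip(records, labels) if l == v))
        for v in variants
    }
    manifest = {
        "generator": "proteome",
        "seed": cfg.seed,
        "n_proteins": cfg.n_proteins,
        "variant_frequencies": cfg.variant_frequencies,
        "planted_counts": planted_counts,
        "planted_totals": planted_totals,
        "abundance_unit": cfg.abundance_unit,
        "planted_ratio_k_h": (
            planted_totals.get("K", 0.0) / planted_totals["H"]
            if planted_totals.get("H", 0.0) > 0
            else None
        ),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "proteome.fasta", "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.sequence}\n")
        pd.DataFrame(
            {
                "id": [r.id for r in records],
                "abundance": [r.abundance for r in records],
                "unit": [r.unit for r in records],
            }
        ).to_csv(out_dir / "abundance.tsv", sep="\t", index=False)
        _write_manifest(manifest, out_dir, "proteome")
    return records, manifest


# ------------------------------------------------------------ binding curves


def _four_pl_truth(x, top, bottom, hill, midpoint):
    return bottom + (top - bottom) / (1.0 + (x / midpoint) ** hill)


def gen_binding_curves(cfg: GeneratorConfig, out_dir=None):
    """Synthetic competition titrations: 4PL responses with multiplicative noise.

    Each curve gets parameters drawn from the configured ranges (midpoint
    log-uniform inside the x range) and responses y = 4PL(x)·exp(σZ). The
    manifest records the planted parameters, the tracer constants and the
    planted apparent K_D implied by the Cheng-Prusoff correction. Returns
    (DataFrame, manifest).
    """
    rng = cfg.rng("binding")
    x = np.geomspace(cfg.x_min_uM, cfg.x_max_uM, cfg.n_points)
    rows = []
    truths = []
    for i in range(cfg.n_curves):
        top = float(rng.uniform(*cfg.top_range))
        bottom = float(rng.uniform(*cfg.bottom_range))
        hill = float(rng.uniform(*cfg.hill_range))
        midpoint = float(
            np.exp(rng.uniform(*np.log(np.asarray(cfg.midpoint_range_uM))))
        )
        y_true = _four_pl_truth(x, top, bottom, hill, midpoint)
        y = y_true * np.exp(cfg.noise_sd * rng.standard_normal(cfg.n_points))
        for xj, yj in zip(x, y):
            rows.append(
                {
                    "assay_id": f"curve{i:03d}",
                    "x_uM": xj,
                    "y": yj,
                    "pH": 5.4,
                    "replicate": 1,
                    "condition": "competition",
                }
            )
        truths.append(
            {
                "assay_id": f"curve{i:03d}",
                "top": top,
                "bottom": bottom,
                "hill": hill,
                "ic50_uM": midpoint,
                "kd_uM": midpoint / (1.0 + cfg.hot_conc_uM / cfg.hot_kd_uM),
            }
        )
    df = pd.DataFrame(rows)
    manifest = {
        "generator": "binding",
        "seed": cfg.seed,
        "n_curves": cfg.n_curves,
        "n_points": cfg.n_points,
        "noise_sd": cfg.noise_sd,
        "hot_conc_uM": cfg.hot_conc_uM,
        "hot_kd_uM": cfg.hot_kd_uM,
        "curves": truths,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "binding.csv", index=False)
        _write_manifest(manifest, out_dir, "binding")
    return df, manifest


# ----------------------------------------------------------- alchemical legs


def gen_alchemical_legs(cfg: GeneratorConfig, out_dir=None):
    """Replicate alchemical-leg tables with exactly known cycle ground truth.

    Solution leg truths are taken from the config; complex deprotonation legs
    are offset so that the site pKas equal the planted targets
    (ΔG_site − ΔG_solution = 2.303·RT·ΔpKa), and the complex LYS→HIP leg is
    solved so that the full protonation-ensemble cycle gives exactly the
    planted ΔΔG_bind at zero noise. Replicates are drawn Normal(truth,
    leg_sd). Returns (DataFrame, manifest).
    """
    rng = cfg.rng("legs")
    ctx = thermo.ThermoContext(cfg.temperature)
    sol = dict(cfg.solution_leg_truths)
    shift_his = 2.303 * ctx.rt * (cfg.target_pka_his - thermo.DEFAULT_REFERENCE_PKA["HIS"])
    shift_lys = 2.303 * ctx.rt * (cfg.target_pka_lys - thermo.DEFAULT_REFERENCE_PKA["LYS"])
    cplx = {
        "LYS2LYN": sol["LYS2LYN"] + shift_lys,
        "HIP2HID": sol["HIP2HID"] + shift_his,
        "HIP2HIE": sol["HIP2HIE"] + shift_his,
    }

    def ensemble_dg(truths, residue):
        ref = thermo.ReferencePka.default(residue)
        trans = ["LYS2LYN"] if residue == "LYS" else ["HIP2HID", "HIP2HIE"]
        legs = [
            thermo.AlchemicalLeg(t, "solution", [truths[t]]) for t in trans if t in truths
        ]
        return thermo.ensemble_deprotonation(legs, ref, ctx).ensemble_dg

    dg_solution = (
        ensemble_dg(sol, "LYS") + sol["LYS2HIP"] - ensemble_dg(sol, "HIS")
    )
    # solve the complex LYS→HIP leg so the planted ΔΔG_bind holds exactly
    cplx["LYS2HIP"] = (
        cfg.target_ddg_bind
        + dg_solution
        - ensemble_dg(cplx, "LYS")
        + ensemble_dg(cplx, "HIS")
    )
    truths = {("complex", t): v for t, v in cplx.items()}
    truths.update({("solution", t): v for t, v in sol.items()})

    rows = []
    for (env, t), truth in sorted(truths.items()):
        for rep in range(1, cfg.n_replicates + 1):
            rows.append(
                {
                    "transformation": t,
                    "environment": env,
                    "replicate": rep,
                    "dG_kcal_mol": float(rng.normal(truth, cfg.leg_sd)),
                }
            )
    df = pd.DataFrame(rows)
    manifest = {
        "generator": "legs",
        "seed": cfg.seed,
        "temperature_K": cfg.temperature,
        "leg_sd_kcal_mol": cfg.leg_sd,
        "n_replicates": cfg.n_replicates,
        "leg_truths_kcal_mol": {f"{env}:{t}": v for (env, t), v in truths.items()},
        "planted_ddg_bind_kcal_mol": cfg.target_ddg_bind,
        "planted_dg_solution_kcal_mol": dg_solution,
        "planted_dg_complex_kcal_mol": dg_solution + cfg.target_ddg_bind,
        "planted_pka_his": cfg.target_pka_his,
        "planted_pka_lys": cfg.target_pka_lys,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "legs.csv", index=False)
        _write_manifest(manifest, out_dir, "legs")
    return df, manifest


# --------------------------------------------------------------- cell tables


def gen_cell_table(cfg: GeneratorConfig, out_dir=None):
    """Per-cell Golgi/total intensity table with planted condition means.

    Golgi fractions are Beta-distributed around the planted mean of each
    condition (common concentration parameter); total intensities are
    log-normal and the Golgi intensity is back-computed so golgi <= total
    holds by construction. Returns (DataFrame, manifest).
    """
    rng = cfg.rng("cells")
    rows = []
    for cond, mean in cfg.condition_means.items():
        a = mean * cfg.beta_concentration
        b = (1.0 - mean) * cfg.beta_concentration
        frac = rng.beta(a, b, size=cfg.n_cells)
        total = rng.lognormal(cfg.total_intensity_mu, cfg.total_intensity_sigma, cfg.n_cells)
        for i, (f, t) in enumerate(zip(frac, total)):
            rows.append(
                {
                    "cell_id": f"{cond}_{i:03d}",
                    "condition": cond,
                    "golgi_intensity": f * t,
                    "total_intensity": t,
                }
            )
    df = pd.DataFrame(rows)
    means = list(cfg.condition_means.values())
    manifest = {
        "generator": "cells",
        "seed": cfg.seed,
        "n_cells_per_condition": cfg.n_cells,
        "condition_means": cfg.condition_means,
        "planted_deltas_vs_first": {
            c: cfg.condition_means[c] - means[0] for c in cfg.condition_means
        },
        "beta_concentration": cfg.beta_concentration,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "cells.csv", index=False)
        _write_manifest(manifest, out_dir, "cells")
    return df, manifest


# ---------------------------------------------------------------- trajectory


def _default_occupancy_profiles(n_bins: int) -> dict[str, np.ndarray]:
    # handover: R47 engaged deep in the pocket, R169 at the entrance, R5 between
    ramp = np.linspace(0.05, 0.95, n_bins)
    bump = 0.1 + 0.8 * (1.0 - np.abs(np.linspace(-1.0, 1.0, n_bins)))
    return {"R169": ramp, "R47": ramp[::-1].copy(), "R5": bump}


def gen_trajectory(cfg: GeneratorConfig, out_dir=None):
    """Toy receptor/peptide trajectory with planted CV ramp, H-bonds and jitter.

    The receptor contributes rigid Cα atoms (the five pocket residues plus the
    arginine-ladder and W120 positions) and three Arg donor groups (N-H); the
    peptide contributes its N-terminal probe nitrogen and three carboxylate
    acceptor oxygens. Per frame, the probe sits at a linearly ramped CV
    distance from the pocket centroid, each hydrogen bond is made or broken
    to hit the planted per-bin occupancy exactly (deterministic within-bin
    assignment), and the flexible W120 side-chain atom gets isotropic Gaussian
    jitter of sd ``jitter_sd``. Returns (Trajectory, bonds, manifest).
    """
    rng = cfg.rng("trajectory")
    F = cfg.n_frames
    edges = DEFAULT_CV_BIN_EDGES_NM
    n_bins = len(edges) - 1
    profiles = cfg.occupancy_profiles or _default_occupancy_profiles(n_bins)
    for name, p in profiles.items():
        p = np.asarray(p, dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise ValueError(f"occupancy profile {name!r} outside [0, 1]")

    pocket = {9: (4, 0, 0), 44: (-4, 0, 0), 64: (0, 4, 0), 124: (0, -4, 0), 162: (0, 0, -4)}
    ladder = {5: (7, 7, 0), 47: (-7, 7, 0), 169: (7, -7, 0)}
    donors = {"R5": (5, "NH1"), "R47": (47, "NH1"), "R169": (169, "NH1")}
    donor_pos = {"R5": (6.0, 6.0, 2.0), "R47": (-6.0, 6.0, 2.0), "R169": (6.0, -6.0, 2.0)}
    acceptors = {"R5": (6, "OE1"), "R47": (7, "O"), "R169": (7, "OXT")}

    topo_rows = []
    static_pos = []

    def add(segment, resnum, resname, atom, pos):
        topo_rows.append(
            {
                "segment": segment,
                "residue_number": resnum,
                "residue_name": resname,
                "atom_name": atom,
            }
        )
        static_pos.append(pos)
        return len(topo_rows) - 1

    for r, pos in sorted({**pocket, **ladder}.items()):
        add("receptor", r, "ALA", "CA", pos)
    w120_idx = add("receptor", 120, "TRP", "CZ2", (2.0, 2.0, 1.0))
    donor_idx = {}
    hydro_idx = {}
    for name, (r, atom) in donors.items():
        donor_idx[name] = add("receptor", r, "ARG", atom, donor_pos[name])
        hydro_idx[name] = add("receptor", r, "ARG", "HH1", donor_pos[name])  # placed per frame
    pep_res = ["THR", "ALA", "GLU", "LYS", "ASP", "GLU", "LEU"]
    probe_idx = add("peptide", 1, pep_res[0], "N", (0.0, 0.0, 0.0))  # placed per frame
    accept_idx = {}
    for name, (r, atom) in acceptors.items():
        accept_idx[name] = add("peptide", r, pep_res[r - 1], atom, (0.0, 0.0, 0.0))

    topology = pd.DataFrame(topo_rows)
    base = np.array(static_pos, dtype=float)
    centroid = np.array([pocket[r] for r in sorted(pocket)], dtype=float).mean(axis=0)

    cv_nm = np.linspace(cfg.cv_start_nm, cfg.cv_end_nm, F)
    bin_idx = np.clip(np.digitize(cv_nm, edges) - 1, 0, n_bins - 1)

    # deterministic within-bin presence: first k frames of each bin are bonded
    present = {name: np.zeros(F, dtype=bool) for name in profiles}
    realized = {name: np.full(n_bins, np.nan) for name in profiles}
    for b in range(n_bins):
        members = np.flatnonzero(bin_idx == b)
        if members.size == 0:
            continue
        for name, p in profiles.items():
            k = int(round(float(np.asarray(p)[b]) * members.size))
            present[name][members[:k]] = True
            realized[name][b] = k / members.size

    frames = np.repeat(base[None, :, :], F, axis=0)
    u = np.array([0.0, 0.0, 1.0])  # bond axis: donor -> acceptor direction
    for f in range(F):
        frames[f, probe_idx] = centroid + cv_nm[f] * 10.0 * np.array([0, 0, 1.0])
        for name in profiles:
            d = np.array(donor_pos[name])
            frames[f, hydro_idx[name]] = d + 1.0 * u
            dist = 2.8 if present[name][f] else 6.0
            frames[f, accept_idx[name]] = d + dist * u
    frames[:, w120_idx, :] += rng.normal(0.0, cfg.jitter_sd, size=(F, 3))

    traj = Trajectory(topology=topology, frames=frames)
    bonds = [
        HBondDefinition(
            name=name,
            donor=("receptor", donors[name][0], donors[name][1]),
            hydrogen=("receptor", donors[name][0], "HH1"),
            acceptor=("peptide", acceptors[name][0], acceptors[name][1]),
        )
        for name in profiles
    ]
    manifest = {
        "generator": "trajectory",
        "seed": cfg.seed,
        "n_frames": F,
        "cv_start_nm": cfg.cv_start_nm,
        "cv_end_nm": cfg.cv_end_nm,
        "cv_values_nm_first_last": [float(cv_nm[0]), float(cv_nm[-1])],
        "bin_edges_nm": [float(e) for e in edges],
        "planted_occupancy": {k: [None if np.isnan(v) else float(v) for v in arr]
                              for k, arr in realized.items()},
        "jitter_sd_A": cfg.jitter_sd,
        "jitter_atom": {"segment": "receptor", "residue_number": 120, "atom_name": "CZ2"},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        traj.to_multimodel_pdb(out_dir / "trajectory.pdb")
        _write_manifest(manifest, out_dir, "trajectory")
    return traj, bonds, manifest


def generate_all(cfg: GeneratorConfig, out_dir) -> dict:
    """Run every generator into ``out_dir``; returns the combined manifests."""
    out_dir = Path(out_dir)
    manifests = {}
    _, manifests["proteome"] = gen_proteome(cfg, out_dir)
    _, manifests["binding"] = gen_binding_curves(cfg, out_dir)
    _, manifests["legs"] = gen_alchemical_legs(cfg, out_dir)
    _, manifests["cells"] = gen_cell_table(cfg, out_dir)
    _, _, manifests["trajectory"] = gen_trajectory(cfg, out_dir)
    return manifests
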