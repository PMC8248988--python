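# kdelquant

Quantitative analyses for ER retrieval by the KDEL receptor.

ER-resident luminal proteins carry a C-terminal tetrapeptide retrieval signal
(canonically **x-D-E-L**, where the variable −4 residue x is typically K, H or
R in mammals). A seven-transmembrane receptor captures these signals in the
mildly acidic Golgi and returns the cargo to the ER. `kdelquant` implements
the quantitative layer of this biology as a tested, reusable Python package:

- **`kdelquant.proteomics`** — extract and classify C-terminal signals from a
  proteome, build frequency- or abundance-weighted position-probability
  matrices (sequence-logo input) with per-column information content
  `log₂20 + Σᵢ pᵢⱼ log₂ pᵢⱼ`, and sum cellular abundance per signal variant.
- **`kdelquant.binding`** — fit competition titrations with the
  four-parameter logistic model
  `y = bottom + (top − bottom)/(1 + (x/IC₅₀)^h)` (log₁₀-x space), convert
  IC₅₀ to an apparent dissociation constant with the Cheng–Prusoff correction
  `K_D = IC₅₀/(1 + [hot]/K_D^hot)`, and convert K_D pairs to free-energy
  differences `ΔΔG = RT ln(K_D,a/K_D,b)`.
- **`kdelquant.thermo`** — protonation-ensemble bookkeeping for the
  KDEL→HDEL alchemical cycle: calibration offsets
  `ΔG_offset = 2.303RT(7 − pK_a)`, Boltzmann weights, configurational entropy
  `ΔS = −RΣw ln w`, ensemble deprotonation free energies, the cycle
  combination `ΔG_KDEL→HDEL = ΔG_LYS→LYS/N + ΔG_LYS→HIP − ΔG_HIP→HIP/D/E`,
  binding ΔΔG (complex − solution) and site pK_a shifts.
- **`kdelquant.estimation`** — estimation statistics for cell-based retrieval
  assays: per-cell Golgi fraction, bootstrap mean differences with 95%
  bias-corrected-and-accelerated (BCa) intervals, and two-sided permutation
  p-values (defaults: 5000 bootstrap samples, 5000 reshuffles).
- **`kdelquant.structure`** — Cα superposition of receptor models (Kabsch,
  reflection-corrected) and plain RMSD over the paired trace.
- **`kdelquant.trajectory`** — the binding-pocket collective variable
  (peptide N-terminal N to the centroid of the Cα atoms of residues 9, 44,
  64, 124, 162), hydrogen-bond occupancy binned along it, and per-atom RMSF
  after iterative superposition.
- **`kdelquant.synthetic`** — seeded generators with truth manifests for
  every stage, so the whole pipeline is exercisable without downloads.

Model-fitting stages follow the statsmodels convention: a model object built
from data whose `fit()` returns a results object with estimates,
uncertainties and a `summary()` (`DoseResponseModel`, `ProtonationCycleModel`,
`TwoSampleEstimation`).

## Worked example

Convert the measured affinities (HDEL K_D = 0.24 µM, KDEL K_D = 1.94 µM) to a
binding free-energy difference, then run the full protonation-cycle analysis
on a synthetic alchemical-leg table whose planted ground truth is
ΔΔG = −1.8 kcal/mol and site pK_a(His) = 8.9:

```python
from kdelquant import binding as bd, synthetic as sy, thermo as th

e = bd.ddg_from_kd(0.24, 1.94, temperature=310.0)
print(round(e.ddg, 3), round(e.fold_ratio, 1))   # -1.287  8.1

legs, truth = sy.gen_alchemical_legs(sy.GeneratorConfig(seed=17))
res = th.ProtonationCycleModel.from_dataframe(legs).fit(n_mc=10000, seed=17)
print(res.summary())
```

```
KDEL→HDEL protonation-cycle analysis (T = 310 K, mc errors)
  ΔG_KDEL→HDEL (complex) :  -36.887 ± 0.133 kcal/mol
  ΔG_KDEL→HDEL (solution):  -35.151 ± 0.348 kcal/mol
  ΔΔG_bind (complex − solution):   -1.736 ± 0.373 kcal/mol
  site pKa (complex vs solution):
    LYS2LYN: 10.03
    HIP2HID: 8.56
    HIP2HIE: 8.91
```

The −1.287 kcal/mol from the measured K_D pair says HDEL binds ~8-fold more
tightly than KDEL at 310 K; the cycle analysis on the noisy synthetic legs
(replicate sd 0.5 kcal/mol, 3 replicates/leg) recovers the planted
−1.8 kcal/mol within its propagated uncertainty, and the elevated histidine
pK_a (~8.9 vs the solution reference 6.0) reflects the planted stabilisation
of the protonated imidazole in the binding pocket.

A cell-assay comparison works the same way:

```python
from kdelquant import estimation as es
df, _ = sy.gen_cell_table(sy.GeneratorConfig(seed=17))
r = es.TwoSampleEstimation.from_dataframe(df, "no_ligand", "KDEL").fit(
    n_boot=5000, n_perm=5000, seed=17)
print(r.summary())
```

```
Mean difference: KDEL − no_ligand
  n = 40 vs 40
  Δmean = -0.3986  95% BCa CI [-0.4245, -0.3732]  (5000 bootstrap samples)
  permutation p = 0  (5000 reshuffles)
```

i.e. the ligand pulls the receptor's Golgi fraction down by ~0.40 — near the
planted −0.4 effect — with a CI that excludes zero and a permutation p below
the 1/5000 resolution floor.

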