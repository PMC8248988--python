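# Methods

This note records the models implemented in `kdelquant`, their assumptions,
the defaults that matter, and what the synthetic generators do and do not
emulate.

## Retrieval-signal proteomics

A protein's retrieval signal is its last four residues; the −4 residue
defines the variant (K/H/R/A/D…), and a signal is canonical when positions
−3…−1 are D-E-L. An extended suffix set adding x-E-E-L (seen on some
FKBP-family ER residents) is available but off by default. Motif matrices
are built over a C-terminal window of L residues (default **L = 6**: the
positions beyond −4 carry little conservation, but a 6-residue window shows
this rather than assuming it). Columns are position-probability vectors;
information content is `log₂20 + Σ p log₂ p` bits with no small-sample
correction (an opt-in flag exists but defaults off, since the plain estimator
is what abundance-weighted logos conventionally use). In abundance mode each
protein is weighted by its abundance; units are metadata only and mixing
units is an error rather than a silent conversion. `X` residues contribute
to no amino-acid row but keep their weight in the column denominator where
they occur — inventing a composition for unknown residues would bias the
logo upward.

## Binding analysis

The 4PL model is fitted in log₁₀-concentration space by bounded nonlinear
least squares (trust-region reflective), initialised at top = max(y),
bottom = min(y), Hill slope 1, midpoint at the median log-concentration, with
the Hill slope constrained to [0.1, 10]. Parameters are canonicalised so
top ≥ bottom. Standard errors come from the Gauss–Newton covariance
`s²(JᵀJ)⁻¹`; the midpoint SE is mapped from log space by the delta method.
Zero-concentration points cannot sit on a log axis; they are placed at half
the smallest nonzero concentration and the fit is flagged. Fewer than five
distinct concentrations is an error, not a warning — a 4-parameter model on
fewer support points is unidentifiable.

The Cheng–Prusoff correction `K_D = IC₅₀/(1 + [hot]/K_D^hot)` uses a default
tracer concentration of **0.01 µM** (a 20 nM tracer stock diluted 1:1 with
receptor) and treats the tracer K_D as a fixed constant, so the reported
uncertainty is the IC₅₀ standard error divided by the same factor.

`ddg_from_kd` uses R = 1.98720425×10⁻³ kcal/(mol·K) and defaults to
**T = 310 K**. The temperature is configurable — binding assays are commonly
run near room temperature, and at 293 K the same K_D pair gives ≈ −1.22
rather than −1.29 kcal/mol — but 310 K matches the simulation conditions the
cycle analysis uses, so the two energy scales are directly comparable. The
fold ratio is additionally reported rounded to one significant figure, the
convention used when quoting e.g. a "60-fold" affinity difference.

## Protonation-ensemble cycle

Relative binding free energies between KDEL and HDEL signals are assembled
from per-leg alchemical free energies (this package consumes per-leg ΔG
values; estimating them from raw alchemical samples is upstream of its
scope). Because the histidine of HDEL has three accessible protonation
states (HIP, HID, HIE) and the lysine of KDEL two (LYS, LYN), each endpoint
is a Boltzmann ensemble:

- calibration offset `ΔG_offset = 2.303RT(7.0 − pK_a_ref)` with reference
  microscopic pK_a values His 6.0 and Lys 8.95, anchoring computed
  deprotonation free energies to experiment at pH 7;
- effective free energies {0, ΔG_leg − ΔG_offset} with the protonated state
  as reference;
- weights `w = e^(−ΔG/RT)/Σe^(−ΔG/RT)` **computed over those effective free
  energies** — the equations as usually written list weights and effective
  ΔGs without pinning down the weight argument, and this self-consistent
  choice (weights and averaged energies from the same quantities) is the
  design decision made here;
- configurational entropy `ΔS = −RΣw ln w`, bounded by R ln n and attained
  only for uniform ensembles;
- ensemble free energy `Σ w·ΔG_eff − TΔS`, which correctly vanishes in the
  fully protonated limit;
- cycle `ΔG_KDEL→HDEL = ΔG_LYS→LYS/N + ΔG_LYS→HIP − ΔG_HIP→HIP/D/E` per
  environment, and `ΔΔG_bind = ΔG(complex) − ΔG(solution)`.

Leg tables identify transformations by the canonical labels LYS2LYN,
LYS2HIP, HIP2HID, HIP2HIE; a reversed label (e.g. HID2HIP) is rejected with
a hint to negate and relabel, preventing silent sign errors.

Site pK_a uses the standard thermodynamic-cycle shift
`pK_a = pK_a_ref + (ΔG_deprot,site − ΔG_deprot,solution)/(2.303RT)`; this
formula is an interpretation choice (several calibrations are possible) and
is stated here rather than hidden. `fraction_protonated` is plain
Henderson–Hasselbalch.

Uncertainty propagation: the default is Monte-Carlo resampling of each leg
mean from Normal(mean, sd/√n_rep) with 10,000 draws and a caller-supplied
seed; a quadrature mode (numerical gradient × leg SE, summed in quadrature)
is available and agrees with Monte-Carlo in the small-noise limit, which the
tests check. With three replicates per leg the SE estimate itself carries
only two degrees of freedom, so standardized errors have Student-t(2) tails;
±2·SE intervals therefore cover the truth in roughly 82–90% of repetitions,
not 95% — the calibration tests use the t-based expectation.

## Estimation statistics

The per-cell statistic is the Golgi fraction (marker-defined Golgi
integrated intensity over whole-cell intensity), validated to lie in [0, 1].
Effects are mean differences (test − control) with, by default, 5000
independent group resamples for the bootstrap and 5000 label reshuffles for
the two-sided permutation p-value. The BCa interval computes the bias
correction z₀ from the fraction of bootstrap replicates below the observed
statistic (clipped away from 0/1 so z₀ stays finite) and the acceleration
from the jackknife skewness of leave-one-out statistics over both groups; it
reduces exactly to the percentile interval when both corrections vanish.
The p-value is the plain proportion of reshuffles with |Δmean| at least the
observed value, ties counted as exceeding (conservative); a (b+1)/(B+1)
variant is available by flag. Resampling is unstratified — there is no
coverslip/experiment stratification by default, though grouping can be done
upstream. Shared-control designs are computed as independent two-group
comparisons against the shared control. Degenerate zero-variance inputs
collapse the interval to the point estimate and are flagged rather than
erroring.

## Structure superposition

Atoms are paired by residue-number intersection on one chain of each model
(the first chain by default), restricted to Cα. The optimal rotation is the
closed-form SVD solution with the reflection branch excluded (det = +1
always), and the RMSD is the plain root-mean-square paired distance — no
outlier rejection or trimming, so the number reported is over all paired
atoms. mmCIF and PDB are read through gemmi; hydrogens are removed and for
alternate locations the highest-occupancy conformer is kept, which makes the
atom pairing deterministic. The solver is cross-checked in the tests against
a brute-force random-rotation search with derivative-free polish and against
an independent vector-alignment implementation.

## Trajectory analysis

The collective variable is the Euclidean distance from the peptide's
N-terminal nitrogen to the unweighted centroid of the Cα atoms of receptor
residues 9, 44, 64, 124 and 162, computed in Å internally and reported in
nm. Default CV bins are 0.1 nm wide from 1.8 to 3.3 nm, mirroring a
16-window umbrella layout over that range.

A hydrogen bond is present in a frame when the donor–acceptor heavy-atom
distance is ≤ **3.5 Å** and the D–H···A angle is ≥ **150°**; both cutoffs
are configurable since no single geometric criterion is canonical. When the
topology carries no hydrogen (coarse fixtures), a tighter distance-only
criterion (3.0 Å) applies and the profile is flagged. Occupancy per CV bin
is the fraction of that bin's frames with the bond present; empty bins are
reported as missing (NaN), never as zero, because "no data" and "never
bonded" are different statements.

RMSF superposes every frame onto the mean structure over the alignment
selection (receptor Cα by default), recomputes the mean and aligns once
more, then reports per-atom `√⟨|r − ⟨r⟩|²⟩`. Isotropic Gaussian jitter of sd
σ gives RMSF = σ√3, which the tests verify to 5% at 2000 frames (the
Monte-Carlo error of the RMSF estimate itself is ~1/√(2F) ≈ 1.6% there, so
tighter tolerances at fewer frames would test the noise, not the code).

## Synthetic data: what it does and does not emulate

Each generator draws from its own stream, derived from the master seed by a
stable hash of the generator name, so outputs are byte-reproducible and
independent of call order. Every planted parameter lands in a JSON manifest.

- **Proteome** (default n = 300, K/H/R frequencies 0.25 each, remainder
  non-canonical tails): log-normal abundances (log-sd 1.5, a typical span
  for per-protein copy numbers), with the KDEL class rescaled so
  ΣKDEL/ΣHDEL = 5.5 exactly — emulating the observation that KDEL-bearing
  proteins dominate total ER-resident abundance several-fold. Sequence
  bodies are i.i.d. uniform amino acids: no real composition, no homology,
  no signal-peptide structure.
- **Binding curves** (default 100 curves, 8 log-spaced points from 1 nM to
  100 µM, 5% multiplicative log-normal noise): parameters drawn per curve,
  midpoints log-uniform in [0.05, 20] µM — spanning the sub-µM to tens-of-µM
  range of measured signal affinities. Real titrations share plates,
  replicates and heteroscedastic counting error; none of that is modelled.
- **Alchemical legs** (3 replicates, sd 0.5 kcal/mol): solution truths are
  fixed so calibrated effective deprotonation energies are O(RT) (genuinely
  mixed ensembles); complex deprotonation legs are shifted to plant site
  pK_a values (His 8.9, Lys 10.2), and the complex LYS→HIP leg is solved so
  the full nonlinear cycle yields exactly ΔΔG_bind = −1.8 kcal/mol. Noise is
  i.i.d. normal per replicate — no correlated sampling error between legs.
- **Cell tables** (40 cells/condition): Golgi fractions Beta-distributed
  around planted means (concentration 50, i.e. sd ≈ 0.07 at mean 0.5);
  default conditions no_ligand 0.55 vs KDEL 0.15, a −0.4 retrieval effect.
  Real data have per-experiment batch structure and segmentation artefacts;
  the generator has neither, so passing tests demonstrate correct inference,
  not robustness to batch effects.
- **Trajectories** (default 300 frames; 2000 where RMSF precision matters):
  a toy topology (pocket Cα atoms, three Arg donor groups, W120 side-chain
  atom, peptide probe and carboxylate acceptors) with a linear CV ramp
  1.8→3.3 nm, hydrogen bonds switched deterministically within each CV bin
  to hit planted occupancies exactly, and Gaussian jitter on the flexible
  atom. This is bookkeeping ground truth, not physics: no force field, no
  correlated dynamics.

## Problem sizes and numerical choices

Simulated calibrations use 200 seeds for cycle coverage, 1000 simulations ×
500 reshuffles for the permutation null, 100 curves for IC₅₀ bias and 2000
frames for RMSF — sizes at which the Monte-Carlo error of each check is
several times smaller than its tolerance. Boltzmann weights use
max-subtraction so arbitrarily large ΔGs cannot overflow; `0·log 0` is taken
as 0 throughout; permutation ties count as exceeding; the 4PL optimiser runs
with tolerances at 1e-14 so zero-noise recovery is limited by conditioning,
not iteration count.

## Known limitations

- The cross-structure RMSD of deposited receptor models depends on the exact
  residue selection; with a different common-residue intersection the third
  decimal will move.
- BCa intervals on very small groups (n ≈ 3–5) inherit the usual bootstrap
  small-sample caveats; the implementation does not try to correct for them.
- The site-pK_a calibration (complex vs solution legs) is one of several
  defensible conventions; comparisons across packages should check which
  convention is in use.
- No depletion or two-site binding in the competition model; curves from
  strongly depleted assays will bias the IC₅₀.
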