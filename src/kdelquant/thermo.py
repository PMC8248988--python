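"""Protonation-ensemble free-energy bookkeeping for the KDEL→HDEL alchemical cycle.

The relative binding free energy of HDEL versus KDEL retrieval signals is
assembled from per-leg alchemical transformation free energies computed in two
environments (receptor-peptide complex and peptide free in solution). Because
the -4 histidine of HDEL can occupy three protonation states (HIP protonated;
HID/HIE neutral tautomers) and the lysine of KDEL two (LYS protonated; LYN
neutral), each endpoint is treated as a Boltzmann-weighted protonation
ensemble rather than a single state:

    ΔG_offset        = 2.303 RT (7.0 − pKa_ref)          (pKa calibration)
    w_i              = exp(−ΔG_i/RT) / Σ_j exp(−ΔG_j/RT)  (state weights)
    ΔS               = −R Σ_i w_i ln w_i                  (configurational entropy)
    ΔG_X→ensemble    = Σ_i w_i ΔG_i,eff − T ΔS
    ΔG_KDEL→HDEL     = ΔG_LYS→LYS/N + ΔG_LYS→HIP − ΔG_HIP→HIP/D/E
    ΔΔG_bind         = ΔG_KDEL→HDEL(complex) − ΔG_KDEL→HDEL(solution)

where ΔG_i,eff = 0 for the protonated reference state and ΔG_i − ΔG_offset for
each deprotonated state. Weights are computed over these effective free
energies (self-consistent choice; documented in docs/methods.md). The same
per-leg inputs also yield a site pKa via the thermodynamic-cycle shift

    pKa_site = pKa_ref + (ΔG_deprot,site − ΔG_deprot,solution) / (2.303 RT).

All free energies are in kcal/mol; R = 1.98720425e-3 kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoContext",
    "ProtonationState",
    "ReferencePka",
    "AlchemicalLeg",
    "ProtonationEnsemble",
    "CycleResult",
    "calibration_offset",
    "boltzmann_weights",
    "configurational_entropy",
    "ensemble_deprotonation",
    "combine_cycle",
    "relative_binding_ddg",
    "site_pka",
    "fraction_protonated",
    "ProtonationCycleModel",
    "CycleResults",
]

GAS_CONSTANT_KCAL = 1.98720425e-3  # kcal/(mol·K)

#: protonation-state labels: protonated flag and parent residue
STATE_TABLE = {
    "LYS": ("LYS", True),
    "LYN": ("LYS", False),
    "HIP": ("HIS", True),
    "HID": ("HIS", False),
    "HIE": ("HIS", False),
}

#: canonical transformation labels accepted in leg tables
TRANSFORMATIONS = ("LYS2LYN", "LYS2HIP", "HIP2HID", "HIP2HIE")

DEFAULT_REFERENCE_PKA = {"HIS": 6.0, "LYS": 8.95}


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and gas constant; RT precomputed in kcal/mol."""

    temperature: float = 310.0
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class ProtonationState:
    label: str

    def __post_init__(self) -> None:
        if self.label not in STATE_TABLE:
            raise ValueError(f"unknown protonation state {self.label!r}")

    @property
    def residue(self) -> str:
        return STATE_TABLE[self.label][0]

    @property
    def protonated(self) -> bool:
        return STATE_TABLE[self.label][1]


@dataclass(frozen=True)
class ReferencePka:
    """Experimental microscopic pKa anchoring the calibration offset."""

    residue: str
    pka: float

    @classmethod
    def default(cls, residue: str) -> "ReferencePka":
        return cls(residue, DEFAULT_REFERENCE_PKA[residue])


@dataclass
class AlchemicalLeg:
    """Replicate free energies (kcal/mol) of one transformation in one environment.

    ``transformation`` is one of the canonical labels LYS2LYN, LYS2HIP,
    HIP2HID, HIP2HIE; reversed legs must be negated by the caller before
    construction (reversed labels are rejected to prevent sign mistakes).
    """

    transformation: str
    environment: str  # 'complex' | 'solution'
    replicates: list[float]

    def __post_init__(self) -> None:
        if self.transformation not in TRANSFORMATIONS:
            rev = self.transformation[4:] + "2" + self.transformation[:3]
            hint = (
                f" (did you mean {rev}? negate the replicate values and relabel)"
                if rev in TRANSFORMATIONS
                else ""
            )
            raise ValueError(f"unknown transformation {self.transformation!r}{hint}")
        if self.environment not in ("complex", "solution"):
            raise ValueError("environment must be 'complex' or 'solution'")
        if len(self.replicates) < 1:
            raise ValueError("need >= 1 replicate")
        self.replicates = [float(g) for g in self.replicates]

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0

    @property
    def start_state(self) -> str:
        return self.transformation[:3]

    @property
    def end_state(self) -> str:
        return self.transformation[4:]


def calibration_offset(ref: ReferencePka, ctx: ThermoContext) -> float:
    """ΔG_offset = 2.303 RT (7.0 − pKa), kcal/mol.

    Anchors a computed deprotonation free energy to the residue's experimental
    microscopic pKa, referenced to pH 7.
    """
    return 2.303 * ctx.rt * (7.0 - ref.pka)


def boltzmann_weights(effective_dg: Sequence[float], ctx: ThermoContext) -> np.ndarray:
    """Normalised Boltzmann weights exp(−ΔG/RT)/Σexp(−ΔG/RT).

    Uses max-subtraction so arbitrarily large ΔG values cannot overflow.
    """
    g = np.asarray(effective_dg, dtype=float)
    if g.size == 0:
        raise ValueError("empty free-energy list")
    if not np.isfinite(g).all():
        raise ValueError("free energies must be finite")
    z = -(g - g.min()) / ctx.rt
    e = np.exp(z)
    return e / e.sum()


def configurational_entropy(weights: Sequence[float], ctx: ThermoContext) -> tuple[float, float]:
    """ΔS = −R Σ w ln w (kcal/(mol·K)) and the −TΔS term (kcal/mol)."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        wlnw = np.where(w > 0, w * np.log(w), 0.0)
    ds = -ctx.gas_constant * float(wlnw.sum())
    return ds, -ctx.temperature * ds


@dataclass
class ProtonationEnsemble:
    """Boltzmann ensemble of one residue's protonation states.

    ``ensemble_dg`` is the free energy of going from the fully protonated
    state to the equilibrium mixture: Σ w·ΔG_eff − TΔS.
    """

    states: list[str]
    effective_dg: np.ndarray
    weights: np.ndarray
    entropy: float  # kcal/(mol·K)
    minus_t_ds: float
    ensemble_dg: float
    residue: str = ""

    @property
    def fraction_protonated(self) -> float:
        return float(
            sum(w for s, w in zip(self.states, self.weights) if STATE_TABLE[s][1])
        )


def ensemble_deprotonation(
    legs: Sequence[AlchemicalLeg], ref: ReferencePka, ctx: ThermoContext
) -> ProtonationEnsemble:
    """Combine deprotonation legs of one residue into a protonation ensemble.

    ``legs`` are the deprotonation transformations of a single residue in a
    single environment (LYS2LYN for lysine; HIP2HID and/or HIP2HIE for
    histidine). The protonated state is the reference with effective ΔG = 0;
    each deprotonated state contributes ΔG_leg − ΔG_offset. With no legs the
    residue is fully protonated and the ensemble free energy is 0.
    """
    states = [_protonated_reference(ref.residue)]
    eff = [0.0]
    envs = {leg.environment for leg in legs}
    if len(envs) > 1:
        raise ValueError(f"legs span multiple environments: {sorted(envs)}")
    offset = calibration_offset(ref, ctx)
    for leg in legs:
        start = ProtonationState(leg.start_state)
        end = ProtonationState(leg.end_state)
        if start.residue != ref.residue:
            raise ValueError(
                f"leg {leg.transformation} is a {start.residue} transformation, "
                f"expected {ref.residue}"
            )
        if not start.protonated or end.protonated:
            raise ValueError(f"leg {leg.transformation} is not a deprotonation")
        states.append(end.label)
        eff.append(leg.mean - offset)
    eff_arr = np.array(eff)
    w = boltzmann_weights(eff_arr, ctx)
    ds, mtds = configurational_entropy(w, ctx)
    dg = float(np.dot(w, eff_arr)) + mtds
    return ProtonationEnsemble(
        states=states,
        effective_dg=eff_arr,
        weights=w,
        entropy=ds,
        minus_t_ds=mtds,
        ensemble_dg=dg,
        residue=ref.residue,
    )


def _protonated_reference(residue: str) -> str:
    return {"LYS": "LYS", "HIS": "HIP"}[residue]


@dataclass
class CycleResult:
    """ΔG_KDEL→HDEL in one environment, with its three components."""

    dg_kdel_to_hdel: float
    uncertainty: float
    components: dict[str, float]
    environment: str = ""


def combine_cycle(
    lys_ensemble: ProtonationEnsemble,
    hip_ensemble: ProtonationEnsemble,
    lys_to_hip: AlchemicalLeg,
    ctx: ThermoContext,
    uncertainty: float = float("nan"),
    environment: str = "",
) -> CycleResult:
    """ΔG_KDEL→HDEL = ΔG_LYS→LYS/N + ΔG_LYS→HIP − ΔG_HIP→HIP/D/E."""
    if lys_ensemble.residue != "LYS" or hip_ensemble.residue != "HIS":
        raise ValueError("need a LYS ensemble and a HIS ensemble, in that order")
    comp = {
        "lys_ensemble": lys_ensemble.ensemble_dg,
        "lys_to_hip": lys_to_hip.mean,
        "hip_ensemble": hip_ensemble.ensemble_dg,
    }
    dg = comp["lys_ensemble"] + comp["lys_to_hip"] - comp["hip_ensemble"]
    return CycleResult(
        dg_kdel_to_hdel=dg,
        uncertainty=uncertainty,
        components=comp,
        environment=environment,
    )


def relative_binding_ddg(complex_result: CycleResult, solution_result: CycleResult) -> float:
    """ΔΔG_bind = ΔG(complex) − ΔG(solution); negative favours the end state (HDEL)."""
    return complex_result.dg_kdel_to_hdel - solution_result.dg_kdel_to_hdel


def site_pka(
    deprot_site: AlchemicalLeg,
    deprot_solution: AlchemicalLeg,
    ref: ReferencePka,
    ctx: ThermoContext,
) -> float:
    """pKa of a residue at its binding site from a deprotonation cycle.

    pKa = pKa_ref + (ΔG_deprot,site − ΔG_deprot,solution)/(2.303 RT): a site
    that disfavours deprotonation relative to solution raises the pKa.
    """
    if deprot_site.transformation != deprot_solution.transformation:
        raise ValueError(
            "site and solution legs must be the same transformation "
            f"({deprot_site.transformation} vs {deprot_solution.transformation})"
        )
    start = ProtonationState(deprot_site.start_state)
    if start.residue != ref.residue:
        raise ValueError("reference pKa residue does not match the legs")
    shift = (deprot_site.mean - deprot_solution.mean) / (2.303 * ctx.rt)
    return ref.pka + shift


def fraction_protonated(pka: float, pH: float) -> float:
    """Henderson-Hasselbalch protonated fraction 1/(1+10^(pH − pKa))."""
    return 1.0 / (1.0 + 10.0 ** (pH - pka))


# ------------------------------------------------------------- model object


class ProtonationCycleModel:
    """Full KDEL→HDEL protonation-cycle analysis over a table of alchemical legs.

    Built from a tidy leg table (columns: transformation, environment,
    replicate, dG_kcal_mol); ``fit()`` assembles per-environment protonation
    ensembles, the KDEL→HDEL cycle in each environment, the binding ΔΔG
    (complex minus solution) and the site pKas, with Monte-Carlo uncertainty
    propagation over the replicate leg means.
    """

    def __init__(
        self,
        legs: Sequence[AlchemicalLeg],
        context: ThermoContext | None = None,
        reference_pkas: Mapping[str, float] | None = None,
    ):
        self.context = context or ThermoContext()
        pkas = dict(DEFAULT_REFERENCE_PKA)
        if reference_pkas:
            pkas.update(reference_pkas)
        self.reference_pkas = pkas
        self._legs: dict[tuple[str, str], AlchemicalLeg] = {}
        for leg in legs:
            key = (leg.transformation, leg.environment)
            if key in self._legs:
                raise ValueError(f"duplicate leg {key}")
            self._legs[key] = leg
        for env in ("complex", "solution"):
            if ("LYS2HIP", env) not in self._legs:
                raise KeyError(f"missing required leg ('LYS2HIP', {env!r})")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ProtonationCycleModel":
        required = {"transformation", "environment", "dG_kcal_mol"}
        if not required <= set(df.columns):
            raise ValueError(f"leg table needs columns {sorted(required)}")
        legs = [
            AlchemicalLeg(t, env, grp["dG_kcal_mol"].tolist())
            for (t, env), grp in df.groupby(["transformation", "environment"], sort=True)
        ]
        return cls(legs, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ProtonationCycleModel":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    def _leg(self, transformation: str, environment: str) -> AlchemicalLeg | None:
        return self._legs.get((transformation, environment))

    def _cycle_for_env(
        self, environment: str, leg_means: Mapping[tuple[str, str], float] | None = None
    ) -> CycleResult:
        def mean_of(t):
            leg = self._leg(t, environment)
            if leg is None:
                return None
            if leg_means is not None:
                return leg_means[(t, environment)]
            return leg.mean

        def leg_with_mean(t):
            leg = self._leg(t, environment)
            if leg is None:
                return None
            m = mean_of(t)
            out = AlchemicalLeg(leg.transformation, leg.environment, [m])
            return out

        ctx = self.context
        lys_legs = [l for l in [leg_with_mean("LYS2LYN")] if l is not None]
        his_legs = [l for l in [leg_with_mean("HIP2HID"), leg_with_mean("HIP2HIE")] if l is not None]
        lys_ens = ensemble_deprotonation(
            lys_legs, ReferencePka("LYS", self.reference_pkas["LYS"]), ctx
        )
        hip_ens = ensemble_deprotonation(
            his_legs, ReferencePka("HIS", self.reference_pkas["HIS"]), ctx
        )
        lys2hip = leg_with_mean("LYS2HIP")
        return combine_cycle(lys_ens, hip_ens, lys2hip, ctx, environment=environment)

    def fit(
        self, n_mc: int = 10_000, seed: int | None = None, method: str = "mc"
    ) -> "CycleResults":
        """Compute the cycle, ΔΔG_bind and pKas, with uncertainty propagation.

        ``method='mc'`` resamples each leg mean from Normal(mean, sd/√n_rep)
        (``n_mc`` draws, seeded); ``method='quadrature'`` propagates leg
        standard errors in quadrature through the (approximately linear) cycle
        combination.
        """
        ctx = self.context
        complex_cycle = self._cycle_for_env("complex")
        solution_cycle = self._cycle_for_env("solution")
        ddg = relative_binding_ddg(complex_cycle, solution_cycle)

        pkas: dict[str, float] = {}
        for residue, trans in (("LYS", "LYS2LYN"), ("HIS", "HIP2HID"), ("HIS", "HIP2HIE")):
            site = self._leg(trans, "complex")
            sol = self._leg(trans, "solution")
            if site is not None and sol is not None:
                pkas[trans] = site_pka(
                    site, sol, ReferencePka(residue, self.reference_pkas[residue]), ctx
                )

        se = {
            key: leg.sd / math.sqrt(len(leg.replicates)) for key, leg in self._legs.items()
        }
        if method == "quadrature":
            unc = self._quadrature_uncertainty(se)
            ddg_sd, cyc_sd = unc
        elif method == "mc":
            ddg_sd, cyc_sd = self._mc_uncertainty(se, n_mc, seed)
        else:
            raise ValueError(f"unknown method {method!r}")
        complex_cycle.uncertainty = cyc_sd["complex"]
        solution_cycle.uncertainty = cyc_sd["solution"]
        return CycleResults(
            model=self,
            complex_cycle=complex_cycle,
            solution_cycle=solution_cycle,
            ddg_bind=ddg,
            ddg_bind_sd=ddg_sd,
            site_pkas=pkas,
            method=method,
        )

    def _quadrature_uncertainty(self, se):
        # the cycle is linear in each leg mean to first order; weights vary
        # slowly, so quadrature over the three (or four) leg SEs is a good
        # small-noise approximation
        cyc_sd = {}
        for env in ("complex", "solution"):
            var = 0.0
            base = self._cycle_for_env(env)
            for t in TRANSFORMATIONS:
                key = (t, env)
                if key not in self._legs or se[key] == 0:
                    continue
                h = max(1e-4, 1e-3 * se[key])
                means = {k: leg.mean for k, leg in self._legs.items()}
                means[key] += h
                bumped = self._cycle_for_env(env, means)
                grad = (bumped.dg_kdel_to_hdel - base.dg_kdel_to_hdel) / h
                var += (grad * se[key]) ** 2
            cyc_sd[env] = math.sqrt(var)
        ddg_sd = math.sqrt(cyc_sd["complex"] ** 2 + cyc_sd["solution"] ** 2)
        return ddg_sd, cyc_sd

    def _mc_uncertainty(self, se, n_mc, seed):
        rng = np.random.default_rng(seed)
        draws = {"complex": np.empty(n_mc), "solution": np.empty(n_mc)}
        keys = list(self._legs)
        samples = {
            k: rng.normal(self._legs[k].mean, se[k], size=n_mc) for k in keys
        }
        for i in range(n_mc):
            means = {k: samples[k][i] for k in keys}
            for env in ("complex", "solution"):
                draws[env][i] = self._cycle_for_env(env, means).dg_kdel_to_hdel
        cyc_sd = {env: float(np.std(draws[env], ddof=1)) for env in draws}
        ddg_sd = float(np.std(draws["complex"] - draws["solution"], ddof=1))
        return ddg_sd, cyc_sd


@dataclass
class CycleResults:
    """Fitted protonation-cycle quantities with propagated uncertainties."""

    model: ProtonationCycleModel
    complex_cycle: CycleResult
    solution_cycle: CycleResult
    ddg_bind: float
    ddg_bind_sd: float
    site_pkas: dict[str, float]
    method: str

    def summary(self) -> str:
        c, s = self.complex_cycle, self.solution_cycle
        lines = [
            "KDEL→HDEL protonation-cycle analysis "
            f"(T = {self.model.context.temperature:.6g} K, {self.method} errors)",
            f"  ΔG_KDEL→HDEL (complex) : {c.dg_kdel_to_hdel:+8.3f} ± {c.uncertainty:.3f} kcal/mol",
            f"  ΔG_KDEL→HDEL (solution): {s.dg_kdel_to_hdel:+8.3f} ± {s.uncertainty:.3f} kcal/mol",
            f"  ΔΔG_bind (complex − solution): {self.ddg_bind:+8.3f} ± {self.ddg_bind_sd:.3f} kcal/mol",
        ]
        if self.site_pkas:
            lines.append("  site pKa (complex vs solution):")
            for t, p in self.site_pkas.items():
                lines.append(f"    {t}: {p:.2f}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "temperature_K": self.model.context.temperature,
            "dg_kdel_to_hdel_complex": self.complex_cycle.dg_kdel_to_hdel,
            "dg_kdel_to_hdel_solution": self.solution_cycle.dg_kdel_to_hdel,
            "components_complex": self.complex_cycle.components,
            "components_solution": self.solution_cycle.components,
            "ddg_bind_kcal_mol": self.ddg_bind,
            "ddg_bind_sd_kcal_mol": self.ddg_bind_sd,
            "site_pkas": self.site_pkas,
            "uncertainty_method": self.method,
        }
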