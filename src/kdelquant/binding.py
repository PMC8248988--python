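"""Saturation/competition binding analysis: 4PL fits, Cheng-Prusoff, and ΔΔG.

Competition binding assays titrate an unlabelled peptide against a fixed
concentration of radiolabelled tracer bound to the receptor. The dose-response
curve is fitted with a four-parameter logistic (4PL) model on a log10
concentration axis,

    y(x) = bottom + (top - bottom) / (1 + (x / midpoint)^hill),

the fitted midpoint (IC50) is converted to an apparent dissociation constant
with the Cheng-Prusoff correction for tracer occupancy,

    K_D = IC50 / (1 + [hot] / K_D(hot)),

and pairs of K_D values are converted to binding free-energy differences
ΔΔG = RT ln(K_D,a / K_D,b).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .thermo import GAS_CONSTANT_KCAL

__all__ = [
    "BindingMeasurement",
    "DoseResponseModel",
    "DoseResponseResults",
    "AffinityResult",
    "EnergyDifference",
    "normalize_binding",
    "fit_4pl",
    "cheng_prusoff_kd",
    "ddg_from_kd",
]

#: default final tracer concentration, µM (20 nM stock diluted 1:1 with receptor)
DEFAULT_HOT_CONC_UM = 0.01


class NormalizationError(ValueError):
    """Reference condition has no usable (nonzero) maximal signal."""


class DataInsufficiencyError(ValueError):
    """Too few distinct concentrations to constrain a 4PL fit."""


@dataclass(frozen=True)
class BindingMeasurement:
    """One assay point: titrant concentration (µM) vs measured signal."""

    x: float
    y: float
    pH: float = 5.4
    replicate: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("concentration must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


def normalize_binding(
    measurements: Sequence[BindingMeasurement], reference_condition: str
) -> list[BindingMeasurement]:
    """Normalise signals to the mean maximal signal of a reference condition.

    The reference maximum is the mean signal at the highest concentration of
    the reference condition (e.g. maximal binding at pH 5.4), which maps to 1.
    """
    ref = [m for m in measurements if m.condition == reference_condition]
    if not ref:
        raise NormalizationError(f"no measurements in condition {reference_condition!r}")
    xmax = max(m.x for m in ref)
    top = [m.y for m in ref if m.x == xmax]
    scale = float(np.mean(top))
    if scale == 0:
        raise NormalizationError("reference maximal signal is zero")
    return [
        BindingMeasurement(m.x, m.y / scale, m.pH, m.replicate, m.condition)
        for m in measurements
    ]


def _four_pl(logx: np.ndarray, top: float, bottom: float, hill: float, logmid: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - logmid)))


class DoseResponseModel:
    """Four-parameter logistic dose-response model for one titration curve.

    Parameters
    ----------
    x : array-like
        Titrant concentrations in µM. Zero concentrations are placed at half
        the smallest nonzero concentration on the log axis and flagged.
    y : array-like
        Signal (counts or normalised fraction).

    The model is fitted in log10-concentration space by nonlinear least
    squares with the Hill slope bounded to [0.1, 10]; ``fit()`` returns a
    :class:`DoseResponseResults`.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not np.isfinite(y).all():
            raise ValueError("y must be finite")
        if len(np.unique(x)) < 5:
            raise DataInsufficiencyError("need >= 5 distinct concentrations")
        self.zero_substituted = bool((x == 0).any())
        nz = x[x > 0]
        if nz.size == 0:
            raise DataInsufficiencyError("all concentrations are zero")
        xeff = np.where(x > 0, x, nz.min() / 2.0)
        self.x, self.y = xeff, y
        self.logx = np.log10(xeff)

    @classmethod
    def from_measurements(cls, measurements: Sequence[BindingMeasurement]):
        return cls([m.x for m in measurements], [m.y for m in measurements])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x_col: str = "x_uM", y_col: str = "y"):
        return cls(df[x_col].to_numpy(), df[y_col].to_numpy())

    def fit(self) -> "DoseResponseResults":
        y = self.y
        top0, bot0 = float(y.max()), float(y.min())
        mid0 = float(np.median(self.logx))
        p0 = np.array([top0, bot0, 1.0, mid0])
        lo = np.array([-np.inf, -np.inf, 0.1, self.logx.min() - 3])
        hi = np.array([np.inf, np.inf, 10.0, self.logx.max() + 3])

        def resid(p):
            return _four_pl(self.logx, *p) - y

        sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        top, bottom, hill, logmid = sol.x
        # canonicalize so top >= bottom (a negative hill mirrors the curve)
        if bottom > top:
            top, bottom, hill = bottom, top, -hill
        dof = max(len(y) - 4, 1)
        s2 = float(np.sum(sol.fun**2)) / dof
        J = sol.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(4, np.nan)
        midpoint = 10.0**logmid
        # delta method: se(mid) = ln(10) * mid * se(logmid)
        se_mid = math.log(10.0) * midpoint * se[3]
        return DoseResponseResults(
            model=self,
            top=float(top),
            bottom=float(bottom),
            hill=float(hill),
            midpoint=float(midpoint),
            standard_errors={
                "top": float(se[0]),
                "bottom": float(se[1]),
                "hill": float(se[2]),
                "midpoint": float(se_mid),
            },
            converged=bool(sol.success and midpoint > 0),
            residual_ss=float(np.sum(sol.fun**2)),
            zero_substituted=self.zero_substituted,
        )


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters with standard errors.

    ``midpoint`` is the IC50 (competition mode) or EC50 in µM.
    """

    model: DoseResponseModel
    top: float
    bottom: float
    hill: float
    midpoint: float
    standard_errors: dict[str, float]
    converged: bool
    residual_ss: float
    zero_substituted: bool = False

    @property
    def params(self) -> dict[str, float]:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "hill": self.hill,
            "midpoint": self.midpoint,
        }

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _four_pl(
            np.log10(x), self.top, self.bottom, self.hill, math.log10(self.midpoint)
        )

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            f"  n points: {len(self.model.y)}   converged: {self.converged}"
            + ("   (zero-conc points placed at half min nonzero x)" if self.zero_substituted else ""),
            f"  {'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for k, v in self.params.items():
            lines.append(f"  {k:<10}{v:>12.6g}{self.standard_errors[k]:>12.3g}")
        lines.append(f"  residual SS: {self.residual_ss:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data points and fitted curve on a log-x axis (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.model.x, self.model.y, "o", label="data")
        xs = np.geomspace(self.model.x.min(), self.model.x.max(), 200)
        ax.semilogx(xs, self.predict(xs), "-", label="4PL fit")
        ax.axvline(self.midpoint, ls=":", color="grey")
        ax.set_xlabel("concentration (µM)")
        ax.set_ylabel("signal")
        ax.legend()
        return ax


def fit_4pl(measurements_or_x, y=None) -> DoseResponseResults:
    """Convenience wrapper: build a :class:`DoseResponseModel` and fit it."""
    if y is None:
        model = DoseResponseModel.from_measurements(measurements_or_x)
    else:
        model = DoseResponseModel(measurements_or_x, y)
    return model.fit()


@dataclass(frozen=True)
class AffinityResult:
    """An apparent dissociation constant in µM with its uncertainty."""

    kd: float
    uncertainty: float
    method: str
    hot_ligand_conc: float = float("nan")
    hot_ligand_kd: float = float("nan")

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")


def cheng_prusoff_kd(
    ic50: float,
    hot_conc: float = DEFAULT_HOT_CONC_UM,
    hot_kd: float = 0.24,
    ic50_se: float = 0.0,
) -> AffinityResult:
    """Apparent K_D from a competition IC50 via the Cheng-Prusoff equation.

    K_D = IC50 / (1 + [hot]/K_D(hot)). The uncertainty is propagated from the
    IC50 standard error only; the tracer K_D is treated as fixed.

    Parameters
    ----------
    ic50 : float
        Fitted IC50 of the cold competitor, µM.
    hot_conc : float
        Final tracer concentration in the assay, µM (default 0.01 µM).
    hot_kd : float
        Tracer dissociation constant, µM.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    if hot_conc < 0:
        raise ValueError("hot_conc must be >= 0")
    if hot_kd <= 0:
        raise ZeroDivisionError("tracer K_D must be > 0 for the Cheng-Prusoff correction")
    factor = 1.0 + hot_conc / hot_kd
    return AffinityResult(
        kd=ic50 / factor,
        uncertainty=ic50_se / factor,
        method="cheng_prusoff",
        hot_ligand_conc=hot_conc,
        hot_ligand_kd=hot_kd,
    )


@dataclass(frozen=True)
class EnergyDifference:
    """Binding free-energy difference RT ln(kd_a/kd_b) between two ligands."""

    ddg: float
    temperature: float
    kd_pair: tuple[float, float]
    fold_ratio: float = field(default=float("nan"))
    fold_ratio_1sf: float = field(default=float("nan"))


def _round_1sf(x: float) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def ddg_from_kd(kd_a: float, kd_b: float, temperature: float = 310.0) -> EnergyDifference:
    """ΔΔG = RT ln(kd_a / kd_b), kcal/mol, plus the fold-affinity ratio.

    Negative ΔΔG means ligand a binds more tightly than ligand b. The fold
    ratio max/min of the K_D pair is also reported rounded to one significant
    figure (the convention used when quoting e.g. a "60-fold" difference).
    """
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    ddg = GAS_CONSTANT_KCAL * temperature * math.log(kd_a / kd_b)
    fold = max(kd_a, kd_b) / min(kd_a, kd_b)
    return EnergyDifference(
        ddg=ddg,
        temperature=temperature,
        kd_pair=(kd_a, kd_b),
        fold_ratio=fold,
        fold_ratio_1sf=_round_1sf(fold),
    )


def read_binding_csv(path) -> pd.DataFrame:
    """Read an assay table (columns: assay_id, x_uM, y, pH, replicate, condition)."""
    df = pd.read_csv(path)
    required = {"x_uM", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"binding CSV needs columns {sorted(required)}")
    return df
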