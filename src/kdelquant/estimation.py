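"""Estimation statistics for cell-based ER retrieval assays.

Each cell contributes a Golgi fraction — the integrated receptor fluorescence
inside the Golgi region (marker-defined) divided by the whole-cell signal.
Condition effects are reported in the estimation-statistics style: the mean
difference between a test condition and a (possibly shared) control, a 95%
bias-corrected and accelerated (BCa) bootstrap confidence interval over the
resampled mean differences, and a two-sided permutation p-value from
reshuffling the group labels. Defaults are 5000 bootstrap samples and 5000
label reshuffles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CellMeasurement",
    "EffectSize",
    "golgi_fraction",
    "mean_difference_bca",
    "permutation_p",
    "percentile_interval",
    "TwoSampleEstimation",
    "EstimationResults",
    "shared_control_effects",
]


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell integrated intensities inside the Golgi region and whole cell."""

    cell_id: str
    condition: str
    golgi_intensity: float
    total_intensity: float

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ZeroDivisionError(f"{self.cell_id}: total intensity must be > 0")
        if self.golgi_intensity < 0:
            raise ValueError(f"{self.cell_id}: Golgi intensity must be >= 0")
        if self.golgi_intensity > self.total_intensity:
            raise ValueError(
                f"{self.cell_id}: Golgi intensity exceeds total cell intensity"
            )


def golgi_fraction(m: CellMeasurement) -> float:
    """Golgi signal divided by total cell signal, in [0, 1]."""
    return m.golgi_intensity / m.total_intensity


@dataclass
class EffectSize:
    """Mean difference (test − control) with BCa CI and permutation p-value."""

    mean_difference: float
    ci_low: float
    ci_high: float
    p_perm: float
    n_boot: int
    n_perm: int
    n_control: int
    n_test: int
    degenerate: bool = False
    warnings: tuple[str, ...] = ()


def _bca_interval(
    boot_stats: np.ndarray,
    observed: float,
    control: np.ndarray,
    test: np.ndarray,
    alpha: float,
) -> tuple[float, float]:
    """BCa interval from bootstrap replicates of the mean difference.

    Bias correction z0 from the fraction of replicates below the observed
    statistic; acceleration from the jackknife skewness of the statistic over
    leave-one-out samples of both groups combined.
    """
    B = len(boot_stats)
    prop = np.mean(boot_stats < observed)
    # clip so z0 stays finite when all replicates fall on one side
    prop = min(max(prop, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = norm.ppf(prop)
    # jackknife over the combined per-observation influence on the statistic
    jack = []
    for i in range(len(test)):
        jack.append(np.delete(test, i).mean() - control.mean())
    for i in range(len(control)):
        jack.append(test.mean() - np.delete(control, i).mean())
    jack = np.asarray(jack)
    d = jack.mean() - jack
    denom = 6.0 * (d**2).sum() ** 1.5
    accel = (d**3).sum() / denom if denom > 0 else 0.0
    out = []
    for a in (alpha / 2, 1 - alpha / 2):
        za = norm.ppf(a)
        adj = norm.cdf(z0 + (z0 + za) / (1 - accel * (z0 + za)))
        out.append(float(np.quantile(boot_stats, adj)))
    return out[0], out[1]


def percentile_interval(boot_stats: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Plain percentile bootstrap interval (the BCa limit with z0 = a = 0)."""
    return (
        float(np.quantile(boot_stats, alpha / 2)),
        float(np.quantile(boot_stats, 1 - alpha / 2)),
    )


def mean_difference_bca(
    control: Sequence[float],
    test: Sequence[float],
    n_boot: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> EffectSize:
    """Mean difference (test − control) with a BCa bootstrap confidence interval.

    Both groups are resampled independently with replacement ``n_boot`` times;
    the interval is bias-corrected and accelerated. Zero-variance groups
    collapse the interval to the point estimate (flagged ``degenerate``).
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(control) < 3 or len(test) < 3:
        raise ValueError("both groups need n >= 3")
    observed = float(test.mean() - control.mean())
    if control.std() == 0 and test.std() == 0:
        return EffectSize(
            observed, observed, observed, float("nan"), n_boot, 0,
            len(control), len(test), degenerate=True,
        )
    rng = np.random.default_rng(seed)
    bc = rng.integers(0, len(control), size=(n_boot, len(control)))
    bt = rng.integers(0, len(test), size=(n_boot, len(test)))
    boot = test[bt].mean(axis=1) - control[bc].mean(axis=1)
    lo, hi = _bca_interval(boot, observed, control, test, alpha)
    return EffectSize(
        observed, lo, hi, float("nan"), n_boot, 0, len(control), len(test)
    )


def permutation_p(
    control: Sequence[float],
    test: Sequence[float],
    n_perm: int = 5000,
    seed: int | None = None,
    plus_one: bool = False,
) -> tuple[float, list[str]]:
    """Two-sided permutation p-value for the mean difference.

    Proportion of label reshuffles whose |mean difference| is at least the
    observed |mean difference| (ties counted as exceeding — conservative).
    ``plus_one`` switches to the (b+1)/(B+1) estimator. Returns the p-value
    and a list of warnings (e.g. for very small n_perm).
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(control) < 3 or len(test) < 3:
        raise ValueError("both groups need n >= 3")
    warnings = []
    if n_perm < 100:
        warnings.append(f"n_perm={n_perm} is very small; p-value is unstable")
    pooled = np.concatenate([control, test])
    n_c = len(control)
    observed = abs(test.mean() - control.mean())
    rng = np.random.default_rng(seed)
    count = 0
    # vectorised in blocks: argsort of random keys gives uniform permutations
    block = max(1, min(n_perm, 200_000 // max(len(pooled), 1)))
    done = 0
    total_mean_term = pooled.sum()
    while done < n_perm:
        b = min(block, n_perm - done)
        keys = rng.random((b, len(pooled)))
        order = np.argsort(keys, axis=1)
        perm = pooled[order]
        ctrl_mean = perm[:, :n_c].mean(axis=1)
        test_mean = (total_mean_term - perm[:, :n_c].sum(axis=1)) / len(test)
        stat = np.abs(test_mean - ctrl_mean)
        count += int((stat >= observed - 1e-12).sum())
        done += b
    p = (count + 1) / (n_perm + 1) if plus_one else count / n_perm
    return float(p), warnings


class TwoSampleEstimation:
    """Estimation-statistics comparison of one test condition against a control.

    Statsmodels-style front end: construct from raw per-group values (or a
    tidy cell table via :meth:`from_dataframe`), then ``fit()`` runs the
    bootstrap and permutation machinery and returns
    :class:`EstimationResults`.
    """

    def __init__(self, control: Sequence[float], test: Sequence[float],
                 control_label: str = "control", test_label: str = "test"):
        self.control = np.asarray(control, dtype=float)
        self.test = np.asarray(test, dtype=float)
        self.control_label = control_label
        self.test_label = test_label

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        control: str,
        test: str,
        condition_col: str = "condition",
    ) -> "TwoSampleEstimation":
        """Build from a per-cell table with intensity columns.

        The table needs ``condition_col`` plus either a precomputed
        ``golgi_fraction`` column or ``golgi_intensity``/``total_intensity``.
        """
        if "golgi_fraction" in df.columns:
            frac = df["golgi_fraction"].to_numpy(dtype=float)
        else:
            frac = np.array(
                [
                    golgi_fraction(
                        CellMeasurement(
                            str(r.get("cell_id", i)),
                            str(r[condition_col]),
                            float(r["golgi_intensity"]),
                            float(r["total_intensity"]),
                        )
                    )
                    for i, r in df.iterrows()
                ]
            )
        cond = df[condition_col].to_numpy()
        return cls(frac[cond == control], frac[cond == test], control, test)

    def fit(
        self,
        n_boot: int = 5000,
        n_perm: int = 5000,
        seed: int | None = None,
        plus_one: bool = False,
    ) -> "EstimationResults":
        rng = np.random.default_rng(seed)
        boot_seed, perm_seed = rng.integers(0, 2**31 - 1, size=2)
        eff = mean_difference_bca(self.control, self.test, n_boot=n_boot, seed=int(boot_seed))
        p, warn = permutation_p(
            self.control, self.test, n_perm=n_perm, seed=int(perm_seed), plus_one=plus_one
        )
        eff.p_perm = p
        eff.n_perm = n_perm
        eff.warnings = tuple(warn)
        return EstimationResults(model=self, effect=eff)


@dataclass
class EstimationResults:
    """Fitted effect size for one comparison."""

    model: TwoSampleEstimation
    effect: EffectSize

    def summary(self) -> str:
        e = self.effect
        return "\n".join(
            [
                f"Mean difference: {self.model.test_label} − {self.model.control_label}",
                f"  n = {e.n_test} vs {e.n_control}",
                f"  Δmean = {e.mean_difference:+.4f}  "
                f"95% BCa CI [{e.ci_low:+.4f}, {e.ci_high:+.4f}]  "
                f"({e.n_boot} bootstrap samples)",
                f"  permutation p = {e.p_perm:.4g}  ({e.n_perm} reshuffles)"
                + (f"  warnings: {'; '.join(e.warnings)}" if e.warnings else ""),
            ]
        )

    def plot(self, ax=None):
        """Gardner-Altman style: raw points plus the mean-difference CI."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        for i, (vals, lab) in enumerate(
            [(m.control, m.control_label), (m.test, m.test_label)]
        ):
            ax.plot(np.full(len(vals), i) + np.linspace(-0.1, 0.1, len(vals)), vals, "o",
                    alpha=0.6, label=lab)
        e = self.effect
        ax.errorbar(
            [2], [m.control.mean() + e.mean_difference],
            yerr=[[e.mean_difference - e.ci_low], [e.ci_high - e.mean_difference]],
            fmt="k_", capsize=4,
        )
        ax.set_xticks([0, 1, 2])
        ax.set_xticklabels([m.control_label, m.test_label, "Δmean + CI"])
        return ax


def shared_control_effects(
    df: pd.DataFrame,
    control: str,
    conditions: Sequence[str] | None = None,
    n_boot: int = 5000,
    n_perm: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Independent two-group comparisons of each condition against a shared control.

    Mirrors the many-ligands-vs-one-control design of the retrieval assays;
    returns a tidy frame with one row per comparison.
    """
    if conditions is None:
        conditions = [c for c in df["condition"].unique() if c != control]
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = TwoSampleEstimation.from_dataframe(df, control, cond).fit(
            n_boot=n_boot, n_perm=n_perm, seed=sub_seed
        )
        e = res.effect
        rows.append(
            {
                "control": control,
                "test": cond,
                "mean_difference": e.mean_difference,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_perm": e.p_perm,
                "n_control": e.n_control,
                "n_test": e.n_test,
                "n_boot": e.n_boot,
                "n_perm": e.n_perm,
            }
        )
    return pd.DataFrame(rows)
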