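"""Hill-model dose-response analysis for enzyme-inhibition assays.

The inhibition assay measures % inhibition of DPP-IV at several inhibitor
concentrations; the potency summary is the IC50, the concentration producing
50% inhibition.  The model is a two-free-parameter Hill curve with asymptotes
pinned by the assay definition (0% inhibition at zero inhibitor, 100% at
saturation):

    inhibition(c) = 100 * c**h / (ic50**h + c**h)

with ``ic50 > 0`` (umol/L) and Hill slope ``h > 0``.  Two estimators are
provided: nonlinear least squares on the log10-concentration axis (the
default) and log-linear interpolation between the two mean-inhibition levels
bracketing 50%, the closest literal reading of "plot log concentration
against inhibition and read off 50%".

A seeded simulator generates synthetic assay datasets (log-spaced
concentration grid, replicate Gaussian noise in percentage points) for
parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HillModelParams",
    "DoseResponseDataset",
    "IC50Fit",
    "SimulationConfig",
    "inhibition_model",
    "simulate_dataset",
    "fit_ic50",
    "potency_ratio",
    "load_dose_response",
]


@dataclass(frozen=True)
class HillModelParams:
    """Hill-curve parameters; asymptotes fixed at 0 and 100%."""

    ic50: float  # umol/L
    hill_slope: float = 1.0
    bottom: float = 0.0
    top: float = 100.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError(f"ic50 must be > 0, got {self.ic50}")
        if self.hill_slope <= 0:
            raise ValueError(f"hill_slope must be > 0, got {self.hill_slope}")
        if not 0.0 <= self.bottom < self.top <= 100.0:
            raise ValueError("asymptotes must satisfy 0 <= bottom < top <= 100")


def inhibition_model(concentration, params: HillModelParams):
    """% inhibition at the given concentration(s) (umol/L).

    Strictly increasing in concentration for ``c > 0``; exactly 50% at
    ``c == ic50`` for any slope; 0% at ``c == 0``.
    """
    c = np.asarray(concentration, dtype=float)
    with np.errstate(divide="ignore"):
        ch = np.power(c, params.hill_slope)
        ic = params.ic50 ** params.hill_slope
        out = params.bottom + (params.top - params.bottom) * ch / (ic + ch)
    out = np.where(c == 0, params.bottom, out)
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponseDataset:
    """Replicate % inhibition measurements over a concentration grid."""

    concentrations: np.ndarray  # umol/L, one per level, sorted ascending
    inhibition: np.ndarray      # shape (n_levels, n_replicates), %
    peptide_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.inhibition = np.atleast_2d(np.asarray(self.inhibition, dtype=float))
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.isfinite(self.inhibition)):
            raise ValueError("inhibition values must be finite")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.inhibition = self.inhibition[order]

    @property
    def means(self) -> np.ndarray:
        return self.inhibition.mean(axis=1)

    def long_format(self) -> pd.DataFrame:
        rows = [
            {"peptide": self.peptide_id, "concentration_umol_L": c,
             "inhibition_pct": y}
            for c, ys in zip(self.concentrations, self.inhibition)
            for y in ys
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated assay.

    Defaults mirror a standard microplate inhibition assay: 8 log-spaced
    concentration levels spanning 1-1000 umol/L, triplicate wells, Gaussian
    measurement noise of 3 percentage points.
    """

    true_params: HillModelParams
    n_levels: int = 8
    c_min: float = 1.0
    c_max: float = 1000.0
    replicates: int = 3
    noise_sd: float = 3.0
    seed: int = 0

    def grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.c_min), np.log10(self.c_max),
                           self.n_levels)


def simulate_dataset(config: SimulationConfig, peptide_id: str = ""
                     ) -> DoseResponseDataset:
    """Draw one synthetic assay dataset.

    Replicate values are the Hill-model mean plus independent Gaussian noise;
    values are *not* clamped to [0, 100] — truncation would bias the fit, and
    real plate readers can report slightly negative or >100% inhibition.
    Identical configs (including seed) give bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    mean = inhibition_model(grid, config.true_params)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_levels,
                                                   config.replicates))
    return DoseResponseDataset(
        concentrations=grid,
        inhibition=mean[:, None] + noise,
        peptide_id=peptide_id,
    )


@dataclass(frozen=True)
class IC50Fit:
    """Fitted potency with uncertainty and fit diagnostics."""

    ic50_estimate: float       # umol/L
    hill_estimate: float
    ic50_stderr: float
    hill_stderr: float
    rss: float                 # residual sum of squares
    method: Literal["nls", "interpolation"]
    extrapolated: bool         # IC50 outside the tested concentration range
    peptide_id: str = ""

    def summary(self) -> str:
        flag = " (extrapolated)" if self.extrapolated else ""
        return (
            f"IC50 = {self.ic50_estimate:.1f} +/- {self.ic50_stderr:.1f} "
            f"umol/L{flag}; Hill slope = {self.hill_estimate:.2f} "
            f"+/- {self.hill_stderr:.2f} [{self.method}]"
        )


def _interpolation_ic50(data: DoseResponseDataset) -> float:
    """Log-linear interpolation of mean inhibition to 50%."""
    means = data.means
    logc = np.log10(data.concentrations)
    below = np.where(means < 50.0)[0]
    above = np.where(means >= 50.0)[0]
    # need a level below 50 with a higher level at/above 50
    candidates = [(i, j) for i in below for j in above if j > i]
    if not candidates:
        raise ValueError(
            "mean inhibition does not bracket 50%; interpolation impossible"
        )
    i, j = max(candidates, key=lambda ij: ij[0])  # tightest bracket from below
    j = min(j2 for i2, j2 in candidates if i2 == i)
    frac = (50.0 - means[i]) / (means[j] - means[i])
    return float(10 ** (logc[i] + frac * (logc[j] - logc[i])))


def _nls_start(data: DoseResponseDataset) -> float:
    """Initial IC50: geometric mean of the levels bracketing 50% inhibition."""
    means = data.means
    c = data.concentrations
    for i in range(len(c) - 1):
        if means[i] < 50.0 <= means[i + 1]:
            return float(np.sqrt(c[i] * c[i + 1]))
    return float(np.median(c))


def fit_ic50(data: DoseResponseDataset,
             method: Literal["nls", "interpolation"] = "nls") -> IC50Fit:
    """Estimate the IC50 (and, for nls, the Hill slope) from assay data.

    ``nls`` fits (log10 IC50, h) by least squares over all replicate points,
    initialized at h = 1 and the geometric mean of the two concentrations
    bracketing 50% mean inhibition.  ``interpolation`` reads the 50% crossing
    off the mean log-concentration curve and reports no slope or uncertainty.
    """
    c = np.repeat(data.concentrations, data.inhibition.shape[1])
    y = data.inhibition.ravel()

    if method == "interpolation":
        ic50 = _interpolation_ic50(data)
        resid = y - inhibition_model(c, HillModelParams(ic50=ic50))
        return IC50Fit(
            ic50_estimate=ic50, hill_estimate=float("nan"),
            ic50_stderr=float("nan"), hill_stderr=float("nan"),
            rss=float(resid @ resid), method="interpolation",
            extrapolated=not (data.concentrations[0] <= ic50
                              <= data.concentrations[-1]),
            peptide_id=data.peptide_id,
        )

    if method != "nls":
        raise ValueError(f"unknown method {method!r}")
    if len(data.concentrations) < 4:
        raise ValueError("nls fit needs at least 4 concentration levels")

    logc = np.log10(c)

    def model(logc_, log_ic50, h):
        return 100.0 / (1.0 + 10 ** (h * (log_ic50 - logc_)))

    p0 = (np.log10(_nls_start(data)), 1.0)
    try:
        popt, pcov = curve_fit(model, logc, y, p0=p0, maxfev=10000,
                               xtol=1e-10, ftol=1e-12)
    except RuntimeError as err:
        raise RuntimeError(
            f"nls fit failed to converge for {data.peptide_id or 'dataset'}: "
            f"{err}"
        ) from err

    log_ic50, h = popt
    ic50 = float(10 ** log_ic50)
    perr = np.sqrt(np.diag(pcov))
    # delta method: sd(ic50) = ln(10) * ic50 * sd(log10 ic50)
    ic50_se = float(np.log(10) * ic50 * perr[0])
    resid = y - model(logc, *popt)
    return IC50Fit(
        ic50_estimate=ic50, hill_estimate=float(h),
        ic50_stderr=ic50_se, hill_stderr=float(perr[1]),
        rss=float(resid @ resid), method="nls",
        extrapolated=not (data.concentrations[0] <= ic50
                          <= data.concentrations[-1]),
        peptide_id=data.peptide_id,
    )


def potency_ratio(f1: IC50Fit, f2: IC50Fit) -> float:
    """Fold difference in potency: ``f1.ic50 / f2.ic50``.

    Greater than 1 means ``f1``'s peptide is the weaker inhibitor.
    """
    return f1.ic50_estimate / f2.ic50_estimate


def load_dose_response(path: str | Path) -> dict[str, DoseResponseDataset]:
    """Read replicate assay data from CSV.

    Expected columns: ``peptide``, ``concentration_umol_L``,
    ``inhibition_pct`` — one row per replicate well.  Returns one dataset per
    peptide; replicate counts may vary across levels only if every level of a
    peptide has the same number of rows.
    """
    df = pd.read_csv(path)
    required = {"peptide", "concentration_umol_L", "inhibition_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out: dict[str, DoseResponseDataset] = {}
    for pid, grp in df.groupby("peptide", sort=False):
        levels = sorted(grp["concentration_umol_L"].unique())
        reps = [
            grp.loc[grp["concentration_umol_L"] == lv,
                    "inhibition_pct"].to_numpy()
            for lv in levels
        ]
        n = {len(r) for r in reps}
        if len(n) != 1:
            raise ValueError(
                f"{path}: unequal replicate counts across levels for {pid}"
            )
        out[str(pid)] = DoseResponseDataset(
            concentrations=np.asarray(levels),
            inhibition=np.vstack(reps),
            peptide_id=str(pid),
        )
    return out
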