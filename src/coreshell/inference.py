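"""Core-shell inference: combining per-sample AFM core diameters with DLS
hydrodynamic diameters into a shell-thickness estimate.

A bare reference series shows a one-to-one relation between AFM and DLS
sizes; after functionalization the DLS trendline shifts upward by twice the
shell thickness, d_dls = d_afm + 2 L.  The estimator fixes the slope at one
and fits the offset by (optionally inverse-variance weighted) least squares:
L is half the mean offset, with the standard error of that mean.  Two
screens protect the estimate: a curvature cutoff excluding cores below
50 nm, where the brush thins on strongly curved surfaces, and a
polydispersity screen excluding broad distributions, where DLS (intensity-
weighted harmonic mean) and AFM (number-weighted mode) respond differently
and open a spurious gap.  That gap is itself a first-class quantity here:
for a log-normal core distribution with median m and width sigma_log it is
m (exp(5.5 sigma_log**2) - exp(-sigma_log**2)).

Measurement uncertainty follows the root-sum-of-squares convention: the
combined standard uncertainty is sqrt(sum u_i**2) over the individual
components, expanded with a coverage factor (k = 2 for ~95% confidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .afm import fit_lognormal
from .dls import z_average_closed_form

__all__ = [
    "SeriesPair",
    "ShellEstimate",
    "UncertaintyBudget",
    "ShellThicknessModel",
    "ShellThicknessResults",
    "build_series_pair",
    "screen_rows",
    "estimate_shell_thickness",
    "polydispersity_gap",
    "predicted_gap",
    "combine_uncertainty",
]

REQUIRED_COLUMNS = ("label", "d_afm_nm", "d_dls_nm")


@dataclass
class SeriesPair:
    """Joined AFM/DLS table: one row per sample, exclusions flagged in place."""

    data: pd.DataFrame
    unmatched: list = field(default_factory=list)

    def __post_init__(self):
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"series pair missing column {col!r}")
        if "excluded" not in df.columns:
            df["excluded"] = False
        if "reason" not in df.columns:
            df["reason"] = ""
        if df["label"].duplicated().any():
            dup = df.loc[df["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate labels in series pair: {dup}")
        if (df["d_afm_nm"] <= 0).any() or (df["d_dls_nm"] <= 0).any():
            raise ValueError("diameters must be positive")

    @property
    def included(self) -> pd.DataFrame:
        return self.data[~self.data["excluded"].astype(bool)]


@dataclass
class ShellEstimate:
    """Shell thickness L = (mean DLS-AFM offset)/2 with its standard error."""

    thickness_nm: float
    se_nm: float
    n_used: int
    excluded: list = field(default_factory=list)
    negative_warning: bool = False


@dataclass
class UncertaintyBudget:
    """Root-sum-of-squares combination of uncertainty components."""

    components: list
    coverage_k: float = 2.0
    combined_pct: float = field(default=None)
    expanded_pct: float = field(default=None)

    def __post_init__(self):
        if not self.components:
            raise ValueError("at least one uncertainty component is required")
        us = np.array([c["u_pct"] for c in self.components], float)
        if np.any(us < 0):
            raise ValueError("uncertainty components must be >= 0")
        self.combined_pct = float(np.sqrt(np.sum(us ** 2)))
        self.expanded_pct = float(self.coverage_k * self.combined_pct)

    @property
    def confidence_label(self) -> str:
        return "95% confidence interval" if self.coverage_k == 2 else f"k={self.coverage_k}"

    def summary(self) -> str:
        lines = ["Uncertainty budget (root sum of squares)"]
        for c in self.components:
            lines.append(f"  {c['name']:<28s} {c['u_pct']:6.2f} %")
        lines.append(f"  combined standard u_c        {self.combined_pct:6.2f} %")
        lines.append(f"  expanded U (k={self.coverage_k:g}, {self.confidence_label}) "
                     f"{self.expanded_pct:6.2f} %")
        return "\n".join(lines)


def build_series_pair(afm_fits: pd.DataFrame, dls_results: pd.DataFrame) -> SeriesPair:
    """Join per-sample AFM fits and DLS results on ``label``.

    ``afm_fits`` needs columns ``label``, ``d_afm_nm`` (modal corrected core
    diameter) and optionally ``sigma_log_afm``; ``dls_results`` needs
    ``label`` and ``d_dls_nm`` (z-average).  Unmatched labels are reported on
    the result, never dropped silently; an empty intersection is an error.
    """
    for df, cols, side in ((afm_fits, ("label", "d_afm_nm"), "AFM"),
                           (dls_results, ("label", "d_dls_nm"), "DLS")):
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"{side} table missing column {c!r}")
    merged = pd.merge(afm_fits, dls_results, on="label", how="inner")
    if merged.empty:
        raise ValueError("no common labels between AFM and DLS tables")
    unmatched = sorted(
        set(afm_fits["label"]).symmetric_difference(set(dls_results["label"])))
    return SeriesPair(merged.reset_index(drop=True), unmatched=unmatched)


def screen_rows(pair: SeriesPair, min_core_nm: float = 50.0,
                max_sigma_log: float = 0.15) -> SeriesPair:
    """Flag rows failing the curvature or polydispersity screens.

    Cores below ``min_core_nm`` are flagged ``curvature`` (brush thinning on
    strongly curved surfaces); rows with ``sigma_log_afm`` above
    ``max_sigma_log`` are flagged ``polydispersity``.  Rows are flagged, not
    deleted.  Fewer than 2 surviving rows is an error.
    """
    if min_core_nm <= 0 or max_sigma_log <= 0:
        raise ValueError("screening thresholds must be positive")
    df = pair.data.copy()
    curv = df["d_afm_nm"] < min_core_nm
    df.loc[curv, ["excluded", "reason"]] = True, "curvature"
    if "sigma_log_afm" in df.columns:
        poly = (df["sigma_log_afm"] > max_sigma_log) & ~curv
        df.loc[poly, ["excluded", "reason"]] = True, "polydispersity"
    n_ok = int((~df["excluded"].astype(bool)).sum())
    if n_ok < 2:
        raise ValueError(f"only {n_ok} rows survive screening; need at least 2")
    return SeriesPair(df, unmatched=list(pair.unmatched))


class ShellThicknessModel:
    """Trendline-shift estimator of shell thickness from a screened pair.

    Fits d_dls = d_afm + Delta with the slope fixed at one; the estimate is
    L = Delta / 2.  Weights are inverse-variance when per-row standard
    uncertainties ``u_afm_nm`` / ``u_dls_nm`` are present, equal otherwise.
    If a ``gap_nm`` column is present (predicted polydispersity gap), it is
    subtracted from d_dls before fitting.  A free-slope ordinary least
    squares fit is reported as a diagnostic but never used for L.
    """

    def __init__(self, pair: SeriesPair, use_gap_correction: bool = True):
        self.pair = pair
        self.use_gap_correction = use_gap_correction

    def fit(self) -> "ShellThicknessResults":
        df = self.pair.included
        n = len(df)
        if n < 2:
            raise ValueError("need at least 2 included rows")
        d_afm = df["d_afm_nm"].to_numpy(float)
        d_dls = df["d_dls_nm"].to_numpy(float)
        if self.use_gap_correction and "gap_nm" in df.columns:
            d_dls = d_dls - df["gap_nm"].to_numpy(float)
        offsets = d_dls - d_afm
        known_var = {"u_afm_nm", "u_dls_nm"}.issubset(df.columns)
        if known_var:
            var = df["u_afm_nm"].to_numpy(float) ** 2 + df["u_dls_nm"].to_numpy(float) ** 2
            w = 1.0 / var
        else:
            w = np.ones(n)
        w = w / w.sum()
        delta = float(np.sum(w * offsets))
        if known_var:
            # propagate the stated per-row uncertainties through the mean
            se_delta = math.sqrt(float(np.sum(w ** 2 * var)))
        else:
            # estimate from residual scatter
            resid = offsets - delta
            se_delta = math.sqrt(float(np.sum(w ** 2 * resid ** 2) * n / max(n - 1, 1)))
        # free-slope diagnostic (OLS)
        slope, intercept = np.polyfit(d_afm, d_dls, 1)
        excluded = [
            (row["label"], row["reason"])
            for _, row in self.pair.data[self.pair.data["excluded"].astype(bool)].iterrows()
        ]
        return ShellThicknessResults(
            thickness_nm=delta / 2.0, se_nm=se_delta / 2.0, n_used=n,
            offset_nm=delta, offset_se_nm=se_delta,
            free_slope=float(slope), free_intercept=float(intercept),
            excluded=excluded, negative_warning=delta < 0, model=self)


@dataclass
class ShellThicknessResults:
    """Fitted shell thickness with uncertainty and diagnostics."""

    thickness_nm: float
    se_nm: float
    n_used: int
    offset_nm: float
    offset_se_nm: float
    free_slope: float
    free_intercept: float
    excluded: list
    negative_warning: bool
    model: ShellThicknessModel = None

    def conf_int(self, k: float = 2.0) -> tuple[float, float]:
        return (self.thickness_nm - k * self.se_nm, self.thickness_nm + k * self.se_nm)

    def as_estimate(self) -> ShellEstimate:
        return ShellEstimate(self.thickness_nm, self.se_nm, self.n_used,
                             excluded=list(self.excluded),
                             negative_warning=self.negative_warning)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Shell thickness (trendline-shift estimator, slope fixed at 1)",
            f"  L = offset/2       {self.thickness_nm:8.2f} nm  (se {self.se_nm:.2f} nm)",
            f"  95% interval       [{lo:.2f}, {hi:.2f}] nm",
            f"  n used             {self.n_used}",
            f"  free-slope check   slope {self.free_slope:.3f}, "
            f"intercept {self.free_intercept:.2f} nm (diagnostic only)",
        ]
        if self.excluded:
            lines.append("  excluded: " + ", ".join(f"{l} ({r})" for l, r in self.excluded))
        if self.negative_warning:
            lines.append("  WARNING: fitted shell is negative; check screening")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of DLS vs AFM diameters with the two trendlines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.pair.data
        inc = ~df["excluded"].astype(bool)
        ax.scatter(df.loc[inc, "d_afm_nm"], df.loc[inc, "d_dls_nm"], label="used")
        if (~inc).any():
            ax.scatter(df.loc[~inc, "d_afm_nm"], df.loc[~inc, "d_dls_nm"],
                       marker="x", label="excluded")
        x = np.linspace(0, df["d_afm_nm"].max() * 1.1, 50)
        ax.plot(x, x, "k--", lw=1, label="1:1 reference")
        ax.plot(x, x + self.offset_nm, "r-", lw=1, label=f"shifted (+{self.offset_nm:.1f} nm)")
        ax.set_xlabel("AFM core diameter (nm)")
        ax.set_ylabel("DLS hydrodynamic diameter (nm)")
        ax.legend()
        return ax


def estimate_shell_thickness(pair: SeriesPair) -> ShellEstimate:
    """Fit the trendline-shift model and return the shell estimate."""
    return ShellThicknessModel(pair).fit().as_estimate()


def predicted_gap(median_nm: float, sigma_log: float) -> float:
    """Closed-form z-average minus mode for a log-normal population:
    m (exp(5.5 s**2) - exp(-s**2)).  Zero at s = 0, increasing in s."""
    if median_nm <= 0 or sigma_log < 0:
        raise ValueError("median must be > 0 and sigma_log >= 0")
    s2 = sigma_log ** 2
    return median_nm * (math.exp(5.5 * s2) - math.exp(-s2))


def polydispersity_gap(pop, config=None, shape_factor: float = 1.0) -> float:
    """Sample polydispersity gap: intensity-weighted harmonic mean (DLS
    z-average) minus the number-weighted mode (AFM), both from the same
    population.  ``shape_factor`` scales the mode when the population holds
    uncorrected heights."""
    z = z_average_closed_form(pop, config)
    d = pop.diameters if hasattr(pop, "diameters") else np.asarray(pop, float)
    if d.size >= 20 and np.std(d) > 0:
        fit = fit_lognormal(d)
        mode = fit.mode_nm
    else:
        mode = float(np.median(d))
    return z - shape_factor * mode


def combine_uncertainty(components, k: float = 2.0) -> UncertaintyBudget:
    """Root-sum-of-squares combination with coverage factor ``k``.

    ``components`` is a list of ``{"name": ..., "u_pct": ...}`` dicts (or
    ``(name, u_pct)`` pairs).
    """
    comps = []
    for c in components:
        if isinstance(c, dict):
            comps.append({"name": str(c["name"]), "u_pct": float(c["u_pct"])})
        else:
            name, u = c
            comps.append({"name": str(name), "u_pct": float(u)})
    return UncertaintyBudget(components=comps, coverage_k=k)
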