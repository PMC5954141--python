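"""Biochemical assay analytics for enzyme-inhibition data.

Percent-of-control normalization, four-parameter logistic (4PL) IC50
fits, Michaelis-Menten kinetics, fold-potency ratios, and the
strain-potency correlation used to judge linker designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponse",
    "FourPLFit",
    "MMFit",
    "percent_of_control",
    "four_pl",
    "fit_four_pl",
    "michaelis_menten",
    "fit_michaelis_menten",
    "fold_potency",
    "pearson_r",
    "strain_potency_correlation",
]


@dataclass
class DoseResponse:
    """Pooled concentration-response observations (one row per well)."""

    conc_nM: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    truth: dict | None = None  # generating parameters when synthetic

    def __post_init__(self) -> None:
        self.conc_nM = np.asarray(self.conc_nM, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc_nM.shape != self.response.shape:
            raise ValueError("concentration and response arrays differ in length")
        if np.any(self.conc_nM < 0):
            raise ValueError("concentrations must be non-negative")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.conc_nM.shape:
                raise ValueError("replicate array length mismatch")

    @property
    def n_distinct_doses(self) -> int:
        return len(np.unique(self.conc_nM))

    def to_frame(self) -> pd.DataFrame:
        d = {"conc_nM": self.conc_nM, "response": self.response}
        if self.replicate is not None:
            d["replicate"] = self.replicate
        return pd.DataFrame(d)


@dataclass
class FourPLFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = False
    message: str = ""


@dataclass
class MMFit:
    km: float  # µM
    vmax: float
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = False
    message: str = ""


def percent_of_control(signal, no_inhibitor_ctrl: float, full_inhibition_ctrl: float):
    """POC: 100% at the uninhibited control, 0% at full inhibition.

    POC = 100 * (signal - full) / (no_inhibitor - full); affine-invariant
    under common rescaling of signals and controls.
    """
    span = no_inhibitor_ctrl - full_inhibition_ctrl
    if span == 0:
        raise ValueError("controls are equal; POC undefined")
    return 100.0 * (np.asarray(signal, dtype=float) - full_inhibition_ctrl) / span


def four_pl(x, bottom, top, ic50, hill):
    """POC = bottom + (top - bottom) / (1 + (x / IC50)^hill)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(x > 0, x / ic50, 0.0)
        term = np.where(x > 0, np.power(ratio, hill), 0.0)
    return bottom + (top - bottom) / (1.0 + term)


def fit_four_pl(d: DoseResponse) -> FourPLFit:
    """Least-squares 4PL fit (Levenberg-Marquardt) on pooled points.

    Plateaus float freely (partial inhibitors plateau well above 0%
    control). IC50 is multi-started at the geometric mean of the dose
    range and at the dose bracketing the half-maximal response; the
    lowest residual sum of squares wins. Non-convergence is flagged on
    the result, not raised.
    """
    if d.n_distinct_doses < 4:
        raise ValueError("need at least 4 distinct concentrations for a 4PL fit")
    x, y = d.conc_nM, d.response
    pos = x[x > 0]
    top0, bot0 = float(np.max(y)), float(np.min(y))
    starts = [float(np.exp(np.mean(np.log(pos))))]
    half = bot0 + 0.5 * (top0 - bot0)
    order = np.argsort(x)
    below = x[order][np.asarray(y)[order] <= half]
    if len(below):
        starts.append(float(below[0]) or starts[0])

    best = None
    for ic0 in starts:
        for hill0 in (1.0, -1.0):
            try:
                popt, pcov = optimize.curve_fit(
                    four_pl, x, y, p0=[bot0, top0, ic0, hill0],
                    method="lm", maxfev=20000,
                )
            except (RuntimeError, optimize.OptimizeWarning):
                continue
            if popt[2] <= 0 or not np.all(np.isfinite(popt)):
                continue
            rss = float(np.sum((four_pl(x, *popt) - y) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
    if best is None:
        return FourPLFit(
            ic50=float("nan"), hill=float("nan"), top=top0, bottom=bot0,
            converged=False, message="no admissible optimum (IC50 > 0) found",
        )
    popt, pcov, rss = best
    if popt[1] < popt[0]:
        # canonicalize the equivalent parameterization with swapped
        # plateaus and negated hill so that top > bottom always holds
        popt = np.array([popt[1], popt[0], popt[2], -popt[3]])
        pcov = pcov[[1, 0, 2, 3]][:, [1, 0, 2, 3]]
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 4
    return FourPLFit(
        ic50=float(popt[2]),
        hill=float(popt[3]),
        top=float(popt[1]),
        bottom=float(popt[0]),
        se={"bottom": perr[0], "top": perr[1], "ic50": perr[2], "hill": perr[3]},
        rss=rss,
        converged=True,
    )


def michaelis_menten(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def fit_michaelis_menten(s, v) -> MMFit:
    """Michaelis-Menten fit v = Vmax*S/(Km+S), Levenberg-Marquardt,
    initialized from the Lineweaver-Burk double-reciprocal line."""
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    mask = s > 0
    if len(np.unique(s[mask])) < 3:
        raise ValueError("need at least 3 distinct positive substrate concentrations")
    if np.allclose(v, v[0]):
        raise ValueError("velocities show no curvature; Km is unidentifiable")
    ok = mask & (v > 0)
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / s[ok], 1.0 / v[ok], 1)
        vmax0 = 1.0 / intercept if intercept > 0 else float(np.max(v)) * 1.2
        km0 = slope * vmax0 if slope * vmax0 > 0 else float(np.median(s[mask]))
    else:
        vmax0, km0 = float(np.max(v)) * 1.2, float(np.median(s[mask]))
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten, s, v, p0=[vmax0, km0], method="lm", maxfev=20000
        )
    except RuntimeError as exc:
        return MMFit(km=float("nan"), vmax=float("nan"), converged=False, message=str(exc))
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    rss = float(np.sum((michaelis_menten(s, *popt) - v) ** 2))
    return MMFit(
        km=float(popt[1]), vmax=float(popt[0]),
        se={"vmax": perr[0], "km": perr[1]}, rss=rss,
        converged=bool(popt[1] > 0 and popt[0] > 0),
    )


def fold_potency(ic50_ref: float, ic50_test: float) -> float:
    """Potency ratio reference/test; >1 means the test article is more
    potent (lower IC50) than the reference."""
    if ic50_ref <= 0 or ic50_test <= 0:
        raise ValueError("IC50 values must be positive")
    return float(ic50_ref) / float(ic50_test)


def pearson_r(x, y) -> float:
    """Product-moment correlation in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def strain_potency_correlation(
    scan: pd.DataFrame,
    ic50s: pd.DataFrame,
    use_log: bool = True,
):
    """Correlate calculated linker strain with measured IC50 per length.

    ``scan`` needs columns ``n_peg, strain_kcal``; ``ic50s`` needs
    ``n_peg, ic50_nM``. Joined on ``n_peg``. By default the correlation
    is against log10 IC50 (potencies span orders of magnitude); the raw
    scale is available with ``use_log=False``. Returns ``(r, paired
    table)`` for audit.
    """
    merged = scan.merge(ic50s, on="n_peg", how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 overlapping linker lengths")
    y = np.log10(merged["ic50_nM"].to_numpy()) if use_log else merged["ic50_nM"].to_numpy()
    merged = merged.assign(ic50_for_corr=y)
    r = pearson_r(merged["strain_kcal"].to_numpy(), y)
    return r, merged
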