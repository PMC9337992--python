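"""Drug screen and dose-response analytics.

Covers the cell-based screen arm of the pipeline: DMSO normalization of
confluence readouts, the hit rule (proliferation reduced by more than 50%
in at least one third of the lines), three-parameter Hill curve fitting,
the area-above-the-curve (AAC) sensitivity metric, absolute IC50 with
explicit censoring, and exponential-phase doubling-time estimation.

AAC is integrated on the log10-dose axis over the tested concentration
range and normalized by that range, so it lives in [0, 1]: 0 means no
response anywhere on the grid, 1 means complete killing at every dose, and
a higher AAC means a more sensitive line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataError, FitError

__all__ = [
    "DoseResponseCurve", "HillFit", "SensitivityProfile", "ScreenMatrix",
    "hill_viability", "normalize_screen", "call_hits", "fit_hill",
    "compute_aac", "doubling_time",
]


# ---------------------------------------------------------------- types

@dataclass
class DoseResponseCurve:
    """Viability fractions (of DMSO control) over an ascending dose grid."""

    doses: np.ndarray       # µM, strictly increasing, positive
    viability: np.ndarray   # fraction of control, mean over replicates
    replicate_sd: np.ndarray | None = None

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.doses.size < 2:
            raise ValueError("need >=2 dose points")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability must be finite")
        if self.viability.size != self.doses.size:
            raise ValueError("doses and viability length mismatch")


@dataclass
class HillFit:
    """Fitted three-parameter Hill curve plus the derived absolute IC50."""

    ec50: float
    hill_slope: float
    e_inf: float
    ic50: float | None      # None when censored
    ic50_censored: bool
    rss: float
    metadata: dict = field(default_factory=dict)


@dataclass
class SensitivityProfile:
    """Per-cell-line sensitivity metrics used as the ranking phenotype."""

    aac: pd.Series                      # line -> AAC in [0,1]
    ic50: pd.Series | None = None       # line -> IC50 (NaN = censored)
    label: pd.Series | None = None      # line -> 'sensitive'/'resistant'

    def __post_init__(self):
        vals = self.aac.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("AAC values must lie in [0,1]")

    @property
    def lines(self) -> list[str]:
        return list(self.aac.index)


@dataclass
class ScreenMatrix:
    """Compound x line confluence normalized to DMSO, with log2 companion."""

    normalized: pd.DataFrame
    log2: pd.DataFrame


# ------------------------------------------------------------ screen ops

def normalize_screen(raw_confluence: pd.DataFrame,
                     dmso_wells: pd.Series | pd.DataFrame) -> ScreenMatrix:
    """Normalize raw confluence to each line's mean DMSO confluence.

    Parameters
    ----------
    raw_confluence
        Rows = compounds (replicate measurements may appear as repeated
        compound index entries), columns = cell lines.
    dmso_wells
        Per-line DMSO confluence; a DataFrame with one row per replicate
        well or a Series of per-line values.

    Returns the mean-over-replicates normalized matrix and its log2.
    """
    if isinstance(dmso_wells, pd.Series):
        dmso_mean = dmso_wells.astype(float)
    else:
        dmso_mean = dmso_wells.astype(float).mean(axis=0)
    bad = dmso_mean[(dmso_mean <= 0) | ~np.isfinite(dmso_mean)]
    if len(bad):
        raise DataError("non-positive DMSO confluence for line(s): "
                        + ", ".join(map(str, bad.index)))
    missing = [c for c in raw_confluence.columns if c not in dmso_mean.index]
    if missing:
        raise DataError(f"no DMSO wells for line(s): {', '.join(map(str, missing))}")
    norm = raw_confluence.astype(float).div(dmso_mean[raw_confluence.columns], axis=1)
    # replicate rows share a compound index entry; average them
    norm = norm.groupby(level=0, sort=False).mean()
    return ScreenMatrix(normalized=norm, log2=np.log2(norm))


def call_hits(screen: ScreenMatrix, inhibition_threshold: float = 0.5,
              line_fraction: float = 1.0 / 3.0) -> pd.DataFrame:
    """Apply the screen hit rule.

    A compound is a hit when the fraction of lines whose normalized
    confluence falls strictly below ``inhibition_threshold`` (i.e. growth
    reduced by more than 50% at the default) is at least ``line_fraction``
    (at least one third of the lines at the default).

    Returns a DataFrame indexed by compound with columns
    ``n_responsive``, ``n_lines``, ``fraction``, ``hit``.
    """
    if not (0 < inhibition_threshold <= 1) or not (0 < line_fraction <= 1):
        raise ValueError("thresholds must lie in (0,1]")
    mat = screen.normalized
    if mat.size == 0:
        raise ValueError("empty screen matrix")
    n_lines = mat.shape[1]
    responsive = (mat < inhibition_threshold).sum(axis=1)
    frac = responsive / n_lines
    return pd.DataFrame({
        "n_responsive": responsive,
        "n_lines": n_lines,
        "fraction": frac,
        "hit": frac >= line_fraction,
    })


# ------------------------------------------------------------- Hill fit

def hill_viability(dose, ec50: float, slope: float, e_inf: float):
    """Descending Hill curve: E(d) = e_inf + (1 - e_inf) / (1 + (d/ec50)^slope)."""
    d = np.asarray(dose, dtype=float)
    return e_inf + (1.0 - e_inf) / (1.0 + (d / ec50) ** slope)


def fit_hill(curve: DoseResponseCurve) -> HillFit:
    """Least-squares three-parameter Hill fit with multi-start on EC50.

    Bounds: e_inf in [0,1], slope in (0,10], ec50 in
    [min dose / 10, max dose * 10].  Five log-spaced EC50 initials are
    tried and the best residual sum of squares wins; the optimization is
    deterministic given the input.  The absolute IC50 is the dose where the
    fitted curve crosses 50% viability; it is censored when the plateau
    e_inf exceeds 0.5 (the curve never reaches 50%) or when the crossing
    lies above the top tested dose.
    """
    d, v = curve.doses, curve.viability
    if d.size < 4:
        raise ValueError("need >=4 dose points for a 3-parameter fit")
    lo_ec, hi_ec = d.min() / 10.0, d.max() * 10.0
    bounds = ([np.log10(lo_ec), 1e-6, 0.0], [np.log10(hi_ec), 10.0, 1.0])
    logd = np.log10(d)

    def residuals(theta):
        log_ec50, slope, e_inf = theta
        # evaluate in log space for numerical stability at extreme slopes
        return e_inf + (1.0 - e_inf) / (1.0 + 10.0 ** (slope * (logd - log_ec50))) - v

    starts = np.log10(np.logspace(np.log10(lo_ec * 1.001), np.log10(hi_ec * 0.999), 5))
    e_inf0 = float(np.clip(v.min(), 0.0, 1.0))
    best = None
    failures = []
    for s0 in starts:
        try:
            res = least_squares(residuals, x0=[s0, 1.0, e_inf0], bounds=bounds,
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception as exc:  # pragma: no cover - scipy rarely raises here
            failures.append(str(exc))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("Hill fit failed from all starts",
                       diagnostics={"starts": list(starts), "errors": failures})
    log_ec50, slope, e_inf = best.x
    ec50 = float(10.0 ** log_ec50)
    rss = float(2.0 * best.cost)
    ic50, censored = _absolute_ic50(ec50, slope, e_inf, d.max())
    return HillFit(ec50=ec50, hill_slope=float(slope), e_inf=float(e_inf),
                   ic50=ic50, ic50_censored=censored, rss=rss,
                   metadata={"ic50_definition": "absolute",
                             "n_starts": len(starts)})


def _absolute_ic50(ec50: float, slope: float, e_inf: float,
                   max_dose: float) -> tuple[float | None, bool]:
    if e_inf >= 0.5:
        return None, True
    # solve e_inf + (1-e_inf)/(1+x) = 0.5 for x = (d/ec50)^slope
    x = (1.0 - e_inf) / (0.5 - e_inf) - 1.0
    ic50 = ec50 * x ** (1.0 / slope)
    if ic50 > max_dose:
        return None, True
    return float(ic50), False


# ------------------------------------------------------------------ AAC

def compute_aac(curve: DoseResponseCurve) -> float:
    """Area above the dose-response curve on the log10-dose axis.

    Viability is clipped to [0,1] first; AAC is the trapezoidal integral of
    (1 - viability) over log10(dose) divided by the log10 dose range, so
    the result lies in [0,1].
    """
    if curve.doses.size < 2:
        raise ValueError("need >=2 doses for AAC")
    v = np.clip(curve.viability, 0.0, 1.0)
    x = np.log10(curve.doses)
    area = np.trapezoid(1.0 - v, x)
    return float(area / (x[-1] - x[0]))


# -------------------------------------------------------- doubling time

def doubling_time(hours, confluence, saturation_cutoff: float = 0.8):
    """Doubling time from log-linear regression on the exponential window.

    Points at or above ``saturation_cutoff`` confluence are excluded
    (log-phase assumption breaks near confluence).  Returns the doubling
    time in hours, or ``None`` for a non-growing series (slope <= 0).
    """
    t = np.asarray(hours, dtype=float)
    c = np.asarray(confluence, dtype=float)
    if np.any(c <= 0):
        raise ValueError("confluence must be positive")
    keep = c < saturation_cutoff
    if keep.sum() == 0:
        raise DataError("all points above the saturation cutoff; no exponential window")
    if keep.sum() < 3:
        raise ValueError("need >=3 time points below the saturation cutoff")
    slope, _ = np.polyfit(t[keep], np.log(c[keep]), 1)
    if slope <= 0:
        return None
    return float(np.log(2.0) / slope)
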