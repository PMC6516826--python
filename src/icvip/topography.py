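"""Topographic plane fits: intrinsic physiology versus IC location.

Neuron somata are mapped to a coronal coordinate frame (medial-lateral
distance from the midline, dorsal-ventral distance from the dorsal edge);
right-side neurons are folded onto the left IC by negating the
medial-lateral coordinate.  Each intrinsic parameter is fit with a plane
``p = a + b*ml + c*dv`` by Levenberg-Marquardt least squares; fit quality is
the Pearson correlation between observed and fitted values and the adjusted
R^2 with two predictors, ``1 - (1 - r^2)(n - 1)/(n - 3)``.

Two p-values are reported: the overall-regression F-test (primary) and a
chi-squared tail probability of the residual sum of squares under unit
weights (a legacy convention kept for comparison only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .errors import ConfigurationError, InsufficientDataError


@dataclass
class ICCoordinate:
    ml: float                      # um from midline (>= 0 before normalization)
    dv: float                      # um from dorsal edge
    side: str                      # left | right
    subdivision: Optional[str] = None   # ICc | ICd | IClc


@dataclass
class PlaneFit:
    parameter_name: str
    intercept: float
    slope_ml: float                # parameter units per um
    slope_dv: float
    r: float                       # multiple correlation, in [0, 1]
    r2_adj: float
    p_value: float                 # overall-regression F test
    p_value_chi2: float            # legacy: chi2 tail of RSS, unit weights
    n: int


def normalize_side(c: ICCoordinate) -> ICCoordinate:
    """Fold right-side neurons onto the left IC (ml -> -ml); idempotent."""
    if c.side == "left":
        return c
    if c.side == "right":
        return ICCoordinate(ml=-c.ml, dv=c.dv, side="left",
                            subdivision=c.subdivision)
    raise ConfigurationError(f"unknown side {c.side!r}")


def adjusted_r2(r: float, n: int, n_predictors: int = 2) -> float:
    """Adjusted R^2 from a correlation coefficient and sample size."""
    return 1.0 - (1.0 - r * r) * (n - 1) / (n - 1 - n_predictors)


def fit_plane(ml: Sequence[float], dv: Sequence[float],
              values: Sequence[float],
              parameter_name: str = "parameter") -> PlaneFit:
    """Levenberg-Marquardt plane fit of a parameter against location."""
    ml = np.asarray(ml, dtype=float)
    dv = np.asarray(dv, dtype=float)
    z = np.asarray(values, dtype=float)
    if not (ml.size == dv.size == z.size):
        raise ConfigurationError("ml, dv, values must have equal length")
    if ml.size < 4:
        raise InsufficientDataError(f"need n >= 4 points, got {ml.size}")
    if not np.all(np.isfinite(ml)) or not np.all(np.isfinite(dv)) \
            or not np.all(np.isfinite(z)):
        raise ConfigurationError("non-finite inputs to plane fit")
    design = np.column_stack([np.ones_like(ml), ml, dv])
    if np.linalg.matrix_rank(design) < 3:
        raise ConfigurationError("collinear predictors: plane is not identifiable")

    def residuals(p):
        return p[0] + p[1] * ml + p[2] * dv - z

    x0 = np.array([z.mean(), 0.0, 0.0])
    sol = least_squares(residuals, x0, method="lm")
    a, b, c = sol.x
    fitted = a + b * ml + c * dv
    if np.ptp(fitted) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(z, fitted)[0])
    r = max(r, 0.0)
    n = int(ml.size)
    r2a = adjusted_r2(r, n)
    dof = n - 3
    if r >= 1.0:
        p_f = 0.0
    else:
        f = (r * r / 2.0) / ((1.0 - r * r) / dof)
        p_f = float(stats.f.sf(f, 2, dof))
    rss = float(np.sum((z - fitted) ** 2))
    p_chi2 = float(stats.chi2.sf(rss, dof))
    return PlaneFit(parameter_name=parameter_name, intercept=float(a),
                    slope_ml=float(b), slope_dv=float(c), r=r, r2_adj=r2a,
                    p_value=p_f, p_value_chi2=p_chi2, n=n)


def fit_parameter_planes(table: pd.DataFrame,
                         parameters: Sequence[str],
                         ml_col: str = "ml", dv_col: str = "dv",
                         icc_only: bool = True,
                         subdivision_col: str = "subdivision") -> list[PlaneFit]:
    """Fit one plane per parameter column of a joined location/physiology
    table, restricted to ICc rows by default (only the central nucleus is
    tonotopically organized)."""
    df = table
    if icc_only and subdivision_col in df.columns:
        df = df[df[subdivision_col] == "ICc"]
    fits = []
    for p in parameters:
        if p not in df.columns:
            warnings.warn(f"parameter column {p!r} missing; skipped")
            continue
        sub = df[[ml_col, dv_col, p]].dropna()
        if len(sub) < 4:
            warnings.warn(f"parameter {p!r} has {len(sub)} usable rows; skipped")
            continue
        fits.append(fit_plane(sub[ml_col], sub[dv_col], sub[p],
                              parameter_name=p))
    return fits


def tonotopy_report(fits: Sequence[PlaneFit]) -> pd.DataFrame:
    """Summary table of plane fits with the gradient sign along the
    dorsolateral -> ventromedial diagonal.

    The tonotopic axis runs perpendicular to the ~45 deg isofrequency
    laminae, from dorsolateral (low frequency) to ventromedial (high
    frequency); the ventromedial unit direction in (ml, dv) coordinates is
    (-1, +1)/sqrt(2).  A positive projection means the parameter increases
    ventromedially, i.e. membrane properties get slower toward high
    frequency regions.
    """
    if not fits:
        raise InsufficientDataError("no fits to report")
    rows = []
    for f in fits:
        diag = (f.slope_dv - f.slope_ml) / np.sqrt(2.0)
        rows.append({
            "parameter": f.parameter_name,
            "intercept": f.intercept,
            "slope_ml": f.slope_ml,
            "slope_dv": f.slope_dv,
            "r": f.r,
            "r2_adj": f.r2_adj,
            "p_value": f.p_value,
            "p_value_chi2": f.p_value_chi2,
            "n": f.n,
            "diagonal_gradient": diag,
            "gradient_direction": ("slower ventromedially" if diag > 0
                                   else "slower dorsolaterally"),
        })
    return pd.DataFrame(rows)
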