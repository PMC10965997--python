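"""DOC decay kinetics: reactivity continuum, per-compound rates, and BGE.

The reactivity continuum (RC) model treats bulk DOC as a continuum of
compounds each decaying with first-order kinetics, with a Gamma distribution
of initial reactivities. Integrating the exponential decays over a
Gamma(shape=nu, rate=alpha) rate distribution gives the bulk decay law

    DOC(t) / DOC(0) = (alpha / (alpha + t)) ** nu

where alpha (time units of t) is the apparent initial age of the most
reactive compounds and nu (dimensionless) governs the predominance of
recalcitrant compounds. The instantaneous decay rate is k(t) = nu/(alpha+t),
so the initial rate is k0 = nu/alpha.

Per-compound degradation/accumulation rates during short incubations are
first-order fits to each compound's relative-intensity time series: linear
regression of ln(intensity) on time per replicate; negative rates indicate
degradation, positive rates accumulation (degradation by-products). A
compound's rate is validated only when the fit is significant in every
replicate of its group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import Dataset

#: Per-replicate significance level for validating a first-order fit.
DECAY_ALPHA_P = 0.05

#: Multi-start grid for the RC fit (the RSS surface is ridge-prone).
RC_ALPHA_STARTS = (0.01, 0.1, 1.0, 10.0, 100.0)
RC_NU_STARTS = (1e-6, 0.05, 0.1, 0.5, 1.0, 2.0)


def rc_model(t, alpha: float, nu: float):
    """Bulk RC decay law (alpha/(alpha+t))**nu."""
    t = np.asarray(t, dtype=float)
    return (alpha / (alpha + t)) ** nu


@dataclass
class RCParams:
    """Fitted reactivity-continuum parameters and diagnostics."""

    alpha: float
    nu: float
    rss: float = math.nan
    stderr_alpha: float = math.nan
    stderr_nu: float = math.nan
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.nu > 0):
            raise ValueError("alpha and nu must be positive")

    @property
    def k0(self) -> float:
        """Initial decay rate nu/alpha (1/time unit of the fitted series)."""
        return self.nu / self.alpha

    def predict(self, t):
        return rc_model(t, self.alpha, self.nu)


def initial_decay_rate(p: RCParams) -> float:
    """Apparent initial decay rate k0 = nu/alpha."""
    return p.k0


def fit_rc_model(t, doc_frac) -> RCParams:
    """Nonlinear least-squares fit of the RC model to a relative DOC series.

    Requires at least 4 timepoints including t=0 with DOC(0)/DOC(0) within 5%
    of 1, values in (0, 1.2]. Fits from a multi-start grid of (alpha, nu)
    initializations with both parameters bounded below by 1e-8 and keeps the
    lowest residual sum of squares. An increasing series triggers a warning
    but the fit is still attempted.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(doc_frac, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and doc_frac must be 1-D arrays of equal length")
    if len(t) < 4:
        raise ValueError("RC fit requires at least 4 timepoints")
    if not (t == 0).any():
        raise ValueError("RC fit requires a t=0 point")
    if abs(y[t == 0][0] - 1.0) > 0.05:
        raise ValueError("doc_frac at t=0 must be 1 within 5%")
    if ((y <= 0) | (y > 1.2)).any():
        raise ValueError("doc_frac values must lie in (0, 1.2]")
    order = np.argsort(t)
    if (np.diff(y[order]) > 0).any():
        warnings.warn("DOC series is not monotonically decreasing", stacklevel=2)

    def residuals(theta):
        return rc_model(t, theta[0], theta[1]) - y

    best = None
    for a0 in RC_ALPHA_STARTS:
        for n0 in RC_NU_STARTS:
            try:
                res = optimize.least_squares(
                    residuals,
                    x0=[a0, n0],
                    bounds=([1e-8, 1e-8], [np.inf, np.inf]),
                    x_scale="jac",
                )
            except Exception:
                continue
            if not res.success:
                continue
            rss = float(2 * res.cost)
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        raise RuntimeError("RC fit failed to converge from every start")
    rss, res = best
    alpha, nu = res.x
    # asymptotic standard errors from the Jacobian
    dof = max(len(t) - 2, 1)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * rss / dof
        se_a, se_n = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se_a = se_n = math.nan
    return RCParams(
        alpha=float(alpha),
        nu=float(nu),
        rss=rss,
        stderr_alpha=float(se_a),
        stderr_nu=float(se_n),
        n_points=len(t),
    )


def fit_compound_rates(d: Dataset, alpha_p: float = DECAY_ALPHA_P) -> pd.DataFrame:
    """First-order decay/accumulation rates of individual compounds.

    For each (lake, treatment) group of a normalized in situ dataset, and for
    each replicate time series with positive intensity at every timepoint
    (and at least 3 timepoints), ln(intensity) is regressed on time; the
    slope is the first-order rate in 1/h. A compound is ``validated`` iff
    every replicate of the group could be fit and every fit has slope p-value
    below ``alpha_p``. The reported rate is the mean of the replicate slopes.

    Returns one row per (formula, lake, treatment) that was fit in at least
    one replicate, with columns ``rate_per_h, rate_per_d, p_max,
    n_replicates, n_replicates_fit, validated``.
    """
    if not d.normalized:
        raise ValueError("fit_compound_rates expects normalized relative intensities")
    rows = []
    samples = [s for s in d.samples if s.role == "sample"]
    by_contrast: dict[tuple[str, str], dict[int, list]] = {}
    for s in samples:
        by_contrast.setdefault((s.lake, s.treatment), {}).setdefault(s.replicate, []).append(s)
    x = d.intensities
    for (lake, treatment), reps in sorted(by_contrast.items()):
        rep_fits = {}
        for rep, specs in sorted(reps.items()):
            specs = sorted(specs, key=lambda s: s.timepoint_h)
            tps = np.array([s.timepoint_h for s in specs], dtype=float)
            if len(tps) < 3:
                continue
            mat = x[[s.sample_id for s in specs]].to_numpy(dtype=float)
            fit_ok = (mat > 0).all(axis=1)
            slopes = np.full(len(mat), np.nan)
            pvals = np.full(len(mat), np.nan)
            logm = np.log(mat[fit_ok])
            for i, row in zip(np.flatnonzero(fit_ok), logm):
                res = stats.linregress(tps, row)
                slopes[i] = res.slope
                pvals[i] = res.pvalue
            rep_fits[rep] = (slopes, pvals)
        if not rep_fits:
            continue
        n_reps = len(rep_fits)
        slope_mat = np.vstack([v[0] for v in rep_fits.values()])
        pval_mat = np.vstack([v[1] for v in rep_fits.values()])
        n_fit = (~np.isnan(slope_mat)).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_rate = np.nanmean(np.where(np.isnan(slope_mat), np.nan, slope_mat), axis=0)
            p_max = np.nanmax(pval_mat, axis=0)
        validated = (n_fit == n_reps) & np.all(
            np.where(np.isnan(pval_mat), np.inf, pval_mat) < alpha_p, axis=0
        )
        sel = n_fit > 0
        for i in np.flatnonzero(sel):
            rows.append(
                {
                    "formula": x.index[i],
                    "lake": lake,
                    "treatment": treatment,
                    "rate_per_h": mean_rate[i],
                    "rate_per_d": mean_rate[i] * 24.0,
                    "p_max": p_max[i],
                    "n_replicates": n_reps,
                    "n_replicates_fit": int(n_fit[i]),
                    "validated": bool(validated[i]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BacterialRates:
    """Bacterial carbon production, respiration and growth efficiency.

    ``bp`` and ``br`` in ug C L^-1 h^-1; ``bge`` = bp / (bp + br), NaN when
    both rates are zero (undefined).
    """

    bp: float
    br: float
    bge: float = field(init=False)

    def __post_init__(self) -> None:
        if self.bp < 0 or self.br < 0:
            raise ValueError("bp and br must be non-negative")
        self.bge = self.bp / (self.bp + self.br) if (self.bp + self.br) > 0 else math.nan


def compute_bge(bp: float, br: float) -> BacterialRates:
    """Bacterial growth efficiency from production and respiration rates."""
    return BacterialRates(bp=float(bp), br=float(br))


def o2_slope_to_br(o2_slope_mg_per_l_h: float, respiratory_quotient: float = 1.0) -> float:
    """Convert an oxygen drawdown slope to bacterial respiration in C units.

    BR (ug C L^-1 h^-1) = -slope(O2, mg L^-1 h^-1) * RQ * (12.011/31.998) * 1000,
    with a configurable respiratory quotient (mol CO2 per mol O2, default 1).
    """
    if o2_slope_mg_per_l_h > 0:
        warnings.warn("positive O2 slope implies negative respiration", stacklevel=2)
    return -o2_slope_mg_per_l_h * respiratory_quotient * (12.011 / 31.998) * 1000.0
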