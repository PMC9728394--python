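"""Michaelis-Menten parameter estimation for transglucosylation assays.

Initial-velocity data (v against substrate concentration [S]) are fitted in
one of two regimes:

* **saturation** — the classical double-reciprocal Lineweaver-Burk fit
  (OLS of 1/v on 1/[S]; Vmax = 1/intercept, Km = slope/intercept, standard
  errors by the delta method), cross-checked by a direct nonlinear
  least-squares fit of v = Vmax [S] / (Km + [S]);
* **linear** — when the enzyme cannot be saturated over the accessible
  concentration range, v is effectively (Vmax/Km) [S] and kcat/Km is read
  off a through-origin linear regression of v on [S].

Units are fixed package-wide: [S] in mM, v in umol min^-1 mg^-1, kcat in
min^-1, and kcat/Km in mM^-1 min^-1.  The turnover number requires the
enzyme molar mass: kcat = Vmax * MW * 1e-3 (umol min^-1 mg^-1 x g mol^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticDataset",
    "KineticFit",
    "FitError",
    "fit_lineweaver_burk",
    "fit_mm_nonlinear",
    "fit_linear_regime",
    "derive_kcat",
    "catalytic_efficiency",
    "fold_change",
    "FoldChange",
    "michaelis_menten",
]

KINETICS_CSV_HEADER = ["substrate_mM", "velocity_umol_min_mg", "replicate"]


class FitError(RuntimeError):
    """A kinetic fit could not be carried out on the given data."""


def michaelis_menten(s, vmax: float, km: float):
    """v = Vmax [S] / (Km + [S])."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


@dataclass
class KineticDataset:
    """Initial-velocity measurements for one variable substrate.

    ``substrate_conc_mM`` and ``velocity`` are parallel arrays (pooled over
    replicates); ``replicate`` carries the replicate label of each point.
    ``enzyme_mw`` (g/mol) is optional and only needed to derive kcat.
    """

    substrate: str
    substrate_conc_mM: np.ndarray
    velocity: np.ndarray
    replicate: np.ndarray | None = None
    enzyme_mw: float | None = None

    def __post_init__(self) -> None:
        self.substrate_conc_mM = np.asarray(self.substrate_conc_mM, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.replicate is None:
            self.replicate = np.ones(self.substrate_conc_mM.size, dtype=int)
        self.replicate = np.asarray(self.replicate)
        if self.substrate_conc_mM.shape != self.velocity.shape:
            raise ValueError("substrate_conc_mM and velocity must have equal length")
        if self.replicate.shape != self.velocity.shape:
            raise ValueError("replicate labels must match the number of points")
        if np.any(self.substrate_conc_mM <= 0):
            raise ValueError("substrate_conc_mM must be strictly positive")
        if np.any(self.velocity < 0):
            raise ValueError("velocity must be nonnegative")

    @property
    def n_distinct_concentrations(self) -> int:
        return np.unique(self.substrate_conc_mM).size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                KINETICS_CSV_HEADER[0]: self.substrate_conc_mM,
                KINETICS_CSV_HEADER[1]: self.velocity,
                KINETICS_CSV_HEADER[2]: self.replicate,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, substrate: str | None = None, enzyme_mw: float | None = None
    ) -> "KineticDataset":
        df = pd.read_csv(path)
        missing = [c for c in KINETICS_CSV_HEADER if c not in df.columns]
        if missing:
            raise ValueError(f"kinetics CSV is missing columns: {missing}")
        return cls(
            substrate=substrate or Path(path).stem,
            substrate_conc_mM=df[KINETICS_CSV_HEADER[0]].to_numpy(),
            velocity=df[KINETICS_CSV_HEADER[1]].to_numpy(),
            replicate=df[KINETICS_CSV_HEADER[2]].to_numpy(),
            enzyme_mw=enzyme_mw,
        )


@dataclass
class KineticFit:
    """Fitted kinetic parameters with standard errors and diagnostics.

    ``regime`` is "saturation" (Km/Vmax defined) or "linear" (only the
    efficiency slope is identifiable; Km and Vmax are None).
    """

    regime: str
    Km: float | None = None
    Km_se: float | None = None
    Vmax: float | None = None
    Vmax_se: float | None = None
    kcat: float | None = None
    kcat_se: float | None = None
    kcat_over_Km: float | None = None
    kcat_over_Km_se: float | None = None
    slope: float | None = None  # linear regime: d v / d [S]
    slope_se: float | None = None
    r_squared: float | None = None
    residuals: np.ndarray | None = None
    method: str = ""
    warnings: list[str] = field(default_factory=list)


def _ols_with_cov(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS of y on [1, x]; returns (beta, covariance, R^2)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    return beta, cov, r2


def fit_lineweaver_burk(data: KineticDataset) -> KineticFit:
    """Double-reciprocal fit: OLS of 1/v on 1/[S].

    Vmax = 1/intercept and Km = slope/intercept; standard errors follow by
    the delta method from the OLS coefficient covariance.  Requires at
    least three distinct concentrations and strictly positive velocities; a
    nonpositive intercept means the data show no approach to saturation.
    """
    if data.n_distinct_concentrations < 3:
        raise FitError("Lineweaver-Burk fit needs >= 3 distinct concentrations")
    if np.any(data.velocity <= 0):
        raise FitError("Lineweaver-Burk fit needs strictly positive velocities")
    x = 1.0 / data.substrate_conc_mM
    y = 1.0 / data.velocity
    (b0, b1), cov, r2 = _ols_with_cov(x, y)
    if b0 <= 0:
        raise FitError("no saturation detectable: nonpositive Lineweaver-Burk intercept")
    vmax = 1.0 / b0
    km = b1 / b0
    g_vmax = np.array([-1.0 / b0**2, 0.0])
    g_km = np.array([-b1 / b0**2, 1.0 / b0])
    vmax_se = float(np.sqrt(g_vmax @ cov @ g_vmax))
    km_se = float(np.sqrt(g_km @ cov @ g_km))
    resid = data.velocity - michaelis_menten(data.substrate_conc_mM, vmax, km)
    return KineticFit(
        regime="saturation",
        Km=float(km),
        Km_se=km_se,
        Vmax=float(vmax),
        Vmax_se=vmax_se,
        r_squared=r2,
        residuals=resid,
        method="lineweaver-burk",
    )


def fit_mm_nonlinear(data: KineticDataset) -> KineticFit:
    """Direct least-squares fit of v = Vmax [S] / (Km + [S]).

    Initialized from the Lineweaver-Burk estimates when available.  This
    route avoids the reciprocal transform's noise amplification at low
    velocities and is the recommended estimator on noisy data.
    """
    if data.n_distinct_concentrations < 3:
        raise FitError("nonlinear Michaelis-Menten fit needs >= 3 distinct concentrations")
    try:
        lb = fit_lineweaver_burk(data)
        p0 = [lb.Vmax, lb.Km]
        if not all(np.isfinite(p0)) or p0[0] <= 0 or p0[1] <= 0:
            raise FitError("bad LB starting point")
    except FitError:
        p0 = [float(data.velocity.max()), float(np.median(data.substrate_conc_mM))]
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten,
            data.substrate_conc_mM,
            data.velocity,
            p0=p0,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"nonlinear fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    if km <= 0 or vmax <= 0:
        raise FitError(f"nonlinear fit left the physical domain (Vmax={vmax:g}, Km={km:g})")
    perr = np.sqrt(np.diag(pcov))
    resid = data.velocity - michaelis_menten(data.substrate_conc_mM, vmax, km)
    tss = float(np.sum((data.velocity - data.velocity.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    return KineticFit(
        regime="saturation",
        Km=km,
        Km_se=float(perr[1]) if np.isfinite(perr[1]) else None,
        Vmax=vmax,
        Vmax_se=float(perr[0]) if np.isfinite(perr[0]) else None,
        r_squared=r2,
        residuals=resid,
        method="nonlinear",
    )


def fit_linear_regime(data: KineticDataset, through_origin: bool = True) -> KineticFit:
    """Efficiency from the non-saturating (linear) regime: OLS of v on [S].

    The regression runs through the origin by default (v = 0 at [S] = 0 is
    mechanistically forced); ``through_origin=False`` frees the intercept
    for diagnostics.  When the dataset carries the enzyme molar mass, the
    slope is converted to kcat/Km in mM^-1 min^-1.  A significant quadratic
    term (lack-of-fit for a straight line) adds a curvature warning.
    """
    if data.n_distinct_concentrations < 2:
        raise FitError("linear-regime fit needs >= 2 distinct concentrations")
    s = data.substrate_conc_mM
    v = data.velocity
    warnings: list[str] = []
    if through_origin:
        slope = float(s @ v / (s @ s))
        resid = v - slope * s
        dof = len(v) - 1
        sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
        slope_se = math.sqrt(sigma2 / float(s @ s))
        tss = float(v @ v)  # uncentered for through-origin R^2
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    else:
        (b0, slope), cov, r2 = _ols_with_cov(s, v)
        slope_se = float(np.sqrt(cov[1, 1]))
        resid = v - (b0 + slope * s)
        warnings.append(f"free intercept = {b0:.4g}")

    # curvature diagnostic: does a quadratic term improve on the line?
    if data.n_distinct_concentrations >= 3 and len(v) >= 4:
        X2 = np.column_stack([s, s**2])
        beta2, _, *_ = np.linalg.lstsq(X2, v, rcond=None)
        resid2 = v - X2 @ beta2
        dof2 = len(v) - 2
        if dof2 > 0:
            sigma2_2 = float(resid2 @ resid2) / dof2
            cov2 = sigma2_2 * np.linalg.inv(X2.T @ X2)
            if cov2[1, 1] > 0:
                t_stat = beta2[1] / math.sqrt(cov2[1, 1])
                p_curv = 2 * stats.t.sf(abs(t_stat), dof2)
                if p_curv < 0.05:
                    warnings.append(
                        f"curvature detected (quadratic-term p = {p_curv:.2g}); "
                        "data may be leaving the linear regime"
                    )

    efficiency = efficiency_se = None
    if data.enzyme_mw is not None:
        efficiency = slope * data.enzyme_mw * 1e-3
        efficiency_se = slope_se * data.enzyme_mw * 1e-3
    return KineticFit(
        regime="linear",
        slope=slope,
        slope_se=slope_se,
        kcat_over_Km=efficiency,
        kcat_over_Km_se=efficiency_se,
        r_squared=r2,
        residuals=resid,
        method="linear-regression" + ("" if through_origin else "-free-intercept"),
        warnings=warnings,
    )


def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat/Km (mM^-1 min^-1) from a (kcat, Km) pair."""
    if km <= 0:
        raise ValueError(f"Km must be positive, got {km}")
    return kcat / km


def derive_kcat(fit: KineticFit, enzyme_mw: float) -> KineticFit:
    """Attach kcat (min^-1) and kcat/Km (mM^-1 min^-1) to a saturation fit.

    kcat = Vmax (umol min^-1 mg^-1) x MW (g/mol) x 1e-3.  The molar mass is
    a required user input; it is not derivable from velocity data.
    """
    if fit.Vmax is None:
        raise ValueError("derive_kcat needs a saturation fit with Vmax; fit one first")
    if enzyme_mw <= 0:
        raise ValueError(f"enzyme_mw must be positive (g/mol), got {enzyme_mw}")
    kcat = fit.Vmax * enzyme_mw * 1e-3
    kcat_se = fit.Vmax_se * enzyme_mw * 1e-3 if fit.Vmax_se is not None else None
    eff = eff_se = None
    if fit.Km:
        eff = catalytic_efficiency(kcat, fit.Km)
        if kcat_se is not None and fit.Km_se is not None and kcat > 0:
            eff_se = abs(eff) * math.sqrt((kcat_se / kcat) ** 2 + (fit.Km_se / fit.Km) ** 2)
    return replace(fit, kcat=kcat, kcat_se=kcat_se, kcat_over_Km=eff, kcat_over_Km_se=eff_se)


@dataclass(frozen=True)
class FoldChange:
    """A ratio of product yields with first-order error propagation."""

    ratio: float
    sd: float

    @property
    def rounded(self) -> float:
        """The ratio at 1-decimal reporting precision."""
        return round(self.ratio, 1)


def fold_change(
    numerator: float,
    numerator_sd: float,
    denominator: float,
    denominator_sd: float,
) -> FoldChange:
    """Fold change a/b of two product yields (e.g. g/l) with propagated sd.

    First-order propagation:
    sd(a/b) = |a/b| * sqrt((sd_a/a)^2 + (sd_b/b)^2).
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    ratio = numerator / denominator
    rel = 0.0
    if numerator != 0:
        rel += (numerator_sd / numerator) ** 2
    rel += (denominator_sd / denominator) ** 2
    return FoldChange(ratio=ratio, sd=abs(ratio) * math.sqrt(rel))
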