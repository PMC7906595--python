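"""Parameter estimation: yields from endpoints, inhibition laws from
mu-vs-Z data, and Monod constants from batch time courses.

Yield coefficients come from simple endpoint stoichiometry (grams formed
per gram of sugar consumed, averaged over initial-sugar levels).  The
inhibition law is fitted by nonlinear least squares of
``mu_max(Z) = mu_max0 * f(Z; Z_m, K_z)`` to observed maximum growth rates,
with multi-start initialisation so no user tuning is needed; candidate
families are then ranked by coefficient of determination, ties going to the
simpler family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (INHIBITION_FAMILIES, BatchState, KineticParameters,
                   YieldCoefficients, inhibition_factor)
from .errors import FitError, SelectionError, ValidationError
from .simulate import simulate_batch

__all__ = [
    "InhibitionObservation",
    "InhibitionFitResult",
    "YieldEstimate",
    "LineFit",
    "FamilySelection",
    "MonodFit",
    "estimate_yields",
    "fit_byproduct_yield",
    "fit_inhibition",
    "select_inhibition_family",
    "fit_monod_params",
    "bootstrap_inhibition",
]

#: Two fits whose R^2 differ by less than this are treated as tied and the
#: family with fewer free parameters wins (the exponential family nests the
#: linear one at K_z = 1, so exact nesting produces numerical near-ties).
R2_TIE_TOL = 1e-6


@dataclass(frozen=True)
class InhibitionObservation:
    """One spiked-byproduct growth experiment.

    ``Z``: byproduct mixture concentration added at t = 0, g/L;
    ``mu_max_obs``: the maximum specific growth coefficient fitted from that
    run, 1/h; ``K_s_obs``: the half-velocity constant from the same run
    (optional; it is expected to be insensitive to Z).
    """

    Z: float
    mu_max_obs: float
    K_s_obs: float | None = None

    def __post_init__(self) -> None:
        if self.Z < 0:
            raise ValidationError(f"Z must be >= 0, got {self.Z}")
        if self.mu_max_obs < 0:
            raise ValidationError(
                f"mu_max_obs must be >= 0, got {self.mu_max_obs}")


@dataclass
class InhibitionFitResult:
    """Nonlinear least-squares fit of one inhibition family."""

    family: str
    mu_max0_hat: float
    Z_m_hat: float | None
    K_z_hat: float | None
    r_squared: float
    converged: bool
    residuals: np.ndarray
    n_free_parameters: int

    def predict(self, Z) -> np.ndarray:
        """Fitted mu_max at byproduct level Z, 1/h."""
        return self.mu_max0_hat * np.asarray(
            inhibition_factor(self.family, Z, self.Z_m_hat, self.K_z_hat))

    def summary(self) -> str:
        parts = [f"family={self.family}",
                 f"mu_max0={self.mu_max0_hat:.4g} 1/h"]
        if self.Z_m_hat is not None:
            parts.append(f"Z_m={self.Z_m_hat:.4g} g/L")
        if self.K_z_hat is not None:
            parts.append(f"K_z={self.K_z_hat:.4g}")
        parts.append(f"R^2={self.r_squared:.4f}")
        parts.append("converged" if self.converged else "NOT converged")
        return "  ".join(parts)

    def to_row(self) -> dict:
        return {
            "family": self.family,
            "mu_max0_per_h": self.mu_max0_hat,
            "Zm_g_L": self.Z_m_hat,
            "Kz": self.K_z_hat,
            "r_squared": self.r_squared,
            "n_free_parameters": self.n_free_parameters,
            "converged": self.converged,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_row()])


@dataclass
class YieldEstimate:
    """Per-initial-sugar yield coefficients and their arithmetic averages."""

    per_s0: pd.DataFrame  # columns: S0_g_L, Y_xs, Y_ps, Y_zs
    Y_xs: float
    Y_ps: float
    Y_zs: float

    @property
    def s0_values(self) -> np.ndarray:
        return self.per_s0["S0_g_L"].to_numpy()

    def as_coefficients(self) -> YieldCoefficients:
        return YieldCoefficients(Y_xs=self.Y_xs, Y_ps=self.Y_ps, Y_zs=self.Y_zs)


@dataclass
class LineFit:
    """Ordinary least-squares line with the slope read as a yield, g/g."""

    slope: float
    intercept: float
    r_squared: float
    stderr: float | None = None


@dataclass
class FamilySelection:
    """Outcome of ranking several inhibition families on one dataset."""

    best: InhibitionFitResult
    ranking: pd.DataFrame  # one row per family, best first
    results: dict[str, InhibitionFitResult] = field(default_factory=dict)


@dataclass
class MonodFit:
    """Classical Monod constants recovered from a batch time course."""

    mu_max_hat: float
    K_s_hat: float
    converged: bool
    cost: float
    n_obs: int


# ---------------------------------------------------------------------------
# Yield estimation
# ---------------------------------------------------------------------------

def estimate_yields(endpoints: Sequence[tuple]) -> YieldEstimate:
    """Yield coefficients from growth-phase endpoint differences.

    Each record is ``(S0, dS, dX, dP, dZ)`` in g/L: initial sugar, sugar
    consumed, and biomass / ethanol / byproduct formed.  Per-record yields
    are the ratios ``dX/dS`` etc.; the reported coefficients are their
    arithmetic means across records.
    """
    if len(endpoints) == 0:
        raise ValidationError("no endpoint records given")
    rows = []
    for i, rec in enumerate(endpoints):
        s0, ds, dx, dp, dz = (float(v) for v in rec)
        if not ds > 0:
            raise ValidationError(
                f"record {i} (S0 = {s0} g/L): consumed substrate must be "
                f"> 0, got {ds}")
        rows.append({"S0_g_L": s0, "Y_xs": dx / ds, "Y_ps": dp / ds,
                     "Y_zs": dz / ds})
    per_s0 = pd.DataFrame(rows)
    return YieldEstimate(
        per_s0=per_s0,
        Y_xs=float(per_s0["Y_xs"].mean()),
        Y_ps=float(per_s0["Y_ps"].mean()),
        Y_zs=float(per_s0["Y_zs"].mean()),
    )


def fit_byproduct_yield(points: Sequence[tuple[float, float]],
                        through_origin: bool = False) -> LineFit:
    """Slope of final byproduct concentration against initial sugar, g/g.

    Byproduct formation rises linearly with initial glucose over
    25-250 g/L, so the slope of an ordinary least-squares line
    ``Z_final = a * S0 + b`` is the lumped byproduct yield; the intercept is
    expected to be near zero and a through-origin variant is available.
    """
    if len(points) < 2:
        raise ValidationError("need at least 2 points to fit a line")
    s0 = np.asarray([p[0] for p in points], dtype=float)
    zf = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(s0) == 0:
        raise FitError("degenerate design: all initial-sugar values equal")
    if through_origin:
        slope = float(s0 @ zf / (s0 @ s0))
        pred = slope * s0
        ss_tot = float(np.sum((zf - zf.mean()) ** 2))
        ss_res = float(np.sum((zf - pred) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
        return LineFit(slope=slope, intercept=0.0, r_squared=r2)
    res = stats.linregress(s0, zf)
    return LineFit(slope=float(res.slope), intercept=float(res.intercept),
                   r_squared=float(res.rvalue**2), stderr=float(res.stderr))


# ---------------------------------------------------------------------------
# Inhibition-law fitting
# ---------------------------------------------------------------------------

def _prepare_obs(obs: Sequence[InhibitionObservation]
                 ) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray([o.Z for o in obs], dtype=float)
    mu = np.asarray([o.mu_max_obs for o in obs], dtype=float)
    order = np.argsort(z)
    return z[order], mu[order]


def fit_inhibition(obs: Sequence[InhibitionObservation], family: str,
                   fix_mu_max0: float | None = None) -> InhibitionFitResult:
    """Fit ``mu_max(Z) = mu_max0 * f(Z; Z_m, K_z)`` by nonlinear least squares.

    Multi-start initialisation: Z_m starts at 1.2x the largest Z with
    observed growth; K_z (exponential family only) starts at 0.5, 1 and 2;
    mu_max0 starts at the observation nearest Z = 0.  ``fix_mu_max0`` pins
    the uninhibited growth rate instead of estimating it.  Never raises on
    non-convergence; the result carries an honest ``converged`` flag.
    """
    fam = INHIBITION_FAMILIES.get(family)
    if fam is None:
        raise ValidationError(f"unknown inhibition family {family!r}")
    if len(obs) < 3:
        raise ValidationError(
            f"need at least 3 observations to fit an inhibition law, "
            f"got {len(obs)}")
    z, mu = _prepare_obs(obs)

    growing = z[mu > 0]
    z_top = float(growing.max()) if growing.size else float(z.max())
    zm_floor = z_top * (1.0 + 1e-6) if z_top > 0 else 1e-6
    mu0_start = float(mu[0]) if mu[0] > 0 else float(mu.max())
    if fix_mu_max0 is not None and not fix_mu_max0 > 0:
        raise ValidationError(f"fix_mu_max0 must be > 0, got {fix_mu_max0}")

    free = list(fam.free_parameters)
    if fix_mu_max0 is not None:
        free.remove("mu_max0")

    def unpack(theta: np.ndarray) -> tuple[float, float | None, float | None]:
        vals = dict(zip(free, theta))
        mu0 = fix_mu_max0 if fix_mu_max0 is not None else vals["mu_max0"]
        return (float(mu0), vals.get("Z_m"), vals.get("K_z"))

    def residuals(theta: np.ndarray) -> np.ndarray:
        mu0, zm, kz = unpack(theta)
        return mu0 * np.asarray(inhibition_factor(family, z, zm, kz)) - mu

    bounds_by_name = {
        "mu_max0": (1e-9, 10.0),
        "Z_m": (zm_floor, 1e4),
        "K_z": (1e-3, 50.0),
    }
    lower = np.array([bounds_by_name[n][0] for n in free])
    upper = np.array([bounds_by_name[n][1] for n in free])

    start_by_name = {"mu_max0": mu0_start, "Z_m": 1.2 * max(z_top, 1e-3)}
    kz_starts = [0.5, 1.0, 2.0] if "K_z" in free else [None]

    best = None
    for kz0 in kz_starts:
        theta0 = np.array([
            start_by_name[n] if n != "K_z" else kz0 for n in free])
        theta0 = np.clip(theta0, lower, upper)
        try:
            sol = optimize.least_squares(residuals, theta0,
                                         bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    ss_tot = float(np.sum((mu - mu.mean()) ** 2))
    n_free = len(free)
    if best is None:
        return InhibitionFitResult(
            family=family, mu_max0_hat=mu0_start,
            Z_m_hat=start_by_name.get("Z_m") if "Z_m" in fam.free_parameters else None,
            K_z_hat=kz_starts[0] if "K_z" in free else None,
            r_squared=-math.inf, converged=False,
            residuals=np.full_like(mu, math.nan), n_free_parameters=n_free)

    mu0, zm, kz = unpack(best.x)
    resid = best.fun
    ss_res = float(resid @ resid)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return InhibitionFitResult(
        family=family, mu_max0_hat=mu0, Z_m_hat=zm, K_z_hat=kz,
        r_squared=r2, converged=bool(best.success),
        residuals=resid, n_free_parameters=n_free)


def select_inhibition_family(obs: Sequence[InhibitionObservation],
                             families: Sequence[str],
                             fix_mu_max0: float | None = None
                             ) -> FamilySelection:
    """Fit each candidate family and rank by R^2 (ties to fewer parameters)."""
    if len(families) < 2:
        raise ValidationError(
            f"need at least 2 candidate families, got {len(families)}")
    results = {f: fit_inhibition(obs, f, fix_mu_max0=fix_mu_max0)
               for f in families}
    converged = {f: r for f, r in results.items() if r.converged}
    if not converged:
        raise SelectionError("no candidate family fit converged")

    def sort_key(item):
        f, r = item
        # quantise R^2 so near-exact ties fall to the simpler family
        return (-round(r.r_squared / R2_TIE_TOL), r.n_free_parameters)

    ordered = sorted(converged.items(), key=sort_key)
    ranking = pd.DataFrame(
        [r.to_row() for _, r in ordered]
        + [results[f].to_row() for f in families if f not in converged])
    return FamilySelection(best=ordered[0][1], ranking=ranking,
                           results=results)


def bootstrap_inhibition(obs: Sequence[InhibitionObservation], family: str,
                         n_boot: int = 200, seed: int = 0,
                         level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Residual-bootstrap percentile intervals for the fitted parameters.

    Growth-rate measurement error scales with the measured value, so raw
    residuals are heteroscedastic; they are standardised by the fitted
    values before resampling and rescaled on reassignment.  Bootstrap
    refits start from the full-data estimates.  Returns
    ``{parameter: (lo, hi)}`` for every free parameter.
    """
    base = fit_inhibition(obs, family)
    if not base.converged:
        raise FitError("cannot bootstrap a non-converged fit")
    z, mu = _prepare_obs(obs)
    fitted = base.predict(z)
    scale = np.maximum(fitted, 1e-3 * max(float(fitted.max()), 1e-12))
    std_resid = (mu - fitted) / scale
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {"mu_max0": [], "Z_m": [], "K_z": []}
    for _ in range(n_boot):
        mu_b = np.maximum(
            fitted + scale * rng.choice(std_resid, size=std_resid.size), 0.0)
        obs_b = [InhibitionObservation(Z=zi, mu_max_obs=mi)
                 for zi, mi in zip(z, mu_b)]
        fit_b = _refit_from(obs_b, family, start=base)
        draws["mu_max0"].append(fit_b.mu_max0_hat)
        if fit_b.Z_m_hat is not None:
            draws["Z_m"].append(fit_b.Z_m_hat)
        if fit_b.K_z_hat is not None:
            draws["K_z"].append(fit_b.K_z_hat)
    alpha = (1.0 - level) / 2.0
    out = {}
    for name, vals in draws.items():
        if vals:
            arr = np.asarray(vals)
            out[name] = (float(np.quantile(arr, alpha)),
                         float(np.quantile(arr, 1.0 - alpha)))
    return out


def _refit_from(obs: Sequence[InhibitionObservation], family: str,
                start: InhibitionFitResult) -> InhibitionFitResult:
    """Single-start refit seeded at a previous estimate (bootstrap helper)."""
    fam = INHIBITION_FAMILIES[family]
    z, mu = _prepare_obs(obs)
    free = list(fam.free_parameters)
    start_vals = {"mu_max0": start.mu_max0_hat, "Z_m": start.Z_m_hat,
                  "K_z": start.K_z_hat}
    growing = z[mu > 0]
    z_top = float(growing.max()) if growing.size else float(z.max())
    zm_floor = z_top * (1.0 + 1e-6) if z_top > 0 else 1e-6
    bounds_by_name = {"mu_max0": (1e-9, 10.0), "Z_m": (zm_floor, 1e4),
                      "K_z": (1e-3, 50.0)}
    lower = np.array([bounds_by_name[n][0] for n in free])
    upper = np.array([bounds_by_name[n][1] for n in free])
    theta0 = np.clip(np.array([start_vals[n] for n in free]), lower, upper)

    def residuals(theta):
        vals = dict(zip(free, theta))
        return vals["mu_max0"] * np.asarray(
            inhibition_factor(family, z, vals.get("Z_m"), vals.get("K_z"))
        ) - mu

    sol = optimize.least_squares(residuals, theta0, bounds=(lower, upper),
                                 method="trf")
    vals = dict(zip(free, sol.x))
    resid = sol.fun
    ss_tot = float(np.sum((mu - mu.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else math.nan
    return InhibitionFitResult(
        family=family, mu_max0_hat=float(vals["mu_max0"]),
        Z_m_hat=vals.get("Z_m"), K_z_hat=vals.get("K_z"), r_squared=r2,
        converged=bool(sol.success), residuals=resid,
        n_free_parameters=len(free))


# ---------------------------------------------------------------------------
# Monod-constant recovery from a time course
# ---------------------------------------------------------------------------

def fit_monod_params(obs_course: pd.DataFrame, yields: YieldCoefficients,
                     dt: float = 0.05) -> MonodFit:
    """Recover (mu_max, K_s) by fitting simulated classical-Monod trajectories
    to an observed batch time course.

    ``obs_course`` needs columns ``time_h``, ``biomass_g_L`` and
    ``glucose_g_L`` with at least 5 samples spanning growth and depletion.
    Biomass and glucose residuals are weighted equally after dividing each
    variable by its observed range, and minimised over simulated
    trajectories started from the first observed sample.
    """
    required = ("time_h", "biomass_g_L", "glucose_g_L")
    for col in required:
        if col not in obs_course.columns:
            raise ValidationError(f"observed course lacks column {col!r}")
    course = obs_course.dropna(subset=list(required)).reset_index(drop=True)
    if len(course) < 5:
        raise ValidationError(
            f"need at least 5 complete samples, got {len(course)}")
    t_obs = course["time_h"].to_numpy(dtype=float)
    x_obs = course["biomass_g_L"].to_numpy(dtype=float)
    s_obs = course["glucose_g_L"].to_numpy(dtype=float)
    x_range = float(np.ptp(x_obs))
    s_range = float(np.ptp(s_obs))
    if s_range <= 0 or x_range <= 0:
        raise FitError(
            "time course carries no depletion/growth information "
            "(constant substrate or biomass)")

    t_end = float(t_obs[-1] - t_obs[0])
    initial = BatchState(t=float(t_obs[0]), X=float(x_obs[0]),
                         S=float(s_obs[0]), P=0.0, Z=0.0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        mu_max, ks = theta
        params = KineticParameters(mu_max0=mu_max, K_s=ks, family="none")
        traj = simulate_batch(initial, params, yields, t_end=t_end, dt=dt)
        sim = traj.sample(t_obs)
        return np.concatenate([
            (sim["biomass_g_L"].to_numpy() - x_obs) / x_range,
            (sim["glucose_g_L"].to_numpy() - s_obs) / s_range,
        ])

    # crude growth-rate guess from the steepest observed log-biomass slope
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.diff(np.log(np.maximum(x_obs, 1e-12))) / np.diff(t_obs)
    mu_guess = float(np.nanmax(slopes)) if np.isfinite(slopes).any() else 0.2
    mu_guess = min(max(mu_guess, 1e-3), 5.0)

    best = None
    for ks0 in (1.0, 10.0, 50.0):
        try:
            sol = optimize.least_squares(
                residuals, np.array([mu_guess, ks0]),
                bounds=(np.array([1e-4, 1e-3]), np.array([5.0, 500.0])),
                method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return MonodFit(mu_max_hat=mu_guess, K_s_hat=10.0, converged=False,
                        cost=math.inf, n_obs=len(course))
    return MonodFit(mu_max_hat=float(best.x[0]), K_s_hat=float(best.x[1]),
                    converged=bool(best.success), cost=float(best.cost),
                    n_obs=len(course))
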