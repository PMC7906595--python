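"""Synthetic data generation and literature-calibrated reference values.

No public repository deposits batch time courses for this system, so every
dataset the calibration and evaluation workflows consume can be generated
here: noisy batch time courses from the model itself, mu-vs-Z inhibition
curves from the spiked-byproduct experiment design, and endpoint yield
tables.  The noise model is multiplicative Gaussian with an additive floor
(sd = relative_sd * value + floor_sd, truncated at zero), an approximation
of HPLC / spectrophotometer repeatability; the default relative sd is 5%.

:func:`reference_dataset` bundles the calibrated constants and printed
measurements of the glucose/S. cerevisiae batch study this package models;
those values are the package defaults throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (BatchState, ByproductMixture, KineticParameters,
                   YieldCoefficients, inhibition_factor)
from .calibrate import InhibitionObservation
from .errors import ValidationError
from .simulate import simulate_batch

__all__ = ["NoiseModel", "generate_timecourse", "generate_mu_vs_z",
           "generate_yield_endpoints", "reference_dataset", "ReferenceData",
           "SAMPLE_SCHEDULE_H"]

#: Sampling schedule of the batch experiments, h (13 samples over 72 h).
SAMPLE_SCHEDULE_H = (0, 2, 4, 6, 8, 10, 12, 18, 24, 30, 36, 48, 72)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-error model: sd = relative_sd * value + floor_sd, >= 0."""

    relative_sd: float = 0.05
    floor_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValidationError(
                f"relative_sd must be >= 0, got {self.relative_sd}")
        if self.floor_sd < 0:
            raise ValidationError(
                f"floor_sd must be >= 0, got {self.floor_sd}")

    def perturb(self, values: np.ndarray, rng: np.random.Generator
                ) -> np.ndarray:
        sd = self.relative_sd * np.abs(values) + self.floor_sd
        return np.maximum(values + rng.normal(0.0, 1.0, values.shape) * sd,
                          0.0)


def generate_timecourse(params: KineticParameters, yields: YieldCoefficients,
                        initial: BatchState, sample_times=SAMPLE_SCHEDULE_H,
                        noise: NoiseModel | None = None,
                        dt: float = 0.01) -> pd.DataFrame:
    """Simulate a batch and sample it at the given times, optionally noisy.

    Returns the standard five-column observed-course table.  Deterministic
    given the noise model's seed; ``noise=None`` returns exact model values.
    """
    times = np.asarray(sample_times, dtype=float)
    t_end = float(times.max() - float(initial.t))
    traj = simulate_batch(initial, params, yields,
                          t_end=max(t_end, dt), dt=dt)
    course = traj.sample(times)
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        for col in ("biomass_g_L", "glucose_g_L", "ethanol_g_L",
                    "byproduct_g_L"):
            course[col] = noise.perturb(course[col].to_numpy(), rng)
    return course


def generate_mu_vs_z(params: KineticParameters, z_grid,
                     noise: NoiseModel | None = None
                     ) -> list[InhibitionObservation]:
    """Emulate the spiked-byproduct growth experiment.

    For each byproduct level in ``z_grid`` the observed maximum growth rate
    is ``mu_max0 * f(Z)`` plus noise (truncated at zero); levels above Z_m
    map to zero growth.  The accompanying K_s observation is drawn uniformly
    from the experimentally stable 11.4-11.7 g/L band.
    """
    z = np.asarray(z_grid, dtype=float)
    if np.any(z < 0):
        raise ValidationError("byproduct levels must be >= 0")
    mu = params.mu_max0 * np.asarray(
        inhibition_factor(params.family, z, params.Z_m, params.K_z))
    rng = np.random.default_rng(noise.seed if noise is not None else 0)
    if noise is not None:
        mu = noise.perturb(mu, rng)
    ks = rng.uniform(11.4, 11.7, size=z.size)
    return [InhibitionObservation(Z=float(zi), mu_max_obs=float(mi),
                                  K_s_obs=float(ki))
            for zi, mi, ki in zip(z, mu, ks)]


def generate_yield_endpoints(params: KineticParameters,
                             yields: YieldCoefficients,
                             s0_values=(25, 50, 100, 150, 200, 250),
                             noise: NoiseModel | None = None,
                             X0: float = 1.0, t_end: float = 200.0,
                             dt: float = 0.02) -> list[tuple]:
    """Endpoint records ``(S0, dS, dX, dP, dZ)`` from simulated complete batches."""
    rng = np.random.default_rng(noise.seed if noise is not None else 0)
    records = []
    for s0 in s0_values:
        traj = simulate_batch(BatchState(t=0, X=X0, S=float(s0), P=0, Z=0),
                              params, yields, t_end=t_end, dt=dt)
        fin = traj.final
        deltas = np.array([s0 - fin.S, fin.X - X0, fin.P, fin.Z])
        if noise is not None:
            deltas = noise.perturb(deltas, rng)
        records.append((float(s0), *map(float, deltas)))
    return records


@dataclass(frozen=True)
class ReferenceData:
    """Calibrated constants and printed measurements of the reference study."""

    #: per-initial-sugar yield coefficients (six levels, 25-250 g/L)
    yield_table: pd.DataFrame
    #: arithmetic averages of the yield-table columns
    yields: YieldCoefficients
    #: calibrated growth/inhibition constants (exponential family)
    params: KineticParameters
    #: observed stability band of K_s across byproduct levels, g/L
    ks_range: tuple[float, float]
    #: byproduct mass fractions at the end of fermentation
    mixture: ByproductMixture
    #: final byproduct concentrations at S0 = 100 g/L, g/L
    endpoint_byproducts: dict[str, float]
    #: per-component byproduct yields, g per g glucose
    component_yields: dict[str, float]
    #: sampling schedule of the batch experiments, h
    sample_times: tuple = SAMPLE_SCHEDULE_H


def reference_dataset() -> ReferenceData:
    """The literature-calibrated parameter set and printed measurements.

    These values anchor the package defaults: mu_max0 = 0.244 1/h,
    K_s = 11.5 g/L (midpoint of the 11.4-11.7 band), Z_m = 60 g/L,
    K_z = 0.83 with the exponential (power-law) inhibition family, and
    average yields Y_xs = 0.28, Y_ps = 0.42, Y_zs = 0.0442 g/g.
    """
    yield_table = pd.DataFrame({
        "S0_g_L": [25, 50, 100, 150, 200, 250],
        "Y_xs": [0.27, 0.28, 0.27, 0.29, 0.30, 0.27],
        "Y_ps": [0.39, 0.43, 0.41, 0.42, 0.44, 0.43],
        "Y_zs": [0.0427, 0.0432, 0.0441, 0.0445, 0.0453, 0.0456],
    })
    return ReferenceData(
        yield_table=yield_table,
        yields=YieldCoefficients(Y_xs=0.28, Y_ps=0.42, Y_zs=0.0442),
        params=KineticParameters(mu_max0=0.244, K_s=11.5, Z_m=60.0,
                                 K_z=0.83, family="exponential"),
        ks_range=(11.4, 11.7),
        mixture=ByproductMixture(frac_glycerol=0.56, frac_acetic=0.36,
                                 frac_succinic=0.08),
        endpoint_byproducts={"glycerol": 1.8, "acetic": 0.95,
                             "succinic": 0.8, "total": 3.55},
        component_yields={"total": 0.0442, "glycerol": 0.023,
                          "acetic": 0.0155, "succinic": 0.0054},
    )
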