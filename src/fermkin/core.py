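"""Rate laws for batch alcoholic fermentation under byproduct inhibition.

The growth model is Monod kinetics in the limiting sugar ``S``,

    mu(S) = mu_max * S / (K_s + S),

multiplied by a dimensionless inhibition factor ``f(Z)`` in [0, 1] driven by
the lumped byproduct pool ``Z`` (glycerol + acetic acid + succinic acid in
yeast glucose fermentations):

    mu(S, Z) = mu_max0 * S / (K_s + S) * f(Z).

``f`` satisfies two limit conditions: no byproduct means no inhibition
(``f(0) = 1``) and growth stops entirely at a critical byproduct
concentration ``Z_m`` (``f(Z) = 0`` for ``Z >= Z_m``).  Three candidate
families with these limits are registered here — linear, parabolic, and a
Luong-type power law (the "exponential" family) — plus the trivial ``none``
family that recovers the classical Monod model.

Biomass ``X``, ethanol ``P`` and byproducts ``Z`` are coupled to sugar
consumption through constant yield coefficients, so a batch culture obeys

    dX/dt =  mu(S, Z) * X
    dS/dt = -mu(S, Z) * X / Y_xs
    dP/dt = -Y_ps * dS/dt
    dZ/dt = -Y_zs * dS/dt

with no maintenance or decay terms.  Units are fixed package-wide: hours,
g/L, and 1/h; there is no unit-conversion layer.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DomainError, ValidationError

__all__ = [
    "KineticParameters",
    "YieldCoefficients",
    "BatchState",
    "ByproductMixture",
    "InhibitionFamily",
    "INHIBITION_FAMILIES",
    "register_family",
    "monod_mu",
    "inhibition_factor",
    "modified_mu",
    "batch_rhs",
    "split_byproducts",
]


# ---------------------------------------------------------------------------
# Inhibition-family registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InhibitionFamily:
    """One candidate analytic form for the inhibition factor ``f(Z)``.

    ``raw`` evaluates the unclamped law on the ratio ``Z/Z_m`` (already
    guaranteed to lie in [0, 1] by the caller); ``free_parameters`` lists the
    parameters estimated when this family is fitted to growth-rate data,
    which also defines the complexity used for selection tie-breaks.
    """

    name: str
    raw: Callable[[np.ndarray, float], np.ndarray]
    free_parameters: tuple[str, ...]
    requires_kz: bool = False

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameters)


INHIBITION_FAMILIES: dict[str, InhibitionFamily] = {}


def register_family(family: InhibitionFamily) -> None:
    """Add an inhibition family to the registry (extension point)."""
    INHIBITION_FAMILIES[family.name] = family


register_family(InhibitionFamily(
    name="none",
    raw=lambda r, kz: np.ones_like(r),
    free_parameters=("mu_max0",),
))
register_family(InhibitionFamily(
    name="linear",
    raw=lambda r, kz: 1.0 - r,
    free_parameters=("mu_max0", "Z_m"),
))
register_family(InhibitionFamily(
    name="parabolic",
    raw=lambda r, kz: 1.0 - r**2,
    free_parameters=("mu_max0", "Z_m"),
))
register_family(InhibitionFamily(
    # Luong-type power law (1 - Z/Z_m)**K_z; reduces to linear at K_z = 1.
    name="exponential",
    raw=lambda r, kz: (1.0 - r) ** kz,
    free_parameters=("mu_max0", "Z_m", "K_z"),
    requires_kz=True,
))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParameters:
    """Growth and inhibition constants of the modified Monod model.

    Parameters
    ----------
    mu_max0
        Maximum specific growth rate without byproduct inhibition, 1/h.
    K_s
        Half-velocity (half-saturation) constant, g/L.
    Z_m
        Byproduct concentration at total inhibition, g/L.  Unused (may be
        ``None``) when ``family`` is ``"none"``.
    K_z
        Dimensionless byproduct-inhibition exponent; required only by the
        exponential family.
    family
        Inhibition-family tag; one of :data:`INHIBITION_FAMILIES`.
    """

    mu_max0: float
    K_s: float
    Z_m: float | None = None
    K_z: float | None = None
    family: str = "none"

    def __post_init__(self) -> None:
        if not self.mu_max0 > 0:
            raise DomainError(f"mu_max0 must be > 0, got {self.mu_max0}")
        if not self.K_s > 0:
            raise DomainError(f"K_s must be > 0, got {self.K_s}")
        fam = INHIBITION_FAMILIES.get(self.family)
        if fam is None:
            raise ConfigError(
                f"unknown inhibition family {self.family!r}; "
                f"known: {sorted(INHIBITION_FAMILIES)}")
        if fam.name != "none":
            if self.Z_m is None or not self.Z_m > 0:
                raise DomainError(
                    f"Z_m must be > 0 for family {fam.name!r}, got {self.Z_m}")
            if fam.requires_kz and (self.K_z is None or not self.K_z > 0):
                raise DomainError(
                    f"K_z must be > 0 for family {fam.name!r}, got {self.K_z}")

    def without_inhibition(self) -> "KineticParameters":
        """Same growth constants with the inhibition term switched off."""
        return replace(self, family="none")


@dataclass(frozen=True)
class YieldCoefficients:
    """Stoichiometric couplings: grams formed per gram of sugar consumed.

    ``Y_xs`` (biomass), ``Y_ps`` (ethanol), ``Y_zs`` (byproducts); the
    remainder of the carbon is CO2 and maintenance, which are not tracked,
    so the three yields must sum to at most 1.
    """

    Y_xs: float
    Y_ps: float
    Y_zs: float

    def __post_init__(self) -> None:
        for name in ("Y_xs", "Y_ps", "Y_zs"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DomainError(f"{name} must lie in (0, 1), got {v}")
        total = self.Y_xs + self.Y_ps + self.Y_zs
        if total > 1.0 + 1e-9:
            raise DomainError(
                f"yield coefficients sum to {total:.4f} > 1 (unphysical)")


@dataclass(frozen=True)
class BatchState:
    """The instantaneous state of a batch culture.

    ``t`` time (h); ``X`` biomass, ``S`` glucose, ``P`` ethanol, ``Z`` total
    byproducts (all g/L).
    """

    t: float
    X: float
    S: float
    P: float
    Z: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise DomainError(f"t must be >= 0, got {self.t}")
        for name in ("X", "S", "P", "Z"):
            v = getattr(self, name)
            if v < 0:
                raise DomainError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class ByproductMixture:
    """Mass fractions of the lumped byproduct pool.

    Defaults are the composition observed at the end of glucose batch
    fermentations: 56% glycerol, 36% acetic acid, 8% succinic acid.
    """

    frac_glycerol: float = 0.56
    frac_acetic: float = 0.36
    frac_succinic: float = 0.08

    def __post_init__(self) -> None:
        fracs = (self.frac_glycerol, self.frac_acetic, self.frac_succinic)
        for name, v in zip(("frac_glycerol", "frac_acetic", "frac_succinic"), fracs):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError(
                f"mixture fractions must sum to 1, got {sum(fracs)!r}")


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def monod_mu(mu_max: float, K_s: float, S):
    """Monod specific growth rate ``mu_max * S / (K_s + S)``, 1/h.

    ``S`` may be a scalar or an array; the result is in ``[0, mu_max)``.
    """
    if not mu_max > 0:
        raise DomainError(f"mu_max must be > 0, got {mu_max}")
    if not K_s > 0:
        raise DomainError(f"K_s must be > 0, got {K_s}")
    s = np.asarray(S, dtype=float)
    if np.any(s < 0):
        raise DomainError(f"S must be >= 0, got {S}")
    out = mu_max * s / (K_s + s)
    return float(out) if out.ndim == 0 else out


def inhibition_factor(family: str, Z, Z_m: float | None = None,
                      K_z: float | None = None):
    """Multiplicative growth-inhibition factor ``f(Z)`` in [0, 1].

    ``f(0) = 1``; ``f(Z) = 0`` for ``Z >= Z_m`` (clamped, never negative);
    monotone non-increasing in ``Z`` for every registered family.  ``Z`` may
    be a scalar or an array.
    """
    fam = INHIBITION_FAMILIES.get(family)
    if fam is None:
        raise ConfigError(
            f"unknown inhibition family {family!r}; known: "
            f"{sorted(INHIBITION_FAMILIES)}")
    z = np.asarray(Z, dtype=float)
    if np.any(z < 0):
        raise DomainError(f"Z must be >= 0, got {Z}")
    if fam.name == "none":
        out = np.ones_like(z)
        return float(out) if out.ndim == 0 else out
    if Z_m is None or not Z_m > 0:
        raise DomainError(f"Z_m must be > 0, got {Z_m}")
    if fam.requires_kz:
        if K_z is None or not K_z > 0:
            raise DomainError(f"K_z must be > 0 for family {fam.name!r}")
        kz = float(K_z)
    else:
        kz = 1.0
    ratio = np.minimum(z / Z_m, 1.0)  # total inhibition beyond Z_m
    out = np.clip(fam.raw(ratio, kz), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def modified_mu(params: KineticParameters, S, Z):
    """Byproduct-inhibited specific growth rate, 1/h.

    The byproduct pool scales only the maximum growth rate; the
    half-velocity constant is unaffected by ``Z``.
    """
    return monod_mu(params.mu_max0, params.K_s, S) * inhibition_factor(
        params.family, Z, params.Z_m, params.K_z)


def _rhs(x: float, s: float, p: float, z: float,
         params: KineticParameters, yields: YieldCoefficients
         ) -> tuple[float, float, float, float]:
    """Raw right-hand side on plain floats (no state-object overhead).

    Exhausted substrate or an absent inoculum freezes the system.  The
    product and byproduct derivatives are exact constant multiples of the
    biomass derivative, which is what makes mass balance hold exactly under
    any linear-combination integrator.
    """
    if s <= 0.0 or x <= 0.0:
        return 0.0, 0.0, 0.0, 0.0
    mu = monod_mu(params.mu_max0, params.K_s, s) * inhibition_factor(
        params.family, z, params.Z_m, params.K_z)
    dx = mu * x
    ds = -dx / yields.Y_xs
    return dx, ds, -yields.Y_ps * ds, -yields.Y_zs * ds


def batch_rhs(state: BatchState, params: KineticParameters,
              yields: YieldCoefficients) -> tuple[float, float, float, float]:
    """Time derivatives ``(dX/dt, dS/dt, dP/dt, dZ/dt)`` of the batch system, g/L/h."""
    return _rhs(state.X, state.S, state.P, state.Z, params, yields)


def split_byproducts(Z: float, mixture: ByproductMixture
                     ) -> tuple[float, float, float]:
    """Partition the lumped pool ``Z`` into (glycerol, acetic, succinic), g/L.

    The succinic component is computed by difference so the three parts sum
    to ``Z`` exactly in floating point.
    """
    if Z < 0:
        raise DomainError(f"Z must be >= 0, got {Z}")
    glycerol = Z * mixture.frac_glycerol
    acetic = Z * mixture.frac_acetic
    succinic = Z - glycerol - acetic
    if succinic < 0:  # roundoff guard for degenerate mixtures
        succinic = 0.0
    return glycerol, acetic, succinic
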