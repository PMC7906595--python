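"""Run configuration: one JSON document describing a complete batch run.

Schema (all keys optional except none — missing sections fall back to the
literature-calibrated defaults; unknown keys anywhere are rejected by name):

.. code-block:: json

    {
      "params":  {"mu_max0": 0.244, "K_s": 11.5, "Z_m": 60.0,
                  "K_z": 0.83, "family": "exponential"},
      "yields":  {"Y_xs": 0.28, "Y_ps": 0.42, "Y_zs": 0.0442},
      "mixture": {"frac_glycerol": 0.56, "frac_acetic": 0.36,
                  "frac_succinic": 0.08},
      "initial": {"X": 1.0, "S": 100.0, "P": 0.0, "Z": 0.0},
      "t_end": 72.0,
      "dt": 0.01,
      "threshold_fraction": 0.01,
      "seed": 0
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import (BatchState, ByproductMixture, KineticParameters,
                   YieldCoefficients)
from .errors import ConfigError

__all__ = ["RunConfig"]


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {unknown} in config section {section!r}; "
            f"allowed: {sorted(allowed)}")


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of everything a simulation or comparison run needs."""

    params: KineticParameters
    yields: YieldCoefficients
    initial: BatchState
    mixture: ByproductMixture = field(default_factory=ByproductMixture)
    t_end: float = 72.0
    dt: float = 0.01
    threshold_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ConfigError(f"t_end must be > 0, got {self.t_end}")
        if not self.dt > 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if self.dt > self.t_end:
            raise ConfigError(f"dt = {self.dt} exceeds t_end = {self.t_end}")
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ConfigError(
                "threshold_fraction must lie in (0, 1], got "
                f"{self.threshold_fraction}")
        if self.seed < 0:
            raise ConfigError(f"seed must be >= 0, got {self.seed}")

    @classmethod
    def calibrated(cls, S0: float = 100.0, X0: float = 1.0,
                   Z0: float = 0.0) -> "RunConfig":
        """Defaults: literature-calibrated constants, X0 = 1 g/L inoculum.

        ``Z0 > 0`` supports spiked-byproduct experiments.
        """
        from .synthetic import reference_dataset
        ref = reference_dataset()
        return cls(params=ref.params, yields=ref.yields, mixture=ref.mixture,
                   initial=BatchState(t=0.0, X=X0, S=S0, P=0.0, Z=Z0))

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        _check_keys("<top level>", doc,
                    {"params", "yields", "mixture", "initial", "t_end", "dt",
                     "threshold_fraction", "seed"})
        defaults = cls.calibrated()

        p = doc.get("params")
        if p is None:
            params = defaults.params
        else:
            _check_keys("params", p, {"mu_max0", "K_s", "Z_m", "K_z",
                                      "family"})
            params = KineticParameters(**p)

        y = doc.get("yields")
        if y is None:
            yields = defaults.yields
        else:
            _check_keys("yields", y, {"Y_xs", "Y_ps", "Y_zs"})
            yields = YieldCoefficients(**y)

        m = doc.get("mixture")
        if m is None:
            mixture = defaults.mixture
        else:
            _check_keys("mixture", m,
                        {"frac_glycerol", "frac_acetic", "frac_succinic"})
            mixture = ByproductMixture(**m)

        i = doc.get("initial")
        if i is None:
            initial = defaults.initial
        else:
            _check_keys("initial", i, {"t", "X", "S", "P", "Z"})
            initial = BatchState(t=float(i.get("t", 0.0)), X=float(i["X"]),
                                 S=float(i["S"]), P=float(i.get("P", 0.0)),
                                 Z=float(i.get("Z", 0.0)))

        return cls(params=params, yields=yields, mixture=mixture,
                   initial=initial,
                   t_end=float(doc.get("t_end", defaults.t_end)),
                   dt=float(doc.get("dt", defaults.dt)),
                   threshold_fraction=float(
                       doc.get("threshold_fraction",
                               defaults.threshold_fraction)),
                   seed=int(doc.get("seed", defaults.seed)))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON in {path}: {exc}") from None
        if not isinstance(doc, dict):
            raise ConfigError(f"config root must be a JSON object in {path}")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {k: v for k, v in {
                "mu_max0": p.mu_max0, "K_s": p.K_s, "Z_m": p.Z_m,
                "K_z": p.K_z, "family": p.family}.items() if v is not None},
            "yields": {"Y_xs": self.yields.Y_xs, "Y_ps": self.yields.Y_ps,
                       "Y_zs": self.yields.Y_zs},
            "mixture": {"frac_glycerol": self.mixture.frac_glycerol,
                        "frac_acetic": self.mixture.frac_acetic,
                        "frac_succinic": self.mixture.frac_succinic},
            "initial": {"t": self.initial.t, "X": self.initial.X,
                        "S": self.initial.S, "P": self.initial.P,
                        "Z": self.initial.Z},
            "t_end": self.t_end,
            "dt": self.dt,
            "threshold_fraction": self.threshold_fraction,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")
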