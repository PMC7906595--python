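"""Delimited-text readers and writers.

All tabular I/O is comma-separated UTF-8 text with a '.' decimal separator
and units spelled out in the header, so files are unambiguous across
locales.  Layouts:

* time courses — ``time_h, biomass_g_L, glucose_g_L, ethanol_g_L,
  byproduct_g_L``; one row per sample, empty cells mark missing
  measurements, times strictly increasing;
* mu-vs-Z observations — ``Z_g_L, mu_max_per_h[, Ks_g_L]``;
* yield endpoints — ``S0_g_L, dS_g_L, dX_g_L, dP_g_L, dZ_g_L``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import InhibitionObservation
from .errors import ParseError

__all__ = [
    "TIMECOURSE_COLUMNS",
    "read_timecourse",
    "write_timecourse",
    "read_mu_observations",
    "write_mu_observations",
    "read_yield_endpoints",
]

TIMECOURSE_COLUMNS = ("time_h", "biomass_g_L", "glucose_g_L", "ethanol_g_L",
                      "byproduct_g_L")
MU_OBS_COLUMNS = ("Z_g_L", "mu_max_per_h", "Ks_g_L")
ENDPOINT_COLUMNS = ("S0_g_L", "dS_g_L", "dX_g_L", "dP_g_L", "dZ_g_L")


def _read_table(path, required: Sequence[str], optional: Sequence[str]
                ) -> pd.DataFrame:
    """Parse a CSV by column name; numeric cells only, empty cells -> NaN.

    Errors carry 1-based line numbers (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ParseError("empty file", line=1) from None
        known = set(required) | set(optional)
        unknown = [h for h in header if h not in known]
        if unknown:
            raise ParseError(
                f"unknown column(s) {unknown}; expected from {sorted(known)}",
                line=1)
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(f"missing required column(s) {missing}", line=1)
        rows = []
        for lineno, raw in enumerate(reader, start=2):
            if not raw or all(not c.strip() for c in raw):
                continue
            if len(raw) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, found {len(raw)}",
                    line=lineno)
            row = {}
            for col, cell in zip(header, raw):
                cell = cell.strip()
                if cell == "":
                    row[col] = np.nan
                    continue
                try:
                    row[col] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"non-numeric value {cell!r} in column {col!r}",
                        line=lineno) from None
            rows.append(row)
    if not rows:
        raise ParseError("no data rows", line=2)
    return pd.DataFrame(rows)


def read_timecourse(path) -> pd.DataFrame:
    """Read an observed batch time course; validates strictly increasing times."""
    df = _read_table(path, required=("time_h",),
                     optional=TIMECOURSE_COLUMNS[1:])
    t = df["time_h"].to_numpy()
    if np.any(~np.isfinite(t)):
        bad = int(np.nonzero(~np.isfinite(t))[0][0])
        raise ParseError("missing time value", line=bad + 2)
    if np.any(np.diff(t) <= 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 1
        raise ParseError(
            f"times must be strictly increasing (t = {t[bad]} h follows "
            f"t = {t[bad - 1]} h)", line=bad + 2)
    # fixed column order regardless of file order
    cols = [c for c in TIMECOURSE_COLUMNS if c in df.columns]
    return df[cols]


def write_timecourse(course: pd.DataFrame, path) -> None:
    cols = [c for c in TIMECOURSE_COLUMNS if c in course.columns]
    course[cols].to_csv(path, index=False, encoding="utf-8")


def read_mu_observations(path) -> list[InhibitionObservation]:
    """Read a mu-vs-Z observation table (``Z_g_L, mu_max_per_h[, Ks_g_L]``)."""
    df = _read_table(path, required=("Z_g_L", "mu_max_per_h"),
                     optional=("Ks_g_L",))
    out = []
    for _, row in df.iterrows():
        ks = row.get("Ks_g_L", np.nan)
        out.append(InhibitionObservation(
            Z=float(row["Z_g_L"]), mu_max_obs=float(row["mu_max_per_h"]),
            K_s_obs=None if pd.isna(ks) else float(ks)))
    return out


def write_mu_observations(obs: Sequence[InhibitionObservation], path) -> None:
    rows = [{"Z_g_L": o.Z, "mu_max_per_h": o.mu_max_obs,
             "Ks_g_L": o.K_s_obs} for o in obs]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_yield_endpoints(path) -> list[tuple]:
    """Read endpoint records ``(S0, dS, dX, dP, dZ)`` for yield estimation."""
    df = _read_table(path, required=ENDPOINT_COLUMNS, optional=())
    return [tuple(float(row[c]) for c in ENDPOINT_COLUMNS)
            for _, row in df.iterrows()]
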