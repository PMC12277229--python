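"""Safe daily water-intake limit (FIR) at a target hazard quotient of 1.

Inverting the hazard-quotient model at THQ = 1 gives the largest daily
water volume a child can drink from a given tubewell without the quotient
exceeding unity:

    FIR_analyte = BW * RfD * AT / (EF * ED * C)          [L/day]

with C in mg/L (the model is unit-aware: a x1000 factor would only appear
if C were given in µg/L).  The combined limit enforces HI = 1 across both
analytes and is the harmonic combination

    FIR_combined = BW * AT / (EF * ED * (C_As/RfD_As + C_Fe/RfD_Fe))

so 1/FIR_combined = 1/FIR_Fe + 1/FIR_As.  A concentration of zero imposes
no limit; the corresponding FIR is reported as an unbounded sentinel
(``math.inf``), optionally capped for presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core_data import Dataset
from .exposure import ANALYTES, ExposureParams

__all__ = ["UNBOUNDED", "SafeIntake", "fir_single", "fir_combined",
           "safe_intake_records", "safe_intake_frame"]

#: Sentinel for "no finite safe-intake limit" (both concentrations zero).
UNBOUNDED = math.inf


@dataclass(frozen=True)
class SafeIntake:
    """Per-sample safe intake limits (L/day)."""

    sample_id: str
    fir: Mapping[str, float]      # analyte -> L/day, may be UNBOUNDED
    fir_combined: float           # L/day, may be UNBOUNDED
    params_name: str
    capped: bool = False


def fir_single(c: float, analyte: str, params: ExposureParams) -> float:
    """THQ=1 intake limit for one analyte; ``c`` = 0 gives UNBOUNDED."""
    if not math.isfinite(c):
        raise ValueError("concentration must be finite")
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if analyte not in params.rfd:
        raise KeyError(f"no RfD for analyte {analyte!r}")
    if c == 0:
        return UNBOUNDED
    return params.bw * params.rfd[analyte] * params.at / (params.ef * params.ed * c)


def fir_combined(c_fe: float, c_as: float, params: ExposureParams) -> float:
    """HI=1 intake limit over both analytes (harmonic combination)."""
    for c in (c_fe, c_as):
        if not math.isfinite(c):
            raise ValueError("concentrations must be finite")
        if c < 0:
            raise ValueError("concentrations must be >= 0")
    burden = c_as / params.rfd["as"] + c_fe / params.rfd["fe"]
    if burden == 0:
        return UNBOUNDED
    return params.bw * params.at / (params.ef * params.ed * burden)


def safe_intake_records(
    dataset: Dataset,
    params: ExposureParams,
    *,
    cap: float | None = None,
) -> list[SafeIntake]:
    """Per-sample FIR per analyte and combined; optional presentation cap."""
    if cap is not None and cap <= 0:
        raise ValueError("cap must be > 0")
    out = []
    cols = dataset.df[["sample_id", "fe", "as"]].itertuples(index=False, name=None)
    for sample_id, fe, as_conc in cols:
        fir = {a: fir_single(c, a, params) for a, c in (("fe", fe), ("as", as_conc))}
        combined = fir_combined(fe, as_conc, params)
        capped = False
        if cap is not None:
            capped = combined > cap or any(v > cap for v in fir.values())
            fir = {a: min(v, cap) for a, v in fir.items()}
            combined = min(combined, cap)
        out.append(SafeIntake(sample_id=sample_id, fir=fir,
                              fir_combined=combined,
                              params_name=params.name, capped=capped))
    return out


def safe_intake_frame(
    dataset: Dataset,
    params: ExposureParams,
    *,
    cap: float | None = None,
) -> pd.DataFrame:
    """Tabular per-sample safe-intake limits with location columns."""
    recs = safe_intake_records(dataset, params, cap=cap)
    out = dataset.df[["sample_id", "union", "longitude", "latitude", "fe", "as"]].copy()
    out["fir_fe"] = [r.fir["fe"] for r in recs]
    out["fir_as"] = [r.fir["as"] for r in recs]
    out["fir_combined"] = [r.fir_combined for r in recs]
    out["capped"] = [r.capped for r in recs]
    out["params"] = params.name
    return out
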