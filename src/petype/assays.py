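"""Closed-form reductions of the wet-lab readouts.

Three small formulas recur in PET-degradation studies and are implemented
here so assay tables can be reduced reproducibly:

* DSC crystallinity: %X = (dHf_sample - dHc_sample) / dHf_100 x 100, with
  140 J/g as the fusion enthalpy of fully crystalline PET;
* residual activity: initial rate after incubation normalized to the rate
  at 0 h, as a percent;
* total product release: the sum of BHET, MHET and TPA concentrations.
  Summing molarities counts terephthalate moieties rather than mass — the
  convention used when the three soluble products are pooled into one
  release number; keep units consistent across the three inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

DHF_100_PET = 140.0  # J/g, fusion enthalpy of 100% crystalline PET


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class DscMeasurement:
    dHf_sample: float  # J/g
    dHc_sample: float  # J/g
    dHf_100: float = DHF_100_PET

    def __post_init__(self):
        if self.dHf_100 <= 0:
            raise AssayError("dHf_100 must be positive")


@dataclass(frozen=True)
class ProductConcentrations:
    bhet: float
    mhet: float
    tpa: float

    def __post_init__(self):
        if min(self.bhet, self.mhet, self.tpa) < 0:
            raise AssayError("concentrations must be non-negative")


@dataclass(frozen=True)
class Crystallinity:
    percent: float
    physical: bool  # False when outside [0, 100] (baseline excursion)


def crystallinity(m: DscMeasurement) -> Crystallinity:
    """Percent crystallinity from first-heating DSC enthalpies.

    Values outside [0, 100] are returned with ``physical=False`` rather than
    raised: DSC baseline handling can produce slight excursions.
    """
    pct = (m.dHf_sample - m.dHc_sample) / m.dHf_100 * 100.0
    return Crystallinity(percent=pct, physical=0.0 <= pct <= 100.0)


def residual_activity(rate_t: float, rate_0: float) -> float:
    """Initial rate at time t as a percent of the rate at 0 h incubation."""
    if rate_0 <= 0:
        raise AssayError("rate at 0 h must be positive to normalize")
    return 100.0 * rate_t / rate_0


def total_product_release(c: ProductConcentrations) -> float:
    """BHET + MHET + TPA in the (shared) input unit."""
    return c.bhet + c.mhet + c.tpa


def reduce_assay_table(path_in: str | Path, path_out: str | Path | None = None) -> pd.DataFrame:
    """Reduce a long-format assay CSV (sample, quantity, value, unit).

    Recognized quantity triplets per sample: (dHf, dHc[, dHf_100]) ->
    crystallinity_pct; (bhet, mhet, tpa) -> total_product_mM (units must
    agree); (rate_t, rate_0) -> residual_activity_pct.
    """
    df = pd.read_csv(path_in)
    required = {"sample", "quantity", "value", "unit"}
    if not required.issubset(df.columns):
        raise AssayError(f"CSV must have columns {sorted(required)}")
    rows = []
    for sample, grp in df.groupby("sample", sort=False):
        q = dict(zip(grp["quantity"], grp["value"]))
        units = dict(zip(grp["quantity"], grp["unit"]))
        if {"dHf", "dHc"}.issubset(q):
            m = DscMeasurement(q["dHf"], q["dHc"], q.get("dHf_100", DHF_100_PET))
            c = crystallinity(m)
            rows.append(
                dict(sample=sample, quantity="crystallinity_pct", value=c.percent,
                     unit="%", flag="" if c.physical else "nonphysical")
            )
        if {"bhet", "mhet", "tpa"}.issubset(q):
            if len({units["bhet"], units["mhet"], units["tpa"]}) != 1:
                raise AssayError(f"sample {sample!r}: product units differ")
            total = total_product_release(
                ProductConcentrations(q["bhet"], q["mhet"], q["tpa"])
            )
            rows.append(
                dict(sample=sample, quantity="total_product", value=total,
                     unit=units["bhet"], flag="")
            )
        if {"rate_t", "rate_0"}.issubset(q):
            rows.append(
                dict(sample=sample, quantity="residual_activity_pct",
                     value=residual_activity(q["rate_t"], q["rate_0"]),
                     unit="%", flag="")
            )
    out = pd.DataFrame(rows)
    if path_out is not None:
        out.to_csv(path_out, index=False)
    return out
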