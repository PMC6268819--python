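"""In vitro -> in vivo extrapolation of CYP3A4 inhibition.

Under competitive (or noncompetitive) Michaelis-Menten inhibition the
substrate's apparent Michaelis constant scales as ``Km,i = Km (1 + [I]/Ki)``;
since pharmacokinetic AUC is inversely proportional to intrinsic clearance,
the fold change of the substrate AUC caused by an inhibitor at concentration
[I] is ``R = 1 + [I]/Ki``.  At low substrate concentration the Cheng-Prusoff
relation ``Ki = IC50 / (1 + [S]/Km)`` reduces to ``Ki ~= IC50``, so an HTS
IC50 can stand in for Ki:

    R = 1 + [I] / IC50

Four variants differ only in how [I] is estimated:

* R-1: maximum recommended daily dose (MRDD, mg/kg/day) times reported oral
  bioavailability, divided by molecular weight -- daily umol per kg of body
  mass, read as umol/L (1 kg of body mass ~ 1 L of distribution volume);
* R-2: as R-1 but with a predicted (ADME-model) bioavailability;
* R-3: as R-1 with bioavailability forced to 100%;
* R-4: the peak plasma concentration Cmax, used directly.

Compounds are called potent (P) when R > 2, weak (W) when 1.25 <= R <= 2, and
not determined (ND) when the value or its confidence interval crosses the
thresholds or falls below the clinically relevant range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .corpus import AssayRecord, Category, ExposureContext, load_extrapolation_fixture

DEFAULT_THRESHOLDS = (1.25, 2.0)


class Variant(str, Enum):
    R1_MRDD_BA = "R1"
    R2_BA_ADME = "R2"
    R3_BA100 = "R3"
    R4_CMAX = "R4"


class Call(str, Enum):
    P = "P"
    W = "W"
    ND = "ND"


@dataclass(frozen=True)
class ExtrapolationResult:
    r: float
    r_ci: tuple[float, float]
    variant: Variant
    call: Call


def apparent_km(km: float, i: float, ki: float) -> float:
    """Apparent Michaelis constant under competitive inhibition, Km (1 + [I]/Ki)."""
    if not km > 0 or not ki > 0:
        raise ValueError("km and ki must be positive")
    if i < 0:
        raise ValueError("inhibitor concentration cannot be negative")
    return km * (1.0 + i / ki)


def cheng_prusoff_ki(ic50: float, s: float, km: float) -> float:
    """Inhibition constant from an IC50: Ki = IC50 / (1 + [S]/Km)."""
    if not ic50 > 0 or not km > 0:
        raise ValueError("ic50 and km must be positive")
    if s < 0:
        raise ValueError("substrate concentration cannot be negative")
    return ic50 / (1.0 + s / km)


def intake_concentration(context: ExposureContext, variant: Variant) -> float:
    """Estimated hepatic inhibitor concentration [I] in uM for a variant.

    Dose-based variants convert MRDD (mg/kg/day) to daily umol per kg of body
    mass, read as umol/L.
    """
    if variant is Variant.R4_CMAX:
        if context.cmax is None:
            raise ValueError("variant R4 requires cmax")
        return context.cmax
    if context.mrdd is None or context.mw is None:
        raise ValueError(f"variant {variant.value} requires mrdd and mw")
    if variant is Variant.R3_BA100:
        ba = 1.0
    elif variant is Variant.R1_MRDD_BA:
        if context.bioavailability is None:
            raise ValueError("variant R1 requires a reported bioavailability")
        ba = context.bioavailability
    elif variant is Variant.R2_BA_ADME:
        if context.ba_adme is None:
            raise ValueError("variant R2 requires a predicted (ADME) bioavailability")
        ba = context.ba_adme
    else:  # pragma: no cover
        raise ValueError(f"unknown variant {variant}")
    return context.mrdd * ba / context.mw * 1000.0


def compute_r(i: float, ic50: float) -> float:
    """AUC fold change R = 1 + [I]/IC50."""
    if not ic50 > 0:
        raise ValueError("ic50 must be positive")
    if i < 0:
        raise ValueError("inhibitor concentration cannot be negative")
    return 1.0 + i / ic50


def propagate_r_ci(i: float, ic50_ci: tuple[float, float]) -> tuple[float, float]:
    """Interval inversion of the IC50 CI: a zero lower IC50 bound gives R upper = +inf."""
    lo, hi = ic50_ci
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid IC50 interval ({lo}, {hi})")
    if i < 0:
        raise ValueError("inhibitor concentration cannot be negative")
    r_lo = 1.0 + (i / hi if hi > 0 else 0.0)
    r_hi = math.inf if lo == 0 else 1.0 + i / lo
    if i == 0:
        return (1.0, 1.0)
    return (r_lo, r_hi)


def categorize_r(result: ExtrapolationResult, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> Call:
    """Potency call from R and its CI; any threshold crossing gives ND."""
    weak_lo, potent_lo = thresholds
    r, (lo, hi) = result.r, result.r_ci
    if r > potent_lo and lo > potent_lo:
        return Call.P
    if weak_lo <= r <= potent_lo and lo >= weak_lo and hi <= potent_lo:
        return Call.W
    return Call.ND


def extrapolate(
    assay: AssayRecord,
    context: ExposureContext,
    variant: Variant,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> ExtrapolationResult:
    i = intake_concentration(context, variant)
    r = compute_r(i, assay.ic50)
    ci = propagate_r_ci(i, assay.ic50_ci)
    interim = ExtrapolationResult(r=r, r_ci=ci, variant=variant, call=Call.ND)
    return ExtrapolationResult(r=r, r_ci=ci, variant=variant, call=categorize_r(interim, thresholds))


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding used for printed R values (computation stays full precision)."""
    if math.isinf(x):
        return x
    q = 10.0**decimals
    return math.floor(x * q + 0.5) / q


#: relative half-ulp of the printed IC50 above which the printed R cannot be
#: reproduced exactly from the rounded IC50 (the row is flagged, not forced)
_IC50_ROUNDING_FLAG = 0.01


def extrapolation_report(thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Recompute R-1..R-4 with CIs and calls for the bundled 17-drug table.

    ``ic50_rounding_flag`` marks rows whose printed IC50 carries more than 1%
    relative rounding error, where exact agreement with the printed R is not
    arithmetically possible.
    """
    rows = []
    for assay, ctx, clinical in load_extrapolation_fixture():
        rec: dict = {
            "id": assay.identifier,
            "clinical_category": clinical.value,
            "ic50": assay.ic50,
            "ic50_rounding_flag": _printed_ic50_half_ulp(assay.ic50) / assay.ic50 > _IC50_ROUNDING_FLAG,
        }
        for variant in Variant:
            try:
                res = extrapolate(assay, ctx, variant, thresholds)
            except ValueError:
                rec[f"{variant.value}"] = None
                continue
            rec[f"{variant.value}"] = round_half_up(res.r)
            rec[f"{variant.value}_lo"] = round_half_up(res.r_ci[0])
            rec[f"{variant.value}_hi"] = round_half_up(res.r_ci[1])
            rec[f"C-{variant.value[1]}"] = res.call.value
        rows.append(rec)
    return pd.DataFrame(rows).set_index("id")


def _printed_ic50_half_ulp(ic50: float) -> float:
    # printed tables carry two decimals -> half-ulp 0.005
    return 0.005
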