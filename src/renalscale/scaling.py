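"""Allometric clearance scaling and its accuracy against the PBPK truth.

Clearance in an obese subject is extrapolated from the normal-weight value
by a bodyweight power law,

    scaled CLr_obese = CLr_normal · (BW_obese / BW_normal)^exponent ,

with exponent 0 corresponding to flat dosing and 0.75 to conventional
allometric scaling (AS0.75).  The PBPK-simulated clearance is taken as
truth; the signed prediction error is

    PE(%) = 100 · (scaled − PBPK) / PBPK ,

a drug is scaled *accurately* when |PE| ≤ 30% (threshold configurable,
boundary inclusive), and a stratum of drugs is *systematically accurate*
when every drug in it is accurate.  The exponent that would scale a given
drug exactly is

    required exponent = ln(CLr_obese / CLr_normal) / ln(BW_obese / BW_normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScalingResult",
    "scaled_clr",
    "prediction_error",
    "required_exponent",
    "is_accurate",
    "scaling_table",
    "classify_systematic_accuracy",
    "DEFAULT_EXPONENTS",
    "DEFAULT_PE_THRESHOLD",
    "DEFAULT_STRATA",
]

DEFAULT_EXPONENTS = (0.0, 0.75)
DEFAULT_PE_THRESHOLD = 30.0

#: default strata for systematic-accuracy verdicts (Kp left free within each)
DEFAULT_STRATA = ("bmi", "rta", "binding_protein", "fu_normal_weight", "clint_ats")


def scaled_clr(clr_normal, bw_normal, bw_obese, exponent):
    """Power-law extrapolation of clearance from normal weight (L/h)."""
    clr_normal = np.asarray(clr_normal, dtype=float)
    bw_normal = np.asarray(bw_normal, dtype=float)
    bw_obese = np.asarray(bw_obese, dtype=float)
    if np.any(clr_normal <= 0):
        raise ValueError("clr_normal must be positive")
    if np.any(bw_normal <= 0) or np.any(bw_obese <= 0):
        raise ValueError("bodyweights must be positive")
    out = clr_normal * (bw_obese / bw_normal) ** np.asarray(exponent, dtype=float)
    return out.item() if out.ndim == 0 else out


def prediction_error(scaled, pbpk):
    """Signed prediction error (%) of scaled vs PBPK-predicted clearance."""
    scaled = np.asarray(scaled, dtype=float)
    pbpk = np.asarray(pbpk, dtype=float)
    if np.any(pbpk <= 0):
        raise ValueError("PBPK clearance must be positive")
    out = 100.0 * (scaled - pbpk) / pbpk
    return out.item() if out.ndim == 0 else out


def required_exponent(clr_obese, clr_normal, bw_obese, bw_normal):
    """The unique exponent for which the power law reproduces the PBPK value."""
    clr_obese = np.asarray(clr_obese, dtype=float)
    clr_normal = np.asarray(clr_normal, dtype=float)
    bw_obese = np.asarray(bw_obese, dtype=float)
    bw_normal = np.asarray(bw_normal, dtype=float)
    if np.any(clr_obese <= 0) or np.any(clr_normal <= 0):
        raise ValueError("clearances must be positive")
    if np.any(bw_obese <= 0) or np.any(bw_normal <= 0):
        raise ValueError("bodyweights must be positive")
    if np.any(bw_obese == bw_normal):
        raise ValueError("bodyweights must differ (log of unit ratio in denominator)")
    out = np.log(clr_obese / clr_normal) / np.log(bw_obese / bw_normal)
    return out.item() if out.ndim == 0 else out


def is_accurate(pe, threshold: float = DEFAULT_PE_THRESHOLD):
    """Accuracy indicator |PE| ≤ threshold (boundary inclusive)."""
    out = np.abs(np.asarray(pe, dtype=float)) <= threshold
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScalingResult:
    """Scaling evaluation of one drug × obese scenario at one exponent."""

    exponent: float
    scaled_clr: float  # L/h
    pbpk_clr: float  # L/h
    prediction_error: float  # %, signed
    accurate: bool
    required_exponent: float


def evaluate_scaling(
    clr_normal: float,
    clr_obese: float,
    bw_normal: float,
    bw_obese: float,
    exponent: float,
    threshold: float = DEFAULT_PE_THRESHOLD,
) -> ScalingResult:
    """Scalar convenience wrapper producing a :class:`ScalingResult`."""
    scaled = scaled_clr(clr_normal, bw_normal, bw_obese, exponent)
    pe = prediction_error(scaled, clr_obese)
    return ScalingResult(
        exponent=float(exponent),
        scaled_clr=scaled,
        pbpk_clr=float(clr_obese),
        prediction_error=pe,
        accurate=is_accurate(pe, threshold),
        required_exponent=required_exponent(clr_obese, clr_normal, bw_obese, bw_normal),
    )


SCALING_COLUMNS = (
    "binding_protein",
    "fu_normal_weight",
    "kp",
    "clint_ats",
    "bmi",
    "rta",
    "exponent",
    "scaled_clr",
    "pbpk_clr",
    "prediction_error",
    "accurate",
    "required_exponent",
)


def scaling_table(
    clearance_df: pd.DataFrame,
    bw_normal: float,
    exponents: Sequence[float] = DEFAULT_EXPONENTS,
    threshold: float = DEFAULT_PE_THRESHOLD,
    baseline_bmi: float = 20.0,
) -> pd.DataFrame:
    """Per-row scaling evaluation over a clearance table, long over exponents.

    Baseline-BMI rows are excluded (there is nothing to scale); one output
    row is emitted per clearance row per exponent.  ``required_exponent`` is
    exponent-independent and repeated within each row pair.
    """
    if len(exponents) == 0:
        raise ValueError("at least one exponent is required")
    obese = clearance_df[clearance_df["bmi"] != baseline_bmi].reset_index(drop=True)
    if obese.empty:
        raise ValueError("clearance table has no non-baseline rows to scale")
    req = required_exponent(
        obese["clr"].to_numpy(), obese["clr_baseline"].to_numpy(),
        obese["bodyweight"].to_numpy(), bw_normal,
    )
    parts = []
    for exp in exponents:
        part = obese[
            ["binding_protein", "fu_normal_weight", "kp", "clint_ats", "bmi", "rta"]
        ].copy()
        part["exponent"] = float(exp)
        part["scaled_clr"] = scaled_clr(
            obese["clr_baseline"].to_numpy(), bw_normal, obese["bodyweight"].to_numpy(), exp
        )
        part["pbpk_clr"] = obese["clr"].to_numpy()
        part["prediction_error"] = prediction_error(part["scaled_clr"].to_numpy(), part["pbpk_clr"].to_numpy())
        part["accurate"] = is_accurate(part["prediction_error"].to_numpy(), threshold)
        part["required_exponent"] = req
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    return out[list(SCALING_COLUMNS)]


def classify_systematic_accuracy(
    scaling_df: pd.DataFrame,
    by: Iterable[str] = DEFAULT_STRATA,
    threshold: float = DEFAULT_PE_THRESHOLD,
) -> pd.DataFrame:
    """Per-stratum, per-exponent verdicts.

    A stratum is systematically accurate for an exponent iff every drug in
    it has |PE| ≤ threshold.  ``by`` may be any subset of the table's key
    columns, so verdicts can be regrouped (e.g. fixing Kp, or pooling fu).
    """
    by = [c for c in by]
    if scaling_df.empty:
        raise ValueError("empty scaling table: no strata to classify")
    missing = [c for c in by if c not in scaling_df.columns]
    if missing:
        raise KeyError(f"stratum columns absent from scaling table: {missing}")
    df = scaling_df.copy()
    df["_abs_pe"] = df["prediction_error"].abs()
    grouped = df.groupby(by + ["exponent"], sort=True, as_index=False).agg(
        n_drugs=("prediction_error", "size"),
        max_abs_pe=("_abs_pe", "max"),
    )
    grouped["systematically_accurate"] = grouped["max_abs_pe"] <= threshold
    return grouped
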