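"""Renal clearance through glomerular filtration and active tubular secretion.

Total renal clearance is modelled as the sum of two pathways,

    CLr = CL_GF + CL_ATS

with a filtration term CL_GF = fu · GFR and a well-stirred secretion term

    CL_ATS = (Qr − GFR) · fu · CL_int_sec / (Qr + fu · CL_int_sec / BP)

where Qr is renal blood flow, fu the unbound plasma fraction in the subject
at hand, BP the blood-to-plasma concentration ratio, and CL_int_sec the
whole-kidney intrinsic secretion clearance

    CL_int_sec = CL_int_ATS · kidney weight · PTCPGK · rTA .

Obesity enters through the subject physiology (GFR, Qr, kidney weight,
binding-protein concentration, via :mod:`renalscale.physiology`) and through
two composite rescalings:

* fu — constant-affinity linear binding, so the unbound fraction shifts
  with the binding-protein concentration ratio relative to normal weight;
* BP — the hematocrit-weighted partition identity 1 + Hct·(fu·Kp − 1).

PTCPGK is applied exactly as the plain multiplicative scalar the product
formula states; its per-gram-kidney semantics against the per-mg-protein
units of CL_int_ATS are deliberately not reinterpreted.  Tubular
reabsorption and renal metabolism are outside the model.

All functions accept scalars or numpy arrays and return values in the
canonical units (clearances L/h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drug_space import DrugSpec
from .physiology import SubjectProfile

__all__ = [
    "ClearanceResult",
    "rescale_fu",
    "blood_to_plasma",
    "total_clint_sec",
    "cl_gf",
    "cl_ats",
    "renal_clearance",
    "relative_clr",
    "clearance_table",
]

#: µl/min → L/h
UL_PER_MIN_TO_L_PER_H = 60.0 / 1.0e6


def rescale_fu(fu_normal_weight, protein_ratio):
    """Unbound fraction after a change in binding-protein concentration.

    Assumes constant drug–protein affinity and linear (non-saturable)
    binding, so fu = 1/(1 + Ka·[P]) with Ka fixed from the normal-weight
    value.  Closed form:

        fu = fu_nw / (fu_nw + (1 − fu_nw) · r),   r = [P]_subject/[P]_normal

    Strictly decreasing in r; identity at r = 1; drugs with fu_nw = 1 do not
    bind and pass through unchanged.
    """
    fu_nw = np.asarray(fu_normal_weight, dtype=float)
    r = np.asarray(protein_ratio, dtype=float)
    if np.any((fu_nw <= 0) | (fu_nw > 1)):
        raise ValueError("fu_normal_weight must lie in (0, 1]")
    if np.any(r <= 0):
        raise ValueError("protein concentration ratio must be positive")
    out = fu_nw / (fu_nw + (1.0 - fu_nw) * r)
    return out.item() if out.ndim == 0 else out


def blood_to_plasma(hematocrit, fu, kp):
    """Blood-to-plasma concentration ratio BP = 1 + Hct·(fu·Kp − 1).

    The whole-blood concentration mixes plasma (fraction 1 − Hct) with red
    cells whose partitioning is fu·Kp; BP is never below 1 − Hct.
    """
    hct = np.asarray(hematocrit, dtype=float)
    fu = np.asarray(fu, dtype=float)
    kp = np.asarray(kp, dtype=float)
    if np.any((hct < 0) | (hct >= 1)):
        raise ValueError("hematocrit must lie in [0, 1)")
    if np.any((fu < 0) | (fu > 1)):
        raise ValueError("fu must lie in [0, 1]")
    if np.any(kp <= 0):
        raise ValueError("kp must be positive")
    out = 1.0 + hct * (fu * kp - 1.0)
    return out.item() if out.ndim == 0 else out


def total_clint_sec(clint_ats, kidney_weight, ptcpgk, rta):
    """Whole-kidney intrinsic secretion clearance, L/h.

    Product CL_int_ATS (µl·min⁻¹·mg⁻¹) × kidney weight (g) × PTCPGK × rTA,
    converted µl/min → L/h.  Linear in every factor; rTA = 0 switches
    secretion off.
    """
    clint = np.asarray(clint_ats, dtype=float)
    kw = np.asarray(kidney_weight, dtype=float)
    scal = np.asarray(ptcpgk, dtype=float)
    rta = np.asarray(rta, dtype=float)
    if np.any(clint < 0) or np.any(kw < 0) or np.any(scal < 0) or np.any(rta < 0):
        raise ValueError("all inputs to total_clint_sec must be non-negative")
    out = clint * kw * scal * rta * UL_PER_MIN_TO_L_PER_H
    return out.item() if out.ndim == 0 else out


def cl_gf(fu, gfr):
    """Glomerular-filtration clearance CL_GF = fu · GFR, L/h."""
    fu = np.asarray(fu, dtype=float)
    gfr = np.asarray(gfr, dtype=float)
    if np.any((fu < 0) | (fu > 1)):
        raise ValueError("fu must lie in [0, 1]")
    if np.any(gfr <= 0):
        raise ValueError("gfr must be positive")
    out = fu * gfr
    return out.item() if out.ndim == 0 else out


def cl_ats(qr, gfr, fu, clint_sec, bp):
    """Active-tubular-secretion clearance, L/h.

        CL_ATS = (Qr − GFR) · fu · CL_int_sec / (Qr + fu · CL_int_sec / BP)

    Monotone non-decreasing in CL_int_sec and fu; tends to the flow-limited
    ceiling (Qr − GFR)·BP as CL_int_sec → ∞ and to the linear regime
    (Qr − GFR)·fu·CL_int_sec/Qr as CL_int_sec → 0.
    """
    qr = np.asarray(qr, dtype=float)
    gfr = np.asarray(gfr, dtype=float)
    fu = np.asarray(fu, dtype=float)
    clint_sec = np.asarray(clint_sec, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if np.any(gfr <= 0) or np.any(qr <= gfr):
        raise ValueError("model requires qr > gfr > 0")
    if np.any((fu < 0) | (fu > 1)):
        raise ValueError("fu must lie in [0, 1]")
    if np.any(clint_sec < 0):
        raise ValueError("clint_sec must be non-negative")
    if np.any(bp <= 0):
        raise ValueError("bp must be positive")
    out = (qr - gfr) * fu * clint_sec / (qr + fu * clint_sec / bp)
    return out.item() if out.ndim == 0 else out


def relative_clr(clr_subject, clr_baseline):
    """Renal clearance as a percentage of the normal-weight subject's value."""
    clr_subject = np.asarray(clr_subject, dtype=float)
    clr_baseline = np.asarray(clr_baseline, dtype=float)
    if np.any(clr_baseline <= 0):
        raise ValueError("baseline clearance must be positive")
    out = 100.0 * clr_subject / clr_baseline
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class ClearanceResult:
    """Clearance breakdown for one drug in one subject × rTA scenario."""

    fu: float
    bp: float
    clint_sec: float  # L/h
    cl_gf: float  # L/h
    cl_ats: float  # L/h
    clr: float  # L/h
    contribution_gf: float  # % of clr (nan when clr = 0)
    contribution_ats: float  # % of clr (nan when clr = 0)
    relative_clr: float | None = None  # % of baseline clr, when a baseline was supplied


def renal_clearance(
    subject: SubjectProfile,
    drug: DrugSpec,
    rta: float = 1.0,
    baseline: SubjectProfile | None = None,
) -> ClearanceResult:
    """Evaluate the full clearance chain for one drug × subject × rTA.

    The unbound fraction is rescaled by the subject/baseline concentration
    ratio of the drug's binding protein; with no baseline the subject is its
    own reference (ratio 1, fu = fu_normal_weight) and relative_clr is not
    reported.  The baseline clearance uses rTA = 1 by definition of rTA.
    """
    if rta < 0:
        raise ValueError(f"rta must be non-negative, got {rta}")
    protein = drug.binding_protein.value
    ratio = 1.0 if baseline is None else subject.protein_conc(protein) / baseline.protein_conc(protein)
    fu = rescale_fu(drug.fu_normal_weight, ratio)
    bp = blood_to_plasma(subject.hematocrit, fu, drug.kp)
    clint_sec = total_clint_sec(drug.clint_ats, subject.kidney_weight, subject.ptcpgk, rta)
    gf = cl_gf(fu, subject.gfr)
    ats = cl_ats(subject.qr, subject.gfr, fu, clint_sec, bp)
    clr = gf + ats
    if clr > 0:
        contrib_gf = 100.0 * gf / clr
        contrib_ats = 100.0 * ats / clr
    else:  # no clearance at all: contributions undefined
        contrib_gf = contrib_ats = float("nan")
    rel = None
    if baseline is not None:
        base = renal_clearance(baseline, drug, rta=1.0, baseline=None)
        rel = relative_clr(clr, base.clr)
    return ClearanceResult(
        fu=fu,
        bp=bp,
        clint_sec=clint_sec,
        cl_gf=gf,
        cl_ats=ats,
        clr=clr,
        contribution_gf=contrib_gf,
        contribution_ats=contrib_ats,
        relative_clr=rel,
    )


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

CLEARANCE_COLUMNS = (
    "binding_protein",
    "fu_normal_weight",
    "kp",
    "clint_ats",
    "bmi",
    "rta",
    "bodyweight",
    "fu",
    "bp",
    "clint_sec",
    "cl_gf",
    "cl_ats",
    "clr",
    "contribution_gf",
    "contribution_ats",
    "clr_baseline",
    "relative_clr",
)


def clearance_table(
    grid_df: pd.DataFrame,
    subjects: dict[float, SubjectProfile],
    baseline_bmi: float = 20.0,
) -> pd.DataFrame:
    """Vectorised clearance evaluation over a study grid.

    ``grid_df`` carries one row per (binding_protein, fu_normal_weight, kp,
    clint_ats, bmi, rta) combination (see :func:`renalscale.drug_space.grid_table`);
    ``subjects`` maps each BMI category to its :class:`SubjectProfile`.  The
    baseline clearance of every drug (baseline BMI, rTA = 1) is merged back
    in so each row reports relative CLr.  Row order follows the input grid.
    """
    if baseline_bmi not in subjects:
        raise ValueError(f"baseline BMI {baseline_bmi} has no subject profile")
    df = grid_df.copy()

    base = subjects[baseline_bmi]
    phys = pd.DataFrame(
        {
            "bmi": list(subjects),
            "bodyweight": [s.bodyweight for s in subjects.values()],
            "_gfr": [s.gfr for s in subjects.values()],
            "_qr": [s.qr for s in subjects.values()],
            "_kw": [s.kidney_weight for s in subjects.values()],
            "_hct": [s.hematocrit for s in subjects.values()],
            "_ptcpgk": [s.ptcpgk for s in subjects.values()],
            "_hsa_ratio": [s.hsa_conc / base.hsa_conc for s in subjects.values()],
            "_aag_ratio": [s.aag_conc / base.aag_conc for s in subjects.values()],
        }
    )
    df = df.merge(phys, on="bmi", how="left", sort=False)
    if df["_gfr"].isna().any():
        missing = sorted(df.loc[df["_gfr"].isna(), "bmi"].unique())
        raise ValueError(f"grid contains BMI categories without subject profiles: {missing}")

    ratio = np.where(df["binding_protein"].to_numpy() == "HSA", df["_hsa_ratio"], df["_aag_ratio"])
    df["fu"] = rescale_fu(df["fu_normal_weight"].to_numpy(), ratio)
    df["bp"] = blood_to_plasma(df["_hct"].to_numpy(), df["fu"].to_numpy(), df["kp"].to_numpy())
    df["clint_sec"] = total_clint_sec(
        df["clint_ats"].to_numpy(), df["_kw"].to_numpy(), df["_ptcpgk"].to_numpy(), df["rta"].to_numpy()
    )
    df["cl_gf"] = cl_gf(df["fu"].to_numpy(), df["_gfr"].to_numpy())
    df["cl_ats"] = cl_ats(
        df["_qr"].to_numpy(), df["_gfr"].to_numpy(), df["fu"].to_numpy(),
        df["clint_sec"].to_numpy(), df["bp"].to_numpy(),
    )
    df["clr"] = df["cl_gf"] + df["cl_ats"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["contribution_gf"] = np.where(df["clr"] > 0, 100.0 * df["cl_gf"] / df["clr"], np.nan)
        df["contribution_ats"] = np.where(df["clr"] > 0, 100.0 * df["cl_ats"] / df["clr"], np.nan)

    drug_keys = ["binding_protein", "fu_normal_weight", "kp", "clint_ats"]
    base_rows = df[(df["bmi"] == baseline_bmi) & (df["rta"] == 1.0)]
    if base_rows.empty:
        raise ValueError("grid lacks the baseline scenario (baseline BMI with rTA = 1)")
    base_clr = base_rows[drug_keys + ["clr"]].rename(columns={"clr": "clr_baseline"})
    df = df.merge(base_clr, on=drug_keys, how="left", sort=False)
    df["relative_clr"] = 100.0 * df["clr"] / df["clr_baseline"]

    return df[list(CLEARANCE_COLUMNS)]
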