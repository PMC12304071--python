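"""Virtual-subject physiology as a function of body mass index.

The renal-clearance model needs, for each typical subject, the system
parameters that obesity alters: glomerular filtration rate (GFR), renal
blood flow (Qr), kidney weight, the plasma concentrations of the two drug
binding proteins (human serum albumin, HSA, and alpha-1 acid glycoprotein,
AAG), hematocrit, and a proximal-tubule scaling factor per gram kidney
(PTCPGK, held at 99.4 and assumed BMI-invariant).

Subjects are *typical*: one deterministic profile per BMI category, no
inter-individual variability.  BMI is the obesity descriptor; bodyweight is
derived from BMI and height and never drives the physiology functions
directly except where a parameter equation is itself written in bodyweight.

Parameter sets are pluggable through a registry.  The package ships the
fully specified ``fixture_linear`` set (simple linear trends in bodyweight,
adequate for exercising every model property).  Published sets — e.g. the
obesity physiology repository equations of Berton and colleagues — can be
registered at run time from a YAML coefficient file via
:func:`load_parameter_set`; their coefficients are not bundled.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Sex",
    "SubjectProfile",
    "PhysiologyParameterSet",
    "bodyweight_from_bmi",
    "make_subject",
    "relative_parameters",
    "get_parameter_set",
    "register_parameter_set",
    "load_parameter_set",
    "available_parameter_sets",
    "subjects_table",
    "PTCPGK_DEFAULT",
    "REFERENCE_HEIGHT_M",
    "BASELINE_BMI",
]

#: Proximal-tubule scaling factor per gram kidney (platform value, BMI-invariant).
PTCPGK_DEFAULT = 99.4

#: Typical adult height (m), the NHANES median used for all typical subjects.
REFERENCE_HEIGHT_M = 1.72

#: BMI of the normal-weight reference subject (kg/m²).
BASELINE_BMI = 20.0

#: Recommended BMI range of validity for the physiology functions.
BMI_RANGE = (20.0, 60.0)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


def bodyweight_from_bmi(bmi: float, height: float) -> float:
    """Total bodyweight (kg) from BMI (kg/m²) and height (m).

    Returns the exact product ``bmi * height**2``; callers that report
    weights round to one decimal, the unrounded value is used internally.
    """
    if bmi <= 0 or height <= 0:
        raise ValueError(f"bmi and height must be positive, got bmi={bmi}, height={height}")
    return bmi * height**2


@dataclass(frozen=True)
class SubjectProfile:
    """System parameters of one typical (virtual) subject.

    Canonical units: clearances/flows L/h, mass g, concentrations g/L,
    hematocrit as a volume fraction in (0, 1).
    """

    bmi: float
    height: float
    bodyweight: float
    sex: Sex
    gfr: float
    qr: float
    kidney_weight: float
    hsa_conc: float
    aag_conc: float
    hematocrit: float
    ptcpgk: float = PTCPGK_DEFAULT

    def __post_init__(self) -> None:
        for name in ("gfr", "qr", "kidney_weight", "hsa_conc", "aag_conc", "ptcpgk"):
            if getattr(self, name) <= 0:
                raise ValueError(f"physiology parameter {name!r} must be positive, got {getattr(self, name)}")
        if not 0 < self.hematocrit < 1:
            raise ValueError(f"hematocrit must lie in (0, 1), got {self.hematocrit}")
        if self.qr <= self.gfr:
            raise ValueError(
                f"renal blood flow ({self.qr} L/h) must exceed GFR ({self.gfr} L/h); "
                "the secretion model requires a positive post-glomerular flow"
            )

    def protein_conc(self, protein: str) -> float:
        """Plasma concentration (g/L) of the named binding protein ('HSA' or 'AAG')."""
        key = str(protein).upper()
        if key == "HSA":
            return self.hsa_conc
        if key == "AAG":
            return self.aag_conc
        raise ValueError(f"unknown binding protein {protein!r}; expected 'HSA' or 'AAG'")

    #: numeric fields compared by :func:`relative_parameters`
    _NUMERIC_FIELDS = (
        "bodyweight",
        "gfr",
        "qr",
        "kidney_weight",
        "hsa_conc",
        "aag_conc",
        "hematocrit",
        "ptcpgk",
    )


# parameters every set must generate (bmi/height/sex/bodyweight are inputs)
GENERATED_PARAMETERS = ("gfr", "qr", "kidney_weight", "hsa_conc", "aag_conc", "hematocrit")

ParamFunction = Callable[[float, Sex], float]


@dataclass(frozen=True)
class PhysiologyParameterSet:
    """A named, deterministic mapping BMI (and sex) → system parameters."""

    name: str
    parameter_functions: Mapping[str, ParamFunction]
    reference: str = ""
    ptcpgk: float = PTCPGK_DEFAULT

    def __post_init__(self) -> None:
        missing = [p for p in GENERATED_PARAMETERS if p not in self.parameter_functions]
        if missing:
            raise ValueError(f"parameter set {self.name!r} lacks generating functions for: {missing}")

    def evaluate(self, parameter: str, bmi: float, sex: Sex) -> float:
        value = self.parameter_functions[parameter](bmi, sex)
        if value <= 0:
            raise ValueError(
                f"parameter set {self.name!r}: function for {parameter!r} returned "
                f"non-positive value {value} at bmi={bmi}, sex={sex.value}"
            )
        return float(value)


def make_subject(
    bmi: float,
    height: float = REFERENCE_HEIGHT_M,
    sex: Sex | str = Sex.MALE,
    params: PhysiologyParameterSet | str = "fixture_linear",
    ptcpgk: float | None = None,
) -> SubjectProfile:
    """Build the typical subject at the given BMI.

    BMI outside the physiology functions' stated range of validity
    ([20, 60] kg/m²) triggers a warning, not an error.
    """
    if isinstance(params, str):
        params = get_parameter_set(params)
    sex = Sex(sex)
    bw = bodyweight_from_bmi(bmi, height)  # validates positivity
    if not BMI_RANGE[0] <= bmi <= BMI_RANGE[1]:
        warnings.warn(
            f"bmi={bmi} lies outside the validated range {BMI_RANGE}; extrapolating physiology",
            stacklevel=2,
        )
    values = {p: params.evaluate(p, bmi, sex) for p in GENERATED_PARAMETERS}
    return SubjectProfile(
        bmi=float(bmi),
        height=float(height),
        bodyweight=bw,
        sex=sex,
        ptcpgk=params.ptcpgk if ptcpgk is None else ptcpgk,
        **values,
    )


def relative_parameters(profile: SubjectProfile, baseline: SubjectProfile) -> dict[str, float]:
    """Ratios subject/baseline for every numeric physiology field.

    By convention the baseline is the normal-weight (BMI 20) subject; the
    self-ratio of the baseline is exactly 1 for every field.
    """
    ratios: dict[str, float] = {}
    for name in SubjectProfile._NUMERIC_FIELDS:
        denom = getattr(baseline, name)
        if denom == 0:
            raise ValueError(f"baseline value for {name!r} is zero; ratio undefined")
        ratios[name] = getattr(profile, name) / denom
    return ratios


# ---------------------------------------------------------------------------
# Parameter-set registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, PhysiologyParameterSet] = {}


def register_parameter_set(pset: PhysiologyParameterSet, overwrite: bool = False) -> None:
    if pset.name in _REGISTRY and not overwrite:
        raise ValueError(f"parameter set {pset.name!r} already registered")
    _REGISTRY[pset.name] = pset


def get_parameter_set(name: str) -> PhysiologyParameterSet:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise LookupError(
            f"unknown physiology set {name!r}; available: {sorted(_REGISTRY)}. "
            "Published sets can be registered from a YAML coefficient file via "
            "load_parameter_set(path)."
        ) from None


def available_parameter_sets() -> list[str]:
    return sorted(_REGISTRY)


# --- coefficient-table function kinds (plain-text configurable) -------------

def _make_function(spec: Mapping) -> ParamFunction:
    """Build a (bmi, sex) → value function from a coefficient-table entry.

    Supported kinds:
      constant       {value}
      by_sex         {male, female}                       (constants per sex)
      linear_bw      {intercept, slope, bw0, [height]}    a + b·(BW − bw0),
                     BW = bmi·height² (height defaults to 1.72 m)
      linear_bmi     {intercept, slope, bmi0}             a + b·(bmi − bmi0)
      power_bmi      {coefficient, exponent}              a·bmi^b
      polynomial_bmi {coefficients}                       c0 + c1·bmi + c2·bmi² …
    An entry may instead map sexes to sub-entries: {male: {...}, female: {...}}.
    """
    if set(spec) <= {"male", "female"} and all(isinstance(v, Mapping) for v in spec.values()):
        subs = {Sex(k): _make_function(v) for k, v in spec.items()}

        def per_sex(bmi: float, sex: Sex) -> float:
            if sex not in subs:
                raise ValueError(f"no coefficients for sex {sex.value!r}")
            return subs[sex](bmi, sex)

        return per_sex

    kind = spec.get("kind", "constant")
    if kind == "constant":
        value = float(spec["value"])
        return lambda bmi, sex: value
    if kind == "by_sex":
        male, female = float(spec["male"]), float(spec["female"])
        return lambda bmi, sex: male if sex is Sex.MALE else female
    if kind == "linear_bw":
        a, b, bw0 = float(spec["intercept"]), float(spec["slope"]), float(spec["bw0"])
        height = float(spec.get("height", REFERENCE_HEIGHT_M))
        return lambda bmi, sex: a + b * (bmi * height**2 - bw0)
    if kind == "linear_bmi":
        a, b, bmi0 = float(spec["intercept"]), float(spec["slope"]), float(spec.get("bmi0", 0.0))
        return lambda bmi, sex: a + b * (bmi - bmi0)
    if kind == "power_bmi":
        a, b = float(spec["coefficient"]), float(spec["exponent"])
        return lambda bmi, sex: a * bmi**b
    if kind == "polynomial_bmi":
        coeffs = [float(c) for c in spec["coefficients"]]
        return lambda bmi, sex: sum(c * bmi**i for i, c in enumerate(coeffs))
    raise ValueError(f"unknown parameter-function kind {kind!r}")


def parameter_set_from_dict(doc: Mapping) -> PhysiologyParameterSet:
    """Build a parameter set from a parsed coefficient table (see _make_function)."""
    funcs = {name: _make_function(entry) for name, entry in doc["parameters"].items()}
    return PhysiologyParameterSet(
        name=doc["name"],
        parameter_functions=funcs,
        reference=doc.get("reference", ""),
        ptcpgk=float(doc.get("ptcpgk", PTCPGK_DEFAULT)),
    )


def load_parameter_set(path, register: bool = True) -> PhysiologyParameterSet:
    """Load a parameter set from a YAML coefficient file and register it."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pset = parameter_set_from_dict(doc)
    if register:
        register_parameter_set(pset, overwrite=True)
    return pset


# --- the built-in fixture set ----------------------------------------------

_FIXTURE_DOC = {
    "name": "fixture_linear",
    "reference": "synthetic linear trends in bodyweight; package-defined test fixture, not literature physiology",
    "parameters": {
        "gfr": {"kind": "linear_bw", "intercept": 6.5, "slope": 0.04, "bw0": 59.2},
        "qr": {"kind": "linear_bw", "intercept": 60.0, "slope": 0.25, "bw0": 59.2},
        "kidney_weight": {"kind": "linear_bw", "intercept": 300.0, "slope": 1.5, "bw0": 59.2},
        "hsa_conc": {"kind": "linear_bw", "intercept": 45.0, "slope": -0.03, "bw0": 59.2},
        "aag_conc": {"kind": "linear_bw", "intercept": 0.8, "slope": 0.004, "bw0": 59.2},
        "hematocrit": {"kind": "by_sex", "male": 0.45, "female": 0.40},
    },
}

register_parameter_set(parameter_set_from_dict(_FIXTURE_DOC))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

SUBJECT_COLUMNS = {
    "bmi": "bmi_kg_per_m2",
    "height": "height_m",
    "bodyweight": "bodyweight_kg",
    "sex": "sex",
    "gfr": "gfr_L_per_h",
    "qr": "qr_L_per_h",
    "kidney_weight": "kidney_weight_g",
    "hsa_conc": "hsa_g_per_L",
    "aag_conc": "aag_g_per_L",
    "hematocrit": "hematocrit_frac",
    "ptcpgk": "ptcpgk_per_g_kidney",
}


def subjects_table(profiles: list[SubjectProfile]) -> pd.DataFrame:
    """One subject per row; column names carry the canonical units."""
    rows = []
    for p in profiles:
        row = {col: getattr(p, attr) for attr, col in SUBJECT_COLUMNS.items()}
        row["sex"] = p.sex.value
        row["bodyweight_kg"] = round(p.bodyweight, 1)  # reporting convention
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SUBJECT_COLUMNS.values()))
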