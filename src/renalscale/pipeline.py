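"""Study orchestration: subjects → grid → clearances → scaling → verdicts.

``run_study`` executes the whole simulation for a :class:`RunConfig` and
returns (and optionally writes) five tidy tables:

* ``subjects``  — one typical subject per BMI category, canonical units;
* ``grid``      — the factorial drug × protein × BMI × rTA input space;
* ``clearance`` — fu, BP, CL_GF, CL_ATS, CLr, pathway contributions and
                  relative CLr for every grid row;
* ``scaling``   — scaled CLr, prediction error and accuracy per exponent,
                  plus the exponent required for exact scaling;
* ``verdicts``  — per-stratum systematic-accuracy verdicts.

Everything is deterministic — there is no randomness anywhere in the
pipeline — so identical configurations produce byte-identical outputs.
Tables are written UTF-8, comma-delimited, '.' decimal, empty missing
values, floats at 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import clearance, drug_space, physiology, scaling

__all__ = ["RunConfig", "run_study", "summarize_exponent_range", "write_tables"]

FLOAT_FORMAT = "%.6g"


def _default_grid_axes() -> dict[str, list]:
    g = drug_space.default_grid_values()
    return {k: g[k] for k in ("fu", "kp", "clint_ats", "rta")}


@dataclass
class RunConfig:
    """Full specification of one study run."""

    physiology_set: str = "fixture_linear"
    height: float = physiology.REFERENCE_HEIGHT_M
    sex: str = "male"
    bmi_categories: Sequence[float] = (20.0, 25.0, 30.0, 40.0, 50.0, 60.0)
    baseline_bmi: float = physiology.BASELINE_BMI
    grid_axes: Mapping[str, Sequence[float]] = field(default_factory=_default_grid_axes)
    proteins: Sequence[str] = ("HSA", "AAG")
    exponents: Sequence[float] = scaling.DEFAULT_EXPONENTS
    pe_threshold: float = scaling.DEFAULT_PE_THRESHOLD
    strata: Sequence[str] = scaling.DEFAULT_STRATA
    output_dir: str | None = None

    def __post_init__(self) -> None:
        self.bmi_categories = [float(b) for b in self.bmi_categories]
        if self.baseline_bmi not in self.bmi_categories:
            raise ValueError(
                f"baseline BMI {self.baseline_bmi} must be among bmi_categories {self.bmi_categories}"
            )
        axes = dict(self.grid_axes)
        for name in ("fu", "kp", "clint_ats", "rta"):
            if name not in axes or len(axes[name]) == 0:
                raise ValueError(f"grid axis {name!r} missing or empty in config")
        if 1.0 not in [float(v) for v in axes["rta"]]:
            raise ValueError("rta axis must contain 1.0 (the normal-weight baseline activity)")
        self.grid_axes = {k: [float(v) for v in axes[k]] for k in ("fu", "kp", "clint_ats", "rta")}
        self.proteins = [drug_space.BindingProtein(p).value for p in self.proteins]
        self.exponents = [float(e) for e in self.exponents]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config from a flat YAML file (keys as in the dataclass).

        The clint_ats axis may be given either as an explicit list or as
        ``{start, stop, count}`` for the equidistant construction.
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        axes = doc.get("grid_axes")
        if axes and isinstance(axes.get("clint_ats"), Mapping):
            c = axes["clint_ats"]
            axes["clint_ats"] = drug_space.clint_ats_values(
                float(c.get("start", 2.0)), float(c.get("stop", 500.0)), int(c.get("count", 32))
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)} (known: {sorted(known)})")
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _study_grid(config: RunConfig) -> pd.DataFrame:
    grid = {
        **{k: list(v) for k, v in config.grid_axes.items()},
        "bmi": list(config.bmi_categories),
        "binding_protein": list(config.proteins),
    }
    return drug_space.grid_table(grid)


def run_study(config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Execute the full study; write tables if ``config.output_dir`` is set."""
    config = RunConfig() if config is None else config
    subjects = {
        bmi: physiology.make_subject(bmi, config.height, config.sex, config.physiology_set)
        for bmi in config.bmi_categories
    }
    subjects_df = physiology.subjects_table(list(subjects.values()))
    grid_df = _study_grid(config)
    clearance_df = clearance.clearance_table(grid_df, subjects, config.baseline_bmi)
    bw_normal = subjects[config.baseline_bmi].bodyweight
    scaling_df = scaling.scaling_table(
        clearance_df, bw_normal, config.exponents, config.pe_threshold, config.baseline_bmi
    )
    verdicts_df = scaling.classify_systematic_accuracy(scaling_df, config.strata, config.pe_threshold)
    tables = {
        "subjects": subjects_df,
        "grid": grid_df,
        "clearance": clearance_df,
        "scaling": scaling_df,
        "verdicts": verdicts_df,
    }
    if config.output_dir is not None:
        write_tables(tables, config)
    return tables


def write_tables(tables: Mapping[str, pd.DataFrame], config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [f"config_hash: {config.config_hash()}"]
    lines += [f"config.{k}: {v}" for k, v in asdict(config).items()]
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
        lines.append(f"table {name}: {len(df)} rows -> {path.name}")
    (out / "run_log.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")


def summarize_exponent_range(
    scaling_df: pd.DataFrame,
    filters: Mapping[str, object] | None = None,
) -> dict:
    """Min/max required exponent over the (filtered) scaling table.

    ``filters`` maps column → value or list of values (e.g.
    ``{"rta": 1.0, "binding_protein": "HSA"}``).  Returns the overall
    extrema and a per-BMI breakdown with the range width, which shrinks as
    BMI rises when physiology-driven clearance changes converge.
    """
    df = scaling_df
    for col, val in (filters or {}).items():
        if col not in df.columns:
            raise KeyError(f"unknown filter column {col!r}")
        values = val if isinstance(val, (list, tuple, set)) else [val]
        df = df[df[col].isin(list(values))]
    if df.empty:
        raise ValueError("no rows left after filtering; cannot summarize exponent range")
    # one value per (drug, scenario): drop the duplication across exponents
    df = df[df["exponent"] == df["exponent"].iloc[0]]
    per_bmi = (
        df.groupby("bmi")["required_exponent"]
        .agg(min="min", max="max")
        .assign(width=lambda t: t["max"] - t["min"])
        .reset_index()
    )
    return {
        "min": float(df["required_exponent"].min()),
        "max": float(df["required_exponent"].max()),
        "n": int(len(df)),
        "per_bmi": per_bmi,
    }
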