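"""Readers, writers and pipeline configuration.

Data travel as long-format delimited text (CSV) with the columns
``subject_id, group, species, route, formulation, analyte, time_h,
conc_ng_ml, bql_flag``; parameter sets as flat YAML key-value documents
with the field names of the parameter types (``k_a, CL, V_d, N_R, ...``).
Output files carry a comment header recording the seed and a hash of the
configuration so any result can be traced to its run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ode import DEFAULT_CLAMP_TOL, DEFAULT_STEP
from .pk import ConcSeries, DepotParams, ParameterError, SolutionPKParams
from .pd import PDParams

__all__ = [
    "InputError",
    "REQUIRED_COLUMNS",
    "read_conc_table",
    "write_conc_table",
    "read_param_file",
    "write_param_file",
    "series_from_frame",
    "group_mean_series",
    "nonmem_export",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


class InputError(ValueError):
    """Malformed input data or configuration."""


REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "species",
    "route",
    "formulation",
    "analyte",
    "time_h",
    "conc_ng_ml",
    "bql_flag",
)


def read_conc_table(path) -> pd.DataFrame:
    """Read and validate a long-format concentration table.

    Rows are typed and sorted per subject/analyte/time; duplicate
    (subject, analyte, time) rows, missing columns, non-numeric or
    negative times and non-numeric concentrations are rejected with a
    message naming the offending row.
    """
    frame = pd.read_csv(path, comment="#", dtype={"group": str, "bql_flag": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"missing required columns: {missing}")
    frame["bql_flag"] = frame["bql_flag"].fillna("")
    for col in ("time_h", "conc_ng_ml"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise InputError(
                f"non-numeric {col} at row {bad[0]} "
                f"(subject {frame.loc[bad[0], 'subject_id']})"
            )
        if coerced.isna().any():
            raise InputError(f"missing {col} at row {coerced.index[coerced.isna()][0]}")
        frame[col] = coerced
    neg = frame.index[frame["time_h"] < 0]
    if len(neg):
        raise InputError(
            f"negative time at row {neg[0]} (subject {frame.loc[neg[0], 'subject_id']})"
        )
    if (frame["conc_ng_ml"] < 0).any():
        row = frame.index[frame["conc_ng_ml"] < 0][0]
        raise InputError(
            f"negative concentration at row {row} "
            f"(subject {frame.loc[row, 'subject_id']})"
        )
    dup = frame.duplicated(subset=["subject_id", "analyte", "time_h"], keep=False)
    if dup.any():
        row = frame[dup].iloc[0]
        raise InputError(
            f"duplicated time point: subject {row['subject_id']}, "
            f"analyte {row['analyte']}, t = {row['time_h']} h"
        )
    return frame.sort_values(
        ["group", "subject_id", "analyte", "time_h"], kind="mergesort"
    ).reset_index(drop=True)


def write_conc_table(frame: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write a long-format table with an optional ``# key: value`` header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)


def series_from_frame(
    frame: pd.DataFrame,
    subject_id: str,
    analyte: str,
    drop_bql: bool = True,
    drop_predose_drug: bool = True,
) -> ConcSeries:
    """Extract one subject/analyte profile as a :class:`ConcSeries`."""
    sel = frame[(frame["subject_id"] == subject_id) & (frame["analyte"] == analyte)]
    if drop_bql:
        sel = sel[sel["bql_flag"] != "BQL"]
    if drop_predose_drug and analyte == "leuprolide":
        sel = sel[sel["time_h"] > 0]
    if sel.empty:
        raise InputError(f"no rows for subject {subject_id!r}, analyte {analyte!r}")
    sel = sel.sort_values("time_h")
    meta = {
        "subject_id": subject_id,
        "group": str(sel["group"].iloc[0]),
        "species": sel["species"].iloc[0],
    }
    return ConcSeries(analyte, sel["time_h"].to_numpy(), sel["conc_ng_ml"].to_numpy(), meta)


def group_mean_series(
    frame: pd.DataFrame, group: str, analyte: str, drop_bql: bool = True
) -> ConcSeries:
    """Mean profile across the subjects of one group."""
    sel = frame[(frame["group"] == str(group)) & (frame["analyte"] == analyte)]
    if drop_bql:
        sel = sel[sel["bql_flag"] != "BQL"]
    if analyte == "leuprolide":
        sel = sel[sel["time_h"] > 0]
    if sel.empty:
        raise InputError(f"no rows for group {group!r}, analyte {analyte!r}")
    mean = sel.groupby("time_h")["conc_ng_ml"].mean().sort_index()
    meta = {"group": str(group), "n": int(sel["subject_id"].nunique())}
    return ConcSeries(analyte, mean.index.to_numpy(), mean.to_numpy(), meta)


_PARAM_TYPES = {"solution": SolutionPKParams, "depot": DepotParams, "pd": PDParams}


def write_param_file(params, path) -> None:
    """Serialise a parameter set as a flat YAML document."""
    kind = {SolutionPKParams: "solution", DepotParams: "depot", PDParams: "pd"}[
        type(params)
    ]
    doc = {"kind": kind, **asdict(params)}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_param_file(path):
    """Read a parameter set written by :func:`write_param_file`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "kind" not in doc:
        raise InputError(f"{path}: parameter file needs a 'kind' key")
    kind = doc.pop("kind")
    try:
        cls = _PARAM_TYPES[kind]
    except KeyError:
        raise InputError(
            f"{path}: unknown parameter kind {kind!r}; expected one of "
            f"{sorted(_PARAM_TYPES)}"
        ) from None
    try:
        return cls(**doc)
    except (TypeError, ParameterError) as exc:
        raise InputError(f"{path}: {exc}") from exc


def nonmem_export(frame: pd.DataFrame, dose_amount_ng: float | None = None) -> pd.DataFrame:
    """Convenience ID/TIME/DV/AMT/CMT export of a long-format table."""
    ids = {s: i + 1 for i, s in enumerate(frame["subject_id"].unique())}
    out = pd.DataFrame(
        {
            "ID": frame["subject_id"].map(ids),
            "TIME": frame["time_h"],
            "DV": frame["conc_ng_ml"],
            "AMT": 0.0,
            "CMT": np.where(frame["analyte"] == "leuprolide", 2, 3),
            "MDV": 0,
        }
    )
    if dose_amount_ng is not None:
        doses = pd.DataFrame(
            {
                "ID": sorted(ids.values()),
                "TIME": 0.0,
                "DV": np.nan,
                "AMT": dose_amount_ng,
                "CMT": 1,
                "MDV": 1,
            }
        )
        out = pd.concat([doses, out], ignore_index=True)
    return out.sort_values(["ID", "TIME", "CMT"]).reset_index(drop=True)


@dataclass
class PipelineConfig:
    """Validated configuration for the full analysis pipeline."""

    data_path: str | None = None
    out_dir: str = "results"
    solver_step: float = DEFAULT_STEP
    clamp_tol: float = DEFAULT_CLAMP_TOL
    weighting: str = "prop2"
    n_starts: int = 5
    seed: int = 0
    terminal_k_points: int = 3
    auec_baseline_mode: str = "subject"  # subject | group
    feedback_form: str = "reciprocal"
    body_weight_kg: float = 0.3
    dose_mg_per_kg: float = 0.1
    fit_target: str = "mean"  # mean | subject
    simplex_maxfev: int = 100
    groups: dict = field(default_factory=dict)  # role -> group label overrides

    def validate(self) -> "PipelineConfig":
        if self.solver_step <= 0:
            raise InputError("solver_step must be > 0")
        if self.weighting not in ("none", "prop", "prop2"):
            raise InputError(f"unknown weighting {self.weighting!r}")
        if self.auec_baseline_mode not in ("subject", "group"):
            raise InputError(
                f"auec_baseline_mode must be 'subject' or 'group', "
                f"got {self.auec_baseline_mode!r}"
            )
        if self.feedback_form not in ("reciprocal", "product"):
            raise InputError(f"unknown feedback_form {self.feedback_form!r}")
        if self.fit_target not in ("mean", "subject"):
            raise InputError(f"fit_target must be 'mean' or 'subject'")
        if self.n_starts < 1:
            raise InputError("n_starts must be >= 1")
        if self.body_weight_kg <= 0:
            raise InputError("body_weight_kg must be > 0")
        return self


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration, rejecting unknown keys."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise InputError(f"{path}: configuration must be a mapping")
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise InputError(
            f"{path}: unknown configuration keys {unknown}; known keys are "
            f"{sorted(known)}"
        )
    return PipelineConfig(**doc).validate()


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of a configuration, for output provenance headers."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
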