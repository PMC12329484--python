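"""Tabular file formats and run configuration.

Everything on disk is tab-separated UTF-8 text with a header row, "." as
the decimal separator, and "NA" as the sole missing-value token — the
study's data are tables of positions and tract statistics, and portability
beats compactness.  Readers validate structure and report offending rows by
number (1-based, counting the header as row 1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .patterns import PositionalPattern
from .scoring import AlignConfig
from .simulate import CohortConfig, Environment
from .association import AssociationConfig

_FLOAT_FMT = "%.10g"

LAYOUT_COLUMNS = ["env_id", "object_label", "x", "y"]
RESPONSE_COLUMNS = ["subject_id", "trial_id", "env_id", "object_label", "x", "y"]
SCORE_COLUMNS = ["subject_id", "trial_id", "env_id", "pattern_accuracy",
                 "raw_accuracy", "environmental_geometry", "object_identity",
                 "failed", "theta", "scale", "tx", "ty"]
TRACT_COLUMNS = ["subject_id", "tract", "hemisphere", "measure", "value",
                 "dropout", "pvf", "age", "in_scanner"]
OUTCOME_COLUMNS = ["subject_id", "trial_id", "env_id",
                   "objects_association", "objects_room"]


def _read_tsv(path, expected_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=["NA"], encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file has no header row")
    if list(df.columns) != list(expected_columns):
        raise ValidationError(
            f"{path}: expected columns {list(expected_columns)}, "
            f"found {list(df.columns)}"
        )
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())][:10]
        raise ValidationError(
            f"{path}: non-numeric value in column {col!r} at row(s) {rows} "
            f"(e.g. {raw[bad].iloc[0]!r}); use '.' as the decimal separator"
        )
    return out


def _write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format=_FLOAT_FMT, encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# layouts (true object positions) and responses
# ---------------------------------------------------------------------------


def write_layout_table(layouts: dict[str, PositionalPattern], path) -> None:
    """Write env_id/object_label/x/y rows, one per object."""
    rows = []
    for env_id, pattern in layouts.items():
        for lab, (x, y) in zip(pattern.labels, pattern.points):
            rows.append({"env_id": env_id, "object_label": lab,
                         "x": float(x), "y": float(y)})
    _write_tsv(pd.DataFrame(rows, columns=LAYOUT_COLUMNS), path)


def read_layout_table(path) -> dict[str, PositionalPattern]:
    """Read a layout table into env_id -> pattern; empty file (header only)
    gives an empty dict."""
    df = _read_tsv(path, LAYOUT_COLUMNS)
    if df.empty:
        return {}
    df = df.copy()
    df["x"] = _numeric(df, "x", path)
    df["y"] = _numeric(df, "y", path)
    dup = df.duplicated(subset=["env_id", "object_label"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in np.flatnonzero(dup.to_numpy())]
        raise ValidationError(
            f"{path}: duplicate (env_id, object_label) at row(s) {rows}"
        )
    out = {}
    for env_id, grp in df.groupby("env_id", sort=True):
        out[str(env_id)] = PositionalPattern(
            grp[["x", "y"]].to_numpy(float), list(grp["object_label"])
        )
    return out


def write_response_table(responses: pd.DataFrame, path) -> None:
    _write_tsv(responses[RESPONSE_COLUMNS], path)


def read_response_table(path) -> pd.DataFrame:
    """Per-trial recalled positions; validates numeric coordinates and
    uniqueness of labels within each trial."""
    df = _read_tsv(path, RESPONSE_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=RESPONSE_COLUMNS)
    df = df.copy()
    df["x"] = _numeric(df, "x", path)
    df["y"] = _numeric(df, "y", path)
    dup = df.duplicated(subset=["subject_id", "trial_id", "object_label"],
                        keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in np.flatnonzero(dup.to_numpy())]
        raise ValidationError(
            f"{path}: duplicate object label within a trial at row(s) {rows}"
        )
    return df


# ---------------------------------------------------------------------------
# scores, thresholds, tracts, outcomes
# ---------------------------------------------------------------------------


def write_score_table(scores: pd.DataFrame, path) -> None:
    df = scores.copy()
    df["failed"] = df["failed"].astype(bool)
    _write_tsv(df[SCORE_COLUMNS], path)


def read_score_table(path) -> pd.DataFrame:
    df = _read_tsv(path, SCORE_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    df = df.copy()
    for col in ["pattern_accuracy", "raw_accuracy", "environmental_geometry",
                "object_identity", "theta", "scale", "tx", "ty"]:
        df[col] = _numeric(df, col, path)
    df["failed"] = df["failed"].map({"True": True, "False": False})
    if df["failed"].isna().any():
        raise ValidationError(f"{path}: failed column must be True/False")
    return df


def write_threshold_report(threshold, path) -> None:
    df = pd.DataFrame([{
        "cutoff": threshold.cutoff,
        "youden": threshold.youden,
        "misclassification": threshold.misclassification,
        "n_pos": threshold.n_pos,
        "n_neg": threshold.n_neg,
    }])
    _write_tsv(df, path)


def read_threshold_report(path):
    from .chance import ChanceThreshold
    df = _read_tsv(path, ["cutoff", "youden", "misclassification",
                          "n_pos", "n_neg"])
    if len(df) != 1:
        raise ValidationError(f"{path}: expected exactly one threshold row")
    row = df.iloc[0]
    return ChanceThreshold(
        cutoff=float(row["cutoff"]), youden=float(row["youden"]),
        misclassification=float(row["misclassification"]),
        n_pos=int(row["n_pos"]), n_neg=int(row["n_neg"]),
    )


def write_tract_table(tracts: pd.DataFrame, path) -> None:
    _write_tsv(tracts[TRACT_COLUMNS], path)


def read_tract_table(path) -> pd.DataFrame:
    df = _read_tsv(path, TRACT_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=TRACT_COLUMNS)
    df = df.copy()
    for col in ["value", "dropout", "pvf", "age", "in_scanner"]:
        df[col] = _numeric(df, col, path)
    bad = ~df["measure"].isin(["FA", "MD"])
    if bad.any():
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise ValidationError(f"{path}: measure must be FA or MD at row(s) {rows}")
    return df


def write_outcome_table(outcomes: pd.DataFrame, path) -> None:
    _write_tsv(outcomes[OUTCOME_COLUMNS], path)


def read_outcome_table(path) -> pd.DataFrame:
    df = _read_tsv(path, OUTCOME_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=OUTCOME_COLUMNS)
    df = df.copy()
    for col in ["objects_association", "objects_room"]:
        df[col] = _numeric(df, col, path)
    return df


def write_perimeters(environments: list[Environment], path) -> None:
    """Room geometry sidecar (JSON): perimeter vertices, family, area."""
    payload = {
        e.env_id: {
            "shape_family": e.shape_family,
            "area": e.area,
            "perimeter": [[float(x), float(y)] for x, y in e.perimeter],
        }
        for e in environments
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n",
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class ChanceConfig:
    """Chance-threshold estimation settings."""

    n_foil_library: int = 120   # foil environments generated for the null
    n_foils: int = 120          # foil comparisons per null response
    n_null_subjects: int = 10   # sub-group of subjects for the null pool
    n_null_trials: int = 10     # trials per null subject
    method: str = "youden"


@dataclass
class RunConfig:
    """Every tunable of an end-to-end run, JSON-serializable.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    chance: ChanceConfig = field(default_factory=ChanceConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    version: str = "0.1.0"


def _from_dict(cls, payload: dict, context: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"valid keys: {sorted(known)}"
        )
    kwargs = {}
    for key, value in payload.items():
        if key in ("cohort", "align", "chance", "association"):
            sub_cls = {"cohort": CohortConfig, "align": AlignConfig,
                       "chance": ChanceConfig,
                       "association": AssociationConfig}[key]
            kwargs[key] = _from_dict(sub_cls, value, f"{context}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v
                                for v in value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path) -> RunConfig:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: config must be a JSON object")
    cfg = _from_dict(RunConfig, payload, "config")
    cfg.cohort.seed = cfg.seed
    return cfg


def dump_run_config(config: RunConfig, path) -> None:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(
        json.dumps(encode(config), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
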