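"""On-disk formats: TPM CSV, mapping CSV, results tables, run configs.

TPM files are plain CSV with a header row of state labels (effect order)
and a first column of state labels (cause order); cells are probabilities
with '.' as the decimal separator. Mapping files are two-column CSV
``micro_state,macro_state``. Results tables are long-format (one value
per row); infinities serialize as ``inf``/``-inf`` and undefined values
as an empty cell alongside ``defined=False``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .core import StateSpace, TransitionModel
from .emergence import CoarseGraining, EmergenceReport
from .errors import FormatError
from .measures import MeasureResult

__all__ = [
    "read_tpm",
    "write_tpm",
    "read_mapping",
    "write_mapping",
    "results_to_dataframe",
    "reports_to_dataframe",
    "write_table",
    "load_config",
]


def read_tpm(path: str | Path) -> TransitionModel:
    """Read and validate a TPM CSV (labels preserved in file order)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, converters={0: str})
    except Exception as exc:
        raise FormatError(f"cannot parse TPM file {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError("a TPM file needs at least 2 states")
    labels = [str(x) for x in df.iloc[:, 0]]
    header = [str(c) for c in df.columns[1:]]
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate cause labels in {path}")
    if len(set(header)) != len(header):
        raise FormatError(f"duplicate effect labels in {path}")
    if set(labels) != set(header):
        raise FormatError("cause and effect label sets differ")
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric probability cell: {exc}") from exc
    # reorder columns to the cause-label (row) order
    order = [header.index(s) for s in labels]
    space = StateSpace.from_labels(labels)
    try:
        return TransitionModel(space, values[:, order])
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"invalid TPM in {path}: {exc}") from exc


def write_tpm(model: TransitionModel, path: str | Path) -> None:
    df = pd.DataFrame(
        model.matrix, index=list(model.space.labels),
        columns=list(model.space.labels),
    )
    df.to_csv(path, index_label="state")


def read_mapping(
    path: str | Path, micro_space: StateSpace | None = None
) -> CoarseGraining | dict[str, str]:
    """Read a two-column micro,macro mapping.

    With a micro space the full CoarseGraining is returned (macrostates
    ordered by first appearance); without one, the raw mapping dict.
    """
    path = Path(path)
    df = pd.read_csv(path, converters={0: str, 1: str})
    if df.shape[1] != 2:
        raise FormatError("mapping files have exactly two columns")
    mapping: dict[str, str] = {}
    for micro, macro in df.itertuples(index=False):
        micro, macro = str(micro), str(macro)
        if micro in mapping and mapping[micro] != macro:
            raise FormatError(
                f"micro state {micro!r} mapped to both "
                f"{mapping[micro]!r} and {macro!r}"
            )
        mapping[micro] = macro
    if micro_space is None:
        return mapping
    unknown = [s for s in mapping if s not in micro_space]
    if unknown:
        raise FormatError(f"mapping references unknown micro label {unknown[0]!r}")
    return CoarseGraining.from_mapping(micro_space, mapping)


def write_mapping(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"micro_state": list(mapping), "macro_state": list(mapping.values())}
    ).to_csv(path, index=False)


def _fmt_value(value: float, defined: bool) -> str:
    if not defined or math.isnan(value):
        return ""
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return repr(float(value))


def results_to_dataframe(results: Sequence[MeasureResult]) -> pd.DataFrame:
    """Long-format table: measure, cause, effect, intervention_kind, value, defined."""
    rows = []
    for r in results:
        t = r.transition
        rows.append({
            "measure": r.measure_name,
            "cause": getattr(t, "cause", str(t)),
            "effect": getattr(t, "effect", str(t)),
            "intervention_kind": r.intervention_kind,
            "value": _fmt_value(r.value, r.defined),
            "defined": r.defined,
        })
    return pd.DataFrame(rows)


def reports_to_dataframe(reports: Sequence[EmergenceReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "measure": r.measure,
            "scope": r.scope,
            "cause": getattr(r.micro_transition, "cause", ""),
            "effect": getattr(r.micro_transition, "effect", ""),
            "macro_cause": getattr(r.macro_transition, "cause", ""),
            "macro_effect": getattr(r.macro_transition, "effect", ""),
            "intervention": r.intervention,
            "cs_micro": _fmt_value(r.cs_micro, r.micro_defined),
            "cs_macro": _fmt_value(r.cs_macro, r.macro_defined),
            "ce": _fmt_value(r.ce, r.ce_defined),
            "defined": r.ce_defined,
            "sign": r.sign,
            **{k: v for k, v in r.params.items()},
        })
    return pd.DataFrame(rows)


def sweep_to_csv(sweep_df: pd.DataFrame, path: str | Path) -> None:
    """Serialize a sweep table with inf/empty-cell conventions."""
    df = sweep_df.copy()
    for col in ("cs_micro", "cs_macro", "ce"):
        df[col] = [
            _fmt_value(float(v), not math.isnan(float(v))) for v in df[col]
        ]
    df.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """A YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError("config must be a mapping")
    return data
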