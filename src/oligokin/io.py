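"""Readers and writers for the package's tabular and config formats.

All tables are CSV with unit-bearing column names; configuration files are
YAML/JSON keyed by parameter names.  See FORMATS.md for the schemas.
Validation errors name the offending column and row.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .biosensor import BindingTrace
from .model import OligomerDistribution, SimulationResult
from .params import Condition, RateParameters, SpaParameters

__all__ = [
    "ParseError",
    "read_condition_table",
    "read_count_table",
    "read_event_table",
    "read_trace_table",
    "write_condition_table",
    "write_count_table",
    "write_distribution_table",
    "load_parameters",
    "dump_parameters",
]


class ParseError(ValueError):
    """A table or config file violated its schema."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(
            f"{path}: non-numeric value in column {column!r} at line {row}"
        )
    if values.isna().any():
        row = int(values.isna().idxmax()) + 2
        raise ParseError(f"{path}: empty cell in column {column!r} at line {row}")
    return values.to_numpy(dtype=float)


CONDITION_COLUMNS = [
    "condition_id", "variant", "mutant", "c_bulk_nM",
    "dnp_fraction", "t_incubation_s", "spa_conc_uM",
]
COUNT_COLUMNS = ["condition_id"] + [f"size_{s}" for s in range(1, 7)]


def read_condition_table(path: str | Path) -> list[tuple[str, Condition]]:
    """Read a condition CSV into ``(condition_id, Condition)`` records."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CONDITION_COLUMNS, path)
    c_bulk = _numeric(df, "c_bulk_nM", path)
    frac = _numeric(df, "dnp_fraction", path)
    t_inc = _numeric(df, "t_incubation_s", path)
    spa = _numeric(df, "spa_conc_uM", path)
    records = []
    for i, row in df.iterrows():
        mutant_label = str(row["mutant"]).strip()
        if mutant_label not in ("WT", "E430G"):
            raise ParseError(
                f"{path}: column 'mutant' at line {i + 2} must be WT or E430G, "
                f"got {mutant_label!r}"
            )
        try:
            cond = Condition(
                variant=str(row["variant"]).strip(),
                mutant=mutant_label == "E430G",
                c_bulk=c_bulk[i] * 1e-9,
                dnp_fraction=frac[i],
                t_incubation=t_inc[i],
                spa_conc=spa[i] * 1e-6,
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from None
        records.append((str(row["condition_id"]), cond))
    return records


def read_count_table(path: str | Path) -> dict[str, OligomerDistribution]:
    """Read an oligomer-count CSV into per-condition distributions."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, path)
    counts = np.column_stack(
        [_numeric(df, f"size_{s}", path) for s in range(1, 7)]
    )
    if np.any(counts < 0):
        raise ParseError(f"{path}: oligomer counts must be non-negative")
    return {
        str(cid): OligomerDistribution(row)
        for cid, row in zip(df["condition_id"], counts)
    }


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read a rupture-event CSV (one row per event)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["loading_rate_pN_s", "force_pN"], path)
    rates = _numeric(df, "loading_rate_pN_s", path)
    _numeric(df, "force_pN", path)
    if np.any(rates <= 0):
        raise ParseError(f"{path}: loading rates must be positive")
    return df


def read_trace_table(path: str | Path) -> list[BindingTrace]:
    """Read a biosensor trace CSV (time_s, response, conc_M, phase)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "response", "conc_M", "phase"], path)
    _numeric(df, "time_s", path)
    _numeric(df, "response", path)
    _numeric(df, "conc_M", path)
    traces = []
    for conc, group in df.groupby("conc_M", sort=True):
        group = group.sort_values("time_s")
        phases = group["phase"].astype(str).str.lower()
        if not phases.isin(["association", "dissociation"]).all():
            raise ParseError(
                f"{path}: phase must be 'association' or 'dissociation'"
            )
        assoc = group.loc[phases == "association", "time_s"]
        if assoc.empty:
            raise ParseError(f"{path}: trace at {conc} M has no association phase")
        traces.append(
            BindingTrace(
                times=group["time_s"].to_numpy(dtype=float),
                response=group["response"].to_numpy(dtype=float),
                analyte_conc=float(conc),
                t_association_end=float(assoc.max()),
            )
        )
    return traces


def write_condition_table(
    records: Sequence[tuple[str, Condition]] | pd.DataFrame, path: str | Path
) -> None:
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, index=False)
        return
    rows = [
        {
            "condition_id": cid,
            "variant": cond.variant,
            "mutant": "E430G" if cond.mutant else "WT",
            "c_bulk_nM": cond.c_bulk * 1e9,
            "dnp_fraction": cond.dnp_fraction,
            "t_incubation_s": cond.t_incubation,
            "spa_conc_uM": cond.spa_conc * 1e6,
        }
        for cid, cond in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_count_table(counts: dict[str, np.ndarray] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(counts, pd.DataFrame):
        counts.to_csv(path, index=False)
        return
    rows = [
        {"condition_id": cid, **{f"size_{s + 1}": int(c[s]) for s in range(6)}}
        for cid, c in counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_distribution_table(
    results: Sequence[tuple[str, SimulationResult]], path: str | Path
) -> None:
    """Per-condition distribution CSV: fractions, densities and total IgG."""
    rows = []
    for cid, res in results:
        dist = res.distribution
        row = {"condition_id": cid}
        for s in range(6):
            row[f"frac_size_{s + 1}"] = dist.fractions[s]
        for s in range(6):
            row[f"per_um2_size_{s + 1}"] = dist.abundance[s]
        row["total_igg_per_um2"] = dist.total_igg_density
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------

def dump_parameters(params: RateParameters, path: str | Path) -> None:
    """Write a RateParameters YAML file (units as in the module docs)."""
    data = {
        "k1b": params.k1b,
        "k2": params.k2,
        "k_minus2": params.k_minus2,
        "k3": params.k3,
        "k4": params.k4,
        "kT": params.kT,
        "e430g_factor": params.e430g_factor,
        "alpha_prefactors": {float(k): float(v) for k, v in params.alpha_prefactors.items()},
        "kon_fab_by_surface": {float(k): float(v) for k, v in params.kon_fab_by_surface.items()},
        "koff_fab_by_surface": {float(k): float(v) for k, v in params.koff_fab_by_surface.items()},
        "spa": {"kC": params.spa.kC, "k_minusC": params.spa.k_minusC},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_parameters(path: str | Path) -> RateParameters:
    """Read a RateParameters YAML/JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: parameter file must be a mapping")
    known = {
        "k1b", "k2", "k_minus2", "k3", "k4", "kT", "e430g_factor",
        "alpha_prefactors", "kon_fab_by_surface", "koff_fab_by_surface", "spa",
    }
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown parameter key(s) {sorted(unknown)}")
    kwargs = {}
    for key in ("k1b", "k2", "k_minus2", "k3", "k4", "kT", "e430g_factor"):
        if key in data:
            kwargs[key] = float(data[key])
    for key in ("alpha_prefactors", "kon_fab_by_surface", "koff_fab_by_surface"):
        if key in data:
            kwargs[key] = {float(k): float(v) for k, v in data[key].items()}
    if "spa" in data:
        kwargs["spa"] = SpaParameters(
            kC=float(data["spa"]["kC"]), k_minusC=float(data["spa"]["k_minusC"])
        )
    try:
        return RateParameters(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from None
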