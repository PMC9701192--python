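"""Readers and writers: measurement tables, run configs, and reports.

Measurement tables are delimited text (comma by default, tab accepted) with
a header row.  The default schema is::

    mass_pg, particle_class, condition_id, role, t_meas_s, instrument_id

A user-supplied column mapping can rename any of these.  ``t_meas_s`` and
``instrument_id`` are optional.  Masses are picograms; no unit detection is
attempted.  Reports are written as a JSON + CSV twin.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    InferenceConfig,
    MassRecord,
    ParticleClass,
    Role,
    TestResult,
    ValidationError,
    coerce_particle_class,
)

__all__ = [
    "DEFAULT_SCHEMA",
    "load_measurements",
    "save_measurements",
    "records_to_frame",
    "load_config",
    "save_config",
    "write_report",
    "read_report",
]

logger = logging.getLogger("massresponse")

DEFAULT_SCHEMA: dict[str, str] = {
    "mass": "mass_pg",
    "particle_class": "particle_class",
    "condition_id": "condition_id",
    "role": "role",
    "t_meas": "t_meas_s",
    "instrument_id": "instrument_id",
}

_REQUIRED = ("mass", "particle_class", "condition_id", "role")


class SchemaError(ValidationError):
    """The measurement table lacks a required column."""


def _resolve_schema(schema: Mapping[str, str] | None) -> dict[str, str]:
    resolved = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown schema fields: {sorted(unknown)}")
        resolved.update(schema)
    return resolved


def load_measurements(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[MassRecord]:
    """Read a measurement table into validated records.

    Rows failing validation (non-numeric or non-positive mass for a cell
    class, negative time) are rejected and counted in the log rather than
    aborting the read.  Unknown particle-class strings map to unclassified
    and a missing role defaults to ``test``, each with a warning.
    """
    path = Path(path)
    cols = _resolve_schema(schema)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [cols[f] for f in _REQUIRED if cols[f] not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[MassRecord] = []
    rejected = 0
    has_t = cols["t_meas"] in df.columns
    has_inst = cols["instrument_id"] in df.columns
    for idx, row in df.iterrows():
        try:
            mass = float(row[cols["mass"]])
            role_raw = row[cols["role"]]
            if pd.isna(role_raw) or str(role_raw).strip() == "":
                warnings.warn(f"row {idx}: missing role, defaulting to 'test'",
                              stacklevel=2)
                role = Role.TEST
            else:
                role = Role(str(role_raw).strip().lower())
            rec = MassRecord(
                mass=mass,
                particle_class=coerce_particle_class(row[cols["particle_class"]]),
                condition_id=str(row[cols["condition_id"]]),
                role=role,
                t_meas=float(row[cols["t_meas"]]) if has_t else 0.0,
                instrument_id=(str(row[cols["instrument_id"]])
                               if has_inst and not pd.isna(row[cols["instrument_id"]])
                               else None),
            )
        except (ValueError, ValidationError) as exc:
            rejected += 1
            logger.warning("%s: row %s rejected: %s", path, idx, exc)
            continue
        records.append(rec)
    if rejected:
        logger.info("%s: %d row(s) rejected during validation", path, rejected)
    return records


def records_to_frame(records: Iterable[MassRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the default schema (plus true_class when
    any record carries one)."""
    records = list(records)
    df = pd.DataFrame({
        "mass_pg": [r.mass for r in records],
        "particle_class": [r.particle_class.value for r in records],
        "condition_id": [r.condition_id for r in records],
        "role": [r.role.value for r in records],
        "t_meas_s": [r.t_meas for r in records],
        "instrument_id": [r.instrument_id for r in records],
    })
    if any(r.true_class is not None for r in records):
        df["true_class"] = [
            r.true_class.value if r.true_class is not None else ""
            for r in records
        ]
    return df


def save_measurements(records: Iterable[MassRecord], path: str | Path) -> Path:
    """Write records as a delimited table (separator chosen by extension).

    Masses are serialized with ``repr`` round-trip precision so a
    save/load cycle preserves values exactly.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    records_to_frame(records).to_csv(path, sep=sep, index=False,
                                     float_format=lambda v: repr(float(v)))
    return path


def load_config(path: str | Path) -> InferenceConfig:
    with open(path) as fh:
        return InferenceConfig.from_dict(json.load(fh))


def save_config(cfg: InferenceConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
    return path


def write_report(
    results: Sequence[TestResult],
    out_dir: str | Path,
    *,
    config: InferenceConfig | None = None,
    curation_summary: Mapping | None = None,
    metadata: Mapping | None = None,
    stem: str = "report",
) -> tuple[Path, Path]:
    """Emit the machine-readable report twin: ``<stem>.json`` and
    ``<stem>.csv``.

    The JSON carries one record per condition (signals as fractions and as
    percent, p, call, sizes) plus the config echo; the CSV is the flat
    per-condition table.  A clearly-labelled Benjamini-Hochberg adjusted
    p-value column is included as optional metadata; the calls themselves
    use the raw per-condition p-values.
    """
    if not results:
        raise ValidationError("cannot write an empty report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    from statsmodels.stats.multitest import multipletests

    pvals = [r.p_value for r in results]
    bh = multipletests(pvals, method="fdr_bh")[1] if len(pvals) > 1 else list(pvals)

    rows = []
    for r, p_bh in zip(results, bh):
        d = r.to_dict()
        d["test_signal_pct"] = 100.0 * r.test_signal
        d["ctrl_signal_pct"] = 100.0 * r.ctrl_signal
        d["theta_hat_pct"] = 100.0 * r.theta_hat
        d["p_value_bh_adjusted"] = float(p_bh)
        rows.append(d)

    payload = {
        "results": rows,
        "config": config.to_dict() if config is not None else None,
        "curation_summary": (dict(curation_summary)
                             if curation_summary is not None else None),
        "metadata": dict(metadata) if metadata is not None else {},
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")

    flat = pd.DataFrame([{
        "condition_id": d["condition_id"],
        "test_signal_pct": d["test_signal_pct"],
        "ctrl_signal_pct": d["ctrl_signal_pct"],
        "theta_hat_pct": d["theta_hat_pct"],
        "se_hat": d["se_hat"],
        "t_obs": d["t_obs"],
        "p_value": d["p_value"],
        "p_value_bh_adjusted": d["p_value_bh_adjusted"],
        "call": d["call"],
        "n_test": d["n_used"].get("test"),
        "n_control": d["n_used"].get("control"),
        "n_reference": d["n_used"].get("reference"),
        "ci_low_pct": (100.0 * d["test_ci"][0]) if d["test_ci"] else None,
        "ci_high_pct": (100.0 * d["test_ci"][1]) if d["test_ci"] else None,
        "low_n": d["low_n"],
    } for d in rows])
    csv_path = out_dir / f"{stem}.csv"
    flat.to_csv(csv_path, index=False)
    return json_path, csv_path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report(json_path: str | Path) -> tuple[list[TestResult], dict]:
    """Re-parse a JSON report into result objects (round-trip of
    :func:`write_report`)."""
    with open(json_path) as fh:
        payload = json.load(fh)
    results = [TestResult.from_dict(d) for d in payload["results"]]
    return results, payload
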