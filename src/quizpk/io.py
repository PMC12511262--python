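"""Dataset schema, NONMEM-style CSV input/output and report serialization.

The on-disk dialect follows NONMEM column conventions (ID, TIME, AMT, EVID,
MDV, DV, CMT), comma-separated UTF-8 with a header row; matching is
case-insensitive and extra columns (covariates, nominal times, BLQ flags)
pass through untouched.  Missing DV is encoded via MDV=1 and an empty DV
cell, never by sentinel numbers.
"""

from __future__ import annotations

import json
import logging
import numbers
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("quizpk")

#: canonical column order; extra columns are preserved after these
CORE_COLUMNS = ["ID", "TIME", "AMT", "EVID", "MDV", "DV", "CMT"]
REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "EVID", "MDV", "DV"]


class SchemaError(ValueError):
    """Input file does not have the required columns/types."""


class ValidationError(ValueError):
    """Dataset rows violate a structural invariant."""


@dataclass(frozen=True)
class DatasetRow:
    """One dosing or observation event.

    ``evid`` 1 marks a dose (``amt`` mg, no ``dv``); ``evid`` 0 marks an
    observation (``dv`` ng/mL, no ``amt``).  ``time`` is hours since the
    subject's first dose.
    """

    subject_id: int
    time: float
    evid: int
    mdv: int
    amt: float | None = None
    dv: float | None = None
    cmt: int = 1
    covariates: dict = field(default_factory=dict)


class CohortDataset:
    """A validated cohort in NONMEM-style long format.

    Thin wrapper over a :class:`pandas.DataFrame` sorted by subject then
    time, with dosing rows preceding same-time observation handling left to
    row order (predose samples precede the co-timed dose row).
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        df = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if "CMT" not in df.columns:
            df["CMT"] = np.where(df["EVID"] == 1, 1, 2)
        if validate:
            self._validate_input_order(df)
        # stable sort keeps within-time row order (predose before co-timed dose)
        df = df.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
        self.frame = df
        if validate:
            self._validate()

    @staticmethod
    def _validate_input_order(df: pd.DataFrame) -> None:
        """Catch disorders the canonical sort would silently repair."""
        ids = df["ID"].to_numpy()
        first_seen: dict = {}
        last = None
        for i, sid in enumerate(ids):
            if sid != last and sid in first_seen:
                raise ValidationError(
                    f"subject {sid}: rows not contiguously grouped"
                )
            first_seen.setdefault(sid, i)
            last = sid
        for sid, g in df.groupby("ID", sort=False):
            if np.any(np.diff(g["TIME"].to_numpy(float)) < 0):
                raise ValidationError(f"subject {sid}: times not non-decreasing")

    # -- structural invariants ------------------------------------------
    def _validate(self) -> None:
        df = self.frame
        if not df["EVID"].isin([0, 1]).all():
            raise ValidationError("EVID must be 0 (observation) or 1 (dose)")
        if (df["TIME"] < 0).any():
            raise ValidationError("times must be non-negative")
        doses = df[df["EVID"] == 1]
        obs = df[df["EVID"] == 0]
        if (doses["AMT"].isna() | (doses["AMT"] <= 0)).any():
            bad = doses.loc[doses["AMT"].isna() | (doses["AMT"] <= 0), "ID"].iloc[0]
            raise ValidationError(f"subject {bad}: dosing row (EVID=1) needs AMT > 0")
        if doses["DV"].notna().any():
            bad = doses.loc[doses["DV"].notna(), "ID"].iloc[0]
            raise ValidationError(f"subject {bad}: DV present on EVID=1 row")
        if obs["AMT"].notna().any() and (obs["AMT"].dropna() != 0).any():
            bad = obs.loc[obs["AMT"].notna() & (obs["AMT"] != 0), "ID"].iloc[0]
            raise ValidationError(f"subject {bad}: AMT present on EVID=0 row")
        measured = obs[obs["MDV"] == 0]
        if measured["DV"].isna().any() or (measured["DV"] < 0).any():
            bad = measured.loc[
                measured["DV"].isna() | (measured["DV"] < 0), "ID"
            ].iloc[0]
            raise ValidationError(f"subject {bad}: observation needs DV >= 0")
        for sid, g in df.groupby("ID", sort=False):
            t = g["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValidationError(f"subject {sid}: times not non-decreasing")
            first_obs = g.index[g["EVID"] == 0]
            first_dose = g.index[g["EVID"] == 1]
            if len(first_obs) and (
                not len(first_dose) or first_dose[0] > first_obs[0]
            ):
                raise ValidationError(
                    f"subject {sid}: observation before any dosing row"
                )

    # -- convenience ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return int(self.frame["ID"].nunique())

    @property
    def n_observations(self) -> int:
        return int((self.frame["EVID"] == 0).sum())

    @property
    def observations(self) -> pd.DataFrame:
        return self.frame[self.frame["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.frame[self.frame["EVID"] == 1]

    @property
    def rows(self) -> list[DatasetRow]:
        core = set(CORE_COLUMNS)
        out = []
        for rec in self.frame.to_dict("records"):
            out.append(
                DatasetRow(
                    subject_id=int(rec["ID"]),
                    time=float(rec["TIME"]),
                    evid=int(rec["EVID"]),
                    mdv=int(rec["MDV"]),
                    amt=None if pd.isna(rec["AMT"]) else float(rec["AMT"]),
                    dv=None if pd.isna(rec["DV"]) else float(rec["DV"]),
                    cmt=int(rec["CMT"]),
                    covariates={k: v for k, v in rec.items() if k not in core},
                )
            )
        return out


def read_dataset(path, dialect: dict | None = None) -> CohortDataset:
    """Read a NONMEM-style CSV into a validated :class:`CohortDataset`.

    Column matching is case-insensitive; a short parse report is logged.
    """
    path = Path(path)
    sep = (dialect or {}).get("sep", ",")
    df = pd.read_csv(path, sep=sep)
    upper = {c: c.upper().strip() for c in df.columns}
    df = df.rename(columns=upper)
    ds = CohortDataset(df)
    logger.info(
        "read %s: %d rows, %d subjects, %d observations",
        path.name,
        len(ds.frame),
        ds.n_subjects,
        ds.n_observations,
    )
    return ds


def write_dataset(dataset: CohortDataset, path) -> None:
    """Write a cohort back to CSV (comma, UTF-8, header row)."""
    df = dataset.frame
    ordered = [c for c in CORE_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in CORE_COLUMNS
    ]
    df[ordered].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# thresholds and configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdConfig:
    """Acceptability thresholds for external validation and assay QC.

    Defaults are the predefined acceptability criteria: MdPE within
    [-20, 20] %, MdAPE <= 30 %, F20 >= 35 %, F30 >= 50 %, concentration
    bands cut at 100 and 150 ng/mL; carryover blank signal < 20 % and
    selectivity interference < 2 % of the LLOQ signal; LLOQ accuracy within
    80-120 % with RSD < 20 % and S/N >= 10.
    """

    mdpe_low: float = -20.0
    mdpe_high: float = 20.0
    mdape_max: float = 30.0
    f20_min: float = 35.0
    f30_min: float = 50.0
    band_edges: tuple[float, float] = (100.0, 150.0)
    carryover_max_frac: float = 0.20
    selectivity_max_frac: float = 0.02
    lloq_accuracy_range: tuple[float, float] = (80.0, 120.0)
    lloq_rsd_max: float = 20.0
    lloq_snr_min: float = 10.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_edges"] = list(self.band_edges)
        d["lloq_accuracy_range"] = list(self.lloq_accuracy_range)
        return d


def load_config(path) -> dict:
    """Load a YAML/JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


_REQUIRED_UNITS = {
    "cl": "L/h",
    "v2": "L",
    "v3": "L",
    "v4": "L",
    "q3": "L/h",
    "q4": "L/h",
    "ka": "1/h",
    "f1": "fraction",
}


def load_parameters(path):
    """Load a PK parameter config; refuses to run when units are absent.

    Expected layout::

        parameters: {cl: 1.76, v2: 227.32, ...}
        units: {cl: L/h, v2: L, ...}
    """
    from .pk import PKParameters

    cfg = load_config(path)
    if "units" not in cfg:
        raise SchemaError(
            "parameter config must declare a 'units' block "
            f"(expected {_REQUIRED_UNITS})"
        )
    units = {k.lower(): str(v) for k, v in cfg["units"].items()}
    for name, unit in _REQUIRED_UNITS.items():
        if name not in units:
            raise SchemaError(f"unit for '{name}' missing (expected '{unit}')")
        if units[name].replace("h-1", "1/h") != unit:
            raise SchemaError(
                f"unit for '{name}' is '{units[name]}', expected '{unit}'"
            )
    pars = {k.lower(): float(v) for k, v in cfg["parameters"].items()}
    return PKParameters(**pars)


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------


def _flatten_report(report, thresholds: ThresholdConfig | None) -> dict:
    from .validation import ValidationReport  # local import avoids a cycle

    if not isinstance(report, ValidationReport):
        raise TypeError("write_report expects a ValidationReport")
    d = report.to_dict()
    if thresholds is not None:
        d["thresholds"] = thresholds.to_dict()
    return d


def write_report(report, path, format: str = "json", thresholds=None) -> None:
    """Serialize a :class:`~quizpk.validation.ValidationReport` to JSON or CSV.

    The file carries every metric, the gate verdicts and (when given) the
    threshold configuration they were judged against.  An unpopulated report
    is an error, never a silent empty file.
    """
    if report is None or getattr(report, "n_obs", 0) in (0, None):
        raise ValueError("refusing to serialize an empty/unpopulated report")
    d = _flatten_report(report, thresholds)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(d, indent=2, default=_json_default) + "\n")
    elif format == "csv":
        flat = _flatten_dict(d)
        pd.DataFrame(
            {"key": list(flat.keys()), "value": [_csv_value(v) for v in flat.values()]}
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format: {format!r}")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _flatten_dict(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten_dict(v, key + "."))
        else:
            out[key] = v
    return out


def _csv_value(v):
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, numbers.Real):
        return repr(float(v)) if isinstance(v, float) else v
    if isinstance(v, (list, tuple, np.ndarray)):
        return ";".join(str(x) for x in v)
    return v


def read_report(path) -> dict:
    """Read back a report written by :func:`write_report` (JSON or CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    df = pd.read_csv(path, keep_default_na=False)
    out: dict = {}
    for key, raw in zip(df["key"], df["value"]):
        parts = key.split(".")
        node = out
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = _parse_csv_value(str(raw))
    return out


def _parse_csv_value(raw: str):
    if raw == "":
        return None
    if raw in ("True", "False"):
        return raw == "True"
    try:
        f = float(raw)
        return int(f) if f.is_integer() and "." not in raw and "e" not in raw else f
    except ValueError:
        if ";" in raw:
            return [_parse_csv_value(x) for x in raw.split(";")]
        return raw
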