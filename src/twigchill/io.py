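"""CSV formats, run configuration and serialization.

Two plain-text interchange formats bind the pipeline together:

temperature CSV
    columns ``timestamp`` (ISO-8601), ``temp_c``, optional ``rh_pct``,
    optional ``location``; one row per 10-min sample, empty ``temp_c``
    marks a missing sample.

observation CSV
    columns ``twig_id, treatment, cutting_index, cutting_date, date, bbch,
    status, status_date``; one row per twig visit, empty ``bbch`` marks a
    missing observation (0 is a valid stage, winter dormancy).

Dates are ISO-8601 and timestamps naive local civil time (the experiment
window is DST-free).  Both read->write->read round-trips are identities.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import BBCH_STAGES, ExpFit, TemperatureSeries, TwigRecord, stage_ordinal

__all__ = [
    "read_temperature_csv",
    "write_temperature_csv",
    "read_observations_csv",
    "write_observations_csv",
    "read_daily_csv",
    "write_table_csv",
    "fit_to_json",
    "RunConfig",
]


def read_temperature_csv(path, location: Optional[str] = None) -> TemperatureSeries:
    """Parse a temperature log CSV into a sorted :class:`TemperatureSeries`.

    Rows may arrive shuffled; duplicate timestamps are rejected with the
    offending line number (1-based, header = line 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"timestamp", "temp_c"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp: {exc}") from exc
    dup = ts.duplicated(keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:5]]
        raise ValueError(f"{path}: duplicate timestamps at lines {lines}")
    loc = location
    if loc is None:
        loc = str(df["location"].iloc[0]) if "location" in df.columns and len(df) else "outdoor"
    cols = {"temp_c": pd.to_numeric(df["temp_c"], errors="raise").to_numpy()}
    if "rh_pct" in df.columns:
        cols["rh_pct"] = pd.to_numeric(df["rh_pct"], errors="raise").to_numpy()
    data = pd.DataFrame(cols, index=pd.DatetimeIndex(ts, name="timestamp")).sort_index()
    resolution = 10
    if len(data) > 1:
        steps = np.diff(data.index.view("int64"))
        resolution = int(np.min(steps) // 60_000_000_000)
    return TemperatureSeries(loc, data, resolution)


def write_temperature_csv(series: TemperatureSeries, path) -> None:
    df = series.data.reset_index()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df["location"] = series.location
    df.to_csv(path, index=False)


def read_observations_csv(path) -> list[TwigRecord]:
    """Parse a per-visit observation CSV into grouped twig records.

    Unknown BBCH codes or treatments are rejected; a decreasing BBCH
    sequence is kept but reported as a warning with the twig id.
    """
    df = pd.read_csv(path, dtype={"twig_id": str, "treatment": str, "status": str})
    required = {"twig_id", "treatment", "cutting_index", "cutting_date",
                "date", "bbch", "status", "status_date"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad_tr = set(df["treatment"].unique()) - {"S", "C"}
    if bad_tr:
        raise ValueError(f"{path}: unknown treatment(s) {sorted(bad_tr)}")
    bbch = df["bbch"]
    bad = bbch.dropna()[~bbch.dropna().astype(int).isin(BBCH_STAGES)]
    if len(bad):
        raise ValueError(
            f"{path}: invalid BBCH code(s) {sorted(set(bad.astype(int)))}; "
            f"valid codes: {BBCH_STAGES}"
        )
    records = []
    for twig_id, g in df.groupby("twig_id", sort=True):
        g = g.sort_values("date")
        obs = [
            (dt.date.fromisoformat(str(r.date)),
             None if pd.isna(r.bbch) else int(r.bbch))
            for r in g.itertuples()
        ]
        seq = [stage_ordinal(c) for _, c in obs if c is not None]
        monotone = all(b >= a for a, b in zip(seq, seq[1:]))
        if not monotone:
            warnings.warn(f"twig {twig_id}: decreasing BBCH sequence; kept as recorded")
            # retain as recorded: repair ordering only for the record invariant
            fixed, last = [], None
            for d, c in obs:
                if c is not None:
                    last = c if last is None or stage_ordinal(c) >= stage_ordinal(last) else last
                    fixed.append((d, last))
                else:
                    fixed.append((d, c))
            obs = fixed
        first = g.iloc[0]
        records.append(
            TwigRecord(
                twig_id=str(twig_id),
                treatment=str(first["treatment"]),
                cutting_index=int(first["cutting_index"]),
                cutting_date=dt.date.fromisoformat(str(first["cutting_date"])),
                observations=obs,
                status=str(first["status"]),
                status_date=dt.date.fromisoformat(str(first["status_date"])),
            )
        )
    return records


def write_observations_csv(records: Sequence[TwigRecord], path) -> None:
    rows = []
    for r in records:
        for d, c in r.observations:
            rows.append(
                {"twig_id": r.twig_id, "treatment": r.treatment,
                 "cutting_index": r.cutting_index,
                 "cutting_date": r.cutting_date.isoformat(),
                 "date": d.isoformat(),
                 "bbch": "" if c is None else c,
                 "status": r.status, "status_date": r.status_date.isoformat()}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_daily_csv(path) -> pd.DataFrame:
    """Read a base-year daily mean temperature CSV (columns date, tmean)."""
    df = pd.read_csv(path)
    if not {"date", "tmean"} <= set(df.columns):
        raise ValueError(f"{path}: need columns 'date' and 'tmean'")
    idx = [dt.date.fromisoformat(str(d)) for d in df["date"]]
    out = pd.DataFrame({"tmean": pd.to_numeric(df["tmean"]).to_numpy()},
                       index=pd.Index(idx, name="date"))
    return out.sort_index()


def write_table_csv(table: pd.DataFrame, path, definitions=("subdaily", "dailymean", "calendar")) -> None:
    """Serialize the analysis table tidily: one row per twig x endpoint x
    definition with paired chilling/forcing values."""
    tidy = []
    for _, row in table.iterrows():
        for d in definitions:
            tidy.append(
                {"twig_id": row["twig_id"], "treatment": row["treatment"],
                 "cutting_index": row["cutting_index"], "endpoint": row["endpoint"],
                 "definition": d, "chilling": row[f"chill_{d}"],
                 "forcing": row[f"force_{d}"], "excluded": row["excluded"]}
            )
    pd.DataFrame(tidy).to_csv(path, index=False)


def fit_to_json(fit: ExpFit, config: Optional[dict] = None, **extra) -> str:
    """JSON report of a fit: parameters, covariance, n, and config used."""
    payload = {
        "a": fit.a, "b": fit.b, "c": fit.c,
        "residual_sd": fit.residual_sd, "n_rows": fit.n_rows,
        "converged": fit.converged, "message": fit.message,
        "covariance": None if fit.covariance is None else fit.covariance.tolist(),
        "config": config or {},
        **extra,
    }
    return json.dumps(payload, indent=2, default=str)


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults reproduce the study setup."""

    seed: int = 0
    n_s: int = 10
    n_c: int = 5
    threshold: float = 5.0
    definitions: tuple[str, ...] = ("subdaily", "dailymean", "calendar")
    endpoints: tuple[str, ...] = ("dead", "bbch7", "bbch9", "bbch11", "leafout")
    # low-support filter
    filter_min_chill_days: float = 25.0
    filter_endpoints: tuple[str, ...] = ("bbch9", "bbch11")
    filter_min_rows: int = 3
    # exponential fit
    fit_grid_size: int = 40
    fit_grid_range: tuple[float, float] = (-1.0, -1e-4)
    fit_ftol: float = 1e-10
    fit_max_iter: int = 200
    exclude_outliers: bool = True
    # comparison
    alpha: float = 0.05
    adjustment: str = "holm"
    comparison_definition: str = "calendar"
    # design evaluation
    design_grid: tuple[tuple[int, int], ...] = (
        (2, 1), (2, 2), (3, 1), (3, 2), (3, 3), (4, 1), (4, 2), (4, 3))
    n_keep_range: tuple[int, ...] = tuple(range(2, 10))
    reps: int = 1000
    # scenario
    cd_threshold: float = 5.0
    gdd_threshold: float = 5.0
    dt_grid: tuple[tuple[float, float], ...] = tuple(
        (float(w), float(s)) for w in (-1, 0, 1, 2, 3, 4, 5) for s in (-1, 0, 1, 2, 3, 4, 5)
    )
    output_dir: str = "twigchill_out"

    def to_yaml(self) -> str:
        return yaml.safe_dump(_to_plain(dataclasses.asdict(self)), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = _from_plain(raw[f.name], getattr(cls(), f.name))
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        plain = _to_plain(dataclasses.asdict(self))
        plain.pop("output_dir", None)
        return hashlib.sha256(yaml.safe_dump(plain, sort_keys=True).encode()).hexdigest()[:12]


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(value, template):
    """Restore tuple-ness lost by YAML (lists come back as lists)."""
    if isinstance(template, tuple):
        return tuple(
            _from_plain(v, template[0] if template else v) for v in value
        )
    return value
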