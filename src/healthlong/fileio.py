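"""Readers and writers for mortality, prevalence, outcome and result files.

All inputs are delimited text (CSV, UTF-8, "." decimal) with a header row.
Mortality files carry columns ``age`` plus ``qx`` (death probability) or
``px`` (survival probability); the HMD period-life-table dialect is
accepted, including its open-age label (``110+``), which makes the last
class open-ended.  Prevalence files carry ``age, prevalence`` (one column
per outcome for polychotomous data); quantitative outcomes come either as
microdata (``age, value``) or pre-aggregated raw moments
(``age, m1, m2, m3``).  Statistics are written as CSV with ``#``-prefixed
metadata lines recording the reward mode and death credit, so every output
is self-describing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chain import MortalitySchedule
from .daly import SeveritySchedule
from .moments import HealthStatistics
from .rewards import OutcomeMomentSchedule, PrevalenceSchedule

__all__ = [
    "ParseError",
    "AnalysisConfig",
    "read_mortality",
    "read_prevalence",
    "read_severity",
    "write_statistics",
    "read_statistics",
    "truncate_schedule",
    "align_to_ages",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """An input file could not be interpreted."""


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, skipinitialspace=True, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _parse_ages(raw, path) -> tuple[np.ndarray, bool]:
    """Integer ages plus an open-ended flag from labels like '110+'."""
    ages = []
    open_ended = False
    n = len(raw)
    for row, label in enumerate(raw, start=2):  # header is line 1
        text = str(label).strip()
        plus = text.endswith("+")
        if plus:
            if row - 2 != n - 1:
                raise ParseError(
                    f"{path}: line {row}: open-age label '{text}' must be last"
                )
            open_ended = True
            text = text[:-1]
        try:
            ages.append(int(float(text)))
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {row}: cannot parse age '{label}'"
            ) from exc
    arr = np.asarray(ages)
    if np.any(np.diff(arr) <= 0):
        bad = int(np.flatnonzero(np.diff(arr) <= 0)[0]) + 3
        raise ParseError(f"{path}: line {bad}: ages must be strictly ascending")
    return arr, open_ended


def read_mortality(path, dialect: str = "plain") -> MortalitySchedule:
    """Read a mortality schedule from CSV.

    ``plain`` dialect: columns ``age`` and ``qx`` or ``px``.  ``hmd``
    dialect: an HMD-style period life table with columns ``Age`` and
    ``qx`` (extra columns ignored); the open-age row ``110+`` sets the
    open-ended flag.  Open-age labels are honored in both dialects.
    """
    if dialect not in ("plain", "hmd"):
        raise ValueError("dialect must be 'plain' or 'hmd'")
    df = _read_table(path)
    if "age" not in df.columns:
        raise ParseError(f"{path}: missing required column 'age'")
    ages, open_ended = _parse_ages(df["age"].tolist(), path)
    if "qx" in df.columns:
        q = pd.to_numeric(df["qx"], errors="coerce").to_numpy(float)
        p = 1.0 - q
        label = "qx"
    elif "px" in df.columns:
        p = pd.to_numeric(df["px"], errors="coerce").to_numpy(float)
        label = "px"
    else:
        raise ParseError(f"{path}: need a 'qx' or 'px' column")
    bad = np.flatnonzero(~np.isfinite(p) | (p < 0) | (p > 1))
    if bad.size:
        raise ParseError(
            f"{path}: line {int(bad[0]) + 2}: {label} outside [0, 1]"
        )
    if open_ended and p[-1] >= 1.0:
        raise ParseError(
            f"{path}: open-ended class must have survival < 1"
        )
    return MortalitySchedule(tuple(int(a) for a in ages), p, open_ended=open_ended)


def align_to_ages(df: pd.DataFrame, ages, path="<data>") -> pd.DataFrame:
    """Inner-join a table onto the mortality age grid, warning on mismatch."""
    ages = [int(a) for a in ages]
    df = df.copy()
    df["age"] = pd.to_numeric(df["age"], errors="coerce").astype("Int64")
    keep = df[df["age"].isin(ages)]
    missing = sorted(set(ages) - set(keep["age"].dropna().astype(int)))
    extra = sorted(set(df["age"].dropna().astype(int)) - set(ages))
    if missing or extra:
        warnings.warn(
            f"{path}: age grids differ from mortality schedule "
            f"(missing {missing[:5]}..., extra {extra[:5]}...); "
            "using the aligned subset",
            stacklevel=2,
        )
    if keep.empty:
        raise ParseError(f"{path}: no ages overlap the mortality schedule")
    return keep.sort_values("age")


def read_prevalence(path, ages=None):
    """Read a health-outcome file.

    Returns a :class:`PrevalenceSchedule` for a binary ``prevalence``
    column, or an :class:`OutcomeMomentSchedule` for microdata
    (``age, value``; per-age raw moments computed here) or pre-aggregated
    moments (``age, m1, m2, m3``).  If ``ages`` is given, rows are aligned
    to that grid (inner join with a warning on mismatches).
    """
    df = _read_table(path)
    if "age" not in df.columns:
        raise ParseError(f"{path}: missing required column 'age'")
    if "value" in df.columns:
        if ages is not None:
            df = align_to_ages(df, ages, path)
        groups = df.groupby("age", sort=True)["value"]
        counts = groups.count()
        if (counts < 1).any():
            empty = counts.index[counts < 1].tolist()
            raise ParseError(f"{path}: no observations in age class {empty}")
        samples = [g.to_numpy(float) for _, g in groups]
        if ages is not None and len(samples) != len(ages):
            raise ParseError(
                f"{path}: microdata covers {len(samples)} of {len(ages)} "
                "age classes; every class needs at least one observation"
            )
        return OutcomeMomentSchedule.from_samples(samples)
    if {"m1", "m2", "m3"} <= set(df.columns):
        if ages is not None:
            df = align_to_ages(df, ages, path)
        return OutcomeMomentSchedule(
            df["m1"].to_numpy(float),
            df["m2"].to_numpy(float),
            df["m3"].to_numpy(float),
        )
    if "prevalence" in df.columns:
        if ages is not None:
            df = align_to_ages(df, ages, path)
        v = pd.to_numeric(df["prevalence"], errors="coerce").to_numpy(float)
        bad = np.flatnonzero(~np.isfinite(v) | (v < 0) | (v > 1))
        if bad.size:
            raise ParseError(
                f"{path}: line {int(bad[0]) + 2}: prevalence outside [0, 1]"
            )
        return PrevalenceSchedule(v)
    raise ParseError(
        f"{path}: expected a 'prevalence', 'value', or 'm1,m2,m3' column set"
    )


def read_severity(path, ages=None) -> SeveritySchedule:
    """Read a disability-weight schedule (columns ``age, severity``)."""
    df = _read_table(path)
    if "age" not in df.columns or "severity" not in df.columns:
        raise ParseError(f"{path}: need columns 'age' and 'severity'")
    if ages is not None:
        df = align_to_ages(df, ages, path)
    return SeveritySchedule(df["severity"].to_numpy(float))


def truncate_schedule(schedule: MortalitySchedule, age: int) -> MortalitySchedule:
    """Truncate a schedule at ``age``: classes beyond it are dropped and the
    last retained class becomes certainly fatal (survival 0, not open-ended).

    This reproduces "statistics up to age X" reporting: lifetimes are cut
    at the truncation age, not conditioned on dying before it.
    """
    ages = np.asarray(schedule.ages)
    if age not in ages:
        raise ValueError(f"truncation age {age} not on the schedule grid")
    k = int(np.flatnonzero(ages == age)[0]) + 1
    p = schedule.survival[:k].copy()
    p[-1] = 0.0
    return MortalitySchedule(tuple(schedule.ages[:k]), p, open_ended=False)


def write_statistics(
    stats: HealthStatistics,
    path,
    ages=None,
    extra_columns: dict | None = None,
) -> None:
    """Write a statistics CSV with ``#`` metadata header lines.

    Missing CV/skewness values (NaN) are written as empty fields.  The
    reward mode and death credit recorded on the statistics object are
    always included in the metadata so the file is self-describing.
    """
    path = Path(path)
    if ages is None:
        ages = np.arange(stats.n_classes)
    data = {
        "age": list(ages),
        "mean": stats.mean,
        "variance": stats.variance,
        "sd": stats.sd,
        "cv": stats.cv,
        "skewness": stats.skewness,
    }
    for name, col in (extra_columns or {}).items():
        data[name] = col
    df = pd.DataFrame(data)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in stats.meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.12g", na_rep="")
    logger.info("wrote statistics for %d classes to %s", stats.n_classes, path)


def read_statistics(path) -> tuple[pd.DataFrame, dict]:
    """Read back a statistics CSV; returns (table, metadata dict)."""
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    return df, meta


@dataclass
class AnalysisConfig:
    """Paths and options for a full analysis run, loadable from YAML."""

    mortality: str
    prevalence: str | None = None
    severity: str | None = None
    standard: str | None = None
    cause_split: str | None = None
    mode: str = "paper_literal"
    death_credit: float = 0.5
    max_order: int = 3
    truncate_age: int | None = None
    start_ages: tuple = field(default_factory=tuple)
    seed: int = 0
    dialect: str = "plain"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("mortality", "prevalence", "severity", "standard", "cause_split"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise ParseError(f"{path}: {name} file '{p}' does not exist")
        return cfg
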