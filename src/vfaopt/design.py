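"""Experimental design, observation tables and VFA yield.

The study this package models fermented two municipal wastewater sludges
(primary, PS; anaerobically digested, DS) in batch reactors across a full
factorial of organic load, initial pH and temperature, measuring total
volatile fatty acids (VFA, as mg COD/L) on destructive triplicate samples
every three days.  Temperature and retention day are continuous covariates
of the downstream response-surface model; sludge type, load and pH define
the 12 discrete *treatments*.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass

import pandas as pd

from .errors import (
    DomainError,
    DuplicateKeyError,
    FieldParseError,
    MissingColumnError,
    ValidationError,
)

#: Admissible organic loads (g VS/L) per sludge type in the study design.
DESIGN_LOADS = {"DS": (4.0, 6.0), "PS": (10.0, 14.0)}
#: Initial pH levels of the study design (alkaline, to suppress methanogenesis).
DESIGN_PH = (9.5, 10.5, 11.5)
#: Incubation temperatures (°C).
DESIGN_TEMPERATURES = (25.0, 35.0, 45.0, 55.0)
#: Sampling every 3 days; 12-day horizon except 9 days at 55 °C where
#: methane production ended the experiment early.
MAX_DAY = 12.0
MAX_DAY_AT_55 = 9.0

OBSERVATION_COLUMNS = (
    "sludge_type",
    "organic_load",
    "initial_ph",
    "temperature",
    "day",
    "replicate",
    "vfa_mg_cod_per_l",
)

_KEY_COLUMNS = OBSERVATION_COLUMNS[:6]


def _fmt(x: float) -> str:
    """Compact numeric formatting for labels (14.0 -> '14', 10.5 -> '10.5')."""
    return f"{x:g}"


@dataclass(frozen=True, order=True)
class TreatmentKey:
    """A discrete treatment: sludge type, organic load (g VS/L), initial pH.

    Equality is exact on all three fields; ordering is lexicographic
    (sludge, load, pH) which fixes the deterministic order used throughout.
    """

    sludge_type: str
    organic_load: float
    initial_ph: float

    def __post_init__(self) -> None:
        if self.sludge_type not in DESIGN_LOADS:
            raise DomainError(
                f"sludge_type must be one of {sorted(DESIGN_LOADS)}, got {self.sludge_type!r}"
            )
        if not self.organic_load > 0:
            raise DomainError(f"organic_load must be positive, got {self.organic_load}")
        if not self.initial_ph > 0:
            raise DomainError(f"initial_ph must be positive, got {self.initial_ph}")

    @property
    def label(self) -> str:
        return f"{self.sludge_type}-{_fmt(self.organic_load)}-{_fmt(self.initial_ph)}"

    @classmethod
    def from_label(cls, label: str) -> "TreatmentKey":
        try:
            sludge, load, ph = label.split("-")
            return cls(sludge, float(load), float(ph))
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"cannot parse treatment label {label!r}") from exc


@dataclass(frozen=True, order=True)
class Combination:
    """A treatment at one incubation temperature (°C)."""

    treatment: TreatmentKey
    temperature: float


def enumerate_design() -> list[Combination]:
    """Full factorial of the study: 48 combinations, 12 distinct treatments.

    Order is deterministic: sludge type, organic load, pH, temperature, all
    ascending (DS before PS alphabetically).
    """
    combos = []
    for sludge in sorted(DESIGN_LOADS):
        for load in sorted(DESIGN_LOADS[sludge]):
            for ph in DESIGN_PH:
                for temp in DESIGN_TEMPERATURES:
                    combos.append(Combination(TreatmentKey(sludge, load, ph), temp))
    return combos


def group_treatments(combinations: list[Combination]) -> list[TreatmentKey]:
    """Collapse combinations to unique treatments, dropping temperature.

    Temperature is a continuous covariate of the regression model, not a
    treatment factor, so the 48 design combinations collapse to 12 keys.
    """
    if not combinations:
        raise ValidationError("group_treatments requires a non-empty collection")
    seen: dict[TreatmentKey, None] = {}
    for combo in combinations:
        seen.setdefault(combo.treatment, None)
    return sorted(seen)


def design_sampling_days(temperature: float, include_day0: bool = False) -> list[float]:
    """Sampling days for a study-design reactor at the given temperature.

    Destructive sampling every 3 days, to day 12 except day 9 at 55 °C.
    Whether day 0 was assayed is ambiguous in the source study, so it is
    optional (off by default).
    """
    last = MAX_DAY_AT_55 if temperature >= 55.0 else MAX_DAY
    days = [d for d in (0.0, 3.0, 6.0, 9.0, 12.0) if d <= last]
    return days if include_day0 else days[1:]


class ObservationTable:
    """Tidy replicate VFA measurements over (temperature, day) per treatment.

    Wraps a pandas DataFrame with the canonical seven columns and enforces
    the schema invariants on construction: no duplicate replicate keys, days
    within [0, 12], finite non-negative VFA, replicate indices >= 1.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "") -> None:
        missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
        if missing:
            raise MissingColumnError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(OBSERVATION_COLUMNS)].reset_index(drop=True)
        self._validate(df)
        self._df = df
        self.provenance = provenance

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        for i, row in enumerate(df.itertuples(index=False), start=1):
            if row.sludge_type not in DESIGN_LOADS:
                raise DomainError(f"row {i}: unknown sludge_type {row.sludge_type!r}")
            if not (0.0 <= row.day <= MAX_DAY):
                raise DomainError(f"row {i}: day {row.day} outside [0, {MAX_DAY}]")
            if not (math.isfinite(row.vfa_mg_cod_per_l) and row.vfa_mg_cod_per_l >= 0):
                raise DomainError(
                    f"row {i}: vfa_mg_cod_per_l must be finite and >= 0, "
                    f"got {row.vfa_mg_cod_per_l}"
                )
            if row.replicate < 1 or int(row.replicate) != row.replicate:
                raise DomainError(f"row {i}: replicate must be an integer >= 1")
        dup = df.duplicated(subset=list(_KEY_COLUMNS))
        if dup.any():
            first = int(dup.idxmax()) + 1
            raise DuplicateKeyError(
                f"row {first}: duplicate (treatment, temperature, day, replicate) key"
            )

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ObservationTable):
            return NotImplemented
        return self._df.equals(other._df)

    def treatments(self) -> list[TreatmentKey]:
        """Unique treatments present, in deterministic sorted order."""
        keys = {
            TreatmentKey(s, float(l), float(p))
            for s, l, p in self._df[["sludge_type", "organic_load", "initial_ph"]]
            .drop_duplicates()
            .itertuples(index=False)
        }
        return sorted(keys)

    def subset(self, treatment: TreatmentKey) -> pd.DataFrame:
        """Rows for one treatment (temperature, day, replicate, vfa)."""
        df = self._df
        mask = (
            (df["sludge_type"] == treatment.sludge_type)
            & (df["organic_load"] == treatment.organic_load)
            & (df["initial_ph"] == treatment.initial_ph)
        )
        return df.loc[mask].reset_index(drop=True)

    def write_csv(self, dest) -> None:
        # %.17g guarantees float round-trip through the text format
        self._df.to_csv(dest, index=False, float_format="%.17g")

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.write_csv(buf)
        return buf.getvalue()


def read_observations(source) -> ObservationTable:
    """Read an observation CSV into a validated :class:`ObservationTable`.

    ``source`` may be a path, an open text buffer, or CSV content itself
    (any string containing a newline).  Errors are distinct, named, and
    identify the offending CSV line (header is line 1).
    """
    provenance = ""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    elif isinstance(source, (str, os.PathLike)):
        provenance = str(source)
    raw = pd.read_csv(source, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in OBSERVATION_COLUMNS if c not in raw.columns]
    if missing:
        raise MissingColumnError(f"missing column(s): {', '.join(missing)}")
    parsed = raw.loc[:, list(OBSERVATION_COLUMNS)].copy()
    numeric = ("organic_load", "initial_ph", "temperature", "day", "vfa_mg_cod_per_l")
    for col in numeric + ("replicate",):
        values = []
        for pos, token in enumerate(parsed[col]):
            try:
                # Python's float() is round-trip exact, unlike the csv fast parser
                value = float(token)
                if math.isnan(value):
                    raise ValueError
            except (TypeError, ValueError):
                raise FieldParseError(
                    f"line {pos + 2}: cannot parse {col!r} value {token!r} as a number"
                ) from None
            values.append(value)
        if col == "replicate":
            bad = next((i for i, v in enumerate(values) if v != int(v)), None)
            if bad is not None:
                raise DomainError(f"line {bad + 2}: replicate must be an integer")
            parsed[col] = pd.array([int(v) for v in values], dtype="int64")
        else:
            parsed[col] = pd.array(values, dtype="float64")
    parsed["sludge_type"] = parsed["sludge_type"].str.strip()
    return ObservationTable(parsed, provenance=provenance)


def write_observations(table: ObservationTable, dest) -> None:
    """Write the canonical CSV dialect (UTF-8, dot decimal separator)."""
    table.write_csv(dest)


def write_design(combinations: list[Combination], dest) -> None:
    """Export combinations in the observation CSV dialect, sans replicate/vfa."""
    df = pd.DataFrame(
        [
            (c.treatment.sludge_type, c.treatment.organic_load, c.treatment.initial_ph, c.temperature)
            for c in combinations
        ],
        columns=list(OBSERVATION_COLUMNS[:4]),
    )
    df.to_csv(dest, index=False, float_format="%.17g")


def compute_yield(vfa_output_mg_cod_per_l: float, vs_fed_g_per_l: float) -> float:
    """VFA yield in g COD per g VS: (VFA output) / (VS fed).

    ``vfa_output`` is in mg COD/L and is converted to g COD/L before
    dividing by the organic load in g VS/L, so 7112 mg COD/L at 14 g VS/L
    gives 0.508 g COD/g VS.
    """
    if not vs_fed_g_per_l > 0:
        raise DomainError(f"vs_fed must be positive, got {vs_fed_g_per_l}")
    if vfa_output_mg_cod_per_l < 0:
        raise DomainError(f"vfa_output must be >= 0, got {vfa_output_mg_cod_per_l}")
    return (vfa_output_mg_cod_per_l / 1000.0) / vs_fed_g_per_l
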