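"""Domain types, units and CSV ingestion for paired EELV measurements.

One *measurement record* is a single animal x experimental-condition row:
ventilator settings (PEEP in cm H2O, tidal volume V_T in mL, respiratory
rate in breaths/min) together with end-expiratory lung volume read by both
methods — quantitative CT (``eelv_ct``, the reference) and the nitrogen
washin-washout technique (``eelv_wiwo``, the bedside method).  Either EELV
value may be missing; a record is only *paired* when both are present.

Units are fixed throughout the package: mL, cm H2O, kg.  Missing values in
CSV input are the empty cell or the string ``NA``; internally they are
represented as ``NaN`` (pandas) / ``None`` (record API), never as a
sentinel number.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from eelvkit.errors import DomainError, ParseError, SchemaError

#: Canonical CSV columns (comma-separated, UTF-8, one header row).
CANONICAL_COLUMNS = (
    "animal_id",
    "weight_kg",
    "stage",
    "order_index",
    "peep_cmH2O",
    "vt_mL",
    "rr_bpm",
    "eelv_ct_mL",
    "eelv_wiwo_mL",
)

#: Factor converting body weight to expected healthy supine EELV at zero
#: end-expiratory pressure (mL per kg), as established for anaesthetized pigs.
THEORETICAL_EELV_ML_PER_KG = 33.0


class Stage(str, enum.Enum):
    """Experimental stage within the single per-animal timeline."""

    ARDS_ONSET = "ards_onset"
    PEEP_TRIAL = "peep_trial"
    VT_LADDER = "vt_ladder"


@dataclass(frozen=True)
class MeasurementRecord:
    """One animal x condition row with ventilator settings and both EELV reads.

    ``eelv_ct`` / ``eelv_wiwo`` are ``None`` when the corresponding
    measurement failed or was not acquired.
    """

    animal_id: str
    weight: float          # kg
    stage: Stage
    order_index: int       # position in the animal's experimental timeline
    peep: float            # cm H2O
    vt: float              # mL
    rr: float              # breaths / min
    eelv_ct: float | None  # mL
    eelv_wiwo: float | None  # mL

    @property
    def is_paired(self) -> bool:
        return self.eelv_ct is not None and self.eelv_wiwo is not None


class StudyTable:
    """Validated collection of measurement records for a whole cohort.

    Wraps a long-format :class:`pandas.DataFrame` with the canonical
    columns.  Validation enforces:

    * ``peep`` in [0, 20], ``vt`` > 0, ``weight`` > 0;
    * EELV values, when present, are >= 0;
    * ``order_index`` strictly increasing within each animal;
    * each animal has exactly one ARDS-onset record (its per-animal
      baseline ``EELV_Base`` is that record's ``eelv_ct``).

    Rows with a missing EELV value are kept (flagged via ``is_paired``);
    rows violating invariants are rejected with row-level diagnostics.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate_frame(frame.copy())

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying long-format table (canonical columns)."""
        return self._frame

    @property
    def animals(self) -> list[str]:
        return list(dict.fromkeys(self._frame["animal_id"]))

    @property
    def n_records(self) -> int:
        return len(self._frame)

    @property
    def eelv_base(self) -> dict[str, float]:
        """Per-animal baseline EELV: the CT value at ARDS onset (PEEP 0)."""
        onset = self._frame[self._frame["stage"] == Stage.ARDS_ONSET.value]
        return dict(zip(onset["animal_id"], onset["eelv_ct_mL"]))

    @property
    def records(self) -> list[MeasurementRecord]:
        out = []
        for row in self._frame.itertuples(index=False):
            out.append(
                MeasurementRecord(
                    animal_id=str(row.animal_id),
                    weight=float(row.weight_kg),
                    stage=Stage(row.stage),
                    order_index=int(row.order_index),
                    peep=float(row.peep_cmH2O),
                    vt=float(row.vt_mL),
                    rr=float(row.rr_bpm),
                    eelv_ct=None if pd.isna(row.eelv_ct_mL) else float(row.eelv_ct_mL),
                    eelv_wiwo=None
                    if pd.isna(row.eelv_wiwo_mL)
                    else float(row.eelv_wiwo_mL),
                )
            )
        return out

    def with_bias(self) -> pd.DataFrame:
        """Paired rows augmented with per-animal baseline, mean and bias.

        Used by the bias model, which needs ``EELV_Base`` as a covariate.
        """
        series = paired_series(self)
        base = self.eelv_base
        frame = series.frame.copy()
        frame["eelv_base_mL"] = frame["animal_id"].map(base)
        return frame

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self._frame)

    def __repr__(self) -> str:
        return (
            f"StudyTable({self.n_records} records, {len(self.animals)} animals)"
        )


class PairedSeries:
    """Per-animal ordered rows where both methods are present.

    Adds the two Bland-Altman coordinates per row: the pairwise mean
    ``m = (eelv_ct + eelv_wiwo) / 2`` and the bias
    ``d = eelv_wiwo - eelv_ct`` (both mL).  An empty series is a valid
    (flagged) object, not an error.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def is_empty(self) -> bool:
        return len(self._frame) == 0

    @property
    def n_pairs(self) -> int:
        return len(self._frame)

    @property
    def n_animals(self) -> int:
        return self._frame["animal_id"].nunique()

    @property
    def m(self) -> np.ndarray:
        """Pairwise means, mL."""
        return self._frame["m_mL"].to_numpy(dtype=float)

    @property
    def d(self) -> np.ndarray:
        """Pairwise biases (WI-WO minus CT), mL."""
        return self._frame["d_mL"].to_numpy(dtype=float)

    @property
    def animal_ids(self) -> np.ndarray:
        return self._frame["animal_id"].to_numpy()

    def swapped(self) -> "PairedSeries":
        """Series with the roles of the two methods exchanged (d negated)."""
        frame = self._frame.copy()
        frame[["eelv_ct_mL", "eelv_wiwo_mL"]] = frame[
            ["eelv_wiwo_mL", "eelv_ct_mL"]
        ].to_numpy()
        frame["d_mL"] = -frame["d_mL"]
        return PairedSeries(frame)

    def __len__(self) -> int:
        return len(self._frame)

    def __repr__(self) -> str:
        return f"PairedSeries({self.n_pairs} pairs, {self.n_animals} animals)"


# ---------------------------------------------------------------------------
# operations


def read_measurements(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> StudyTable:
    """Read a paired-measurement CSV into a validated :class:`StudyTable`.

    Parameters
    ----------
    path
        CSV file with one header row.  Canonical column names are in
        :data:`CANONICAL_COLUMNS`; ``column_map`` maps canonical name ->
        actual header for files using different headers.
    column_map
        Optional renaming, e.g. ``{"eelv_ct_mL": "ct_volume"}``.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ParseError
        If a cell cannot be converted, naming row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"measurement file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing} in {path.name}; "
            f"found {list(raw.columns)}"
        )
    frame = pd.DataFrame({"animal_id": raw["animal_id"].astype(str)})
    frame["stage"] = raw["stage"].str.strip()
    for col in ("weight_kg", "order_index", "peep_cmH2O", "vt_mL", "rr_bpm"):
        frame[col] = _parse_numeric(raw[col], col, allow_missing=False)
    for col in ("eelv_ct_mL", "eelv_wiwo_mL"):
        frame[col] = _parse_numeric(raw[col], col, allow_missing=True)
    frame["order_index"] = frame["order_index"].astype(int)
    return StudyTable(frame[list(CANONICAL_COLUMNS)])


def paired_series(table: StudyTable) -> PairedSeries:
    """Extract rows with both methods present, in per-animal timeline order.

    Adds the Bland-Altman mean ``m`` and bias ``d`` per retained row.
    Single-method rows stay visible in the :class:`StudyTable` but are
    dropped here; the returned series may be empty.
    """
    frame = table.frame
    keep = frame["eelv_ct_mL"].notna() & frame["eelv_wiwo_mL"].notna()
    paired = frame.loc[
        keep,
        [
            "animal_id",
            "stage",
            "order_index",
            "peep_cmH2O",
            "vt_mL",
            "eelv_ct_mL",
            "eelv_wiwo_mL",
        ],
    ].copy()
    paired = paired.sort_values(
        ["animal_id", "order_index"], kind="stable"
    ).reset_index(drop=True)
    paired["m_mL"] = (paired["eelv_ct_mL"] + paired["eelv_wiwo_mL"]) / 2.0
    paired["d_mL"] = paired["eelv_wiwo_mL"] - paired["eelv_ct_mL"]
    return PairedSeries(paired)


def theoretical_eelv(weight: float) -> float:
    """Expected EELV (mL) at zero end-expiratory pressure for a healthy
    anaesthetized pig of the given body weight (kg): 33 mL/kg."""
    if not (weight > 0):
        raise DomainError(f"weight must be > 0 kg, got {weight}")
    return THEORETICAL_EELV_ML_PER_KG * weight


# ---------------------------------------------------------------------------
# validation helpers


def _parse_numeric(
    col: pd.Series, name: str, allow_missing: bool
) -> pd.Series:
    values = []
    for i, cell in enumerate(col):
        text = str(cell).strip()
        if text in ("", "NA", "NaN", "nan"):
            if allow_missing:
                values.append(math.nan)
                continue
            raise ParseError(f"row {i}: column {name!r} is missing but required")
        try:
            values.append(float(text))
        except ValueError as exc:
            raise ParseError(
                f"row {i}: column {name!r} has non-numeric value {text!r}"
            ) from exc
    return pd.Series(values, index=col.index, dtype=float)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"StudyTable frame missing column(s) {missing}")
    frame = frame[list(CANONICAL_COLUMNS)].reset_index(drop=True)

    problems: list[str] = []
    valid_stages = {s.value for s in Stage}
    bad_stage = ~frame["stage"].isin(valid_stages)
    for i in frame.index[bad_stage]:
        problems.append(f"row {i}: unknown stage {frame.at[i, 'stage']!r}")
    for i, (peep, vt, w) in enumerate(
        zip(frame["peep_cmH2O"], frame["vt_mL"], frame["weight_kg"])
    ):
        if not (0 <= peep <= 20):
            problems.append(f"row {i}: peep {peep} outside [0, 20] cm H2O")
        if not vt > 0:
            problems.append(f"row {i}: vt {vt} must be > 0 mL")
        if not w > 0:
            problems.append(f"row {i}: weight {w} must be > 0 kg")
    for col in ("eelv_ct_mL", "eelv_wiwo_mL"):
        neg = frame[col].notna() & (frame[col] < 0)
        for i in frame.index[neg]:
            problems.append(f"row {i}: {col} = {frame.at[i, col]} is negative")
    if problems:
        raise SchemaError(
            "invalid measurement rows:\n  " + "\n  ".join(problems)
        )

    for animal, grp in frame.groupby("animal_id", sort=False):
        order = grp["order_index"].to_numpy()
        if not np.all(np.diff(order) > 0):
            raise SchemaError(
                f"animal {animal!r}: order_index not strictly increasing "
                f"({order.tolist()})"
            )
        n_onset = int((grp["stage"] == Stage.ARDS_ONSET.value).sum())
        if n_onset != 1:
            raise SchemaError(
                f"animal {animal!r}: expected exactly one ards_onset record, "
                f"found {n_onset}"
            )
    return frame


def table_from_records(records: Iterable[MeasurementRecord]) -> StudyTable:
    """Build a :class:`StudyTable` from record objects (convenience)."""
    rows = [
        {
            "animal_id": r.animal_id,
            "weight_kg": r.weight,
            "stage": r.stage.value,
            "order_index": r.order_index,
            "peep_cmH2O": r.peep,
            "vt_mL": r.vt,
            "rr_bpm": r.rr,
            "eelv_ct_mL": math.nan if r.eelv_ct is None else r.eelv_ct,
            "eelv_wiwo_mL": math.nan if r.eelv_wiwo is None else r.eelv_wiwo,
        }
        for r in records
    ]
    return StudyTable(pd.DataFrame(rows))
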