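"""Domain types and CSV I/O for fortnightly pain panel data.

The measurement instrument is a single fortnightly question: "how many days
has your back bothered/troubled you over the past two weeks?", answered as an
integer day-count between 0 and 14. A study consists of a fixed number of
waves (fortnights; 26 over one year) per participant; any wave may be
missing.

Two CSV dialects are supported:

* wide  — header ``participant_id,f1,...,fW``; one row per participant.
* long  — header ``participant_id,wave,days``; one row per (participant, wave).

Missing responses are encoded as an empty field (``NA`` also accepted on
read). Baseline covariates (sex, employment, education, prior-year LBP
category) live in a separate table with closed category sets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DAY_MIN",
    "DAY_MAX",
    "DEFAULT_WAVES",
    "MISSING_TOKENS",
    "PanelValidationError",
    "ParticipantSeries",
    "PanelStudy",
    "BaselineTable",
    "SEX_CATEGORIES",
    "EMPLOYMENT_CATEGORIES",
    "EDUCATION_CATEGORIES",
    "PRIOR_YEAR_LBP_CATEGORIES",
    "read_panel",
    "write_panel",
    "read_baseline",
    "write_baseline",
]

DAY_MIN = 0
DAY_MAX = 14
DEFAULT_WAVES = 26

#: tokens understood as a missing response on read; written back as ""
MISSING_TOKENS = frozenset({"", "NA"})

SEX_CATEGORIES = ("Male", "Female")
EMPLOYMENT_CATEGORIES = (
    "Self employed",
    "Assisting spouse",
    "Employed",
    "Unemployed",
    "Pensioners",
    "Others outside labour force",
)
EDUCATION_CATEGORIES = (
    "Basic school",
    "General upper-secondary education",
    "Vocational education and training",
    "Short-cycle higher education",
    "Medium-cycle higher education",
    "Long-cycle higher education",
)
PRIOR_YEAR_LBP_CATEGORIES = ("0 days", "1-30 days", ">30 days")

_BASELINE_COLUMNS = ("participant_id", "sex", "employment", "education", "prior_year_lbp")
_BASELINE_CATEGORY_SETS = {
    "sex": SEX_CATEGORIES,
    "employment": EMPLOYMENT_CATEGORIES,
    "education": EDUCATION_CATEGORIES,
    "prior_year_lbp": PRIOR_YEAR_LBP_CATEGORIES,
}


class PanelValidationError(ValueError):
    """Raised when panel or baseline data violate the domain contracts."""


def _parse_day_count(token: str, *, where: str) -> Optional[int]:
    token = token.strip()
    if token in MISSING_TOKENS:
        return None
    try:
        value = int(token)
    except ValueError:
        raise PanelValidationError(
            f"{where}: value {token!r} is not an integer day-count "
            f"(expected {DAY_MIN}-{DAY_MAX} or missing)"
        ) from None
    if not DAY_MIN <= value <= DAY_MAX:
        raise PanelValidationError(
            f"{where}: day-count {value} outside the {DAY_MIN}-{DAY_MAX} fortnight scale"
        )
    return value


@dataclass(frozen=True)
class ParticipantSeries:
    """One participant's ordered fortnightly responses.

    ``responses`` has one entry per wave: an ``int`` in ``[0, 14]`` (days with
    low back pain in that fortnight) or ``None`` for a missing response.
    """

    participant_id: str
    responses: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise PanelValidationError("participant_id must be non-empty")
        object.__setattr__(self, "responses", tuple(self.responses))
        for i, v in enumerate(self.responses, start=1):
            if v is None:
                continue
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise PanelValidationError(
                    f"participant {self.participant_id}, wave {i}: "
                    f"value {v!r} is not an integer day-count"
                )
            if not DAY_MIN <= v <= DAY_MAX:
                raise PanelValidationError(
                    f"participant {self.participant_id}, wave {i}: "
                    f"day-count {v} outside the {DAY_MIN}-{DAY_MAX} fortnight scale"
                )

    @property
    def n_waves(self) -> int:
        return len(self.responses)

    @property
    def n_answered(self) -> int:
        return sum(v is not None for v in self.responses)

    @property
    def n_missing(self) -> int:
        return self.n_waves - self.n_answered

    def answered_values(self) -> list[int]:
        return [v for v in self.responses if v is not None]

    def is_complete(self) -> bool:
        return self.n_missing == 0


@dataclass(frozen=True)
class PanelStudy:
    """A collection of participant series plus enrolment bookkeeping.

    ``invited_count`` counts everyone asked to join; ``declined_ids`` those
    who never enrolled (and hence have no series). Every series must have
    exactly ``waves`` responses and a unique participant id.
    """

    series: tuple[ParticipantSeries, ...]
    waves: int = DEFAULT_WAVES
    invited_count: int = -1  # -1: default to len(series) in __post_init__
    declined_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))
        object.__setattr__(self, "declined_ids", frozenset(self.declined_ids))
        if self.invited_count < 0:
            object.__setattr__(self, "invited_count", len(self.series))
        if self.waves < 1:
            raise PanelValidationError(f"waves must be >= 1, got {self.waves}")
        seen: set[str] = set()
        for s in self.series:
            if s.n_waves != self.waves:
                raise PanelValidationError(
                    f"participant {s.participant_id}: {s.n_waves} responses, "
                    f"expected {self.waves} waves"
                )
            if s.participant_id in seen:
                raise PanelValidationError(
                    f"duplicate participant_id {s.participant_id!r}"
                )
            seen.add(s.participant_id)
        overlap = seen & self.declined_ids
        if overlap:
            raise PanelValidationError(
                f"declined_ids overlap with enrolled series: {sorted(overlap)}"
            )
        if self.invited_count < len(self.declined_ids) + len(self.series):
            raise PanelValidationError(
                f"invited_count {self.invited_count} < declined "
                f"({len(self.declined_ids)}) + enrolled ({len(self.series)})"
            )

    def __len__(self) -> int:
        return len(self.series)

    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.series]

    def get(self, participant_id: str) -> ParticipantSeries:
        for s in self.series:
            if s.participant_id == participant_id:
                return s
        raise KeyError(participant_id)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: index participant_id, columns f1..fW, NaN = missing."""
        cols = [f"f{w}" for w in range(1, self.waves + 1)]
        data = [
            [np.nan if v is None else float(v) for v in s.responses]
            for s in self.series
        ]
        return pd.DataFrame(
            data,
            index=pd.Index(self.participant_ids(), name="participant_id"),
            columns=cols,
            dtype=float,
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        *,
        invited_count: int = -1,
        declined_ids: Iterable[str] = (),
    ) -> "PanelStudy":
        """Inverse of :meth:`to_frame`; NaN cells become missing responses."""
        series = []
        for pid, row in frame.iterrows():
            responses = tuple(
                None if pd.isna(v) else int(v) for v in row.to_numpy()
            )
            series.append(ParticipantSeries(str(pid), responses))
        return cls(
            series=tuple(series),
            waves=frame.shape[1],
            invited_count=invited_count,
            declined_ids=frozenset(declined_ids),
        )

    def with_series(self, series: Sequence[ParticipantSeries]) -> "PanelStudy":
        return replace(self, series=tuple(series))


@dataclass
class BaselineTable:
    """Baseline covariates: one row per participant.

    Columns: sex, employment, education, prior_year_lbp, each restricted to
    the closed category sets declared at module level. ``responder_flag`` is
    assigned by the pipeline (True for participants retained in analysis).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in _BASELINE_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise PanelValidationError(f"baseline table missing columns: {missing_cols}")
        if self.data["participant_id"].duplicated().any():
            dupes = self.data.loc[
                self.data["participant_id"].duplicated(), "participant_id"
            ].tolist()
            raise PanelValidationError(f"duplicate participant_id in baseline: {dupes}")
        for col, categories in _BASELINE_CATEGORY_SETS.items():
            values = self.data[col]
            bad = values[values.notna() & ~values.isin(categories)]
            if len(bad):
                row = int(bad.index[0])
                raise PanelValidationError(
                    f"baseline row {row}, column {col!r}: unknown category "
                    f"{bad.iloc[0]!r} (allowed: {list(categories)})"
                )
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def assign_responders(self, responder_ids: Iterable[str]) -> "BaselineTable":
        """Return a copy with ``responder_flag`` set from the analysed id set."""
        ids = set(responder_ids)
        out = self.data.copy()
        out["responder_flag"] = out["participant_id"].isin(ids)
        return BaselineTable(out)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_rows(path: Path) -> list[list[str]]:
    with open(path, newline="") as fh:
        return [row for row in csv.reader(fh)]


def read_panel(
    path: str | Path,
    dialect: str = "wide",
    *,
    waves: Optional[int] = None,
    invited_count: int = -1,
    declined_ids: Iterable[str] = (),
) -> PanelStudy:
    """Read a fortnightly panel CSV into a validated :class:`PanelStudy`.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    dialect : {"wide", "long"}
        ``wide`` expects ``participant_id,f1,...,fW`` (W inferred from the
        header); ``long`` expects ``participant_id,wave,days`` with ``waves``
        fixing W (default 26).
    waves : int, optional
        Number of waves for the long dialect; ignored for wide.

    Raises
    ------
    PanelValidationError
        On malformed values (out of the 0-14 range, non-integer), duplicate
        participant ids, or wave indices outside ``1..W``.
    """
    path = Path(path)
    rows = _read_rows(path)
    if not rows:
        raise PanelValidationError(f"{path}: empty file, header expected")
    header, body = rows[0], rows[1:]

    if dialect == "wide":
        if not header or header[0] != "participant_id":
            raise PanelValidationError(
                f"{path}: wide header must start with 'participant_id', got {header[:1]}"
            )
        n_waves = len(header) - 1
        if n_waves < 1:
            raise PanelValidationError(f"{path}: wide header declares no wave columns")
        series = []
        for lineno, row in enumerate(body, start=2):
            if not row or (len(row) == 1 and row[0] == ""):
                continue
            if len(row) != n_waves + 1:
                raise PanelValidationError(
                    f"{path} line {lineno}: expected {n_waves + 1} fields, got {len(row)}"
                )
            pid = row[0].strip()
            responses = tuple(
                _parse_day_count(tok, where=f"{path} line {lineno} (participant {pid!r}, wave {w})")
                for w, tok in enumerate(row[1:], start=1)
            )
            series.append(ParticipantSeries(pid, responses))
        return PanelStudy(
            series=tuple(series),
            waves=n_waves,
            invited_count=invited_count,
            declined_ids=frozenset(declined_ids),
        )

    if dialect == "long":
        if header[:3] != ["participant_id", "wave", "days"]:
            raise PanelValidationError(
                f"{path}: long header must be participant_id,wave,days, got {header}"
            )
        n_waves = waves if waves is not None else DEFAULT_WAVES
        cells: dict[str, dict[int, Optional[int]]] = {}
        order: list[str] = []
        for lineno, row in enumerate(body, start=2):
            if not row or (len(row) == 1 and row[0] == ""):
                continue
            if len(row) != 3:
                raise PanelValidationError(
                    f"{path} line {lineno}: expected 3 fields, got {len(row)}"
                )
            pid = row[0].strip()
            try:
                wave = int(row[1])
            except ValueError:
                raise PanelValidationError(
                    f"{path} line {lineno}: wave {row[1]!r} is not an integer"
                ) from None
            if not 1 <= wave <= n_waves:
                raise PanelValidationError(
                    f"{path} line {lineno}: wave {wave} outside 1..{n_waves}"
                )
            value = _parse_day_count(
                row[2], where=f"{path} line {lineno} (participant {pid!r}, wave {wave})"
            )
            if pid not in cells:
                cells[pid] = {}
                order.append(pid)
            if wave in cells[pid]:
                raise PanelValidationError(
                    f"{path} line {lineno}: duplicate (participant {pid!r}, wave {wave})"
                )
            cells[pid][wave] = value
        series = [
            ParticipantSeries(
                pid, tuple(cells[pid].get(w) for w in range(1, n_waves + 1))
            )
            for pid in order
        ]
        return PanelStudy(
            series=tuple(series),
            waves=n_waves,
            invited_count=invited_count,
            declined_ids=frozenset(declined_ids),
        )

    raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def write_panel(study: PanelStudy, path: str | Path, dialect: str = "wide") -> None:
    """Write a :class:`PanelStudy` as CSV; missing responses become empty fields."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "wide":
            writer.writerow(["participant_id"] + [f"f{w}" for w in range(1, study.waves + 1)])
            for s in study.series:
                writer.writerow(
                    [s.participant_id] + ["" if v is None else str(v) for v in s.responses]
                )
        elif dialect == "long":
            writer.writerow(["participant_id", "wave", "days"])
            for s in study.series:
                for w, v in enumerate(s.responses, start=1):
                    writer.writerow([s.participant_id, w, "" if v is None else str(v)])
        else:
            raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def read_baseline(path: str | Path) -> BaselineTable:
    """Read a baseline covariate CSV, validating closed category sets."""
    path = Path(path)
    rows = _read_rows(path)
    if not rows:
        return BaselineTable(pd.DataFrame(columns=list(_BASELINE_COLUMNS)))
    header, body = rows[0], rows[1:]
    expected = list(_BASELINE_COLUMNS)
    if header[: len(expected)] != expected:
        raise PanelValidationError(
            f"{path}: baseline header must start with {expected}, got {header}"
        )
    records = []
    for lineno, row in enumerate(body, start=2):
        if not row or (len(row) == 1 and row[0] == ""):
            continue
        if len(row) < len(expected):
            raise PanelValidationError(
                f"{path} line {lineno}: expected >= {len(expected)} fields, got {len(row)}"
            )
        records.append(
            {col: (row[i].strip() or None) for i, col in enumerate(expected)}
        )
    frame = pd.DataFrame(records, columns=expected)
    return BaselineTable(frame)


def write_baseline(table: BaselineTable, path: str | Path) -> None:
    path = Path(path)
    table.data.loc[:, list(_BASELINE_COLUMNS)].to_csv(path, index=False)
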