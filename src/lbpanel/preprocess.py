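"""Analysis-set exclusion and manual mean imputation.

Two rules turn a raw panel into a complete analysis panel:

1. **Exclusion** — a participant is analysed only if they answered at least
   ``min_responses`` of the study waves (default 20 of 26). Below that, the
   individual reporting pattern is considered too sparse to interpret.
2. **Manual imputation** — each remaining missing fortnight is filled with
   the participant's own mean day-count over their answered fortnights,
   rounded half-up to an integer and clamped to the 0-14 scale. An imputed
   value of 0 counts as a pain-free fortnight downstream.

Both rules are available as scikit-learn transformers over a wide
participants x waves DataFrame (NaN = missing), and as functions over the
domain types. Exclusion runs before imputation, so values are only ever
imputed for analysed participants.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import round_half_up
from .panel import DAY_MAX, DAY_MIN, PanelStudy, ParticipantSeries

__all__ = [
    "DEFAULT_MIN_RESPONSES",
    "AnalysisPanel",
    "ResponseCountFilter",
    "ManualMeanImputer",
    "apply_exclusion",
    "impute_manual",
    "preprocess",
    "write_imputation_audit",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_RESPONSES = 20


@dataclass(frozen=True)
class AnalysisPanel:
    """A complete (no missing cells) panel ready for episode classification."""

    series: tuple[ParticipantSeries, ...]
    waves: int
    excluded_ids: tuple[str, ...]
    imputed_cells: tuple[tuple[str, int], ...]  # (participant_id, 1-indexed wave)
    invited_count: int
    declined_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for s in self.series:
            if not s.is_complete():
                raise ValueError(
                    f"AnalysisPanel requires complete series; participant "
                    f"{s.participant_id} still has missing cells"
                )
        overlap = set(self.excluded_ids) & {s.participant_id for s in self.series}
        if overlap:
            raise ValueError(f"excluded ids present in analysis set: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def n_cells_total(self) -> int:
        return len(self.series) * self.waves

    @property
    def n_imputed(self) -> int:
        return len(self.imputed_cells)

    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.series]

    def as_study(self) -> PanelStudy:
        """View the analysis set as a (complete) PanelStudy."""
        return PanelStudy(
            series=self.series,
            waves=self.waves,
            invited_count=self.invited_count,
            declined_ids=self.declined_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return self.as_study().to_frame().astype(int)


class ResponseCountFilter(BaseEstimator, TransformerMixin):
    """Drop participants with fewer than ``min_responses`` answered waves.

    Operates on a wide DataFrame (rows = participants, columns = waves,
    NaN = missing). Row filtering is a per-sample decision, so the ids
    dropped by the most recent :meth:`transform` are recorded on
    ``excluded_ids_``.
    """

    def __init__(self, min_responses: int = DEFAULT_MIN_RESPONSES):
        self.min_responses = min_responses

    def fit(self, X: pd.DataFrame, y=None) -> "ResponseCountFilter":
        X = self._validate(X)
        self.n_waves_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._validate(X)
        keep = X.notna().sum(axis=1) >= self.min_responses
        self.excluded_ids_ = [str(i) for i in X.index[~keep]]
        return X.loc[keep]

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        if self.min_responses > X.shape[1]:
            raise ValueError(
                f"min_responses ({self.min_responses}) exceeds the number of "
                f"waves ({X.shape[1]})"
            )
        if self.min_responses < 0:
            raise ValueError("min_responses must be non-negative")
        return X


class ManualMeanImputer(BaseEstimator, TransformerMixin):
    """Fill missing cells with the participant's own rounded mean day-count.

    Each NaN in a row becomes ``round_half_up(sum(answered) / n_answered)``,
    clamped to the 0-14 day scale; answered cells are never altered. Rows
    with no answered cells cannot be imputed and raise.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "ManualMeanImputer":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        self.n_waves_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        answered = X.notna()
        empty = answered.sum(axis=1) == 0
        if empty.any():
            raise ValueError(
                f"cannot impute participants with zero answered waves: "
                f"{[str(i) for i in X.index[empty]]}"
            )
        fill = (
            X.sum(axis=1, skipna=True) / answered.sum(axis=1)
        ).map(round_half_up).clip(DAY_MIN, DAY_MAX)
        out = X.copy()
        self.imputed_cells_ = []
        for pid in X.index[~answered.all(axis=1)]:
            row_missing = ~answered.loc[pid]
            out.loc[pid, row_missing] = float(fill.loc[pid])
            for w, col in enumerate(X.columns, start=1):
                if row_missing[col]:
                    self.imputed_cells_.append((str(pid), w))
        return out.astype(int)


def apply_exclusion(
    study: PanelStudy, min_responses: int = DEFAULT_MIN_RESPONSES
) -> tuple[PanelStudy, list[str]]:
    """Partition a study by the answered-wave threshold.

    Returns the retained study (same bookkeeping, filtered series) and the
    ids of excluded participants; every enrolled participant lands in
    exactly one of the two.
    """
    if min_responses > study.waves:
        raise ValueError(
            f"min_responses ({min_responses}) exceeds study waves ({study.waves})"
        )
    retained, excluded = [], []
    for s in study.series:
        (retained if s.n_answered >= min_responses else excluded).append(s)
    for s in excluded:
        logger.info(
            "excluding participant %s: %d of %d responses (< %d)",
            s.participant_id, s.n_answered, study.waves, min_responses,
        )
    return study.with_series(retained), [s.participant_id for s in excluded]


def impute_manual(series: ParticipantSeries) -> tuple[ParticipantSeries, list[int]]:
    """Complete one series by participant-mean imputation.

    Missing waves get ``round_half_up(total days / answered waves)`` clamped
    to [0, 14]. Returns the completed series and the 1-indexed waves filled.
    """
    answered = series.answered_values()
    if not answered:
        raise ValueError(
            f"participant {series.participant_id}: no answered waves, cannot impute"
        )
    value = min(DAY_MAX, max(DAY_MIN, round_half_up(sum(answered) / len(answered))))
    imputed_waves = [w for w, v in enumerate(series.responses, start=1) if v is None]
    completed = ParticipantSeries(
        series.participant_id,
        tuple(value if v is None else v for v in series.responses),
    )
    return completed, imputed_waves


def preprocess(
    study: PanelStudy, min_responses: int = DEFAULT_MIN_RESPONSES
) -> AnalysisPanel:
    """Exclusion then imputation: the full raw-panel -> analysis-panel step."""
    retained, excluded_ids = apply_exclusion(study, min_responses)
    completed = []
    imputed_cells: list[tuple[str, int]] = []
    for s in retained.series:
        filled, waves_filled = impute_manual(s)
        completed.append(filled)
        imputed_cells.extend((s.participant_id, w) for w in waves_filled)
    logger.info(
        "analysis set: %d participants, %d excluded, %d imputed cells",
        len(completed), len(excluded_ids), len(imputed_cells),
    )
    return AnalysisPanel(
        series=tuple(completed),
        waves=study.waves,
        excluded_ids=tuple(excluded_ids),
        imputed_cells=tuple(imputed_cells),
        invited_count=study.invited_count,
        declined_ids=study.declined_ids,
    )


def write_imputation_audit(panel: AnalysisPanel, path: str | Path) -> None:
    """Audit CSV of every imputed cell: participant_id, wave, imputed_value."""
    by_id = {s.participant_id: s for s in panel.series}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "wave", "imputed_value"])
        for pid, wave in panel.imputed_cells:
            writer.writerow([pid, wave, by_id[pid].responses[wave - 1]])
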