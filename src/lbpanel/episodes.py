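"""Run-length episode classification of complete fortnightly pain series.

Definitions (after de Vet et al.'s one-month criterion):

* **zero-fortnight** — a fortnight with a recorded day-count of exactly 0;
* **non-episode** — two consecutive zero-fortnights, i.e. one calendar month
  without low back pain;
* **separate non-episodes** — distinct *maximal* runs of >= 2 consecutive
  zero-fortnights, separated by at least one fortnight containing a pain
  day. A single long pain-free run counts as one non-episode however long
  it is.

The per-participant summary answers the study's three questions: did the
participant have at least one non-episode, were they inside one over the
final month of follow-up, and did they have at least two separate ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import ParticipantSeries
from .preprocess import AnalysisPanel

__all__ = [
    "EpisodeProfile",
    "EpisodeClassifier",
    "classify_participant",
    "cohort_profiles",
    "max_run_distribution",
    "profiles_to_frame",
]


@dataclass(frozen=True)
class EpisodeProfile:
    """Per-participant episode summary derived from the zero-fortnight mask.

    ``nonepisode_runs`` lists the maximal runs of consecutive zero-fortnights
    of length >= 2 as ``(start_wave, length)`` with 1-indexed start waves.
    """

    participant_id: str
    zero_mask: tuple[bool, ...]
    max_zero_run: int
    nonepisode_runs: tuple[tuple[int, int], ...]
    has_nonepisode: bool
    in_nonepisode_at_end: bool
    nonepisode_count: int
    pain_free_all_year: bool

    def __post_init__(self) -> None:
        assert self.has_nonepisode == (self.max_zero_run >= 2)
        assert self.has_nonepisode == (self.nonepisode_count >= 1)
        if self.in_nonepisode_at_end:
            assert self.has_nonepisode
        if self.pain_free_all_year and len(self.zero_mask) >= 2:
            assert self.nonepisode_count == 1
            assert self.max_zero_run == len(self.zero_mask)

    @property
    def n_waves(self) -> int:
        return len(self.zero_mask)


def _zero_runs(mask: Sequence[bool]) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (1-indexed start, length)."""
    runs = []
    pos = 1
    for is_zero, group in groupby(mask):
        length = sum(1 for _ in group)
        if is_zero:
            runs.append((pos, length))
        pos += length
    return runs


def classify_participant(series: ParticipantSeries) -> EpisodeProfile:
    """Classify one complete series (preprocess first if cells are missing)."""
    if not series.is_complete():
        raise ValueError(
            f"participant {series.participant_id} has missing cells; "
            "run preprocessing (exclusion + imputation) before classification"
        )
    mask = tuple(v == 0 for v in series.responses)
    runs = _zero_runs(mask)
    max_run = max((length for _, length in runs), default=0)
    nonepisode_runs = tuple((s, l) for s, l in runs if l >= 2)
    n_waves = len(mask)
    return EpisodeProfile(
        participant_id=series.participant_id,
        zero_mask=mask,
        max_zero_run=max_run,
        nonepisode_runs=nonepisode_runs,
        has_nonepisode=bool(nonepisode_runs),
        in_nonepisode_at_end=n_waves >= 2 and mask[-1] and mask[-2],
        nonepisode_count=len(nonepisode_runs),
        pain_free_all_year=all(mask),
    )


def cohort_profiles(panel: AnalysisPanel) -> list[EpisodeProfile]:
    """One profile per analysed participant, in panel order."""
    return [classify_participant(s) for s in panel.series]


def max_run_distribution(profiles: Iterable[EpisodeProfile]) -> dict[int, int]:
    """Histogram of max zero-run lengths over 0..W (every bin present)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot build a distribution from zero profiles")
    n_waves = profiles[0].n_waves
    counts = dict.fromkeys(range(n_waves + 1), 0)
    for p in profiles:
        counts[p.max_zero_run] += 1
    return counts


def profiles_to_frame(profiles: Iterable[EpisodeProfile]) -> pd.DataFrame:
    """Export profiles to the flat CSV-ready schema."""
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "max_zero_run": p.max_zero_run,
                "nonepisode_count": p.nonepisode_count,
                "has_nonepisode": p.has_nonepisode,
                "in_nonepisode_at_end": p.in_nonepisode_at_end,
                "pain_free_all_year": p.pain_free_all_year,
            }
            for p in profiles
        ],
        columns=[
            "participant_id",
            "max_zero_run",
            "nonepisode_count",
            "has_nonepisode",
            "in_nonepisode_at_end",
            "pain_free_all_year",
        ],
    )


class EpisodeClassifier(BaseEstimator, TransformerMixin):
    """Transform a complete wide panel into per-participant episode features.

    Input: DataFrame of integer day-counts (rows = participants, columns =
    waves, no NaN). Output: DataFrame indexed by participant with columns
    max_zero_run, nonepisode_count, has_nonepisode, in_nonepisode_at_end
    and pain_free_all_year. Composes with
    :class:`~lbpanel.preprocess.ResponseCountFilter` and
    :class:`~lbpanel.preprocess.ManualMeanImputer` in an sklearn Pipeline.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "EpisodeClassifier":
        self.n_waves_in_ = pd.DataFrame(X).shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError(
                "panel contains missing cells; run preprocessing "
                "(exclusion + imputation) before classification"
            )
        profiles = [
            classify_participant(
                ParticipantSeries(str(pid), tuple(int(v) for v in row))
            )
            for pid, row in zip(X.index, X.to_numpy())
        ]
        return profiles_to_frame(profiles).set_index("participant_id")
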