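"""Synthetic cohort generator for fortnightly pain panel studies.

Emulates the reporting structure of a one-year SMS panel: each enrolled
participant belongs to a fixed latent reporter class for the whole year —

* ``never_pain`` — reports 0 days at every answered fortnight;
* ``low_pain``   — alternates pain runs (small day-counts) and pain-free runs;
* ``high_pain``  — alternates pain runs (large day-counts) and pain-free runs.

Pain-class reporters start the year inside a pain run and flip between pain
and pain-free runs with a fixed per-wave switch probability, the minimal
mechanism that produces both episodes and month-long pain-free periods while
keeping within-person reporting highly consistent. Missingness is completely
at random for ordinary responders; a configurable number of "low response"
participants receive 7+ missing fortnights and thus fall under the
at-least-20-of-26 analysis threshold, and decliners contribute no series at
all.

Baseline covariates (sex, employment, education, prior-year LBP category)
are sampled independently from configurable marginals whose defaults mirror
the responder profile of a Danish general-population cohort aged 50.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .panel import (
    BaselineTable,
    DEFAULT_WAVES,
    PanelStudy,
    ParticipantSeries,
)

__all__ = [
    "REPORTER_CLASSES",
    "CohortConfig",
    "DEFAULT_BASELINE_MARGINALS",
    "generate_cohort",
    "generate_baseline",
    "write_truth",
    "read_truth",
]

REPORTER_CLASSES = ("never_pain", "low_pain", "high_pain")

#: Default covariate marginals (responder column of the study's baseline
#: description table, normalised).
DEFAULT_BASELINE_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"Male": 0.46, "Female": 0.54},
    "employment": {
        "Self employed": 0.07,
        "Assisting spouse": 0.00,
        "Employed": 0.87,
        "Unemployed": 0.03,
        "Pensioners": 0.01,
        "Others outside labour force": 0.02,
    },
    "education": {
        "Basic school": 0.19,
        "General upper-secondary education": 0.02,
        "Vocational education and training": 0.34,
        "Short-cycle higher education": 0.21,
        "Medium-cycle higher education": 0.19,
        "Long-cycle higher education": 0.05,
    },
    "prior_year_lbp": {"0 days": 0.33, "1-30 days": 0.46, ">30 days": 0.21},
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic panel study.

    Defaults reproduce the study conditions: 293 invited, 16 decliners,
    16 low-response participants (excluded by the >=20-of-26 rule), 26
    fortnightly waves, ~1.9% missing cells among ordinary responders, and a
    reporter-class mixture whose never_pain share matches the observed 19%
    of participants with a fully pain-free year.
    """

    n_invited: int = 293
    n_declined: int = 16
    n_low_response: int = 16
    class_probs: tuple[float, float, float] = (0.19, 0.51, 0.30)
    low_pain_day_range: tuple[int, int] = (1, 5)
    high_pain_day_range: tuple[int, int] = (6, 14)
    episode_switch_prob: float = 0.08
    cell_missing_prob: float = 0.019
    seed: int = 0
    waves: int = DEFAULT_WAVES

    def __post_init__(self) -> None:
        if self.n_invited < 0 or self.n_declined < 0 or self.n_low_response < 0:
            raise ValueError("counts must be non-negative")
        if self.n_declined + self.n_low_response > self.n_invited:
            raise ValueError(
                f"n_declined ({self.n_declined}) + n_low_response "
                f"({self.n_low_response}) exceeds n_invited ({self.n_invited})"
            )
        if len(self.class_probs) != 3:
            raise ValueError("class_probs must have 3 entries (never, low, high)")
        if any(not 0.0 <= p <= 1.0 for p in self.class_probs):
            raise ValueError("class_probs entries must lie in [0, 1]")
        if abs(sum(self.class_probs) - 1.0) > 1e-12:
            raise ValueError(f"class_probs must sum to 1, got {sum(self.class_probs)}")
        for name in ("episode_switch_prob", "cell_missing_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("low_pain_day_range", "high_pain_day_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= 14):
                raise ValueError(f"{name} must be an integer interval within [1, 14]")
        if self.waves < 1:
            raise ValueError("waves must be >= 1")
        if self.n_low_response and self.waves < 7:
            raise ValueError("low-response participants need waves >= 7")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("class_probs", "low_pain_day_range", "high_pain_day_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("class_probs", "low_pain_day_range", "high_pain_day_range"):
            d[key] = list(d[key])
        return d


def _simulate_series(
    reporter_class: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Day-counts for one participant before missingness, shape (waves,)."""
    W = config.waves
    if reporter_class == "never_pain":
        return np.zeros(W, dtype=int)
    lo, hi = (
        config.low_pain_day_range
        if reporter_class == "low_pain"
        else config.high_pain_day_range
    )
    # wave 1 starts inside a pain run; flips between runs are i.i.d. per wave
    flips = rng.random(W - 1) < config.episode_switch_prob
    in_pain = np.empty(W, dtype=bool)
    in_pain[0] = True
    if W > 1:
        # even number of flips so far => still in the starting (pain) state
        in_pain[1:] = np.cumsum(flips) % 2 == 0
    values = np.zeros(W, dtype=int)
    n_pain = int(in_pain.sum())
    values[in_pain] = rng.integers(lo, hi + 1, size=n_pain)
    return values


def generate_cohort(
    config: CohortConfig,
) -> tuple[PanelStudy, BaselineTable, pd.DataFrame]:
    """Generate a synthetic panel study.

    Returns
    -------
    study : PanelStudy
        Series for every enrolled participant (invited minus decliners),
        including the deliberately low-response ones.
    baseline : BaselineTable
        Covariates for every invited participant (decliners included, so a
        responder/non-responder comparison is possible).
    truth : DataFrame
        Columns ``participant_id``, ``class`` (generating reporter class;
        NA for decliners) and ``status`` in
        {declined, low_response, responder}.

    The output is a deterministic function of ``config`` (including its
    ``seed``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_invited
    width = max(3, len(str(n)))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]

    status = np.array(["responder"] * n, dtype=object)
    special = rng.choice(n, size=config.n_declined + config.n_low_response, replace=False)
    status[special[: config.n_declined]] = "declined"
    status[special[config.n_declined:]] = "low_response"

    enrolled = status != "declined"
    classes = np.full(n, None, dtype=object)
    classes[enrolled] = rng.choice(
        REPORTER_CLASSES, size=int(enrolled.sum()), p=list(config.class_probs)
    )

    series = []
    for i in range(n):
        if status[i] == "declined":
            continue
        values = _simulate_series(str(classes[i]), config, rng)
        if status[i] == "low_response":
            n_missing = int(rng.integers(7, config.waves + 1))
            missing_idx = rng.choice(config.waves, size=n_missing, replace=False)
            mask = np.zeros(config.waves, dtype=bool)
            mask[missing_idx] = True
        else:
            mask = rng.random(config.waves) < config.cell_missing_prob
        responses = tuple(
            None if mask[w] else int(values[w]) for w in range(config.waves)
        )
        series.append(ParticipantSeries(ids[i], responses))

    study = PanelStudy(
        series=tuple(series),
        waves=config.waves,
        invited_count=n,
        declined_ids=frozenset(ids[i] for i in range(n) if status[i] == "declined"),
    )
    truth = pd.DataFrame(
        {"participant_id": ids, "class": classes, "status": status}
    )
    baseline = generate_baseline(truth, seed=int(rng.integers(0, 2**31 - 1)))
    return study, baseline, truth


def generate_baseline(
    truth: pd.DataFrame,
    seed: int,
    marginals: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> BaselineTable:
    """Sample baseline covariates for every participant in ``truth``.

    Covariates are sampled independently per participant from categorical
    ``marginals`` (default: :data:`DEFAULT_BASELINE_MARGINALS`); each
    marginal must sum to 1. Deterministic given ``seed``.
    """
    if marginals is None:
        marginals = DEFAULT_BASELINE_MARGINALS
    rng = np.random.default_rng(seed)
    n = len(truth)
    out = {"participant_id": truth["participant_id"].to_numpy()}
    for col in ("sex", "employment", "education", "prior_year_lbp"):
        dist = marginals[col]
        labels = list(dist)
        probs = np.array([dist[k] for k in labels], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"marginal for {col!r} sums to {probs.sum()}, expected 1")
        out[col] = rng.choice(labels, size=n, p=probs)
    return BaselineTable(pd.DataFrame(out))


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False).replace({"": None})
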