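"""Prevalence estimation with Wald confidence intervals and study reporting.

Every cohort-level estimate is a binomial proportion reported as an integer
percentage with a 95% Wald (normal-approximation) interval,

    p +/- 1.96 * sqrt(p * (1 - p) / n),

computed on the exact proportion, clamped to [0, 1], and only then rounded
half-up to integer percent. This convention reproduces the printed brackets
of the study this pipeline re-implements (e.g. 83% -> 78-88 at n = 261).

Five classification predicates are supported:

* ``has_nonepisode``        — at least one month pain-free during the year;
* ``in_nonepisode_at_end``  — final two fortnights both pain-free;
* ``two_or_more_nonepisodes`` — at least two separate pain-free months;
* ``never_zero_fortnight``  — not a single pain-free fortnight (max run 0);
* ``pain_free_all_year``    — every fortnight pain-free.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from ._utils import percent_of, round_half_up
from .episodes import EpisodeProfile, cohort_profiles, max_run_distribution
from .panel import BaselineTable
from .preprocess import AnalysisPanel

__all__ = [
    "Z_95",
    "PREDICATES",
    "PrevalenceEstimate",
    "StudyReport",
    "wald_ci",
    "prevalence",
    "responder_comparison",
    "run_study_analysis",
]

#: normal quantile used for 95% intervals (conventional two-decimal value)
Z_95 = 1.96

PREDICATES: dict[str, Callable[[EpisodeProfile], bool]] = {
    "has_nonepisode": lambda p: p.has_nonepisode,
    "in_nonepisode_at_end": lambda p: p.in_nonepisode_at_end,
    "two_or_more_nonepisodes": lambda p: p.nonepisode_count >= 2,
    "never_zero_fortnight": lambda p: p.max_zero_run == 0,
    "pain_free_all_year": lambda p: p.pain_free_all_year,
}


def wald_ci(p: float, n: int, z: float = Z_95) -> tuple[float, float]:
    """95% Wald interval for a binomial proportion, clamped to [0, 1].

    Parameters
    ----------
    p : float
        Point proportion in [0, 1].
    n : int
        Number of trials; must be >= 1.

    Returns
    -------
    (low, high) : tuple of float
        ``p -/+ z * sqrt(p(1-p)/n)``, each clamped into [0, 1].
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    half_width = z * math.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half_width), min(1.0, p + half_width)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A proportion with its integer-percent point estimate and 95% CI."""

    label: str
    numerator: int
    denominator: int
    proportion: float
    percent: int
    ci_low_percent: int
    ci_high_percent: int

    def __post_init__(self) -> None:
        assert 0 <= self.numerator <= self.denominator
        assert 0 <= self.ci_low_percent <= self.percent <= self.ci_high_percent <= 100

    def __str__(self) -> str:
        return f"{self.label}: {self.percent}% ({self.ci_low_percent}-{self.ci_high_percent})"

    @classmethod
    def from_counts(cls, numerator: int, denominator: int, label: str = "") -> "PrevalenceEstimate":
        if denominator < 1:
            raise ValueError("denominator must be >= 1")
        if not 0 <= numerator <= denominator:
            raise ValueError(f"need 0 <= numerator <= denominator, got {numerator}/{denominator}")
        p = numerator / denominator
        low, high = wald_ci(p, denominator)
        return cls(
            label=label,
            numerator=numerator,
            denominator=denominator,
            proportion=p,
            percent=round_half_up(100.0 * p),
            ci_low_percent=round_half_up(100.0 * low),
            ci_high_percent=round_half_up(100.0 * high),
        )


def prevalence(
    profiles: Sequence[EpisodeProfile],
    predicate: Union[str, Callable[[EpisodeProfile], bool]],
) -> PrevalenceEstimate:
    """Cohort prevalence of a classification predicate with its 95% CI."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot estimate prevalence on an empty cohort")
    if isinstance(predicate, str):
        label = predicate
        try:
            fn = PREDICATES[predicate]
        except KeyError:
            raise ValueError(
                f"unknown predicate {predicate!r}; expected one of {sorted(PREDICATES)}"
            ) from None
    else:
        fn, label = predicate, getattr(predicate, "__name__", "custom")
    numerator = sum(bool(fn(p)) for p in profiles)
    return PrevalenceEstimate.from_counts(numerator, len(profiles), label=label)


def responder_comparison(baseline: BaselineTable) -> pd.DataFrame:
    """Column-percentage table of baseline covariates by responder status.

    Rows are (covariate, category) pairs; missing covariate values are
    tallied in an explicit ``unknown`` row. Percentages are integer,
    rounded half-up, within the responder and the non-responder column
    separately, so each covariate's rows sum to 100 up to rounding.
    """
    if "responder_flag" not in baseline.data.columns:
        raise ValueError("responder_flag not assigned; call assign_responders first")
    df = baseline.data
    groups = {
        "responders_pct": df[df["responder_flag"]],
        "nonresponders_pct": df[~df["responder_flag"]],
    }
    records = []
    for covariate in ("sex", "employment", "education", "prior_year_lbp"):
        categories = list(dict.fromkeys(df[covariate].dropna()))
        if df[covariate].isna().any():
            categories.append("unknown")
        for category in categories:
            row: dict[str, object] = {"covariate": covariate, "category": category}
            for col, sub in groups.items():
                n = len(sub)
                if category == "unknown":
                    k = int(sub[covariate].isna().sum())
                else:
                    k = int((sub[covariate] == category).sum())
                row[col] = percent_of(k, n) if n else 0
            records.append(row)
    return pd.DataFrame.from_records(
        records, columns=["covariate", "category", "responders_pct", "nonresponders_pct"]
    ).set_index(["covariate", "category"])


@dataclass
class StudyReport:
    """Full cohort-level result bundle, serialisable to JSON and text."""

    invited: int
    declined: int
    excluded: int
    analysed: int
    analysed_percent_of_invited: int
    n_cells_total: int
    n_imputed_cells: int
    imputed_percent: int
    n_participants_with_imputation: int
    estimates: dict[str, PrevalenceEstimate]
    max_run_histogram: dict[int, int]
    comparison: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {
            "flow": {
                "invited": self.invited,
                "declined": self.declined,
                "excluded": self.excluded,
                "analysed": self.analysed,
                "analysed_percent_of_invited": self.analysed_percent_of_invited,
            },
            "imputation": {
                "n_cells_total": self.n_cells_total,
                "n_imputed_cells": self.n_imputed_cells,
                "imputed_percent": self.imputed_percent,
                "n_participants_with_imputation": self.n_participants_with_imputation,
            },
            "estimates": {
                k: dataclasses.asdict(v) for k, v in self.estimates.items()
            },
            "max_run_histogram": {str(k): v for k, v in self.max_run_histogram.items()},
        }
        if self.comparison is not None:
            d["responder_comparison"] = [
                {
                    "covariate": cov,
                    "category": cat,
                    "responders_pct": int(row["responders_pct"]),
                    "nonresponders_pct": int(row["nonresponders_pct"]),
                }
                for (cov, cat), row in self.comparison.iterrows()
            ]
        return d

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [
            "Fortnightly low back pain panel — study report",
            "=" * 46,
            f"Invited: {self.invited}; declined: {self.declined}; "
            f"excluded (<min responses): {self.excluded}; "
            f"analysed: {self.analysed} ({self.analysed_percent_of_invited}% of invited)",
            f"Imputed cells: {self.n_imputed_cells}/{self.n_cells_total} "
            f"({self.imputed_percent}%) across "
            f"{self.n_participants_with_imputation} participants",
            "",
            "Prevalence estimates (95% Wald CI):",
        ]
        lines += [f"  {est}" for est in self.estimates.values()]
        lines += ["", "Max pain-free run distribution (fortnights: participants):"]
        lines += [
            f"  {k:>2}: {v}" for k, v in self.max_run_histogram.items() if v > 0
        ]
        if self.comparison is not None:
            lines += ["", "Responder vs non-responder baseline profile (%):"]
            lines += ["  " + line for line in self.comparison.to_string().splitlines()]
        return "\n".join(lines) + "\n"

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"max_zero_run": list(self.max_run_histogram),
             "count": list(self.max_run_histogram.values())}
        )


def run_study_analysis(
    panel: AnalysisPanel,
    baseline: Optional[BaselineTable] = None,
    *,
    profiles: Optional[Sequence[EpisodeProfile]] = None,
) -> StudyReport:
    """Compute the full study report from a preprocessed panel.

    All five prevalence estimates, the max-run histogram, the participant
    flow (invited / declined / excluded / analysed), the imputation summary,
    and — when a baseline table is supplied — the responder/non-responder
    comparison with responder_flag assigned from the analysed id set.
    """
    if panel.invited_count < 1:
        raise ValueError("cannot report a study with zero invited participants")
    if len(panel) == 0:
        raise ValueError("cannot report a study with an empty analysis set")
    if profiles is None:
        profiles = cohort_profiles(panel)
    estimates = {name: prevalence(profiles, name) for name in PREDICATES}
    comparison = None
    if baseline is not None:
        comparison = responder_comparison(
            baseline.assign_responders(panel.participant_ids())
        )
    return StudyReport(
        invited=panel.invited_count,
        declined=len(panel.declined_ids),
        excluded=len(panel.excluded_ids),
        analysed=len(panel),
        analysed_percent_of_invited=percent_of(len(panel), panel.invited_count),
        n_cells_total=panel.n_cells_total,
        n_imputed_cells=panel.n_imputed,
        imputed_percent=percent_of(panel.n_imputed, panel.n_cells_total),
        n_participants_with_imputation=len({pid for pid, _ in panel.imputed_cells}),
        estimates=estimates,
        max_run_histogram=max_run_distribution(profiles),
        comparison=comparison,
    )


def plot_max_run_distribution(histogram: Mapping[int, int], path: str | Path) -> None:
    """Bar chart of the max pain-free run histogram (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(list(histogram.keys()), list(histogram.values()), color="#4878a8")
    ax.set_xlabel("Maximum number of pain-free fortnights in a row")
    ax.set_ylabel("Participants")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
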