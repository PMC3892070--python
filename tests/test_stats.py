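"""Wald intervals, prevalence estimates, responder comparison, study report."""

from __future__ import annotations

import json
import math

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lbpanel._utils import percent_of, round_half_up
from lbpanel.episodes import classify_participant, cohort_profiles
from lbpanel.panel import BaselineTable, PanelStudy, ParticipantSeries
from lbpanel.preprocess import preprocess
from lbpanel.stats import (
    PrevalenceEstimate,
    prevalence,
    responder_comparison,
    run_study_analysis,
    wald_ci,
)


# --- rounding helpers -------------------------------------------------------

@pytest.mark.parametrize("x,expected", [(2.5, 3), (2.49, 2), (0.5, 1), (1.9009, 2)])
def test_round_half_up_convention(x, expected):
    assert round_half_up(x) == expected


def test_percent_of_flow_values():
    assert percent_of(261, 293) == 89
    assert percent_of(277, 412) == 67
    assert percent_of(277, 625) == 44
    assert percent_of(129, 6786) == 2


# --- Wald interval ----------------------------------------------------------

@pytest.mark.parametrize(
    "p,low,high",
    [
        (0.83, 78, 88),
        (0.59, 53, 65),
        (0.52, 46, 58),
        (0.19, 14, 24),
    ],
)
def test_wald_interval_reproduces_published_brackets(p, low, high):
    """Integer-rounded Wald bounds at n=261 match the printed 95% CIs."""
    lo, hi = wald_ci(p, 261)
    assert round_half_up(100 * lo) == low
    assert round_half_up(100 * hi) == high


def test_wald_degenerate_proportions():
    assert wald_ci(0.0, 100) == (0.0, 0.0)
    assert wald_ci(1.0, 100) == (1.0, 1.0)


@given(st.floats(0.01, 0.99), st.integers(2, 10_000))
def test_wald_symmetry_and_width(p, n):
    lo, hi = wald_ci(p, n)
    width = 2 * 1.96 * math.sqrt(p * (1 - p) / n)
    if lo > 0.0 and hi < 1.0:  # unclamped
        assert hi - lo == pytest.approx(width, rel=1e-12)
        assert (lo + hi) / 2 == pytest.approx(p, rel=1e-12)
    assert 0.0 <= lo <= p <= hi <= 1.0


@given(st.integers(0, 200), st.integers(1, 200))
def test_wald_matches_statsmodels_normal_interval(k, n):
    """Independent cross-check against statsmodels' normal-approximation CI."""
    from statsmodels.stats.proportion import proportion_confint

    k = min(k, n)
    lo, hi = wald_ci(k / n, n)
    ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="normal")
    # statsmodels uses z=1.95996..., we use the conventional 1.96
    assert lo == pytest.approx(ref_lo, abs=1e-4)
    assert hi == pytest.approx(ref_hi, abs=1e-4)


def test_wald_rejects_bad_inputs():
    with pytest.raises(ValueError):
        wald_ci(0.5, 0)
    with pytest.raises(ValueError):
        wald_ci(1.5, 10)


# --- prevalence -------------------------------------------------------------

def _cohort(n_true, n_false, waves=26):
    series = [ParticipantSeries(f"T{i}", (0,) * waves) for i in range(n_true)]
    series += [ParticipantSeries(f"F{i}", (5,) * waves) for i in range(n_false)]
    return [classify_participant(s) for s in series]


def test_prevalence_at_end_example():
    profiles = _cohort(154, 107)  # 154/261
    est = prevalence(profiles, "in_nonepisode_at_end")
    assert (est.numerator, est.denominator) == (154, 261)
    assert est.percent == 59
    assert (est.ci_low_percent, est.ci_high_percent) == (53, 65)


def test_prevalence_everyone_satisfies():
    est = prevalence(_cohort(10, 0), "has_nonepisode")
    assert est.percent == 100
    assert (est.ci_low_percent, est.ci_high_percent) == (100, 100)


def test_prevalence_tiny_cohort_is_clamped():
    est = prevalence(_cohort(1, 1), "pain_free_all_year")
    assert est.percent == 50
    assert 0 <= est.ci_low_percent <= 50 <= est.ci_high_percent <= 100


def test_prevalence_empty_cohort_rejected():
    with pytest.raises(ValueError):
        prevalence([], "has_nonepisode")


def test_prevalence_unknown_predicate_rejected():
    with pytest.raises(ValueError, match="unknown predicate"):
        prevalence(_cohort(1, 1), "sometimes_pain")


def test_prevalence_ordering_consistency(default_cohort):
    """P(any non-episode) dominates both the end-of-study and the >=2 rates."""
    _, (study, _, _) = default_cohort
    profiles = cohort_profiles(preprocess(study))
    p_any = prevalence(profiles, "has_nonepisode").proportion
    assert p_any >= prevalence(profiles, "in_nonepisode_at_end").proportion
    assert p_any >= prevalence(profiles, "two_or_more_nonepisodes").proportion


# --- responder comparison ---------------------------------------------------

def _baseline_frame(rows):
    return BaselineTable(
        pd.DataFrame(
            rows,
            columns=["participant_id", "sex", "employment", "education", "prior_year_lbp"],
        )
    )


def test_responder_comparison_column_percentages():
    rows = (
        [[f"R{i}", "Male", "Employed", "Basic school", "0 days"] for i in range(46)]
        + [[f"S{i}", "Female", "Employed", "Basic school", "0 days"] for i in range(54)]
        + [[f"N{i}", "Male", "Employed", "Basic school", "0 days"] for i in range(8)]
    )
    table = _baseline_frame(rows).assign_responders(
        [f"R{i}" for i in range(46)] + [f"S{i}" for i in range(54)]
    )
    cmp = responder_comparison(table)
    assert cmp.loc[("sex", "Male"), "responders_pct"] == 46
    assert cmp.loc[("sex", "Female"), "responders_pct"] == 54
    assert cmp.loc[("sex", "Male"), "nonresponders_pct"] == 100
    # each covariate's rows sum to 100 up to rounding units
    sums = cmp.groupby(level="covariate")["responders_pct"].sum()
    n_rows = cmp.groupby(level="covariate").size()
    assert ((sums - 100).abs() <= n_rows).all()


def test_responder_comparison_single_category_is_100():
    table = _baseline_frame(
        [["P1", "Male", "Employed", "Basic school", "0 days"],
         ["P2", "Male", "Employed", "Basic school", "0 days"]]
    ).assign_responders(["P1"])
    cmp = responder_comparison(table)
    assert cmp.loc[("employment", "Employed"), "responders_pct"] == 100


def test_responder_comparison_counts_missing_as_unknown():
    frame = pd.DataFrame(
        [["P1", "Male", "Employed", None, "0 days"],
         ["P2", "Female", "Employed", "Basic school", "0 days"]],
        columns=["participant_id", "sex", "employment", "education", "prior_year_lbp"],
    )
    table = BaselineTable(frame).assign_responders(["P1", "P2"])
    cmp = responder_comparison(table)
    assert cmp.loc[("education", "unknown"), "responders_pct"] == 50


def test_responder_comparison_requires_flag():
    with pytest.raises(ValueError, match="responder_flag"):
        responder_comparison(_baseline_frame([["P1", "Male", "Employed", "Basic school", "0 days"]]))


# --- study report -----------------------------------------------------------

def test_report_flow_and_serialisation(default_cohort, tmp_path):
    _, (study, baseline, _) = default_cohort
    panel = preprocess(study)
    report = run_study_analysis(panel, baseline)
    assert (report.invited, report.declined, report.excluded) == (293, 16, 16)
    assert report.analysed == 261
    assert report.analysed_percent_of_invited == 89
    assert report.n_cells_total == 6786
    assert sum(report.max_run_histogram.values()) == 261

    payload = json.loads(report.to_json(tmp_path / "r.json"))
    assert payload["flow"]["analysed"] == 261
    assert set(payload["estimates"]) == {
        "has_nonepisode", "in_nonepisode_at_end", "two_or_more_nonepisodes",
        "never_zero_fortnight", "pain_free_all_year",
    }
    text = report.to_text()
    assert "analysed: 261 (89% of invited)" in text


def test_report_requires_nonempty_analysis_set():
    panel = preprocess(PanelStudy(series=(ParticipantSeries("a", (0,) * 26),), waves=26))
    empty = panel.__class__(
        series=(), waves=26, excluded_ids=("a",), imputed_cells=(),
        invited_count=0,
    )
    with pytest.raises(ValueError):
        run_study_analysis(empty)


def test_estimate_invariants_enforced():
    with pytest.raises(ValueError):
        PrevalenceEstimate.from_counts(5, 4)
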