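"""Cohort filtering, normality gate and two-group statistics."""

import itertools

import numpy as np
import pytest

from lungdens import (CaseRecord, ParameterError, apply_inclusion_criteria,
                      assess_normality, compare_groups, subgroup_summary,
                      summarize_group, ttest_from_summary)
from lungdens.cohort import EXCLUDED_CONTROL_CAUSES


def make_record(case_id="X1", group="HA", age=48, pmi=2.0, **kw):
    return CaseRecord(case_id=case_id, group=group, age=age, pmi_days=pmi, **kw)


# ---------------------------------------------------------------------------
# inclusion / exclusion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs, reason", [
    (dict(pmi=6.0), "PMI > 5 days"),
    (dict(age=15), "age below 16"),
    (dict(age=81), "age above 80"),
    (dict(chest_trauma=True), "penetrating chest injury"),
    (dict(lung_disease=True), "prior or current lung disease"),
    (dict(putrefaction="severe"), "severe putrefaction"),
])
def test_exclusion_reasons(kwargs, reason):
    included, log = apply_inclusion_criteria([make_record(**kwargs)])
    assert included == []
    assert log == [("X1", reason)]


def test_control_specific_exclusions():
    for cause in EXCLUDED_CONTROL_CAUSES:
        rec = make_record(group="control", control_cause=cause)
        _, log = apply_inclusion_criteria([rec])
        assert cause in log[0][1]
    rec = make_record(group="control", hospitalized=True, control_cause="cardiac")
    _, log = apply_inclusion_criteria([rec])
    assert "hospitalization" in log[0][1]
    # hospitalization does not exclude asphyxia cases
    inc, _ = apply_inclusion_criteria([make_record(hospitalized=True)])
    assert len(inc) == 1


def test_first_matching_reason_wins():
    rec = make_record(pmi=7.0, age=90, chest_trauma=True)
    _, log = apply_inclusion_criteria([rec])
    assert log[0][1] == "PMI > 5 days"


def test_valid_case_included_and_filter_idempotent():
    recs = [make_record(case_id=f"C{i}", pmi=2.0, putrefaction="mild")
            for i in range(3)] + [make_record(case_id="bad", pmi=9.0)]
    once, log1 = apply_inclusion_criteria(recs)
    twice, log2 = apply_inclusion_criteria(once)
    assert [r.case_id for r in once] == [r.case_id for r in twice] == \
        ["C0", "C1", "C2"]
    assert log2 == []


def test_unknown_group_rejected():
    with pytest.raises(ParameterError):
        make_record(group="XX")


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def test_normality_on_gaussian_and_skewed_samples():
    rng = np.random.default_rng(42)
    gauss_hits = sum(assess_normality(rng.normal(0, 1, 50)) == "parametric"
                     for _ in range(100))
    skew_hits = sum(assess_normality(rng.lognormal(0, 1.5, 50)) == "nonparametric"
                    for _ in range(100))
    assert gauss_hits >= 90
    assert skew_hits >= 90


def test_normality_degenerate_inputs_default_nonparametric():
    assert assess_normality([1.0, 2.0]) == "nonparametric"       # n < 3
    assert assess_normality([5.0, 5.0, 5.0, 5.0]) == "nonparametric"  # constant


# ---------------------------------------------------------------------------
# rank-sum test vs full enumeration
# ---------------------------------------------------------------------------

def enumeration_wilcoxon_p(a, b):
    """Exact two-sided p by enumerating all group-label assignments."""
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * (n - n1)
    u_lo = min(u_obs, n1n2 - u_obs)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_lo or u >= n1n2 - u_lo:
            hits += 1
    return hits / total


def test_wilcoxon_exact_simple_example():
    res = compare_groups([1, 2, 3], [4, 5, 6], mode="wilcoxon")
    assert res.method == "wilcoxon" and res.variant == "exact"
    assert res.p_value == pytest.approx(0.1)   # 2 of C(6,3)=20 assignments


def test_wilcoxon_identical_groups():
    res = compare_groups([5, 7, 9], [5, 7, 9], mode="wilcoxon")
    assert res.p_value == pytest.approx(1.0)


@pytest.mark.parametrize("n1, n2", [(1, 3), (2, 2), (3, 4), (4, 4), (5, 6), (2, 8)])
def test_wilcoxon_matches_enumeration(n1, n2):
    rng = np.random.default_rng(n1 * 100 + n2)
    for _ in range(5):
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        a, b = pooled[:n1], pooled[n1:]
        res = compare_groups(a, b, mode="wilcoxon")
        assert res.p_value == pytest.approx(enumeration_wilcoxon_p(a, b))


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def test_summary_ttest_matches_printed_age_row():
    res = ttest_from_summary(48.1, 15.2, 20, 46.9, 12.4, 21, variant="pooled")
    assert res.p_value == pytest.approx(0.79, abs=0.02)


def test_summary_ttest_identical_groups():
    res = ttest_from_summary(10.0, 2.0, 12, 10.0, 2.0, 12)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_summary_ttest_welch_symmetric():
    res = ttest_from_summary(0, 1, 10, 0, 1, 10, variant="welch")
    assert res.statistic == 0.0
    assert res.df == pytest.approx(18.0)
    assert res.p_value == 1.0


def test_summary_ttest_preconditions():
    with pytest.raises(ParameterError):
        ttest_from_summary(1, 1, 1, 2, 1, 10)
    with pytest.raises(ParameterError):
        ttest_from_summary(1, 0, 10, 2, 0, 10)


def test_compare_groups_auto_picks_t_for_gaussian():
    rng = np.random.default_rng(8)
    res = compare_groups(rng.normal(0, 1, 40), rng.normal(0, 1, 40))
    assert res.method == "t_test"
    assert 0 <= res.p_value <= 1


def test_compare_groups_validation():
    with pytest.raises(ParameterError):
        compare_groups([], [1, 2, 3])
    with pytest.raises(ParameterError):
        compare_groups([1, 2], [1, 2, 3], mode="auto")   # auto needs n >= 3
    with pytest.raises(ParameterError):
        compare_groups([1], [1, 2, 3], mode="t_test")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summarize_group_conventions():
    np_sum = summarize_group([1, 2, 3, 4, 5], "nonparametric")
    assert (np_sum["median"], np_sum["q1"], np_sum["q3"]) == (3, 2, 4)
    p_sum = summarize_group([2, 2, 2], "parametric")
    assert (p_sum["mean"], p_sum["sd"]) == (2, 0)
    single = summarize_group([7.0], "parametric")
    assert single["mean"] == 7.0 and single["sd"] is None


def test_subgroup_summary_structure():
    recs = []
    from lungdens import DensitometryResult
    for i, (grp, perc) in enumerate([("CH", -600), ("CH", -610), ("CH", -590),
                                     ("LS", -800)]):
        dens = DensitometryResult(laa950=1.0, laa910=2.0, perc15=perc,
                                  pd15=perc + 1000, volume_ml=2500,
                                  n_voxels=2500000, mean_hu=-700)
        recs.append(make_record(case_id=f"S{i}", group=grp, densitometry=dens))
    table = subgroup_summary(recs)
    assert set(table["subgroup"]) == {"CH", "LS"}      # empty subtypes omitted
    ch = table[table["subgroup"] == "CH"].iloc[0]
    assert ch["n"] == 3 and ch["perc15_median"] == -600
    ls = table[table["subgroup"] == "LS"].iloc[0]
    assert ls["n"] == 1 and ls["perc15_q1"] == ls["perc15_q3"] == -800
    assert not any("p" == c or c.endswith("p_value") for c in table.columns)
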