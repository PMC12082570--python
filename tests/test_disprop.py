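import math

import numpy as np
import pytest
from scipy import stats

from _factories import make_case
from pvkit.disprop import (
    BCPNNPriors,
    ContingencyTable,
    OverlappingBinsError,
    Thresholds,
    adjust_pvalues,
    bcpnn_stat,
    build_table,
    ebgm_stat,
    evaluate_pair,
    make_strata,
    prr_stat,
    ror_stat,
    signal_decision,
    stratified_scan,
)
from pvkit.faers_ingest import SMQDefinition, flag_event_cases

T_REF = ContingencyTable(20, 80, 100, 9800)
T_INDEP = ContingencyTable(10, 90, 10, 90)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def _universe():
    smq_pt = "Pancreatitis acute"
    return [
        make_case(primary_id="1", case_id="1", drugs=[("X", "PS", None)], reactions=[smq_pt]),
        make_case(primary_id="2", case_id="2", drugs=[("X", "PS", None)], reactions=["Other"]),
        make_case(primary_id="3", case_id="3", drugs=[("Y", "PS", None)], reactions=[smq_pt]),
        make_case(primary_id="4", case_id="4", drugs=[("Y", "PS", None)], reactions=["Other"]),
    ]


def test_build_table_enumeration():
    reports = _universe()
    smq = SMQDefinition("ap", frozenset({"Pancreatitis acute"}))
    flags = flag_event_cases(reports, smq, "narrow")
    t = build_table(reports, "X", flags)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_build_table_empty_stratum_is_zero():
    reports = _universe()
    flags = {r.primary_id: True for r in reports}
    t = build_table(reports, "X", flags, stratum=lambda r: False)
    assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)
    assert t.N == 0


def test_build_table_a_matches_truth(planted_dataset, planted_reports, smq):
    flags = flag_event_cases(planted_reports, smq, "narrow")
    t = build_table(planted_reports, "DRUG_001", flags)
    tc = planted_dataset.truth_cases
    occur = planted_dataset.event_matrix
    target_col = planted_dataset.truth.event_names().index("Pancreatitis acute")
    truth_a = int(((tc["ps_drug"] == "DRUG_001") & occur[:, target_col]).sum())
    assert t.a == truth_a
    assert t.N == len(planted_reports)


def test_negative_cell_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 0)


# ---------------------------------------------------------------------------
# ROR
# ---------------------------------------------------------------------------

def test_ror_hand_value():
    r = ror_stat(T_REF)
    assert r.point == pytest.approx(24.5)  # 20*9800 / (80*100)
    assert r.ci95[0] < 24.5 < r.ci95[1]
    assert not r.zero_corrected


def test_ror_identical_rows_is_one():
    assert ror_stat(T_INDEP).point == pytest.approx(1.0)


def test_ror_row_swap_inverts():
    t = ContingencyTable(7, 13, 29, 51)
    swapped = ContingencyTable(29, 51, 7, 13)
    assert ror_stat(swapped).point == pytest.approx(1.0 / ror_stat(t).point)


def test_ror_zero_cell_corrected():
    r = ror_stat(ContingencyTable(0, 10, 10, 100))
    assert r.zero_corrected
    assert math.isfinite(r.point) and r.point > 0
    assert r.ci95[0] < r.point < r.ci95[1]


# ---------------------------------------------------------------------------
# PRR / chi-square
# ---------------------------------------------------------------------------

def test_prr_hand_value():
    r = prr_stat(T_REF)
    assert r.point == pytest.approx(19.8)  # (20/100)/(100/9900)
    assert r.ci95[0] < r.point < r.ci95[1]


def test_chi2_matches_pearson_oracle():
    expected = stats.chi2_contingency([[20, 80], [100, 9800]], correction=False)[0]
    assert prr_stat(T_REF).chi2 == pytest.approx(expected, rel=1e-12)
    assert prr_stat(T_REF).chi2 == pytest.approx(301.1, abs=0.1)


def test_prr_independence():
    r = prr_stat(T_INDEP)
    assert r.point == pytest.approx(1.0)
    assert r.chi2 == pytest.approx(0.0, abs=1e-12)


def test_chi2_zero_margin_degenerates_to_zero():
    assert prr_stat(ContingencyTable(0, 0, 5, 5)).chi2 == 0.0


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------

def test_bcpnn_independence_near_zero():
    r = bcpnn_stat(ContingencyTable(100, 900, 900, 8100))
    assert abs(r.ic) < 0.05
    assert r.ic025 < r.ic


def test_bcpnn_all_zero_table_is_finite():
    r = bcpnn_stat(ContingencyTable(0, 0, 0, 0))
    assert math.isfinite(r.ic)
    assert math.isfinite(r.ic025)
    assert r.ic == pytest.approx(0.0)  # priors only


def test_bcpnn_prior_influence_vanishes_with_scale():
    # ad = bc tables; |E(IC)| shrinks toward 0 as cells grow
    last = None
    for k in (1, 10, 100, 1000, 10000):
        r = bcpnn_stat(ContingencyTable(10 * k, 90 * k, 90 * k, 810 * k))
        value = abs(r.ic)
        if last is not None:
            assert value < last
        last = value
    assert last < 1e-3


def test_bcpnn_priors_must_be_positive():
    with pytest.raises(ValueError):
        BCPNNPriors(alpha1=0.0)


# ---------------------------------------------------------------------------
# EBGM
# ---------------------------------------------------------------------------

def test_ebgm_hand_value():
    r = ebgm_stat(T_REF)
    assert r.point == pytest.approx(20 * 10000 / (120 * 100))  # 16.667
    assert r.point == pytest.approx(16.667, abs=1e-3)


def test_ebgm_independence_is_one():
    assert ebgm_stat(T_INDEP).point == pytest.approx(1.0)


def test_ebgm05_below_point():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b, c, d = rng.integers(1, 1000, size=4)
        r = ebgm_stat(ContingencyTable(int(a), int(b), int(c), int(d)))
        assert r.ci95[0] < r.point


def test_ic_converges_to_log2_ebgm_at_scale():
    for k in (10, 1000, 100000):
        t = ContingencyTable(30 * k, 70 * k, 50 * k, 850 * k)
        gap = abs(2 ** bcpnn_stat(t).ic - ebgm_stat(t).point)
        if k == 100000:
            assert gap < 1e-3


# ---------------------------------------------------------------------------
# monotonicity in a (b, c, d fixed)
# ---------------------------------------------------------------------------

def test_ror_and_prr_nondecreasing_in_a():
    b, c, d = 50, 70, 5000
    previous = None
    for a in range(1, 200, 7):
        t = ContingencyTable(a, b, c, d)
        current = (ror_stat(t).point, prr_stat(t).point)
        if previous is not None:
            assert all(x >= y - 1e-12 for x, y in zip(current, previous))
        previous = current


def test_ebgm_and_ic_nondecreasing_in_a_for_rare_events():
    # the observed/expected ratio a*N/((a+b)(a+c)) is only monotone in a while
    # 1/a + 1/N >= 1/(a+b) + 1/(a+c); that holds throughout a <= min(b, c),
    # the regime disproportionality tables live in
    b, c, d = 50, 70, 5000
    previous = None
    for a in range(1, min(b, c) + 1, 3):
        t = ContingencyTable(a, b, c, d)
        current = (bcpnn_stat(t).ic, ebgm_stat(t).point)
        if previous is not None:
            assert all(x >= y - 1e-12 for x, y in zip(current, previous))
        previous = current


def test_ebgm_monotonicity_counterexample_outside_rare_regime():
    # documents why the previous test restricts its domain
    low = ebgm_stat(ContingencyTable(183, 50, 70, 5000)).point
    high = ebgm_stat(ContingencyTable(190, 50, 70, 5000)).point
    assert high < low


# ---------------------------------------------------------------------------
# decision
# ---------------------------------------------------------------------------

def test_small_a_blocks_ror_flag():
    # a=2 with a huge odds ratio still fails the a>=3 requirement
    t = ContingencyTable(2, 1, 1, 10000)
    r = evaluate_pair(t, "X", "E")
    assert r.ror > 100
    assert r.flags["ror"] is False
    assert r.signal is False


def test_reference_table_flags_all_four():
    r = evaluate_pair(T_REF, "X", "E")
    assert all(r.flags.values())
    assert r.signal is True


def test_independence_table_flags_none():
    r = evaluate_pair(T_INDEP, "X", "E")
    assert not any(r.flags.values())
    assert r.signal is False


def test_signal_requires_all_four(monkeypatch):
    r = evaluate_pair(T_REF, "X", "E")
    flags, signal = signal_decision(r, Thresholds(ebgm05_min=1e9))
    assert flags["ror"] and flags["prr"] and flags["bcpnn"]
    assert not flags["ebgm"]
    assert signal is False


def test_result_invariants(planted_reports, smq):
    flags = flag_event_cases(planted_reports, smq, "narrow")
    t = build_table(planted_reports, "DRUG_001", flags)
    r = evaluate_pair(t, "DRUG_001", smq.name)
    assert r.ror_ci95[0] <= r.ror <= r.ror_ci95[1]
    assert r.prr_ci95[0] <= r.prr <= r.prr_ci95[1]
    assert r.ic025 <= r.ic
    assert r.ebgm05 <= r.ebgm
    assert r.signal == all(r.flags.values())


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------

def _result_with_p(p):
    t = ContingencyTable(5, 5, 5, 5)
    r = evaluate_pair(t, "X", "E")
    import dataclasses
    return dataclasses.replace(r, p_raw=p)


def test_bh_single_result_unchanged():
    out = adjust_pvalues([_result_with_p(0.042)])
    assert out[0].p_adjusted == pytest.approx(0.042)


def test_bh_hand_computation():
    out = adjust_pvalues([_result_with_p(p) for p in (0.01, 0.02, 0.03)])
    assert [r.p_adjusted for r in out] == pytest.approx([0.03, 0.03, 0.03])


def test_adjusted_all_ones_stay_one():
    out = adjust_pvalues([_result_with_p(1.0) for _ in range(5)])
    assert all(r.p_adjusted == 1.0 for r in out)


def test_bonferroni_available():
    out = adjust_pvalues([_result_with_p(0.01), _result_with_p(0.04)], "bonferroni")
    assert [r.p_adjusted for r in out] == pytest.approx([0.02, 0.08])


def test_unknown_adjustment_method_rejected():
    with pytest.raises(ValueError, match="unknown adjustment"):
        adjust_pvalues([_result_with_p(0.5)], "fishy")


def test_adjust_empty_list():
    assert adjust_pvalues([]) == []


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def test_all_male_universe_female_stratum_is_empty(smq):
    reports = [
        make_case(primary_id=str(i), case_id=str(i), sex="male",
                  drugs=[("X", "PS", None)], reactions=["Pancreatitis acute"])
        for i in range(5)
    ]
    results = stratified_scan(reports, "X", smq, {"sex": None}, include_overall=False)
    by_label = {r.stratum: r for r in results}
    assert by_label["sex=female"].table.N == 0
    assert by_label["sex=male"].table.a == 5


def test_missing_stratifier_drops_from_that_stratification_only(planted_reports, smq):
    results = stratified_scan(planted_reports, "DRUG_001", smq, {"age": 65.0})
    overall = next(r for r in results if r.stratum == "overall")
    strata = [r for r in results if r.stratum != "overall"]
    assert sum(r.table.a for r in strata) <= overall.table.a
    assert sum(r.table.N for r in strata) < overall.table.N  # ages go missing
    for r in strata:
        assert r.table.a <= overall.table.a


def test_overlapping_bins_rejected():
    with pytest.raises(OverlappingBinsError):
        make_strata({"age": [("lo", 0, 50), ("hi", 40, 100)]})


def test_custom_bins_accepted():
    strata = make_strata({"age": [("young", 0, 18), ("adult", 18, 65), ("old", 65, 200)]})
    assert [label for label, _ in strata] == ["young", "adult", "old"]


def test_unknown_stratifier_rejected():
    with pytest.raises(ValueError, match="stratification variable"):
        make_strata({"height": 180})


def test_sex_independent_signal_gives_overlapping_cis(smq):
    """With no sex effect planted, male and female ROR CIs should overlap."""
    from pvkit.faers_ingest import deduplicate
    from pvkit.synth_faers import SimulationConfig, simulate

    overlaps = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = SimulationConfig(
            n_cases=10_000, n_drugs=5, n_events=3, background_rate=0.02,
            signal_matrix={("DRUG_001", "Pancreatitis acute"): 8.0}, seed=100 + seed,
        )
        reports = deduplicate(simulate(cfg).tables)
        results = stratified_scan(reports, "DRUG_001", smq, {"sex": None},
                                  include_overall=False)
        (lo_m, hi_m), (lo_f, hi_f) = [r.ror_ci95 for r in results]
        if max(lo_m, lo_f) <= min(hi_m, hi_f):
            overlaps += 1
    assert overlaps >= int(0.9 * n_seeds)
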