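"""PSI quantification, control profiles, specificity, QC and allele skew."""

import math

import numpy as np
import pytest
from scipy import stats

from splicedx import (
    ControlProfile,
    JunctionTable,
    PsiObservation,
    SkewCall,
    Specificity,
    allele_skew_test,
    compute_psi,
    control_profile,
    detect_events,
    needs_rtpcr_confirmation,
    rna_sample_qc,
    specificity_test,
)
from splicedx.simulate import blueprint_esf, make_gene_model, simulate_sample

from conftest import make_toy


def table(counts, sample_id="S1"):
    return JunctionTable(sample_id=sample_id, counts=dict(counts))


def esf_event(model):
    """Exon-2 skip event on a 3-exon toy gene, detected from a table."""
    i1s = model.exons[0][1]
    i2e = model.exons[2][0]
    t = table({(model.chrom, i1s + 1, i2e, "+"): 30})
    (ev,) = detect_events(t, model, 3)
    return ev


class TestComputePsi:
    def test_simple_ratio(self, toy_plus):
        ev = esf_event(toy_plus)
        t = table(
            {
                ("chrT", 201, 500, "+"): 30,
                ("chrT", 201, 300, "+"): 70,
                ("chrT", 421, 500, "+"): 70,
            }
        )
        obs = compute_psi(ev, t, toy_plus)
        assert obs.psi == pytest.approx(0.30)
        assert (obs.supporting_reads, obs.region_total_reads) == (30, 100)

    def test_absent_event_with_coverage_is_zero(self, toy_plus):
        ev = esf_event(toy_plus)
        t = table({("chrT", 201, 300, "+"): 500, ("chrT", 421, 500, "+"): 500})
        obs = compute_psi(ev, t, toy_plus)
        assert obs.psi == 0.0 and obs.region_total_reads == 500

    def test_ic_event_mean_numerator(self, toy_plus):
        # flanking novel junctions 38 and 42 reads, host canonical 60
        t = table(
            {
                ("chrT", 201, 230, "+"): 38,
                ("chrT", 261, 300, "+"): 42,
                ("chrT", 201, 300, "+"): 60,
                ("chrT", 421, 500, "+"): 900,
            }
        )
        (ev,) = detect_events(t, toy_plus, 3)
        obs = compute_psi(ev, t, toy_plus)
        assert (obs.supporting_reads, obs.region_total_reads) == (40, 100)
        assert obs.psi == pytest.approx(0.40)

    def test_no_coverage_flagged_undefined(self, toy_plus):
        ev = esf_event(toy_plus)
        obs = compute_psi(ev, table({}), toy_plus)
        assert not obs.defined and "no_coverage" in obs.flags

    def test_psi_always_within_unit_interval(self, toy_plus):
        ev = esf_event(toy_plus)
        rng = np.random.default_rng(11)
        for _ in range(100):
            t = table(
                {
                    ("chrT", 201, 500, "+"): int(rng.integers(0, 2000)),
                    ("chrT", 201, 300, "+"): int(rng.integers(0, 2000)),
                    ("chrT", 421, 500, "+"): int(rng.integers(0, 2000)),
                }
            )
            obs = compute_psi(ev, t, toy_plus)
            if obs.defined:
                assert 0.0 <= obs.psi <= 1.0


class TestControlProfile:
    def test_event_absent_in_all_controls(self, toy_plus):
        ev = esf_event(toy_plus)
        controls = [
            table({("chrT", 201, 300, "+"): 800, ("chrT", 421, 500, "+"): 800}, f"HC{i}")
            for i in range(10)
        ]
        prof = control_profile(ev, controls, toy_plus)
        assert prof.median_psi == 0.0 and prof.max_psi == 0.0
        assert prof.n_controls == 10 and prof.n_undefined == 0

    def test_order_statistics_by_hand(self, toy_plus):
        ev = esf_event(toy_plus)
        # depth 100 with 0, 0, 1, 2 supporting reads -> PSI 0, 0, 0.01, 0.02
        controls = []
        for i, k in enumerate([0, 0, 1, 2]):
            counts = {("chrT", 201, 300, "+"): 100 - k, ("chrT", 421, 500, "+"): 100 - k}
            if k:
                counts[("chrT", 201, 500, "+")] = k
            controls.append(table(counts, f"HC{i}"))
        prof = control_profile(ev, controls, toy_plus)
        assert prof.median_psi == pytest.approx(0.005)
        assert prof.max_psi == pytest.approx(0.02)
        assert prof.per_sample_psi == (0.0, 0.0, 1 / 100, 2 / 100)

    def test_statistics_match_brute_force_recomputation(self, toy_plus):
        ev = esf_event(toy_plus)
        rng = np.random.default_rng(5)
        controls = []
        for i in range(37):
            k = int(rng.integers(0, 30))
            controls.append(
                table(
                    {
                        ("chrT", 201, 500, "+"): k,
                        ("chrT", 201, 300, "+"): 1000 - k,
                        ("chrT", 421, 500, "+"): 1000 - k,
                    },
                    f"HC{i}",
                )
            )
        prof = control_profile(ev, controls, toy_plus)
        vals = sorted(prof.per_sample_psi)
        n = len(vals)
        assert prof.max_psi == vals[-1]
        # median by hand
        med = (vals[n // 2 - 1] + vals[n // 2]) / 2 if n % 2 == 0 else vals[n // 2]
        assert prof.median_psi == pytest.approx(med)
        # p95 via the linear-interpolation formula
        h = (n - 1) * 0.95
        lo = int(math.floor(h))
        p95 = vals[lo] + (h - lo) * (vals[min(lo + 1, n - 1)] - vals[lo])
        assert prof.p95_psi == pytest.approx(p95)

    def test_undefined_controls_excluded_with_count(self, toy_plus):
        ev = esf_event(toy_plus)
        controls = [
            table({("chrT", 201, 300, "+"): 500, ("chrT", 421, 500, "+"): 500}, "HC0"),
            table({}, "HC1"),
        ]
        prof = control_profile(ev, controls, toy_plus)
        assert prof.n_undefined == 1 and prof.per_sample_psi == (0.0,)

    def test_empty_pool_raises(self, toy_plus):
        with pytest.raises(ValueError):
            control_profile(esf_event(toy_plus), [], toy_plus)

    def test_simulated_baseline_median_within_binomial_band(self, toy_plus):
        """345 simulated controls at true baseline PSI 0.01, depth 1000."""
        model, _ = make_gene_model(3, seed=9, chrom="chrS")
        bp = blueprint_esf(model, 2)
        rng = np.random.default_rng(1234)
        controls = [
            simulate_sample(model, [(bp, 0.01)], 1000, rng, f"HC{i}") for i in range(345)
        ]
        (ev,) = detect_events(controls[0], model, 1)
        prof = control_profile(ev, controls, model)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.01) / 1000
        assert lo <= prof.median_psi <= hi


class TestSpecificity:
    def _obs(self, psi, denom=1000):
        return PsiObservation("E", "S", int(psi * denom), denom, psi)

    def test_positive_against_silent_controls(self):
        prof = ControlProfile("E", 10, (0.0,) * 10)
        assert specificity_test(self._obs(0.35), prof) is Specificity.SPECIFIC

    def test_low_psi_matching_controls_not_specific(self):
        prof = ControlProfile("E", 10, (0.0, 0.01, 0.02, 0.02))
        assert specificity_test(self._obs(0.02), prof) is Specificity.NOT_SPECIFIC

    def test_shallow_denominator_indeterminate(self):
        prof = ControlProfile("E", 10, (0.0,) * 10)
        assert specificity_test(self._obs(0.35, 80), prof) is Specificity.INDETERMINATE

    def test_fold_rule_blocks_events_present_in_controls(self):
        prof = ControlProfile("E", 10, (0.30,) * 10)
        assert specificity_test(self._obs(0.35), prof) is Specificity.NOT_SPECIFIC

    def test_monotone_in_carrier_psi(self):
        """Raising carrier PSI never flips specific -> not_specific."""
        prof = ControlProfile("E", 20, tuple(np.linspace(0, 0.04, 20)))
        last_specific = False
        for psi in np.linspace(0.0, 1.0, 101):
            spec = specificity_test(self._obs(float(psi)), prof)
            if last_specific:
                assert spec is Specificity.SPECIFIC
            last_specific = spec is Specificity.SPECIFIC


class TestRtpcrRule:
    @pytest.mark.parametrize("denom,expected", [(499, True), (500, False), (10000, False)])
    def test_strict_500x_boundary(self, denom, expected):
        obs = PsiObservation("E", "S", 10, denom, 10 / denom)
        assert needs_rtpcr_confirmation(obs) is expected


class TestAlleleSkew:
    def test_symmetric_counts_balanced(self):
        call, p = allele_skew_test(50, 50)
        assert call is SkewCall.BALANCED and p == pytest.approx(1.0)

    def test_eighty_twenty_skewed(self):
        call, p = allele_skew_test(80, 20)
        # independent oracle: two-sided exact tail sum at n=100
        tail = sum(math.comb(100, k) * 0.5**100 for k in range(0, 21))
        assert call is SkewCall.SKEWED
        assert p == pytest.approx(2 * tail, rel=1e-6)
        assert p < 0.01

    def test_too_few_reads_indeterminate(self):
        call, _ = allele_skew_test(6, 4)
        assert call is SkewCall.INDETERMINATE

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            allele_skew_test(-1, 10)


class TestRnaQc:
    @pytest.mark.parametrize(
        "metrics,passed,reason",
        [
            ((80, 35, 90, 90), True, None),
            ((80, 35, 90, 80), False, "exon coverage"),
            ((70, 35, 90, 90), False, "Q30"),
            ((80, 30, 90, 90), False, "mean base quality"),  # strict >30
            ((80, 35, 85, 90), False, "perfect index"),  # strict >85
            ((76, 31, 86, 85), True, None),  # >=85 exon coverage passes
        ],
    )
    def test_threshold_table(self, metrics, passed, reason):
        res = rna_sample_qc(*metrics)
        assert res.passed is passed
        if reason:
            assert reason in res.failure_reasons

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError):
            rna_sample_qc(80, None, 90, 90)


class TestEstimatorRecovery:
    def test_binomial_recovery_within_99pct_interval(self):
        """Seeded replicates at depth 1000 recover the true PSI."""
        model, _ = make_gene_model(3, seed=2, chrom="chrS")
        bp = blueprint_esf(model, 2)
        rng = np.random.default_rng(77)
        for true_psi in (0.05, 0.35):
            hits = 0
            n_rep = 200
            lo, hi = stats.binom.ppf([0.005, 0.995], 1000, true_psi) / 1000
            for i in range(n_rep):
                t = simulate_sample(model, [(bp, true_psi)], 1000, rng, f"S{i}")
                (ev,) = detect_events(t, model, 1)
                obs = compute_psi(ev, t, model)
                hits += lo <= obs.psi <= hi
            assert hits / n_rep >= 0.99
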