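"""Hard-filter engine: per-record criteria, cluster windows, monotonicity."""

import dataclasses

import numpy as np
import pytest

from equindel.filters import (
    CRITERIA,
    FAIL,
    LOWQUAL,
    PASS,
    FilterThresholds,
    FilterVerdict,
    apply_filters,
    filter_clusters,
    filter_record,
)
from equindel.loci import VariantLocus
from equindel.simulate import SimulationConfig, simulate_population

CLEAN = {"DP": 40, "QUAL": 80.0, "QD": 5.0, "MQ0": 0.0, "HRun": 2.0, "SB": -0.5}


class TestFilterRecord:
    def test_all_criteria_satisfied_passes(self):
        v = filter_record(CLEAN)
        assert v.status == PASS and not v.reasons

    @pytest.mark.parametrize(
        "overrides,expected_reason",
        [
            ({"DP": 9}, "DP"),
            ({"QUAL": 29.9}, "QUAL"),
            ({"QD": 1.49}, "QD"),
            ({"HRun": 6.0}, "HRun"),
            ({"SB": 0.0}, "SB"),
        ],
    )
    def test_single_criterion_failures(self, overrides, expected_reason):
        v = filter_record({**CLEAN, **overrides})
        assert v.status == FAIL
        assert v.reasons == {expected_reason}

    def test_mq0_requires_both_count_and_ratio(self):
        # MQ0=4, DP=30 -> ratio 0.133 > 0.1 -> fails
        assert "MQ0" in filter_record({**CLEAN, "MQ0": 4.0, "DP": 30}).reasons
        # MQ0=4, DP=50 -> ratio 0.08 -> passes that criterion
        assert "MQ0" not in filter_record({**CLEAN, "MQ0": 4.0, "DP": 50}).reasons
        # MQ0=3 never fires regardless of ratio
        assert "MQ0" not in filter_record({**CLEAN, "MQ0": 3.0, "DP": 10}).reasons

    def test_qual_band_is_lowqual_not_fail(self):
        v = filter_record({**CLEAN, "QUAL": 35.0})
        assert v.status == LOWQUAL
        assert v.reasons == {"LOWQUAL"}
        # band lower bound is the hard-fail boundary
        assert filter_record({**CLEAN, "QUAL": 30.0}).status == LOWQUAL
        assert filter_record({**CLEAN, "QUAL": 50.0}).status == PASS

    def test_multiple_reasons_all_reported(self):
        v = filter_record({**CLEAN, "DP": 5, "QD": 1.0, "SB": 0.5})
        assert v.status == FAIL
        assert v.reasons == {"DP", "QD", "SB"}

    def test_missing_fields_not_evaluated_not_failed(self):
        v = filter_record({"DP": 40, "QUAL": 80.0})
        assert v.status == PASS
        assert {"QD", "HRun", "SB", "MQ0"} <= v.not_evaluated

    def test_negative_dp_rejected(self):
        with pytest.raises(ValueError, match="negative DP"):
            filter_record({**CLEAN, "DP": -1})

    def test_pure_function(self):
        info = {**CLEAN, "DP": 5}
        assert filter_record(info) == filter_record(info)

    def test_verdict_invariants_enforced(self):
        with pytest.raises(ValueError):
            FilterVerdict(PASS, frozenset({"DP"}))
        with pytest.raises(ValueError):
            FilterVerdict(LOWQUAL, frozenset({"DP", "LOWQUAL"}))


def _loci(positions, chrom="1"):
    return [VariantLocus(chrom, p, "A", ("AT",)) for p in positions]


def _brute_force_clusters(loci, window, size):
    flags = [False] * len(loci)
    for i, li in enumerate(loci):
        for start in range(li.pos - window + 1, li.pos + 1):
            inside = [
                j
                for j, lj in enumerate(loci)
                if lj.chrom == li.chrom and start <= lj.pos <= start + window - 1
            ]
            if i in inside and len(inside) >= size:
                flags[i] = True
                break
    return flags


class TestClusterFilter:
    def test_three_in_window_all_flagged(self):
        flags = filter_clusters(_loci([100, 105, 109]))
        assert flags.all()

    def test_two_in_window_none_flagged(self):
        assert not filter_clusters(_loci([100, 105])).any()

    def test_single_variant_never_flagged(self):
        assert not filter_clusters(_loci([100])).any()

    def test_window_boundary(self):
        # positions spanning exactly 10 bp fit one window; 11 bp do not
        assert filter_clusters(_loci([100, 105, 109])).all()
        assert not filter_clusters(_loci([100, 105, 110])).any()  # 100..110 spans 11 bp
        assert not filter_clusters(_loci([100, 109, 118])).any()

    def test_chromosome_boundary_resets_window(self):
        loci = _loci([100, 105], "1") + _loci([106, 109], "2")
        assert not filter_clusters(loci).any()

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            filter_clusters(_loci([200, 100]))

    def test_sliding_window_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            n = int(rng.integers(5, 120))
            positions = np.sort(rng.choice(np.arange(1, 400), size=n, replace=False))
            loci = _loci([int(p) for p in positions])
            got = filter_clusters(loci).tolist()
            exp = _brute_force_clusters(loci, 10, 3)
            assert got == exp


@pytest.fixture(scope="module")
def dirty_population():
    cfg = SimulationConfig(
        n_samples=10, n_diallelic=1500, n_multiallelic=100,
        n_artifact_allhet=0, n_all_alt_hom=0,
        filter_fail_fractions={"DP": 0.06, "QUAL": 0.04, "LOWQUAL": 0.04,
                               "QD": 0.03, "MQ0": 0.03, "HRun": 0.03, "SB": 0.03},
        seed=77,
    )
    return simulate_population(cfg)


class TestApplyFilters:
    def test_retained_equals_truth(self, dirty_population):
        res = dirty_population
        retained, counts, _ = apply_filters(res.matrix)
        exp_clean = (res.truth["filter_violations"] == "").sum()
        assert retained.n_loci == exp_clean
        truth_counts = {}
        for s in res.truth["filter_violations"]:
            for c in s.split(";") if s else []:
                truth_counts[c] = truth_counts.get(c, 0) + 1
        for c, n in truth_counts.items():
            assert counts[c] == n

    def test_non_binding_thresholds_identity(self, dirty_population):
        thr = FilterThresholds(
            mq0_min=1e9, dp_min=-1, qual_min=-1, qual_low_max=-1,
            qd_min=-1, hrun_max=1e9, sb_max=1e9,
        )
        retained, counts, _ = apply_filters(dirty_population.matrix, thr)
        assert retained.n_loci == dirty_population.matrix.n_loci
        assert all(v == 0 for v in counts.values())

    def test_all_dp_zero_empty(self, dirty_population):
        m = dirty_population.matrix.subset(np.arange(50))
        m.info = [{**i, "DP": 0} for i in m.info]
        retained, _, _ = apply_filters(m)
        assert retained.n_loci == 0

    def test_relaxing_any_threshold_never_decreases_retention(self, dirty_population):
        base = FilterThresholds()
        baseline, _, _ = apply_filters(dirty_population.matrix, base)
        relaxed_variants = [
            dataclasses.replace(base, dp_min=5),
            dataclasses.replace(base, qual_min=10.0, qual_low_max=10.0),
            dataclasses.replace(base, qd_min=0.5),
            dataclasses.replace(base, hrun_max=10),
            dataclasses.replace(base, sb_max=0.5),
            dataclasses.replace(base, mq0_min=100),
            dataclasses.replace(base, cluster_window=5),
        ]
        for thr in relaxed_variants:
            retained, _, _ = apply_filters(dirty_population.matrix, thr)
            assert retained.n_loci >= baseline.n_loci

    def test_retain_lowqual_toggle(self, dirty_population):
        strict, counts, _ = apply_filters(dirty_population.matrix)
        lenient, _, _ = apply_filters(dirty_population.matrix, retain_lowqual=True)
        only_lowqual = (dirty_population.truth["filter_violations"] == "LOWQUAL").sum()
        assert lenient.n_loci == strict.n_loci + only_lowqual


def test_yaml_round_trip(tmp_path):
    thr = FilterThresholds(dp_min=12, cluster_size=4)
    p = tmp_path / "thr.yaml"
    import yaml

    p.write_text(yaml.safe_dump(thr.to_dict()))
    assert FilterThresholds.from_yaml(str(p)) == thr
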