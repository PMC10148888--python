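import numpy as np
import pytest
from helpers import make_subject
from hypothesis import given
from hypothesis import strategies as st

from pwmmrm.labeling import (
    HAMD17_RESPONSE_THRESHOLD,
    MADRS_RESPONSE_THRESHOLD,
    ThresholdSpec,
    derive_threshold_from_anchors,
    equipercentile_link,
    label_response,
)


def _subject_with(baseline_total: int, week8_total: int | None):
    base = [0] * 17
    remaining = baseline_total
    for j, mx in enumerate((4, 4, 4, 2, 2, 2, 4, 4, 4, 4, 4, 2, 2, 2, 4, 2, 2)):
        take = min(mx, remaining)
        base[j] = take
        remaining -= take
    totals = {} if week8_total is None else {"week8": week8_total}
    return make_subject("S", "placebo", tuple(base), tuple(base), totals)


class TestThresholdDerivation:
    def test_midpoint_of_cgi_anchors(self):
        spec = derive_threshold_from_anchors({3: 0.245, 2: 0.525}, 3, 2)
        assert spec.percent_reduction == pytest.approx(0.385)

    def test_override_records_midpoint(self):
        spec = derive_threshold_from_anchors(
            {3: 0.245, 2: 0.525}, 3, 2, rule="override", override=0.38
        )
        assert spec.percent_reduction == 0.38
        assert spec.derived_midpoint == pytest.approx(0.385)

    def test_degenerate_midpoint(self):
        spec = derive_threshold_from_anchors({3: 0.30, 2: 0.31}, 3, 2)
        assert spec.percent_reduction == pytest.approx(0.305)

    def test_missing_anchor_level(self):
        with pytest.raises(KeyError):
            derive_threshold_from_anchors({3: 0.245}, 3, 2)

    def test_nonmonotone_anchors_rejected(self):
        with pytest.raises(ValueError):
            derive_threshold_from_anchors({3: 0.6, 2: 0.5, 1: 0.7}, 3, 2)

    def test_shipped_defaults(self):
        assert MADRS_RESPONSE_THRESHOLD.percent_reduction == 0.38
        assert HAMD17_RESPONSE_THRESHOLD.percent_reduction == 0.41

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            ThresholdSpec("HAMD17", 1.0)


class TestEquipercentileLink:
    def test_discrete_example(self):
        assert equipercentile_link([0, 1, 2, 3], [0, 2, 4, 6], 1) == pytest.approx(2.0)

    @given(
        sample=st.lists(st.integers(0, 30), min_size=1, max_size=40),
        x=st.integers(0, 30),
    )
    def test_self_linking_identity_on_observed_scores(self, sample, x):
        if x not in sample:
            sample = sample + [x]
        assert equipercentile_link(sample, sample, x) == pytest.approx(float(x))

    @given(
        src=st.lists(st.integers(0, 50), min_size=3, max_size=21).filter(
            lambda s: len(s) % 2 == 1
        ),
        tgt=st.lists(st.integers(0, 50), min_size=3, max_size=21).filter(
            lambda s: len(s) % 2 == 1
        ),
    )
    def test_median_maps_to_median_for_odd_samples(self, src, tgt):
        # distinct values so the median has a unique mid-rank of exactly 0.5
        src, tgt = sorted(set(src)), sorted(set(tgt))
        if len(src) % 2 == 0:
            src = src[:-1]
        if len(tgt) % 2 == 0:
            tgt = tgt[:-1]
        if not src or not tgt:
            return
        got = equipercentile_link(src, tgt, float(np.median(src)))
        assert got == pytest.approx(float(np.median(tgt)))

    @given(
        src=st.lists(st.integers(0, 20), min_size=2, max_size=30),
        tgt=st.lists(st.integers(0, 20), min_size=2, max_size=30),
        xs=st.tuples(st.integers(0, 20), st.integers(0, 20)),
    )
    def test_monotone_nondecreasing(self, src, tgt, xs):
        lo, hi = min(xs), max(xs)
        assert equipercentile_link(src, tgt, lo) <= equipercentile_link(src, tgt, hi)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            equipercentile_link([], [1, 2], 1)


class TestResponseLabel:
    @pytest.mark.parametrize(
        "baseline,week8,threshold,expected",
        [
            (24, 14, 0.41, 1),   # 10/24 = 0.4167 >= 0.41
            (24, 15, 0.41, 0),   # 9/24 = 0.375
            (20, 20, 0.01, 0),   # no change
            (24, 24, 0.41, 0),
        ],
    )
    def test_threshold_rule(self, baseline, week8, threshold, expected):
        rec = _subject_with(baseline, week8)
        lab = label_response(rec, ThresholdSpec("HAMD17", threshold), "week8")
        assert lab.label == expected

    def test_missing_eos_excluded_by_default(self):
        lab = label_response(_subject_with(24, None), HAMD17_RESPONSE_THRESHOLD, "week8")
        assert lab.label is None and lab.missing

    def test_locf_uses_last_observed(self):
        rec = _subject_with(24, None)
        rec.post_baseline_totals["week2"] = 10  # 58% reduction
        lab = label_response(
            rec, HAMD17_RESPONSE_THRESHOLD, "week8",
            missing_rule="locf", visit_order=("week2", "week8"),
        )
        assert lab.label == 1

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError):
            label_response(_subject_with(0, 0), HAMD17_RESPONSE_THRESHOLD, "week8")

    @given(
        baseline=st.integers(1, 52),
        week8=st.integers(0, 52),
        t_pair=st.tuples(st.floats(0.01, 0.99), st.floats(0.01, 0.99)),
    )
    def test_monotone_in_threshold(self, baseline, week8, t_pair):
        """Lowering the threshold never flips a responder to non-responder."""
        lo, hi = sorted(t_pair)
        rec = _subject_with(baseline, min(week8, 52))
        lab_hi = label_response(rec, ThresholdSpec("HAMD17", hi), "week8")
        lab_lo = label_response(rec, ThresholdSpec("HAMD17", lo), "week8")
        assert lab_lo.label >= lab_hi.label
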