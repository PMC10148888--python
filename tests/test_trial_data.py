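import dataclasses

import numpy as np
import pytest
from helpers import make_subject, tiny_trial
from hypothesis import given
from hypothesis import strategies as st

from pwmmrm.data import (
    HAMD17,
    IntegrityError,
    SchemaError,
    TrialDataset,
    TrialValidationError,
    change_from_baseline,
    item_changes,
    read_trial_long,
    write_trial_long,
)


class TestRoundTrip:
    def test_write_read_identity(self, tiny_dataset, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial_long(tiny_dataset, str(path))
        back = read_trial_long(str(path))
        assert back.visit_schedule == tiny_dataset.visit_schedule
        assert back.arms == tiny_dataset.arms
        assert back.placebo_arm == tiny_dataset.placebo_arm
        for a, b in zip(tiny_dataset.subjects, back.subjects):
            assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_tsv_dialect(self, tiny_dataset, tmp_path):
        path = tmp_path / "trial.tsv"
        write_trial_long(tiny_dataset, str(path))
        assert "\t" in path.read_text().splitlines()[0]
        back = read_trial_long(str(path))
        assert back.n_subjects == tiny_dataset.n_subjects

    def test_missing_visit_row_absent(self, tiny_dataset, tmp_path):
        # P3 misses week4: its row must simply not exist (sparse convention)
        path = tmp_path / "trial.csv"
        write_trial_long(tiny_dataset, str(path))
        lines = [l for l in path.read_text().splitlines() if l.startswith("P3,")]
        assert len(lines) == 4  # screening, baseline, week2, week8

    def test_empty_dataset_header_only(self, tmp_path):
        ds = TrialDataset(
            subjects=[], visit_schedule=(("week8", 8),), arms=("placebo",),
            placebo_arm="placebo",
        )
        path = tmp_path / "empty.csv"
        write_trial_long(ds, str(path))
        assert len(path.read_text().splitlines()) == 1

    def test_zero_post_baseline_rows_valid(self, tmp_path):
        ds = TrialDataset(
            subjects=[make_subject("S1", "placebo", (0,) * 17, (0,) * 17, {})],
            visit_schedule=(("week8", 8),),
            arms=("placebo",),
            placebo_arm="placebo",
        )
        path = tmp_path / "nopost.csv"
        write_trial_long(ds, str(path))
        back = read_trial_long(str(path), placebo_arm="placebo")
        assert back.subjects[0].post_baseline_totals == {}


class TestValidation:
    def test_item_out_of_range_names_subject(self):
        bad = make_subject("SX", "placebo", (5,) + (0,) * 16, (0,) * 17)
        with pytest.raises(TrialValidationError, match="SX.*item 1"):
            TrialDataset([bad], (("week8", 8),), ("placebo",), "placebo")

    def test_perturbed_file_rejected(self, tiny_dataset, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial_long(tiny_dataset, str(path))
        text = path.read_text()
        # corrupt P1's screening item01 (first data row) to 9 (max is 4)
        lines = text.splitlines()
        fields = lines[1].split(",")
        fields[4] = "9"
        fields[3] = str(int(fields[3]) + 9 - int(lines[1].split(",")[4]))
        lines[1] = ",".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrialValidationError, match="P1"):
            read_trial_long(str(path))

    def test_duplicate_row_integrity_error(self, tiny_dataset, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial_long(tiny_dataset, str(path))
        lines = path.read_text().splitlines()
        lines.append(lines[-1])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(IntegrityError):
            read_trial_long(str(path))

    def test_missing_column_schema_error(self, tiny_dataset, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial_long(tiny_dataset, str(path))
        import pandas as pd

        df = pd.read_csv(path).drop(columns=["item07"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="item07"):
            read_trial_long(str(path))

    def test_baseline_total_cross_check(self, tiny_dataset, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial_long(tiny_dataset, str(path))
        import pandas as pd

        df = pd.read_csv(path)
        df.loc[(df.subject_id == "P2") & (df.visit == "baseline"), "total"] += 1
        df.to_csv(path, index=False)
        with pytest.raises(TrialValidationError, match="P2"):
            read_trial_long(str(path))

    def test_duplicate_subject_ids_rejected(self):
        s = make_subject("S1", "placebo", (0,) * 17, (0,) * 17)
        with pytest.raises(IntegrityError):
            TrialDataset([s, s], (("week8", 8),), ("placebo",), "placebo")

    def test_nonincreasing_weeks_rejected(self):
        with pytest.raises(TrialValidationError):
            TrialDataset([], (("week4", 4), ("week2", 2)), ("placebo",), "placebo")


item_scores = st.tuples(*(st.integers(0, m) for m in HAMD17.maxima))


class TestDerivedQuantities:
    @given(scr=item_scores, base=item_scores)
    def test_item_changes_is_elementwise_subtraction(self, scr, base):
        rec = make_subject("S", "placebo", scr, base)
        np.testing.assert_array_equal(
            item_changes(rec), np.array(base) - np.array(scr)
        )

    def test_item_changes_identity_and_single_item(self):
        base = (2,) + (0,) * 16
        scr = (4,) + (0,) * 16
        assert item_changes(make_subject("S", "a", base, base)).sum() == 0
        deltas = item_changes(make_subject("S", "a", scr, base))
        assert deltas[0] == -2 and not deltas[1:].any()

    def test_change_from_baseline(self, tiny_dataset):
        p1 = tiny_dataset.subject("P1")  # baseline 24
        assert change_from_baseline(p1, "week8") == 15 - 24
        assert change_from_baseline(tiny_dataset.subject("P3"), "week4") is None

    def test_changes_frame_matches_by_hand(self, tiny_dataset):
        fr = tiny_dataset.changes_frame()
        expected = {
            ("P1", "week2"): -4, ("P1", "week4"): -6, ("P1", "week8"): -9,
            ("P2", "week2"): -2, ("P2", "week4"): -4, ("P2", "week8"): -12,
            ("P3", "week2"): -1, ("P3", "week8"): -3,
            ("D1", "week2"): -5, ("D1", "week4"): -9, ("D1", "week8"): -14,
            ("D2", "week2"): -3, ("D2", "week4"): -7, ("D2", "week8"): -10,
            ("D3", "week2"): -2, ("D3", "week4"): -5, ("D3", "week8"): -8,
        }
        got = {(r.subject_id, r.visit): r.change for r in fr.itertuples()}
        assert got == expected
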