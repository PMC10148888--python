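"""Data model and long-format I/O for randomized-trial rating-scale data.

The central container is :class:`TrialDataset`: one :class:`SubjectRecord` per
randomized subject, holding the 17 (or, for other scales, ``n_items``)
item-level scores at the two pre-randomization visits (screening and baseline)
plus the post-baseline total scores, and a visit schedule shared across
subjects.  Missing post-baseline visits are simply absent keys — the
repeated-measures model downstream consumes incomplete data natively, so
nothing is ever imputed at I/O time.

On disk the data live in a sparse long format: one row per subject x visit,
item columns populated only on the two pre-randomization rows, and a total
score column on every row.  ``read_trial_long`` / ``write_trial_long`` are
exact inverses on this representation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ItemScale",
    "HAMD17",
    "MADRS",
    "SubjectRecord",
    "TrialDataset",
    "SchemaError",
    "TrialValidationError",
    "IntegrityError",
    "item_changes",
    "change_from_baseline",
    "read_trial_long",
    "write_trial_long",
    "DEFAULT_SCHEMA",
]


class SchemaError(ValueError):
    """A mandatory column is missing or mislabeled in an input file."""


class TrialValidationError(ValueError):
    """A record violates a scale range or internal-consistency invariant."""


class IntegrityError(ValueError):
    """Duplicate or contradictory rows in an input file."""


@dataclass(frozen=True)
class ItemScale:
    """Per-item score maxima for a clinician rating scale (minimum is 0)."""

    name: str
    maxima: tuple[int, ...]

    @property
    def n_items(self) -> int:
        return len(self.maxima)

    @property
    def max_total(self) -> int:
        return int(sum(self.maxima))


#: 17-item Hamilton Depression Rating Scale: items 1-3, 7-11 and 15 are rated
#: 0-4; the remaining eight items are rated 0-2 (maximum total 52).
HAMD17 = ItemScale("HAMD17", (4, 4, 4, 2, 2, 2, 4, 4, 4, 4, 4, 2, 2, 2, 4, 2, 2))

#: Montgomery-Asberg Depression Rating Scale: ten items rated 0-6.
MADRS = ItemScale("MADRS", (6,) * 10)


@dataclass
class SubjectRecord:
    subject_id: str
    arm: str
    screening_items: tuple[int, ...]
    baseline_items: tuple[int, ...]
    screening_to_baseline_days: int
    post_baseline_totals: dict[str, int] = field(default_factory=dict)

    @property
    def baseline_total(self) -> int:
        return int(sum(self.baseline_items))

    @property
    def screening_total(self) -> int:
        return int(sum(self.screening_items))


@dataclass
class TrialDataset:
    """A randomized trial: subjects, a shared visit schedule, and arm labels.

    Parameters
    ----------
    subjects
        One record per randomized subject; subject identifiers must be unique.
    visit_schedule
        Ordered ``(label, week)`` pairs for the post-baseline visits; weeks
        must be strictly increasing and positive (week 0 is reserved for
        baseline, screening carries only a day offset).
    arms
        Declared arm labels; every subject's arm must be among them.
    placebo_arm
        The reference arm, required to appear in ``arms``.
    scale
        The rating scale the item scores live on (default HAMD-17).
    """

    subjects: list[SubjectRecord]
    visit_schedule: tuple[tuple[str, int], ...]
    arms: tuple[str, ...]
    placebo_arm: str
    scale: ItemScale = HAMD17

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.placebo_arm not in self.arms:
            raise TrialValidationError(
                f"placebo arm {self.placebo_arm!r} not among declared arms {self.arms}"
            )
        weeks = [w for _, w in self.visit_schedule]
        if any(w <= 0 for w in weeks):
            raise TrialValidationError("post-baseline visit weeks must be positive")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise TrialValidationError("visit weeks must be strictly increasing")
        labels = {lab for lab, _ in self.visit_schedule}
        seen: set[str] = set()
        for rec in self.subjects:
            if rec.subject_id in seen:
                raise IntegrityError(f"duplicate subject id {rec.subject_id!r}")
            seen.add(rec.subject_id)
            if rec.arm not in self.arms:
                raise TrialValidationError(
                    f"subject {rec.subject_id!r}: unknown arm {rec.arm!r}"
                )
            self._check_items(rec.subject_id, "screening", rec.screening_items)
            self._check_items(rec.subject_id, "baseline", rec.baseline_items)
            if rec.screening_to_baseline_days < 0:
                raise TrialValidationError(
                    f"subject {rec.subject_id!r}: negative screening-to-baseline days"
                )
            extra = set(rec.post_baseline_totals) - labels
            if extra:
                raise TrialValidationError(
                    f"subject {rec.subject_id!r}: visits {sorted(extra)} not in schedule"
                )
            for lab, tot in rec.post_baseline_totals.items():
                if not 0 <= tot <= self.scale.max_total:
                    raise TrialValidationError(
                        f"subject {rec.subject_id!r}: total {tot} at {lab} outside "
                        f"[0, {self.scale.max_total}]"
                    )

    def _check_items(self, sid: str, visit: str, items: tuple[int, ...]) -> None:
        if len(items) != self.scale.n_items:
            raise TrialValidationError(
                f"subject {sid!r}: expected {self.scale.n_items} {visit} items, "
                f"got {len(items)}"
            )
        for j, (score, mx) in enumerate(zip(items, self.scale.maxima), start=1):
            if not 0 <= score <= mx:
                raise TrialValidationError(
                    f"subject {sid!r}: {visit} item {j} score {score} outside [0, {mx}]"
                )

    # -- conveniences -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def visit_labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.visit_schedule)

    def arm_census(self) -> dict[str, int]:
        census = {a: 0 for a in self.arms}
        for rec in self.subjects:
            census[rec.arm] += 1
        return census

    def subject(self, subject_id: str) -> SubjectRecord:
        for rec in self.subjects:
            if rec.subject_id == subject_id:
                return rec
        raise KeyError(subject_id)

    def subset(self, subject_ids) -> "TrialDataset":
        """Restrict to the given subjects (schedule and arms unchanged)."""
        keep = set(subject_ids)
        return replace(self, subjects=[r for r in self.subjects if r.subject_id in keep])

    def changes_frame(self) -> pd.DataFrame:
        """Long change-from-baseline table: one row per observed visit."""
        rows = []
        for rec in self.subjects:
            for lab, week in self.visit_schedule:
                if lab in rec.post_baseline_totals:
                    rows.append(
                        {
                            "subject_id": rec.subject_id,
                            "arm": rec.arm,
                            "visit": lab,
                            "week": week,
                            "baseline": rec.baseline_total,
                            "change": rec.post_baseline_totals[lab] - rec.baseline_total,
                        }
                    )
        return pd.DataFrame(
            rows, columns=["subject_id", "arm", "visit", "week", "baseline", "change"]
        )


def item_changes(subject: SubjectRecord) -> np.ndarray:
    """Screening-to-baseline item change vector, baseline minus screening."""
    return np.asarray(subject.baseline_items, dtype=int) - np.asarray(
        subject.screening_items, dtype=int
    )


def change_from_baseline(subject: SubjectRecord, visit: str) -> int | None:
    """Total-score change at ``visit`` (negative = improvement); None if missing."""
    if visit not in subject.post_baseline_totals:
        return None
    return subject.post_baseline_totals[visit] - subject.baseline_total


# ---------------------------------------------------------------------------
# Long-format I/O
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {
    "subject": "subject_id",
    "arm": "arm",
    "visit": "visit",
    "total": "total",
    "item_prefix": "item",
    "days": "screen_to_baseline_days",
}

_SCREENING = "screening"
_BASELINE = "baseline"


def _item_columns(schema: dict, n_items: int) -> list[str]:
    prefix = schema.get("item_prefix", "item")
    return [f"{prefix}{j:02d}" for j in range(1, n_items + 1)]


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_trial_long(
    path: str,
    schema: dict | None = None,
    scale: ItemScale = HAMD17,
    placebo_arm: str | None = None,
) -> TrialDataset:
    """Read a sparse long-format delimited file into a validated dataset.

    The file needs one row per subject x visit with a visit tag column
    (``screening``, ``baseline`` or ``week<k>``), item columns populated on
    the two pre-randomization rows, and a total-score column.  The baseline
    total is recomputed from the items and cross-checked against the total
    column.  The placebo arm is taken from ``placebo_arm`` or, failing that,
    detected as the unique arm label containing "placebo" (case-insensitive).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=_sep_for(path))
    item_cols = _item_columns(schema, scale.n_items)
    mandatory = [schema["subject"], schema["arm"], schema["visit"], schema["total"]]
    for col in mandatory + item_cols:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")

    dup = df.duplicated(subset=[schema["subject"], schema["visit"]])
    if dup.any():
        first = df.loc[dup, [schema["subject"], schema["visit"]]].iloc[0]
        raise IntegrityError(
            f"duplicate row for subject {first[schema['subject']]!r} at visit "
            f"{first[schema['visit']]!r}"
        )

    visit_tags = [v for v in df[schema["visit"]].unique() if v not in (_SCREENING, _BASELINE)]
    schedule = []
    for tag in visit_tags:
        if not str(tag).startswith("week"):
            raise SchemaError(f"unrecognized visit tag {tag!r} (expected week<k>)")
        schedule.append((str(tag), int(str(tag)[4:])))
    schedule.sort(key=lambda lw: lw[1])

    arms = list(dict.fromkeys(df[schema["arm"]]))
    if placebo_arm is None:
        cand = [a for a in arms if "placebo" in str(a).lower()]
        if len(cand) != 1:
            raise SchemaError(
                "cannot auto-detect the placebo arm; pass placebo_arm explicitly"
            )
        placebo_arm = cand[0]

    subjects = []
    for sid, grp in df.groupby(schema["subject"], sort=False):
        grp = grp.set_index(schema["visit"])
        for tag in (_SCREENING, _BASELINE):
            if tag not in grp.index:
                raise TrialValidationError(f"subject {sid!r}: missing {tag} row")
        scr = grp.loc[_SCREENING]
        base = grp.loc[_BASELINE]

        def _items(row, visit):
            vals = []
            for j, col in enumerate(item_cols, start=1):
                v = row[col]
                if pd.isna(v):
                    raise TrialValidationError(
                        f"subject {sid!r}: missing {visit} item {j}"
                    )
                vals.append(int(v))
            return tuple(vals)

        screening_items = _items(scr, _SCREENING)
        baseline_items = _items(base, _BASELINE)
        if int(base[schema["total"]]) != sum(baseline_items):
            raise TrialValidationError(
                f"subject {sid!r}: baseline total column {int(base[schema['total']])} "
                f"!= item sum {sum(baseline_items)}"
            )
        days_val = scr.get(schema["days"], 0)
        days = 0 if pd.isna(days_val) else int(days_val)
        totals = {}
        for lab, _week in schedule:
            if lab in grp.index:
                totals[lab] = int(grp.loc[lab, schema["total"]])
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                arm=str(scr[schema["arm"]]),
                screening_items=screening_items,
                baseline_items=baseline_items,
                screening_to_baseline_days=days,
                post_baseline_totals=totals,
            )
        )

    return TrialDataset(
        subjects=subjects,
        visit_schedule=tuple(schedule),
        arms=tuple(arms),
        placebo_arm=placebo_arm,
        scale=scale,
    )


def write_trial_long(dataset: TrialDataset, path: str, schema: dict | None = None) -> None:
    """Write the sparse long format consumed by :func:`read_trial_long`."""
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    item_cols = _item_columns(schema, dataset.scale.n_items)
    cols = [schema["subject"], schema["arm"], schema["visit"], schema["total"]]
    cols += item_cols + [schema["days"]]
    rows = []
    for rec in dataset.subjects:
        scr_row = {
            schema["subject"]: rec.subject_id,
            schema["arm"]: rec.arm,
            schema["visit"]: _SCREENING,
            schema["total"]: rec.screening_total,
            schema["days"]: rec.screening_to_baseline_days,
        }
        scr_row.update({c: v for c, v in zip(item_cols, rec.screening_items)})
        rows.append(scr_row)
        base_row = {
            schema["subject"]: rec.subject_id,
            schema["arm"]: rec.arm,
            schema["visit"]: _BASELINE,
            schema["total"]: rec.baseline_total,
        }
        base_row.update({c: v for c, v in zip(item_cols, rec.baseline_items)})
        rows.append(base_row)
        for lab, _week in dataset.visit_schedule:
            if lab in rec.post_baseline_totals:
                rows.append(
                    {
                        schema["subject"]: rec.subject_id,
                        schema["arm"]: rec.arm,
                        schema["visit"]: lab,
                        schema["total"]: rec.post_baseline_totals[lab],
                    }
                )
    frame = pd.DataFrame(rows, columns=cols)
    for col in item_cols + [schema["days"], schema["total"]]:
        frame[col] = frame[col].astype("Int64")
    out_dir = os.path.dirname(os.path.abspath(path))
    if out_dir and not os.path.isdir(out_dir):
        raise IOError(f"directory does not exist: {out_dir}")
    frame.to_csv(path, sep=_sep_for(path), index=False)
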