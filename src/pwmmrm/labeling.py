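"""Response-threshold derivation and end-of-study placebo-response labels.

Clinical response is defined as a clinically relevant percent reduction of the
total depression score from baseline to the end-of-study visit.  The relevant
fraction is anchored to the Clinical Global Impression--Improvement (CGI-I)
scale: each CGI-I level maps to the mean percent reduction observed among
patients rated at that level, and the response cut-off is placed between
"minimally improved" (CGI-I 3) and "much improved" (CGI-I 2).  The shipped
defaults are a 38% MADRS reduction and its equipercentile HAMD-17 equivalent
of 41%; both are overridable, and the anchor/linking machinery is exposed so
the derivation is auditable rather than re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SubjectRecord, TrialDataset

__all__ = [
    "ThresholdSpec",
    "ResponseLabel",
    "DEFAULT_CGI_ANCHORS",
    "MADRS_RESPONSE_THRESHOLD",
    "HAMD17_RESPONSE_THRESHOLD",
    "derive_threshold_from_anchors",
    "equipercentile_link",
    "label_response",
    "label_dataset",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """A response definition: scale plus fractional percent reduction."""

    scale: str
    percent_reduction: float
    derived_midpoint: float | None = None  # audit trail when overridden

    def __post_init__(self) -> None:
        if not 0.0 < self.percent_reduction < 1.0:
            raise ValueError("percent_reduction must lie strictly in (0, 1)")


#: CGI-I anchor means on the MADRS percent-reduction scale: 1 = very much
#: improved (82%), 2 = much improved (52.5%), 3 = minimally improved (24.5%).
DEFAULT_CGI_ANCHORS: dict[int, float] = {1: 0.82, 2: 0.525, 3: 0.245}

MADRS_RESPONSE_THRESHOLD = ThresholdSpec("MADRS", 0.38, derived_midpoint=0.385)
HAMD17_RESPONSE_THRESHOLD = ThresholdSpec("HAMD17", 0.41)


@dataclass(frozen=True)
class ResponseLabel:
    subject_id: str
    label: int | None
    observed_percent_change: float | None

    @property
    def missing(self) -> bool:
        return self.label is None


def _check_anchor_order(anchors: dict[int, float]) -> None:
    levels = sorted(anchors)
    reductions = [anchors[k] for k in levels]
    if any(b >= a for a, b in zip(reductions, reductions[1:])):
        raise ValueError(
            "anchor percent reductions must decrease as the CGI-I score increases"
        )


def derive_threshold_from_anchors(
    anchors: dict[int, float],
    lower_cgi: int,
    upper_cgi: int,
    rule: str = "midpoint",
    override: float | None = None,
    scale: str = "MADRS",
) -> ThresholdSpec:
    """Place the response cut-off between two CGI-I anchor levels.

    ``midpoint`` returns the arithmetic mean of the two anchor reductions;
    ``override`` returns the supplied fraction while recording the computed
    midpoint for audit.
    """
    _check_anchor_order(anchors)
    for level in (lower_cgi, upper_cgi):
        if level not in anchors:
            raise KeyError(f"CGI-I level {level} not present in the anchor map")
    midpoint = (anchors[lower_cgi] + anchors[upper_cgi]) / 2.0
    if rule == "midpoint":
        return ThresholdSpec(scale, midpoint)
    if rule == "override":
        if override is None:
            raise ValueError("rule='override' requires an override fraction")
        return ThresholdSpec(scale, override, derived_midpoint=midpoint)
    raise ValueError(f"unknown rule {rule!r}")


def _level_percentile_ranks(sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct score levels and their mid-rank percentile ranks in [0, 1]."""
    levels, counts = np.unique(sample, return_counts=True)
    below = np.concatenate(([0], np.cumsum(counts)[:-1]))
    pr = (below + 0.5 * counts) / sample.size
    return levels.astype(float), pr


def equipercentile_link(dist_source, dist_target, x: float) -> float:
    """Map a source-scale score to the target score of equal percentile rank.

    Percentile ranks use the mid-rank (average-rank) convention, linearly
    interpolated between adjacent discrete score levels; the result is clamped
    to the observed range of the target sample.
    """
    src = np.asarray(dist_source, dtype=float)
    tgt = np.asarray(dist_target, dtype=float)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("equipercentile linking requires nonempty samples")
    src_levels, src_pr = _level_percentile_ranks(src)
    tgt_levels, tgt_pr = _level_percentile_ranks(tgt)
    # rank of x in the source, then invert the target rank function
    p = float(np.interp(x, src_levels, src_pr))
    return float(np.interp(p, tgt_pr, tgt_levels))


def label_response(
    subject: SubjectRecord,
    threshold: ThresholdSpec,
    eos_visit: str,
    missing_rule: str = "exclude",
    visit_order: tuple[str, ...] | None = None,
) -> ResponseLabel:
    """Binary end-of-study response: 1 iff the fractional reduction of the
    baseline total at ``eos_visit`` reaches the threshold.

    Subjects missing the end-of-study visit are labeled ``None`` under the
    default observed-case rule (``exclude``), or from their last observed
    visit under ``locf`` (requires ``visit_order``).
    """
    baseline = subject.baseline_total
    if baseline <= 0:
        raise ValueError(
            f"subject {subject.subject_id!r}: percent change undefined at baseline 0"
        )
    total = subject.post_baseline_totals.get(eos_visit)
    if total is None and missing_rule == "locf":
        if visit_order is None:
            raise ValueError("missing_rule='locf' requires visit_order")
        observed = [v for v in visit_order if v in subject.post_baseline_totals]
        if observed:
            total = subject.post_baseline_totals[observed[-1]]
    if total is None:
        return ResponseLabel(subject.subject_id, None, None)
    pct = (baseline - total) / baseline
    return ResponseLabel(subject.subject_id, int(pct >= threshold.percent_reduction), pct)


def label_dataset(
    dataset: TrialDataset,
    threshold: ThresholdSpec = HAMD17_RESPONSE_THRESHOLD,
    eos_visit: str | None = None,
    missing_rule: str = "exclude",
    arm: str | None = None,
) -> dict[str, ResponseLabel]:
    """Label every subject (optionally restricted to one arm)."""
    if eos_visit is None:
        eos_visit = dataset.visit_labels[-1]
    out = {}
    for rec in dataset.subjects:
        if arm is not None and rec.arm != arm:
            continue
        out[rec.subject_id] = label_response(
            rec, threshold, eos_visit, missing_rule, dataset.visit_labels
        )
    return out
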