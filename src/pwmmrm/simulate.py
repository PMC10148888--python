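"""Synthetic fixed-dose MDD trial generator with latent placebo propensity.

The generator produces trials with the statistical structure the
propensity-weighted analysis assumes but which no public dataset provides:
each subject carries a latent propensity ``pi`` to respond to placebo that
expresses itself twice —

1. **before randomization**, as a drift of the item-level scores between the
   screening and baseline visits (high-propensity subjects improve slightly
   while waiting to start treatment), making the 17-dimensional item-change
   vector informative about ``pi``; and
2. **after randomization**, as the asymptote of the placebo component of the
   change-from-baseline trajectory.

The drug component is additive in time but attenuated by the placebo
component (a subject already improving non-specifically has less room to
show a drug-specific effect), which is exactly the confounding mechanism the
inverse-propensity weighting is meant to undo: high-propensity subjects carry
a smaller realized drug effect, so the unweighted treatment-effect estimate
is pulled toward zero.

Default calibration targets a three-arm, 8-week paroxetine-CR-like trial:
arm sizes 156/154/149 (placebo last), baseline HAMD-17 totals around 23-24
with SD about 3, visits at weeks 1, 2, 3, 4, 6 and 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import HAMD17, ItemScale, SubjectRecord, TrialDataset
from .roc import roc_auc

__all__ = ["SimConfig", "SimTruth", "generate_trial", "propensity_oracle_auc",
           "confounded_config"]


@dataclass
class SimConfig:
    """Trial-generator settings.

    The defaults are the study conditions the package is tested under; every
    knob is a plain field so alternative scenarios (no signal, confounded
    propensity, matched covariance) are one ``replace`` away.
    """

    arms: tuple[str, ...] = ("active_12.5mg", "active_25mg", "placebo")
    arm_sizes: tuple[int, ...] = (156, 154, 149)
    placebo_arm: str = "placebo"
    visit_weeks: tuple[int, ...] = (1, 2, 3, 4, 6, 8)
    scale: ItemScale = field(default_factory=lambda: HAMD17)
    #: baseline total mean / SD per arm, same order as ``arms``
    baseline_mean: tuple[float, ...] = (23.13, 23.51, 23.81)
    baseline_sd: tuple[float, ...] = (2.89, 3.28, 3.23)
    #: latent propensity pi ~ Beta(a, b)
    propensity_beta: tuple[float, float] = (2.0, 2.0)
    #: expected fractional screening->baseline drift per unit propensity
    kappa: float = 0.12
    #: SD of the total screening->baseline drift noise (points)
    drift_sd: float = 1.5
    #: expected number of zero-sum one-point item swaps (test-retest scatter)
    item_jitter: float = 4.0
    #: placebo asymptotic fractional improvement a0 + a1 * pi
    placebo_asymptote: tuple[float, float] = (0.10, 0.55)
    #: exponential time constant of the placebo trajectory (weeks)
    placebo_tau: float = 2.5
    #: additive drug effect at week 8 (points of change; negative = benefit),
    #: linear in time and attenuated by the subject's placebo improvement
    drug_effect_week8: tuple[float, ...] = (-2.5, -4.0, 0.0)
    #: residual noise: compound-symmetric generator covariance
    resid_sd: float = 4.0
    resid_corr: float = 0.5
    #: optional full T x T covariance overriding the compound-symmetric one
    resid_cov: np.ndarray | None = None
    #: per-visit monotone dropout hazard
    dropout_hazard: float = 0.03
    #: fractional reduction defining a placebo responder
    response_threshold: float = 0.41
    seed: int | None = None

    def validate(self) -> None:
        if len(self.arm_sizes) != len(self.arms):
            raise ValueError("arm_sizes must match arms")
        if any(n < 1 for n in self.arm_sizes):
            raise ValueError("arm sizes must be at least 1")
        if self.placebo_arm not in self.arms:
            raise ValueError("placebo_arm must be one of arms")
        a, b = self.propensity_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        if not 0.0 <= self.dropout_hazard < 1.0:
            raise ValueError("dropout hazard must lie in [0, 1)")
        if len(self.drug_effect_week8) != len(self.arms):
            raise ValueError("drug_effect_week8 must match arms")
        if any(m >= self.scale.max_total for m in self.baseline_mean):
            raise ValueError("baseline mean above the scale maximum is infeasible")
        if any(w <= 0 for w in self.visit_weeks) or any(
            b <= a for a, b in zip(self.visit_weeks, self.visit_weeks[1:])
        ):
            raise ValueError("visit weeks must be positive and strictly increasing")


def confounded_config(**overrides) -> SimConfig:
    """A scenario with most propensity mass above 0.8 plus a low tail.

    The U-shaped Beta(0.8, 0.3) latent distribution concentrates subjects at
    high propensity (the pattern that inflates the placebo arm and masks the
    drug signal) while keeping enough low-propensity subjects for the
    low-removed sensitivity subset to be meaningful.  The pre-randomization
    drift signal is strengthened so the fitted propensity is informative.
    """
    cfg = SimConfig(propensity_beta=(0.8, 0.3), kappa=0.16, drift_sd=1.2)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


@dataclass
class SimTruth:
    """Ground truth for one generated trial."""

    frame: pd.DataFrame  # subject_id, arm, pi, true_label, drug_effect_week8
    true_te: dict[str, float]  # active arm -> mean realized drug effect at EOS

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)


def _apply_drift(
    items: np.ndarray,
    total_drift: int,
    maxima: np.ndarray,
    jitter_swaps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move ``total_drift`` points on/off the item vector, then apply
    zero-sum one-point swaps between items (test-retest scatter)."""
    out = items.astype(int).copy()
    step = 1 if total_drift > 0 else -1
    for _ in range(abs(int(total_drift))):
        room = np.nonzero(out < maxima)[0] if step > 0 else np.nonzero(out > 0)[0]
        if room.size == 0:
            break
        out[rng.choice(room)] += step
    for _ in range(jitter_swaps):
        src = np.nonzero(out > 0)[0]
        dst = np.nonzero(out < maxima)[0]
        if src.size == 0 or dst.size == 0:
            break
        out[rng.choice(src)] -= 1
        out[rng.choice(dst)] += 1
    return out


def _allocate_total(total: int, maxima: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Distribute ``total`` points over items, respecting per-item maxima."""
    items = np.zeros(maxima.size, dtype=int)
    cap = maxima.astype(int).copy()
    remaining = int(total)
    while remaining > 0 and cap.sum() > 0:
        probs = cap / cap.sum()
        add = rng.multinomial(remaining, probs)
        add = np.minimum(add, cap)
        items += add
        cap -= add
        remaining = total - int(items.sum())
    return items


def generate_trial(cfg: SimConfig, seed: int | None = None) -> tuple[TrialDataset, SimTruth]:
    """Generate one trial and its ground truth; deterministic given the seed."""
    cfg.validate()
    if seed is None:
        seed = cfg.seed if cfg.seed is not None else 0
    rng = np.random.default_rng(seed)

    maxima = np.asarray(cfg.scale.maxima)
    max_total = cfg.scale.max_total
    weeks = np.asarray(cfg.visit_weeks, dtype=float)
    T = weeks.size
    visit_labels = tuple(f"week{int(w)}" for w in cfg.visit_weeks)

    a, b = cfg.propensity_beta
    e_pi = a / (a + b)
    a0, a1 = cfg.placebo_asymptote

    if cfg.resid_cov is not None:
        cov = np.asarray(cfg.resid_cov, dtype=float)
        if cov.shape != (T, T):
            raise ValueError("resid_cov must be T x T")
    else:
        cov = cfg.resid_sd**2 * (
            (1 - cfg.resid_corr) * np.eye(T) + cfg.resid_corr * np.ones((T, T))
        )
    chol = np.linalg.cholesky(cov)

    subjects: list[SubjectRecord] = []
    truth_rows = []
    drug_at_eos: dict[str, list[float]] = {arm: [] for arm in cfg.arms}
    sid = 0
    for arm, n, mu_b, sd_b, drug8 in zip(
        cfg.arms, cfg.arm_sizes, cfg.baseline_mean, cfg.baseline_sd, cfg.drug_effect_week8
    ):
        # screening mean chosen so the expected baseline total hits the target
        mu_scr = mu_b / max(1.0 - cfg.kappa * e_pi, 1e-6)
        if mu_scr >= max_total:
            raise ValueError("infeasible config: screening mean above scale maximum")
        for _ in range(n):
            sid += 1
            pi = float(rng.beta(a, b))
            scr_total = int(np.clip(np.rint(rng.normal(mu_scr, sd_b)), 1, max_total))
            scr_items = _allocate_total(scr_total, maxima, rng)

            total_drift = int(
                np.clip(
                    np.rint(-cfg.kappa * pi * scr_total + rng.normal(0.0, cfg.drift_sd)),
                    -(scr_total - 1),
                    max_total - scr_total,
                )
            )
            n_swaps = int(rng.poisson(cfg.item_jitter))
            base_items = _apply_drift(scr_items, total_drift, maxima, n_swaps, rng)
            base_total = int(base_items.sum())

            asym = a0 + a1 * pi
            placebo_part = -asym * base_total * (1.0 - np.exp(-weeks / cfg.placebo_tau))
            drug_part = drug8 * (weeks / weeks[-1]) * (
                1.0 - asym * (1.0 - np.exp(-weeks / cfg.placebo_tau))
            )
            noise = chol @ rng.standard_normal(T)
            change = placebo_part + drug_part + noise
            totals_complete = np.clip(np.rint(base_total + change), 0, max_total).astype(int)

            # monotone dropout
            u = rng.random(T)
            dropped = np.nonzero(u < cfg.dropout_hazard)[0]
            last = dropped[0] if dropped.size else T
            totals = {visit_labels[t]: int(totals_complete[t]) for t in range(last)}

            days = int(min(4 + rng.poisson(3.5), 24))
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{sid:04d}",
                    arm=arm,
                    screening_items=tuple(int(v) for v in scr_items),
                    baseline_items=tuple(int(v) for v in base_items),
                    screening_to_baseline_days=days,
                    post_baseline_totals=totals,
                )
            )
            pct = (base_total - totals_complete[-1]) / base_total if base_total > 0 else 0.0
            drug_at_eos[arm].append(float(drug_part[-1]))
            truth_rows.append(
                {
                    "subject_id": f"S{sid:04d}",
                    "arm": arm,
                    "pi": pi,
                    "true_label": int(pct >= cfg.response_threshold),
                    "drug_effect_week8": float(drug_part[-1]),
                }
            )

    dataset = TrialDataset(
        subjects=subjects,
        visit_schedule=tuple(zip(visit_labels, cfg.visit_weeks)),
        arms=cfg.arms,
        placebo_arm=cfg.placebo_arm,
        scale=cfg.scale,
    )
    true_te = {
        arm: float(np.mean(v))
        for arm, v in drug_at_eos.items()
        if arm != cfg.placebo_arm
    }
    truth = SimTruth(frame=pd.DataFrame(truth_rows), true_te=true_te)
    return dataset, truth


def propensity_oracle_auc(truth: SimTruth, dataset: TrialDataset) -> float:
    """AUC of the *true* latent propensity for the placebo-arm response labels.

    This is the ceiling any fitted propensity model can approach: no function
    of the pre-randomization data can rank responders better than the latent
    propensity that generated them, up to sampling noise.
    """
    sub = truth.frame[truth.frame["arm"] == dataset.placebo_arm]
    return roc_auc(sub["pi"].to_numpy(), sub["true_label"].to_numpy())
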