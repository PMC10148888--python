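"""Placebo-response propensity: training split, topology search, weights.

The workflow mirrors how a propensity model is actually built for a trial
re-analysis: label the placebo arm for end-of-study response, split it 75/25
(stratified by label) into training and validation subsets, grid-search the
network topology by validation AUC, bootstrap the validation AUC for an
honest performance interval, then score *every* randomized subject and invert
the clipped probability into an analysis weight.

:class:`PlaceboPropensityModel` packages those steps in a model/results pair;
the individual operations remain importable for piecemeal use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialDataset, item_changes
from .labeling import HAMD17_RESPONSE_THRESHOLD, ThresholdSpec, label_dataset
from .mlp import MLPNet, TrainConfig, train_mlp
from .roc import ROCResult, bootstrap_auc_ci, roc_auc

__all__ = [
    "split_placebo",
    "default_candidates",
    "grid_search_topology",
    "predict_propensity",
    "PlaceboPropensityModel",
    "PropensityResults",
]


def split_placebo(
    subject_labels: dict[str, int],
    fraction: float = 0.75,
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """Partition labeled placebo subjects into training / validation id sets.

    Stratified by response label so both labels appear on both sides whenever
    counts permit; reproducible given ``seed``.  ``subject_labels`` maps
    subject id to the binary label (unlabeled subjects must be filtered out
    beforehand).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly in (0, 1)")
    if not subject_labels:
        raise ValueError("no labeled placebo subjects to split")
    rng = np.random.default_rng(seed)
    ids = sorted(subject_labels)
    labels = {0: [s for s in ids if subject_labels[s] == 0],
              1: [s for s in ids if subject_labels[s] == 1]}
    if not labels[0] or not labels[1]:
        warnings.warn("single response label present; falling back to a plain split")
        perm = list(rng.permutation(ids))
        k = int(round(fraction * len(ids)))
        return set(perm[:k]), set(perm[k:])
    train: set[str] = set()
    valid: set[str] = set()
    for lab in (0, 1):
        group = labels[lab]
        perm = list(rng.permutation(group))
        k = int(round(fraction * len(group)))
        k = min(max(k, 1), len(group) - 1) if len(group) >= 2 else k
        train.update(perm[:k])
        valid.update(perm[k:])
    return train, valid


def default_candidates(n_features: int = 17) -> list[tuple[int, ...]]:
    """Default topology grid: 1-3 hidden layers, 1..n_features lead nodes.

    Single-layer candidates sweep every width; deeper candidates taper each
    extra layer to half the previous one (a conventional funnel), keeping the
    grid exhaustive in the lead width while bounded in total size.
    """
    grid: list[tuple[int, ...]] = [(k,) for k in range(1, n_features + 1)]
    for k in range(2, n_features + 1):
        grid.append((k, max(1, math.ceil(k / 2))))
    for k in range(4, n_features + 1):
        grid.append((k, max(1, math.ceil(k / 2)), max(1, math.ceil(k / 4))))
    return grid


def _topology_seed(master_seed: int, index: int) -> int:
    # fixed per-candidate seed so the selection itself is reproducible
    return int((master_seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1))


def grid_search_topology(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_valid: np.ndarray,
    y_valid: np.ndarray,
    candidates: list[tuple[int, ...]] | None = None,
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[tuple[int, ...], pd.DataFrame, MLPNet]:
    """Exhaustively evaluate candidate topologies; select by validation AUC.

    Ties (within 1e-12) are broken by fewer total hidden nodes, then fewer
    layers.  Returns the winning topology, the full per-candidate score table
    for audit, and the winning trained network.
    """
    if candidates is None:
        candidates = default_candidates(X_train.shape[1])
    if not candidates:
        raise ValueError("empty topology grid")
    y_valid = np.asarray(y_valid).astype(int)
    if y_valid.min() == y_valid.max():
        raise ValueError("validation split must contain both labels")
    rows = []
    nets: list[MLPNet] = []
    for i, topo in enumerate(candidates):
        net = train_mlp(X_train, y_train, tuple(topo), cfg, seed=_topology_seed(seed, i))
        auc = roc_auc(net.forward(X_valid), y_valid)
        nets.append(net)
        rows.append(
            {
                "topology": tuple(topo),
                "n_layers": len(topo),
                "n_hidden_nodes": int(sum(topo)),
                "val_auc": auc,
                "final_train_loss": net.loss_trace[-1],
                "epochs": len(net.loss_trace) - 1,
            }
        )
    table = pd.DataFrame(rows)
    best_auc = table["val_auc"].max()
    tied = table.index[table["val_auc"] >= best_auc - 1e-12]
    sub = table.loc[tied].sort_values(
        ["n_hidden_nodes", "n_layers"], kind="stable"
    )
    winner = int(sub.index[0])
    return tuple(table.loc[winner, "topology"]), table, nets[winner]


def predict_propensity(
    model: MLPNet,
    dataset: TrialDataset,
    p_min: float = 0.05,
    p_max: float = 1.0,
) -> pd.DataFrame:
    """Score every subject and derive the inverse-probability analysis weight.

    ``weight = 1 / clip(p, p_min, p_max)``: the clip guards against the
    unbounded weights that raw near-zero probabilities would produce.  Set
    ``p_min=0, p_max=1`` to invert raw probabilities.  Returns a table with
    columns ``subject_id, arm, probability, weight``.
    """
    if not 0.0 <= p_min < p_max <= 1.0:
        raise ValueError("need 0 <= p_min < p_max <= 1")
    rows = []
    for rec in dataset.subjects:
        p = float(model.forward(item_changes(rec)[None, :])[0])
        pc = min(max(p, p_min), p_max)
        rows.append(
            {"subject_id": rec.subject_id, "arm": rec.arm, "probability": p,
             "weight": 1.0 / pc}
        )
    return pd.DataFrame(rows)


@dataclass
class PropensityResults:
    """Fitted propensity model plus everything needed to audit it."""

    net: MLPNet
    topology: tuple[int, ...]
    grid_table: pd.DataFrame
    roc: ROCResult
    table: pd.DataFrame  # subject_id, arm, probability, weight
    train_ids: set[str]
    valid_ids: set[str]
    n_unlabeled: int

    def weights(self) -> pd.Series:
        return self.table.set_index("subject_id")["weight"]

    def summary(self) -> str:
        lines = [
            "Placebo-response propensity model",
            "=" * 40,
            f"selected topology : {self.topology}",
            f"training subjects : {len(self.train_ids)}",
            f"validation subjects: {len(self.valid_ids)}",
            f"unlabeled (excluded from training): {self.n_unlabeled}",
            f"validation AUC    : {self.roc.auc:.3f} "
            f"({self.roc.level:.0%} CI {self.roc.ci_low:.3f}-{self.roc.ci_high:.3f}, "
            f"{self.roc.n_bootstrap} bootstrap resamples)",
        ]
        return "\n".join(lines)


@dataclass
class PlaceboPropensityModel:
    """End-to-end propensity estimation for one trial dataset.

    ``fit(seed)`` labels the placebo arm, splits it, grid-searches the
    topology, bootstraps the validation AUC and scores all subjects.
    """

    dataset: TrialDataset
    threshold: ThresholdSpec = HAMD17_RESPONSE_THRESHOLD
    split_fraction: float = 0.75
    candidates: list[tuple[int, ...]] | None = None
    train_config: TrainConfig = field(default_factory=TrainConfig)
    clip: tuple[float, float] = (0.05, 1.0)
    n_boot: int = 1000
    eos_visit: str | None = None

    def fit(self, seed: int = 0) -> PropensityResults:
        ds = self.dataset
        labels = label_dataset(ds, self.threshold, self.eos_visit, arm=ds.placebo_arm)
        labeled = {s: r.label for s, r in labels.items() if r.label is not None}
        n_unlabeled = sum(1 for r in labels.values() if r.label is None)
        if len(labeled) < 4:
            raise ValueError("too few labeled placebo subjects to train a model")
        train_ids, valid_ids = split_placebo(labeled, self.split_fraction, seed=seed)

        feat = {r.subject_id: item_changes(r) for r in ds.subjects}
        X_tr = np.array([feat[s] for s in sorted(train_ids)], dtype=float)
        y_tr = np.array([labeled[s] for s in sorted(train_ids)])
        X_va = np.array([feat[s] for s in sorted(valid_ids)], dtype=float)
        y_va = np.array([labeled[s] for s in sorted(valid_ids)])

        topology, grid_table, net = grid_search_topology(
            X_tr, y_tr, X_va, y_va, self.candidates, self.train_config, seed=seed
        )
        roc = bootstrap_auc_ci(
            net.forward(X_va), y_va, n_boot=self.n_boot, seed=seed + 1
        )
        table = predict_propensity(net, ds, *self.clip)
        return PropensityResults(
            net=net,
            topology=topology,
            grid_table=grid_table,
            roc=roc,
            table=table,
            train_ids=train_ids,
            valid_ids=valid_ids,
            n_unlabeled=n_unlabeled,
        )
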