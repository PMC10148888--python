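"""Shared test utilities: independent oracles and tiny dataset builders.

The REML oracle here deliberately shares nothing with the package's fit path:
it builds the full block-diagonal covariance densely, evaluates the
restricted likelihood with generic linear algebra, parameterizes the
covariance through a matrix exponential (not a Cholesky factor), and
maximizes with derivative-free Nelder-Mead from neutral starts.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import block_diag, expm
from scipy.optimize import minimize

from pwmmrm.data import SubjectRecord, TrialDataset


def make_subject(sid, arm, scr, base, totals=None, days=7):
    return SubjectRecord(
        subject_id=sid,
        arm=arm,
        screening_items=tuple(scr),
        baseline_items=tuple(base),
        screening_to_baseline_days=days,
        post_baseline_totals=dict(totals or {}),
    )


def tiny_trial() -> TrialDataset:
    """Six subjects, two arms, three visits, one sparse (missing week 4)."""
    base_a = (2, 2, 2, 1, 1, 1, 2, 2, 2, 2, 2, 1, 1, 1, 2, 0, 0)  # total 24
    scr_a = (3, 2, 2, 1, 1, 1, 2, 2, 2, 2, 2, 1, 1, 1, 2, 0, 1)   # total 26
    subs = [
        make_subject("P1", "placebo", scr_a, base_a, {"week2": 20, "week4": 18, "week8": 15}),
        make_subject("P2", "placebo", base_a, base_a, {"week2": 22, "week4": 20, "week8": 12}),
        make_subject("P3", "placebo", scr_a, base_a, {"week2": 23, "week8": 21}),
        make_subject("D1", "drug", scr_a, base_a, {"week2": 19, "week4": 15, "week8": 10}),
        make_subject("D2", "drug", base_a, base_a, {"week2": 21, "week4": 17, "week8": 14}),
        make_subject("D3", "drug", scr_a, base_a, {"week2": 22, "week4": 19, "week8": 16}),
    ]
    return TrialDataset(
        subjects=subs,
        visit_schedule=(("week2", 2), ("week4", 4), ("week8", 8)),
        arms=("placebo", "drug"),  # appearance order, preserved by I/O
        placebo_arm="placebo",
    )


def dense_reml_nll(svec: np.ndarray, design) -> float:
    """Dense restricted negative log-likelihood at Sigma = expm(sym(svec))."""
    T = design.T
    S = np.zeros((T, T))
    iu = np.triu_indices(T)
    S[iu] = svec
    S = S + S.T - np.diag(np.diag(S))
    Sigma = expm(S)
    Xs, ys, Vs = [], [], []
    for pat in design.patterns:
        sub = Sigma[np.ix_(pat.obs, pat.obs)]
        for i in range(pat.y.shape[0]):
            Xs.append(pat.X[i])
            ys.append(pat.y[i])
            Vs.append(sub / pat.w[i])
    V = block_diag(*Vs)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVX)
    N, p = X.shape
    return 0.5 * ((N - p) * np.log(2 * np.pi) + ld_v + ld_x + float(r @ Vi @ r))


def oracle_reml_fit(design):
    """Maximize the dense REML likelihood by Nelder-Mead from neutral starts."""
    T = design.T
    k = T * (T + 1) // 2
    best = None
    for start in (np.zeros(k), np.full(k, 1.0), np.r_[np.full(T, 3.0), np.zeros(k - T)]):
        res = minimize(
            dense_reml_nll,
            start,
            args=(design,),
            method="Nelder-Mead",
            options={"maxiter": 40000, "maxfev": 40000, "xatol": 1e-11, "fatol": 1e-13},
        )
        if best is None or res.fun < best.fun:
            best = res
    # recover beta at the oracle optimum
    S = np.zeros((T, T))
    iu = np.triu_indices(T)
    S[iu] = best.x
    S = S + S.T - np.diag(np.diag(S))
    Sigma = expm(S)
    XtVX = 0.0
    XtVy = 0.0
    for pat in design.patterns:
        sub = np.linalg.inv(Sigma[np.ix_(pat.obs, pat.obs)])
        XtVX = XtVX + np.einsum("i,itp,tu,iuq->pq", pat.w, pat.X, sub, pat.X)
        XtVy = XtVy + np.einsum("i,itp,tu,iu->p", pat.w, pat.X, sub, pat.y)
    beta = np.linalg.solve(XtVX, XtVy)
    return -best.fun, beta


def brute_force_auc(scores, labels) -> float:
    """Exhaustive Mann-Whitney pair count."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(1.0 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
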