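"""Weighted mixed model for repeated measures (MMRM) fit by REML.

Model
-----
For subject ``i`` with observed post-baseline visits ``obs(i)``, the change
from baseline ``y_i`` follows

    y_i ~ N(X_i beta,  Sigma[obs(i), obs(i)] / w_i)

with a single unstructured T x T covariance ``Sigma`` shared across subjects
and a positive per-subject weight ``w_i`` dividing the residual covariance
(the weighted-regression convention: a weight of 2 counts a subject like two
independent half-variance copies).  The fixed effects encode, in full-rank
form, visit-specific intercepts (the placebo mean at each visit), a
treatment x visit interaction with placebo as reference, a grand-mean-centered
baseline covariate and its baseline x visit interaction.  Under this coding
the treatment-by-visit coefficient *is* the covariate-adjusted treatment
effect (active minus placebo) at that visit.

``Sigma`` is parameterized by its Cholesky factor with log-transformed
diagonal, so every iterate is symmetric positive definite, and the restricted
log-likelihood (with ``beta`` profiled out) is maximized by L-BFGS-B with an
analytic gradient.  Degrees of freedom for contrasts use the Satterthwaite
approximation by default ("residual", N_obs - rank X, by switch).

Weights are internally normalized to mean one, which leaves the model
invariant (``Sigma`` absorbs the scale) and makes the fit exactly independent
of the overall weight scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .data import TrialDataset

__all__ = [
    "MMRMSpec",
    "MMRM",
    "MMRMResults",
    "TreatmentEffect",
    "build_design",
    "effect_size",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MMRMSpec:
    """Analysis settings shared by the pipeline and the sensitivity grid."""

    alpha: float = 0.05
    df_method: str = "satterthwaite"  # or "residual"
    analysis_visit: str | None = None  # None = last scheduled visit

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.df_method not in ("satterthwaite", "residual"):
            raise ValueError(f"unknown df method {self.df_method!r}")


@dataclass(frozen=True)
class TreatmentEffect:
    comparison: str
    visit: str
    te: float
    se: float
    df: float
    p: float
    effect_size: float
    n_active: int
    n_placebo: int
    ci_low: float
    ci_high: float


def effect_size(te: float, se: float, n1: int, n2: int) -> float:
    """Standardized effect size |TE| / pooled SD.

    The pooled SD is reconstructed from the contrast standard error as
    ``se / sqrt(1/n1 + 1/n2)`` — the two-sample identity relating the SE of a
    mean difference to the common SD.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be at least 1")
    pooled_sd = se / np.sqrt(1.0 / n1 + 1.0 / n2)
    return abs(te) / pooled_sd


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class _Pattern:
    obs: np.ndarray          # visit indices observed, shape (t,)
    X: np.ndarray            # (m, t, p)
    y: np.ndarray            # (m, t)
    w: np.ndarray            # (m,)
    subject_ids: list[str]


@dataclass
class Design:
    patterns: list[_Pattern]
    col_names: list[str]
    visit_labels: tuple[str, ...]
    arms: tuple[str, ...]
    placebo_arm: str
    grand_mean_baseline: float
    n_subjects: int
    n_obs: int
    n_dropped_subjects: int
    dropped_visits: tuple[str, ...]
    subjects_per_arm: dict[str, int]
    subjects_per_arm_visit: dict[tuple[str, str], int]

    @property
    def p(self) -> int:
        return len(self.col_names)

    @property
    def T(self) -> int:
        return len(self.visit_labels)


def build_design(
    data: pd.DataFrame,
    placebo_arm: str,
    weights: pd.Series | dict | None = None,
    visit_order: tuple[str, ...] | None = None,
) -> Design:
    """Assemble per-subject response vectors and design matrices.

    ``data`` is a long change-from-baseline table with columns
    ``subject_id, arm, visit, baseline, change`` (one row per observed
    subject x visit).  Visits observed for no subject are dropped with a
    warning; subjects with zero post-baseline rows never appear in ``data``
    and are counted by the caller.
    """
    required = {"subject_id", "arm", "visit", "baseline", "change"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"design table missing columns {sorted(missing)}")
    if data.empty:
        raise ValueError("no post-baseline observations to model")

    if visit_order is None:
        if "week" in data.columns:
            visit_order = tuple(
                data[["visit", "week"]].drop_duplicates().sort_values("week")["visit"]
            )
        else:
            visit_order = tuple(pd.unique(data["visit"]))
    observed_visits = set(data["visit"])
    dropped_visits = tuple(v for v in visit_order if v not in observed_visits)
    if dropped_visits:
        warnings.warn(f"visits observed for no subject dropped: {dropped_visits}")
    visits = tuple(v for v in visit_order if v in observed_visits)
    T = len(visits)
    visit_idx = {v: k for k, v in enumerate(visits)}

    arms = tuple(pd.unique(data["arm"]))
    if placebo_arm not in arms:
        raise ValueError(f"placebo arm {placebo_arm!r} absent from the data")
    active_arms = tuple(a for a in arms if a != placebo_arm)

    col_names = [f"visit[{v}]" for v in visits]
    for a in active_arms:
        col_names += [f"{a}:visit[{v}]" for v in visits]
    col_names.append("baseline_c")
    col_names += [f"baseline_c:visit[{v}]" for v in visits[1:]]
    p = len(col_names)
    col_idx = {c: k for k, c in enumerate(col_names)}

    per_subject = data.groupby("subject_id", sort=True)
    grand_mean_baseline = float(
        per_subject["baseline"].first().mean()
    )

    if weights is None:
        wmap = {}
    elif isinstance(weights, pd.Series):
        wmap = weights.to_dict()
    else:
        wmap = dict(weights)

    rows_by_pattern: dict[tuple[int, ...], _Pattern] = {}
    staging: dict[tuple[int, ...], list] = {}
    subjects_per_arm: dict[str, int] = {a: 0 for a in arms}
    cell_counts: dict[tuple[str, str], int] = {}
    for sid, grp in per_subject:
        grp = grp.sort_values("visit", key=lambda s: s.map(visit_idx))
        obs = tuple(visit_idx[v] for v in grp["visit"])
        if len(set(obs)) != len(obs):
            raise ValueError(f"duplicate visit rows for subject {sid!r}")
        arm = grp["arm"].iloc[0]
        subjects_per_arm[arm] += 1
        w = float(wmap.get(sid, 1.0))
        if w <= 0:
            raise ValueError(f"nonpositive weight for subject {sid!r}")
        base_c = float(grp["baseline"].iloc[0]) - grand_mean_baseline
        Xi = np.zeros((len(obs), p))
        for r, (v, ti) in enumerate(zip(grp["visit"], obs)):
            Xi[r, col_idx[f"visit[{v}]"]] = 1.0
            if arm != placebo_arm:
                Xi[r, col_idx[f"{arm}:visit[{v}]"]] = 1.0
            Xi[r, col_idx["baseline_c"]] = base_c
            if ti > 0:
                Xi[r, col_idx[f"baseline_c:visit[{v}]"]] = base_c
            cell_counts[(arm, v)] = cell_counts.get((arm, v), 0) + 1
        staging.setdefault(obs, []).append(
            (Xi, grp["change"].to_numpy(dtype=float), w, str(sid))
        )

    # normalize weights to mean 1 across the subjects actually used
    all_w = np.array([w for lst in staging.values() for _, _, w, _ in lst])
    wbar = all_w.mean()

    patterns = []
    n_obs = 0
    for obs, lst in sorted(staging.items()):
        X = np.stack([x for x, _, _, _ in lst])
        y = np.stack([yy for _, yy, _, _ in lst])
        w = np.array([w for _, _, w, _ in lst]) / wbar
        sids = [s for _, _, _, s in lst]
        patterns.append(_Pattern(np.array(obs), X, y, w, sids))
        n_obs += y.size

    design = Design(
        patterns=patterns,
        col_names=col_names,
        visit_labels=visits,
        arms=arms,
        placebo_arm=placebo_arm,
        grand_mean_baseline=grand_mean_baseline,
        n_subjects=int(all_w.size),
        n_obs=n_obs,
        n_dropped_subjects=0,
        dropped_visits=dropped_visits,
        subjects_per_arm=subjects_per_arm,
        subjects_per_arm_visit=cell_counts,
    )
    _prune_empty_columns(design)
    return design


def _prune_empty_columns(design: Design) -> None:
    """Drop all-zero columns (empty arm x visit cells) to keep X full rank."""
    p = design.p
    seen = np.zeros(p, dtype=bool)
    for pat in design.patterns:
        seen |= np.any(pat.X != 0.0, axis=(0, 1))
    if seen.all():
        return
    dropped = [c for c, s in zip(design.col_names, seen) if not s]
    warnings.warn(f"design columns with no data dropped: {dropped}")
    keep = np.nonzero(seen)[0]
    for pat in design.patterns:
        pat.X = pat.X[:, :, keep]
    design.col_names = [design.col_names[k] for k in keep]


# ---------------------------------------------------------------------------
# REML machinery (log-Cholesky parameterization)
# ---------------------------------------------------------------------------


def _theta_indices(T: int) -> list[tuple[int, int]]:
    """Lower-triangular (row, col) order: diagonal entries first."""
    idx = [(i, i) for i in range(T)]
    idx += [(i, j) for i in range(T) for j in range(i)]
    return idx


def _build_L(theta: np.ndarray, T: int) -> np.ndarray:
    L = np.zeros((T, T))
    idx = _theta_indices(T)
    for k, (i, j) in enumerate(idx):
        L[i, j] = np.exp(np.clip(theta[k], -30, 30)) if i == j else theta[k]
    return L


def _theta_from_sigma(Sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(Sigma)
    T = Sigma.shape[0]
    idx = _theta_indices(T)
    return np.array(
        [np.log(L[i, i]) if i == j else L[i, j] for (i, j) in idx]
    )


def _reml_nll_and_grad(theta: np.ndarray, design: Design, want_grad: bool = True):
    """Negative restricted log-likelihood (beta profiled out) and gradient."""
    T, p = design.T, design.p
    L = _build_L(theta, T)
    Sigma = L @ L.T

    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet_sum = 0.0
    cache = []
    for pat in design.patterns:
        Sg = Sigma[np.ix_(pat.obs, pat.obs)]
        try:
            cf = np.linalg.cholesky(Sg)
            Ag = linalg.cho_solve((cf, True), np.eye(Sg.shape[0]))
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        if not np.all(np.isfinite(Ag)):
            return 1e10, np.zeros_like(theta)
        logdet_g = 2.0 * float(np.sum(np.log(np.diag(cf))))
        m, t = pat.y.shape
        logdet_sum += m * logdet_g - t * float(np.sum(np.log(pat.w)))
        XtVX += np.einsum("i,itp,tu,iuq->pq", pat.w, pat.X, Ag, pat.X, optimize=True)
        XtVy += np.einsum("i,itp,tu,iu->p", pat.w, pat.X, Ag, pat.y, optimize=True)
        ytVy += float(np.einsum("i,it,tu,iu->", pat.w, pat.y, Ag, pat.y, optimize=True))
        cache.append(Ag)

    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return 1e10, np.zeros_like(theta)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    quad = ytVy - float(beta @ XtVy)
    N = design.n_obs
    ll = -0.5 * ((N - p) * np.log(2 * np.pi) + logdet_sum + logdet_XtVX + quad)
    if not want_grad:
        return -ll, None

    C = np.linalg.inv(XtVX)
    G = np.zeros((T, T))
    for pat, Ag in zip(design.patterns, cache):
        r = pat.y - np.einsum("itp,p->it", pat.X, beta)
        Ar = np.einsum("tu,iu->it", Ag, r)
        AX = np.einsum("tu,iup->itp", Ag, pat.X)
        m = pat.y.shape[0]
        S1 = m * Ag
        S2 = np.einsum("i,itp,pq,iuq->tu", pat.w, AX, C, AX, optimize=True)
        S3 = np.einsum("i,it,iu->tu", pat.w, Ar, Ar)
        G[np.ix_(pat.obs, pat.obs)] += S1 - S2 - S3

    GL = G @ L
    idx = _theta_indices(T)
    grad_ll = np.empty_like(theta)
    for k, (i, j) in enumerate(idx):
        g = -GL[i, j]
        if i == j:
            g *= L[i, i]
        grad_ll[k] = g
    return -ll, -grad_ll


def _gls_beta_cov(theta: np.ndarray, design: Design):
    """GLS solution and fixed-effect covariance at a given Sigma(theta)."""
    T, p = design.T, design.p
    Sigma = _build_L(theta, T) @ _build_L(theta, T).T
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    for pat in design.patterns:
        Sg = Sigma[np.ix_(pat.obs, pat.obs)]
        Ag = linalg.cho_solve(
            (np.linalg.cholesky(Sg), True), np.eye(Sg.shape[0])
        )
        XtVX += np.einsum("i,itp,tu,iuq->pq", pat.w, pat.X, Ag, pat.X, optimize=True)
        XtVy += np.einsum("i,itp,tu,iu->p", pat.w, pat.X, Ag, pat.y, optimize=True)
    C = np.linalg.inv(XtVX)
    return C @ XtVy, C


def _start_theta(design: Design) -> np.ndarray:
    """Diagonal start: per-visit residual variances from unweighted OLS."""
    T = design.T
    var = np.full(T, np.nan)
    # gather per-visit (change, arm, baseline) across patterns
    for ti in range(T):
        ys, Xs = [], []
        for pat in design.patterns:
            sel = np.nonzero(pat.obs == ti)[0]
            if sel.size:
                r = sel[0]
                ys.append(pat.y[:, r])
                Xs.append(pat.X[:, r, :])
        if not ys:
            continue
        yv = np.concatenate(ys)
        Xv = np.vstack(Xs)
        keep = np.any(Xv != 0, axis=0)
        Xv = Xv[:, keep]
        if yv.size > Xv.shape[1]:
            resid = yv - Xv @ np.linalg.lstsq(Xv, yv, rcond=None)[0]
            dof = max(yv.size - np.linalg.matrix_rank(Xv), 1)
            var[ti] = float(resid @ resid) / dof
        else:
            var[ti] = float(np.var(yv)) or 1.0
    var = np.where(np.isfinite(var) & (var > 0), var, np.nanmax(var[var > 0]) if np.any(var > 0) else 1.0)
    theta = np.zeros(T * (T + 1) // 2)
    theta[:T] = 0.5 * np.log(var)
    return theta


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------


class MMRM:
    """Mixed model for repeated measures on change from baseline.

    Parameters
    ----------
    data
        Long table with columns ``subject_id, arm, visit, baseline, change``
        (plus optional ``week`` used to order visits).
    placebo_arm
        Reference arm for the treatment x visit coding.
    weights
        Per-subject positive weights (mapping or Series indexed by subject
        id); missing subjects default to 1.  The inverse-propensity weights
        from :mod:`pwmmrm.propensity` plug in directly.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        placebo_arm: str,
        weights=None,
        visit_order: tuple[str, ...] | None = None,
    ):
        self.design = build_design(data, placebo_arm, weights, visit_order)

    @classmethod
    def from_dataset(cls, dataset: TrialDataset, weights=None) -> "MMRM":
        frame = dataset.changes_frame()
        n_total = dataset.n_subjects
        model = cls(
            frame,
            placebo_arm=dataset.placebo_arm,
            weights=weights,
            visit_order=dataset.visit_labels,
        )
        model.design.n_dropped_subjects = n_total - model.design.n_subjects
        return model

    def fit(self, maxiter: int = 500, start: np.ndarray | None = None) -> "MMRMResults":
        design = self.design
        if design.n_obs <= design.p:
            raise ValueError(
                f"{design.n_obs} observations cannot identify {design.p} fixed effects "
                "plus an unstructured covariance"
            )
        theta0 = _start_theta(design) if start is None else np.asarray(start, float)

        def objective(th):
            return _reml_nll_and_grad(th, design)

        res = optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
        )
        converged = bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-6
        if not converged:
            # ridge restart: inflate the diagonal and retry once
            restart = res.x.copy()
            restart[: design.T] += 0.5
            res2 = optimize.minimize(
                objective,
                restart,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
            )
            if res2.fun < res.fun:
                res = res2
            converged = bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-6

        theta, nll, hessian = self._newton_polish(res.x, float(res.fun))
        _, grad = _reml_nll_and_grad(theta, design)
        converged = converged or float(np.linalg.norm(grad)) < 1e-6
        Lhat = _build_L(theta, design.T)
        Sigma = Lhat @ Lhat.T
        beta, C = _gls_beta_cov(theta, design)
        return MMRMResults(
            design=design,
            theta=theta,
            sigma=Sigma,
            params=pd.Series(beta, index=design.col_names),
            cov=C,
            llf=-nll,
            converged=converged,
            _hessian=hessian,
        )

    def _newton_polish(self, theta: np.ndarray, nll: float):
        """Damped Newton steps with a fixed finite-difference Hessian.

        L-BFGS stops within ~1e-6 of the optimum; a few Newton iterations
        push the gradient to ~1e-10 so results are invariant to benign
        reparameterizations (e.g. rescaling all weights) at full precision.
        The Hessian is reused afterwards as the REML observed information.
        """
        design = self.design
        K = theta.size
        h = 1e-5
        H = np.zeros((K, K))
        for k in range(K):
            tp = theta.copy(); tp[k] += h
            tm = theta.copy(); tm[k] -= h
            _, gp = _reml_nll_and_grad(tp, design)
            _, gm = _reml_nll_and_grad(tm, design)
            H[k] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            return theta, nll, H
        _, g = _reml_nll_and_grad(theta, design)
        for _ in range(20):
            if float(np.linalg.norm(g)) < 1e-11:
                break
            step = np.linalg.solve(H, g)
            scale = 1.0
            for _ in range(20):
                cand = theta - scale * step
                nll_c, g_c = _reml_nll_and_grad(cand, design)
                if nll_c <= nll + 1e-12:
                    theta, nll, g = cand, nll_c, g_c
                    break
                scale *= 0.5
            else:
                break
        return theta, nll, H


@dataclass
class MMRMResults:
    """REML estimates, covariance, LS means and treatment-effect contrasts."""

    design: Design
    theta: np.ndarray
    sigma: np.ndarray
    params: pd.Series
    cov: np.ndarray
    llf: float
    converged: bool
    _hessian: np.ndarray | None = field(default=None, repr=False)

    # -- basic accessors --------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def n_subjects_used(self) -> int:
        return self.design.n_subjects

    @property
    def n_obs_used(self) -> int:
        return self.design.n_obs

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov, index=self.params.index, columns=self.params.index)

    def sigma_frame(self) -> pd.DataFrame:
        labs = list(self.design.visit_labels)
        return pd.DataFrame(self.sigma, index=labs, columns=labs)

    @property
    def resid_df(self) -> float:
        return float(self.design.n_obs - self.design.p)

    # -- LS means ----------------------------------------------------------
    def _lsmean_contrast(self, arm: str, visit: str) -> np.ndarray:
        cols = self.params.index
        c = np.zeros(len(cols))
        key = f"visit[{visit}]"
        if key not in cols:
            raise KeyError(f"visit {visit!r} not in the fitted model")
        c[cols.get_loc(key)] = 1.0
        if arm != self.design.placebo_arm:
            ikey = f"{arm}:visit[{visit}]"
            if ikey not in cols:
                raise KeyError(f"no data for arm {arm!r} at visit {visit!r}")
            c[cols.get_loc(ikey)] = 1.0
        # baseline columns are centered at the grand mean => contribute 0
        return c

    def ls_means(self, visit: str | None = None) -> pd.DataFrame:
        """Adjusted mean change per arm (at the grand-mean baseline)."""
        visits = [visit] if visit is not None else list(self.design.visit_labels)
        rows = []
        for v in visits:
            for arm in self.design.arms:
                try:
                    c = self._lsmean_contrast(arm, v)
                except KeyError:
                    continue
                est = float(c @ self.params.to_numpy())
                se = float(np.sqrt(c @ self.cov @ c))
                rows.append({"arm": arm, "visit": v, "ls_mean": est, "se": se})
        return pd.DataFrame(rows)

    # -- Satterthwaite machinery ------------------------------------------
    def _information(self) -> np.ndarray:
        if self._hessian is None:
            K = self.theta.size
            H = np.zeros((K, K))
            h = 1e-5
            for k in range(K):
                tp = self.theta.copy()
                tp[k] += h
                _, gp = _reml_nll_and_grad(tp, self.design)
                tm = self.theta.copy()
                tm[k] -= h
                _, gm = _reml_nll_and_grad(tm, self.design)
                H[k] = (gp - gm) / (2 * h)
            self._hessian = 0.5 * (H + H.T)  # observed information of the NLL
        return self._hessian

    def _satterthwaite_df(self, c: np.ndarray) -> float:
        var_c = float(c @ self.cov @ c)
        K = self.theta.size
        g = np.zeros(K)
        h = 1e-5
        for k in range(K):
            tp = self.theta.copy()
            tp[k] += h
            _, Cp = _gls_beta_cov(tp, self.design)
            tm = self.theta.copy()
            tm[k] -= h
            _, Cm = _gls_beta_cov(tm, self.design)
            g[k] = (float(c @ Cp @ c) - float(c @ Cm @ c)) / (2 * h)
        H = self._information()
        try:
            denom = float(g @ np.linalg.solve(H, g))
        except np.linalg.LinAlgError:
            denom = 0.0
        if denom <= 0:
            return self.resid_df
        df = 2.0 * var_c**2 / denom
        return float(min(max(df, 1.0), self.resid_df))

    # -- contrasts ---------------------------------------------------------
    def treatment_effect(
        self,
        active_arm: str,
        visit: str | None = None,
        alpha: float = 0.05,
        df_method: str = "satterthwaite",
    ) -> TreatmentEffect:
        """LS-mean difference (active - placebo) at ``visit`` with test and
        standardized effect size."""
        if visit is None:
            visit = self.design.visit_labels[-1]
        placebo = self.design.placebo_arm
        if active_arm not in self.design.arms:
            raise ValueError(f"arm {active_arm!r} absent from the fit")
        n_act = self.design.subjects_per_arm.get(active_arm, 0)
        n_pla = self.design.subjects_per_arm.get(placebo, 0)
        label = f"{active_arm}_vs_{placebo}"
        if active_arm == placebo:
            return TreatmentEffect(label, visit, 0.0, 0.0, self.resid_df, 1.0,
                                   0.0, n_act, n_pla, 0.0, 0.0)
        cols = self.params.index
        ikey = f"{active_arm}:visit[{visit}]"
        if ikey not in cols:
            raise ValueError(f"no estimable contrast for {active_arm!r} at {visit!r}")
        c = np.zeros(len(cols))
        c[cols.get_loc(ikey)] = 1.0
        te = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov @ c))
        df = (
            self._satterthwaite_df(c)
            if df_method == "satterthwaite"
            else self.resid_df
        )
        tval = te / se
        p = 2.0 * float(stats.t.sf(abs(tval), df))
        es = effect_size(te, se, n_act, n_pla)
        tcrit = float(stats.t.ppf(1 - alpha / 2.0, df))
        return TreatmentEffect(
            comparison=label,
            visit=visit,
            te=te,
            se=se,
            df=df,
            p=p,
            effect_size=es,
            n_active=n_act,
            n_placebo=n_pla,
            ci_low=te - tcrit * se,
            ci_high=te + tcrit * se,
        )

    # -- presentation ------------------------------------------------------
    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            "Mixed model for repeated measures (REML, unstructured covariance)",
            "=" * 68,
            f"subjects: {self.n_subjects_used}   observations: {self.n_obs_used}   "
            f"visits: {self.design.T}",
            f"REML log-likelihood: {self.llf:.4f}   converged: {self.converged}",
            "",
            "Fixed effects",
            "-" * 68,
        ]
        bse = self.bse
        for name, est in self.params.items():
            lines.append(f"{name:<36s} {est:>10.4f}  (SE {bse[name]:.4f})")
        lines += ["", "Treatment effects at the final visit", "-" * 68]
        for arm in self.design.arms:
            if arm == self.design.placebo_arm:
                continue
            try:
                eff = self.treatment_effect(arm, alpha=alpha)
            except ValueError:
                continue
            lines.append(
                f"{eff.comparison:<28s} TE {eff.te:>8.3f}  SE {eff.se:.3f}  "
                f"df {eff.df:6.1f}  p {eff.p:.4g}  ES {eff.effect_size:.3f}"
            )
        return "\n".join(lines)

    def plot_ls_means(self, ax=None):
        """Adjusted mean change trajectory per arm (diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lsm = self.ls_means()
        for arm, grp in lsm.groupby("arm"):
            ax.errorbar(
                range(len(grp)), grp["ls_mean"], yerr=grp["se"], label=arm, marker="o"
            )
        ax.set_xticks(range(self.design.T))
        ax.set_xticklabels(self.design.visit_labels)
        ax.set_ylabel("LS mean change from baseline")
        ax.legend()
        return ax
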