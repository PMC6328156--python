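"""Hierarchical spatial model of the cup-to-disc-ratio profile.

The profile ``Y_i`` of eye ``i`` is modelled as

    Y_{i,d} = x(d, group_i)' beta + d_i + e_{i,d},

with harmonic (sine/cosine) fixed effects of direction per diagnostic
group, a per-eye random intercept ``d_i ~ N(0, sigma_d^2)`` absorbing
between-eye disc-size variation, and iid error
``e_{i,d} ~ N(0, sigma_e^2)``.  The induced per-eye marginal covariance is
compound symmetric, ``V = sigma_d^2 J + sigma_e^2 I``, whose inverse and
determinant are available in closed form via the rank-one update identity
— estimation therefore scales linearly in the number of eyes and handles
missing directions exactly (each eye contributes its observed subset, no
imputation).

Variance components are estimated by restricted maximum likelihood
(REML; ML optionally, used for harmonic-order selection where candidate
models differ in their fixed effects), with the profiled Gaussian
likelihood optimised over ``(log sigma_d^2, log sigma_e^2)`` and the
boundary ``sigma_d = 0`` permitted and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import CONVENTION, N_DIRECTIONS, CDRProfile

MODEL_GROUPS = ("glaucoma", "healthy")  # column order: glaucoma block first


class ModelDataError(ValueError):
    """Input profiles unsuitable for fitting (labels, counts, rank)."""


class ConvergenceError(RuntimeError):
    """Variance-component optimisation failed to converge."""


# ---------------------------------------------------------------------------
# harmonic design
# ---------------------------------------------------------------------------


def n_fixed_effects(order: int) -> int:
    """Number of fixed-effect columns ``q = 2(1 + 2m)`` at harmonic order ``m``."""
    return 2 * (1 + 2 * order)


def design_labels(order: int) -> list[str]:
    """Column labels of the group-specific parametrization."""
    labels = ["G:intercept", "H:intercept"]
    for g in ("G", "H"):
        for k in range(1, order + 1):
            labels += [f"{g}:sin{k}", f"{g}:cos{k}"]
    return labels


def harmonic_basis(directions: np.ndarray, order: int) -> np.ndarray:
    """Columns ``sin(2 pi k d / 24), cos(2 pi k d / 24)`` for ``k = 1..order``."""
    d = np.asarray(directions, dtype=float).reshape(-1, 1)
    k = np.arange(1, order + 1, dtype=float)
    arg = 2.0 * np.pi * d * k / N_DIRECTIONS
    out = np.empty((d.shape[0], 2 * order))
    out[:, 0::2] = np.sin(arg)
    out[:, 1::2] = np.cos(arg)
    return out


def design_rows(directions: np.ndarray, group: str, order: int) -> np.ndarray:
    """Group-specific design rows for given directions (1-based)."""
    if group not in MODEL_GROUPS:
        raise ModelDataError(f"group must be one of {MODEL_GROUPS}, got {group!r}")
    n = len(np.atleast_1d(directions))
    q = n_fixed_effects(order)
    X = np.zeros((n, q))
    H = harmonic_basis(directions, order)
    if group == "glaucoma":
        X[:, 0] = 1.0
        X[:, 2 : 2 + 2 * order] = H
    else:
        X[:, 1] = 1.0
        X[:, 2 + 2 * order :] = H
    return X


@dataclass(frozen=True)
class DesignData:
    """Stacked design for the observed (eye, direction) pairs."""

    X: np.ndarray  # (n_obs, q)
    y: np.ndarray  # (n_obs,)
    eye_index: np.ndarray  # (n_obs,) integer codes 0..n_eyes-1
    eye_ids: list[str]
    directions: np.ndarray  # (n_obs,) 1-based direction index
    groups: np.ndarray  # (n_obs,) group label per row
    order: int
    labels: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_eyes(self) -> int:
        return len(self.eye_ids)


def build_design(profiles: list[CDRProfile], order: int) -> DesignData:
    """One design row per *observed* value; missing directions produce no row."""
    if not 1 <= order <= 5:
        raise ModelDataError(f"harmonic order must be in 1..5, got {order}")
    if not profiles:
        raise ModelDataError("no profiles supplied")
    bad = sorted({p.group for p in profiles} - set(MODEL_GROUPS))
    if bad:
        raise ModelDataError(
            f"profiles must be labelled healthy or glaucoma for fitting; found {bad}"
        )
    rows_X, rows_y, rows_e, rows_d, rows_g = [], [], [], [], []
    eye_ids: list[str] = []
    for p in profiles:
        mask = p.observed_mask
        d = np.nonzero(mask)[0] + 1
        rows_X.append(design_rows(d, p.group, order))
        rows_y.append(p.values[mask])
        rows_e.append(np.full(d.shape[0], len(eye_ids)))
        rows_d.append(d)
        rows_g.append(np.full(d.shape[0], p.group, dtype=object))
        eye_ids.append(p.eye_id)
    return DesignData(
        X=np.vstack(rows_X),
        y=np.concatenate(rows_y),
        eye_index=np.concatenate(rows_e).astype(int),
        eye_ids=eye_ids,
        directions=np.concatenate(rows_d).astype(int),
        groups=np.concatenate(rows_g),
        order=order,
        labels=design_labels(order),
    )


# ---------------------------------------------------------------------------
# REML engine for the random-intercept model
# ---------------------------------------------------------------------------


@dataclass
class SpatialModelFit:
    """A fitted random-intercept harmonic model."""

    order: int
    estimation: str
    beta: np.ndarray
    beta_labels: list[str]
    beta_cov: np.ndarray  # (X' V^-1 X)^-1 at the optimum
    sigma_d: float
    sigma_e: float
    log_likelihood: float
    aic: float
    bic: float
    n_eyes: int
    n_obs: int
    converged: bool
    boundary_sigma_d: bool = False
    convention: dict = field(default_factory=lambda: dict(CONVENTION))

    @property
    def q(self) -> int:
        return self.beta.shape[0]

    def group_mean_profile(self, group: str) -> np.ndarray:
        """Fitted mean CDR at directions ``d = 1..24`` for a group."""
        return design_rows(np.arange(1, N_DIRECTIONS + 1), group, self.order) @ self.beta


class _RandomInterceptLikelihood:
    """Profiled -2 log-likelihood of the random-intercept Gaussian model.

    Sufficient statistics are precomputed so each evaluation is
    O(n_eyes * q^2) regardless of the number of observations.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, eye_index: np.ndarray):
        self.n, self.q = X.shape
        self.E = int(eye_index.max()) + 1
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.m = np.bincount(eye_index, minlength=self.E).astype(float)
        if np.any(self.m == 0):
            raise ModelDataError("every eye must contribute >= 1 observed direction")
        self.Sx = np.zeros((self.E, self.q))
        np.add.at(self.Sx, eye_index, X)
        self.sy = np.bincount(eye_index, weights=y, minlength=self.E)

    def gls(self, sd2: float, se2: float):
        """GLS pieces at fixed variance components (rank-one inverse identity)."""
        denom = se2 + self.m * sd2
        gamma = sd2 / (se2 * denom)  # per-eye coefficient of the J correction
        A = self.XtX / se2 - (self.Sx.T * gamma) @ self.Sx
        b = self.Xty / se2 - self.Sx.T @ (gamma * self.sy)
        beta = np.linalg.solve(A, b)
        yVy = self.yty / se2 - float(gamma @ (self.sy * self.sy))
        quad = yVy - float(beta @ b)
        logdetV = (self.n - self.E) * np.log(se2) + float(np.log(denom).sum())
        return beta, A, quad, logdetV

    def neg2loglik(self, sd2: float, se2: float, estimation: str) -> float:
        beta, A, quad, logdetV = self.gls(sd2, se2)
        if estimation == "ML":
            return self.n * np.log(2.0 * np.pi) + logdetV + quad
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return (self.n - self.q) * np.log(2.0 * np.pi) + logdetV + logdetA + quad

    def profiled_pieces(self, lam: float):
        """GLS pieces with ``V = se2 * W``, ``W_i = I + lam J`` (lam = sd2/se2)."""
        c = lam / (1.0 + self.m * lam)
        A = self.XtX - (self.Sx.T * c) @ self.Sx
        b = self.Xty - self.Sx.T @ (c * self.sy)
        beta = np.linalg.solve(A, b)
        quad = self.yty - float(c @ (self.sy * self.sy)) - float(beta @ b)
        logdetW = float(np.log1p(self.m * lam).sum())
        return beta, A, quad, logdetW

    def profiled_neg2loglik(self, lam: float, estimation: str) -> tuple[float, float]:
        """-2 log-likelihood profiled over both beta and se2.

        Returns the criterion and the profiling ``se2`` at this ``lam``:
        ``se2 = quad / (n - q)`` for REML, ``quad / n`` for ML.
        """
        _, A, quad, logdetW = self.profiled_pieces(lam)
        if quad <= 0:
            return np.inf, np.nan
        if estimation == "ML":
            se2 = quad / self.n
            val = self.n * (np.log(2.0 * np.pi) + np.log(se2) + 1.0) + logdetW
        else:
            dof = self.n - self.q
            se2 = quad / dof
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf, np.nan
            val = dof * (np.log(2.0 * np.pi) + np.log(se2) + 1.0) + logdetW + logdetA
        return float(val), float(se2)

    def profiled_score(self, lam: float, estimation: str) -> float:
        """Analytic derivative of the profiled criterion with respect to lam.

        Used to polish the optimum by root finding: derivative-free
        minimisation alone cannot localise a flat quadratic optimum beyond
        about sqrt(machine epsilon).
        """
        c = lam / (1.0 + self.m * lam)
        cp = 1.0 / (1.0 + self.m * lam) ** 2  # d c / d lam
        A = self.XtX - (self.Sx.T * c) @ self.Sx
        b = self.Xty - self.Sx.T @ (c * self.sy)
        beta = np.linalg.solve(A, b)
        quad = self.yty - float(c @ (self.sy * self.sy)) - float(beta @ b)
        u = self.sy - self.Sx @ beta  # per-eye residual sums
        quad_p = -float(cp @ (u * u))  # envelope theorem at the GLS beta
        dlogdetW = float((self.m / (1.0 + self.m * lam)).sum())
        if estimation == "ML":
            return self.n * quad_p / quad + dlogdetW
        Z = np.linalg.solve(A, self.Sx.T)
        dlogdetA = -float(cp @ np.einsum("ij,ji->i", self.Sx, Z))
        return (self.n - self.q) * quad_p / quad + dlogdetW + dlogdetA


def _initial_components(lik: _RandomInterceptLikelihood, y, X, eye_index):
    """Moment starting values from the OLS residual decomposition."""
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta0
    rbar = np.bincount(eye_index, weights=r, minlength=lik.E) / lik.m
    within = r - rbar[eye_index]
    dof_w = max(lik.n - lik.E, 1)
    se2 = float(within @ within) / dof_w
    sd2 = max(float(np.var(rbar, ddof=1)) - se2 / float(lik.m.mean()), se2 / 10.0)
    return max(sd2, 1e-8), max(se2, 1e-10)


def reml_fit(
    profiles: list[CDRProfile],
    order: int = 2,
    estimation: str = "REML",
    min_eyes_per_group: int = 2,
) -> SpatialModelFit:
    """Fit the spatial model by (restricted) maximum likelihood.

    Deterministic given the data: the profiled likelihood is optimised by
    Nelder–Mead on the log-variance scale (tolerance 1e-13 on the
    objective) after a quasi-Newton warm start, with moment starting
    values.  A boundary solution ``sigma_d = 0`` is allowed and flagged.
    """
    if estimation not in ("REML", "ML"):
        raise ValueError(f"estimation must be REML or ML, got {estimation!r}")
    data = build_design(profiles, order)
    counts = {g: sum(1 for p in profiles if p.group == g) for g in MODEL_GROUPS}
    lacking = [g for g, c in counts.items() if c < min_eyes_per_group]
    if lacking:
        raise ModelDataError(
            f"need >= {min_eyes_per_group} eyes per group, insufficient: {lacking}"
        )
    return _fit_design(data, estimation)


_LOG_LAM_LO, _LOG_LAM_HI = -30.0, 12.0  # search range for log variance ratio


def _fit_design(data: DesignData, estimation: str) -> SpatialModelFit:
    lik = _RandomInterceptLikelihood(data.y, data.X, data.eye_index)
    sd2_0, se2_0 = _initial_components(lik, data.y, data.X, data.eye_index)
    t0 = float(np.clip(np.log(sd2_0 / se2_0), _LOG_LAM_LO + 1.0, _LOG_LAM_HI - 1.0))

    def objective(t: float) -> float:
        return lik.profiled_neg2loglik(float(np.exp(t)), estimation)[0]

    res = optimize.minimize_scalar(
        objective,
        bounds=(_LOG_LAM_LO, _LOG_LAM_HI),
        method="bounded",
        options={"xatol": 1e-13, "maxiter": 500},
    )
    # take the better of the bounded optimum and the warm start
    t_hat = res.x if objective(res.x) <= objective(t0) else t0
    converged = bool(res.success)
    # polish with the analytic score: bracket a sign change around t_hat
    score = lambda t: lik.profiled_score(float(np.exp(t)), estimation)
    lo, hi = t_hat - 0.5, t_hat + 0.5
    try:
        s_lo, s_hi = score(lo), score(hi)
        if np.isfinite(s_lo) and np.isfinite(s_hi) and s_lo < 0.0 < s_hi:
            t_hat = float(optimize.brentq(score, lo, hi, xtol=1e-14, rtol=1e-15))
            converged = True
    except (ValueError, np.linalg.LinAlgError):  # pragma: no cover - keep bounded optimum
        pass
    lam = float(np.exp(t_hat))
    _, se2 = lik.profiled_neg2loglik(lam, estimation)
    sd2 = lam * se2

    boundary = False
    if t_hat <= _LOG_LAM_LO + 1e-6 or sd2 < 1e-12 * se2:
        # random intercept vanishes: closed-form boundary fit
        boundary = True
        sd2, lam = 0.0, 0.0
        _, se2 = lik.profiled_neg2loglik(0.0, estimation)
    beta, A, _, _ = lik.gls(sd2, se2)
    neg2 = lik.neg2loglik(sd2, se2, estimation)
    loglik = -0.5 * neg2
    k = lik.q + 2  # fixed effects + two variance components
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(lik.n)
    return SpatialModelFit(
        order=data.order,
        estimation=estimation,
        beta=beta,
        beta_labels=list(data.labels),
        beta_cov=np.linalg.inv(A),
        sigma_d=float(np.sqrt(sd2)),
        sigma_e=float(np.sqrt(se2)),
        log_likelihood=float(loglik),
        aic=float(aic),
        bic=float(bic),
        n_eyes=data.n_eyes,
        n_obs=data.n_obs,
        converged=converged,
        boundary_sigma_d=boundary,
    )


# ---------------------------------------------------------------------------
# covariance helpers
# ---------------------------------------------------------------------------


def marginal_covariance(fit: SpatialModelFit, observed_count: int = N_DIRECTIONS) -> np.ndarray:
    """Compound-symmetric marginal covariance over ``m`` observed directions."""
    return compound_symmetric(fit.sigma_d, fit.sigma_e, observed_count)


def compound_symmetric(sigma_d: float, sigma_e: float, m: int) -> np.ndarray:
    if m < 1:
        raise ValueError("need at least one observed direction")
    return sigma_d**2 * np.ones((m, m)) + sigma_e**2 * np.eye(m)


def compound_symmetric_inverse(sigma_d: float, sigma_e: float, m: int) -> np.ndarray:
    """Analytic inverse via the rank-one (Sherman–Morrison) identity."""
    se2, sd2 = sigma_e**2, sigma_d**2
    coef = sd2 / (se2 * (se2 + m * sd2))
    return np.eye(m) / se2 - coef * np.ones((m, m))


def spatial_correlation(sigma_d: float, sigma_e: float) -> float:
    """Within-eye correlation between two directions: sigma_d^2 / (sigma_d^2 + sigma_e^2)."""
    return sigma_d**2 / (sigma_d**2 + sigma_e**2)


def icc(fit: SpatialModelFit) -> float:
    """Spatial (intra-eye) correlation implied by the fitted components."""
    return spatial_correlation(fit.sigma_d, fit.sigma_e)


# ---------------------------------------------------------------------------
# order selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrderSelection:
    table: pd.DataFrame  # columns: order, loglik, aic, bic, converged
    selected_order: int


def select_order(
    profiles: list[CDRProfile], orders=(1, 2, 3, 4, 5), criterion: str = "bic"
) -> OrderSelection:
    """Compare harmonic orders by ML information criteria.

    ML (not REML) likelihoods are used because the candidate models differ
    in their fixed effects; the reported selection minimises the chosen
    criterion (BIC by default) with ties broken toward the smaller order.
    Refit the winning order with REML for final reporting.
    """
    orders = sorted(set(int(m) for m in orders))
    if not orders:
        raise ValueError("no candidate orders supplied")
    rows = []
    for m in orders:
        try:
            f = reml_fit(profiles, order=m, estimation="ML")
            rows.append(
                {"order": m, "loglik": f.log_likelihood, "aic": f.aic, "bic": f.bic,
                 "converged": f.converged, "error": ""}
            )
        except (ModelDataError, np.linalg.LinAlgError) as exc:
            rows.append(
                {"order": m, "loglik": np.nan, "aic": np.nan, "bic": np.nan,
                 "converged": False, "error": str(exc)}
            )
    table = pd.DataFrame(rows)
    usable = table.dropna(subset=[criterion])
    if usable.empty:
        raise ModelDataError("no candidate order could be fitted")
    best = usable.sort_values([criterion, "order"], kind="stable").iloc[0]
    return OrderSelection(table=table, selected_order=int(best["order"]))


# ---------------------------------------------------------------------------
# fixed-effect tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedEffectTest:
    term: str
    num_df: int
    den_df: int
    F_statistic: float
    p_value: float
    chi2_p_value: float  # asymptotic chi-square version of the same Wald test


def _contrast_matrices(order: int) -> dict[str, np.ndarray]:
    """Wald contrasts on the group-specific parametrization.

    Intercept: mean of the two group intercepts.  Group: their difference.
    Direction: the 2m group-averaged harmonic coefficients.
    Direction x Group: the 2m group differences of harmonic coefficients.
    """
    q = n_fixed_effects(order)
    h = 2 * order
    gi, hi = 0, 1
    gh = slice(2, 2 + h)
    hh = slice(2 + h, 2 + 2 * h)
    L: dict[str, np.ndarray] = {}
    row = np.zeros((1, q)); row[0, gi] = row[0, hi] = 0.5
    L["Intercept"] = row
    row = np.zeros((1, q)); row[0, gi], row[0, hi] = 1.0, -1.0
    L["Group"] = row
    M = np.zeros((h, q)); M[:, gh] = 0.5 * np.eye(h); M[:, hh] = 0.5 * np.eye(h)
    L["Direction"] = M
    M = np.zeros((h, q)); M[:, gh] = np.eye(h); M[:, hh] = -np.eye(h)
    L["Direction x Group"] = M
    return L


def fixed_effect_tests(fit: SpatialModelFit) -> list[FixedEffectTest]:
    """Wald-type F tests of the fixed-effect terms.

    Denominator degrees of freedom use a containment-style convention:
    between-eye terms (Intercept, Group) get ``n_eyes - 2``; within-eye
    terms get ``n_obs - n_eyes - q + rank(L)``.  This is a reporting
    convention only — the asymptotic chi-square p-value is reported
    alongside and does not depend on it.
    """
    out = []
    for term, L in _contrast_matrices(fit.order).items():
        r = L.shape[0]
        Lb = L @ fit.beta
        mid = L @ fit.beta_cov @ L.T
        try:
            F = float(Lb @ np.linalg.solve(mid, Lb)) / r
        except np.linalg.LinAlgError as exc:
            raise ModelDataError(f"rank-deficient contrast for term {term!r}") from exc
        if term in ("Intercept", "Group"):
            den = fit.n_eyes - 2
        else:
            den = fit.n_obs - fit.n_eyes - fit.q + r
        out.append(
            FixedEffectTest(
                term=term,
                num_df=r,
                den_df=int(den),
                F_statistic=F,
                p_value=float(stats.f.sf(F, r, den)),
                chi2_p_value=float(stats.chi2.sf(r * F, r)),
            )
        )
    return out


def group_mean_profile(fit: SpatialModelFit, group: str) -> np.ndarray:
    """Fitted population mean CDR curve of a group at directions 1..24."""
    return fit.group_mean_profile(group)


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariogramResult:
    lags: np.ndarray  # angular lag in direction units (1..12)
    semivariance: np.ndarray
    slope: float
    slope_se: float
    slope_ci: tuple[float, float]  # 95% interval


def residual_diagnostics(
    fit: SpatialModelFit, profiles: list[CDRProfile]
) -> tuple[pd.DataFrame, VariogramResult]:
    """Conditional residuals and their empirical variogram over direction lag.

    Residuals subtract both the fixed effects and the BLUP of the per-eye
    random intercept.  A flat variogram (slope CI covering 0) is consistent
    with the assumed iid within-eye error; an increasing trend indicates
    residual spatial correlation the model does not capture.
    """
    data = build_design(profiles, fit.order)
    r_marg = data.y - data.X @ fit.beta
    m = np.bincount(data.eye_index).astype(float)
    sums = np.bincount(data.eye_index, weights=r_marg)
    sd2, se2 = fit.sigma_d**2, fit.sigma_e**2
    blup = sd2 * sums / (se2 + m * sd2)  # predicted random intercept per eye
    resid = r_marg - blup[data.eye_index]
    table = pd.DataFrame(
        {
            "eye_id": [data.eye_ids[i] for i in data.eye_index],
            "direction": data.directions,
            "group": data.groups,
            "residual": resid,
        }
    )
    # semivariance by circular angular lag, pooled over eyes
    max_lag = N_DIRECTIONS // 2
    sums_by_lag = np.zeros(max_lag)
    counts_by_lag = np.zeros(max_lag)
    for _, sub in table.groupby("eye_id", sort=False):
        d = sub["direction"].to_numpy()
        r = sub["residual"].to_numpy()
        dd = np.abs(d[:, None] - d[None, :])
        lag = np.minimum(dd, N_DIRECTIONS - dd)
        sq = 0.5 * (r[:, None] - r[None, :]) ** 2
        iu = np.triu_indices(len(d), k=1)
        lags_flat, sq_flat = lag[iu], sq[iu]
        for h in range(1, max_lag + 1):
            sel = lags_flat == h
            sums_by_lag[h - 1] += sq_flat[sel].sum()
            counts_by_lag[h - 1] += sel.sum()
    valid = counts_by_lag > 0
    lags = np.arange(1, max_lag + 1)[valid]
    gamma = sums_by_lag[valid] / counts_by_lag[valid]
    if lags.size >= 3:
        reg = stats.linregress(lags.astype(float), gamma)
        tcrit = stats.t.ppf(0.975, lags.size - 2)
        vg = VariogramResult(
            lags=lags,
            semivariance=gamma,
            slope=float(reg.slope),
            slope_se=float(reg.stderr),
            slope_ci=(float(reg.slope - tcrit * reg.stderr), float(reg.slope + tcrit * reg.stderr)),
        )
    else:  # pragma: no cover - tiny inputs
        vg = VariogramResult(lags, gamma, float("nan"), float("nan"), (float("nan"), float("nan")))
    return table, vg
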