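"""Empirical-Bayes discrimination on the cup-to-disc-ratio profile.

A new profile ``Y`` is scored against the two fitted group distributions
``N(mu_G, V)`` and ``N(mu_H, V)`` (common compound-symmetric covariance).
The posterior probability of glaucoma follows Bayes' theorem; because the
covariance is shared, the log odds reduce exactly to

    log odds = log(p_G / p_H) + (D_H - D_G) / 2,

where ``D_H`` and ``D_G`` are the squared Mahalanobis distances of ``Y``
from the healthy and glaucomatous mean profiles.  The difference
``D_H - D_G`` is the Disc Deformation Index: large positive values mean
the disc shape is more like glaucoma.  Missing directions are handled by
subsetting the means and covariance to the observed directions — both
group densities then live in the same dimension, so the comparison stays
well defined without imputation.

Both the density-ratio form and the Mahalanobis identity are evaluated on
every call and cross-checked; a disagreement indicates a numerical bug
and raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .geometry import CDRProfile, EmptyProfileError
from .model import (
    SpatialModelFit,
    compound_symmetric,
    compound_symmetric_inverse,
    reml_fit,
)

_DUALITY_TOL = 1e-9  # internal cross-check of the two posterior formulas


class EvaluationError(ValueError):
    """ROC/evaluation input invalid (single class, degenerate priors...)."""


@dataclass(frozen=True)
class GroupPriors:
    """Prior class probabilities; default to training-set proportions."""

    p_G: float
    p_H: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_G < 1.0 and 0.0 < self.p_H < 1.0):
            raise EvaluationError("priors must lie strictly in (0, 1)")
        if abs(self.p_G + self.p_H - 1.0) > 1e-12:
            raise EvaluationError("priors must sum to 1")

    @classmethod
    def from_labels(cls, labels) -> "GroupPriors":
        labels = list(labels)
        n_g = sum(1 for g in labels if g == "glaucoma")
        n_h = sum(1 for g in labels if g == "healthy")
        if n_g == 0 or n_h == 0:
            raise EvaluationError("both classes required to estimate priors")
        return cls(p_G=n_g / (n_g + n_h), p_H=n_h / (n_g + n_h))


@dataclass(frozen=True)
class ClassificationResult:
    eye_id: str
    D_H: float  # squared Mahalanobis distance to the healthy mean
    D_G: float  # squared Mahalanobis distance to the glaucoma mean
    ddi: float  # Disc Deformation Index = D_H - D_G
    log_odds: float
    posterior: float  # p_new,G
    n_used: int

    def decision(self, p_th: float) -> str:
        return classify(self, p_th)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def mahalanobis_to_group(
    profile: CDRProfile, fit: SpatialModelFit, group: str
) -> float:
    """Squared Mahalanobis distance of the observed profile subset to a group mean."""
    mask = profile.observed_mask
    m = int(mask.sum())
    if m == 0:
        raise EmptyProfileError(f"eye {profile.eye_id}: no observed direction")
    diff = profile.values[mask] - fit.group_mean_profile(group)[mask]
    se2, sd2 = fit.sigma_e**2, fit.sigma_d**2
    coef = sd2 / (se2 * (se2 + m * sd2))
    # diff' V_S^-1 diff with the rank-one analytic inverse
    return float(diff @ diff / se2 - coef * diff.sum() ** 2)


def _log_density(diff: np.ndarray, fit: SpatialModelFit) -> float:
    """Log MVN density (up to data-only constants shared by both groups)."""
    m = diff.shape[0]
    V = compound_symmetric(fit.sigma_d, fit.sigma_e, m)
    sign, logdet = np.linalg.slogdet(V)
    quad = float(diff @ np.linalg.solve(V, diff))
    return -0.5 * (m * math.log(2.0 * math.pi) + logdet + quad)


def posterior_probability(
    profile: CDRProfile, fit: SpatialModelFit, priors: GroupPriors
) -> ClassificationResult:
    """Posterior probability of glaucoma for a new profile.

    Evaluates the Bayes density-ratio form (in log space, dense solve) and
    the Mahalanobis/log-odds identity (analytic inverse); the two are
    cross-checked on every call.
    """
    mask = profile.observed_mask
    n_used = int(mask.sum())
    D_H = mahalanobis_to_group(profile, fit, "healthy")
    D_G = mahalanobis_to_group(profile, fit, "glaucoma")
    ddi = D_H - D_G
    log_odds = math.log(priors.p_G / priors.p_H) + 0.5 * ddi

    y = profile.values[mask]
    lg = _log_density(y - fit.group_mean_profile("glaucoma")[mask], fit)
    lh = _log_density(y - fit.group_mean_profile("healthy")[mask], fit)
    log_odds_density = math.log(priors.p_G) + lg - math.log(priors.p_H) - lh
    if abs(log_odds - log_odds_density) > _DUALITY_TOL * max(1.0, abs(log_odds)):
        raise AssertionError(
            "density-ratio and Mahalanobis log-odds disagree: "
            f"{log_odds_density} vs {log_odds}"
        )
    return ClassificationResult(
        eye_id=profile.eye_id,
        D_H=D_H,
        D_G=D_G,
        ddi=ddi,
        log_odds=log_odds,
        posterior=float(expit(log_odds)),
        n_used=n_used,
    )


def classify(result: ClassificationResult, p_th: float) -> str:
    """Decision rule: glaucoma iff the posterior is >= the threshold (inclusive)."""
    if not 0.0 < p_th < 1.0:
        raise EvaluationError(f"threshold must lie in (0, 1), got {p_th}")
    return "glaucoma" if result.posterior >= p_th else "healthy"


def score_profiles(
    profiles: list[CDRProfile], fit: SpatialModelFit, priors: GroupPriors
) -> list[ClassificationResult]:
    return [posterior_probability(p, fit, priors) for p in profiles]


# ---------------------------------------------------------------------------
# ROC evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray  # decreasing score thresholds
    sensitivity: np.ndarray  # TPR at score >= threshold
    specificity: np.ndarray  # 1 - FPR
    auroc: float
    optimal_threshold: float  # closest point to the (0, 1) corner

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve, tie-corrected AUROC and corner-optimal threshold.

    Positive class is ``glaucoma`` (or truthy/1 labels).  The optimal
    threshold minimises the Euclidean distance to the top-left corner,
    ties broken toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    if y.min() == y.max():
        raise EvaluationError("both classes must be present to evaluate a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    auroc = float(roc_auc_score(y, scores))
    dist2 = fpr**2 + (1.0 - tpr) ** 2
    # stable argmin over (distance, fpr): prefer higher specificity on ties
    order = np.lexsort((fpr, dist2))
    best = order[0]
    optimal = float(min(thr[best], scores.max()))  # sklearn pads thr[0] = max + 1
    return ROCCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auroc=auroc,
        optimal_threshold=optimal,
    )


def _binary_labels(labels) -> np.ndarray:
    out = []
    for g in labels:
        if isinstance(g, str):
            if g == "glaucoma":
                out.append(1)
            elif g == "healthy":
                out.append(0)
            else:
                raise EvaluationError(f"cannot use label {g!r} in a ROC evaluation")
        else:
            out.append(int(bool(g)))
    return np.asarray(out)


def confusion_at_threshold(posteriors, labels, p_th: float) -> dict:
    """Counts and rates of the inclusive threshold rule at ``p_th``."""
    post = np.asarray(posteriors, dtype=float)
    y = _binary_labels(labels)
    pred = post >= p_th
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    pos, neg = tp + fn, tn + fp
    return {
        "TP": tp,
        "FP": fp,
        "TN": tn,
        "FN": fn,
        "sensitivity": tp / pos if pos else float("nan"),
        "specificity": tn / neg if neg else float("nan"),
    }


# ---------------------------------------------------------------------------
# repeated-split evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitEvaluation:
    per_split: pd.DataFrame  # columns: split, auroc, sensitivity, specificity, threshold
    summary: dict  # mean/sd/min/max per metric


def repeated_split_evaluation(
    profiles: list[CDRProfile],
    n_splits: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    order: int = 2,
    max_resample: int = 200,
) -> SplitEvaluation:
    """Repeated random train/test split evaluation of the whole pipeline.

    Each split refits the spatial model on the training part, estimates
    priors from the training proportions, scores the test part, and
    records the AUROC together with sensitivity/specificity at the
    corner-optimal posterior threshold of that split.  Suspect/unknown
    eyes are excluded.  Deterministic given ``seed``.
    """
    labelled = [p for p in profiles if p.group in ("healthy", "glaucoma")]
    if not labelled:
        raise EvaluationError("no labelled profiles to evaluate")
    n = len(labelled)
    n_train = int(round(train_frac * n))
    if n_train < 4 or n - n_train < 2:
        raise EvaluationError("dataset too small for the requested split fraction")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_splits):
        for attempt in range(max_resample):
            idx = rng.permutation(n)
            train = [labelled[i] for i in idx[:n_train]]
            test = [labelled[i] for i in idx[n_train:]]
            tr_groups = {g: sum(1 for p in train if p.group == g) for g in ("healthy", "glaucoma")}
            te_groups = {p.group for p in test}
            if min(tr_groups.values()) >= 2 and len(te_groups) == 2:
                break
        else:
            raise EvaluationError(
                f"split {s}: a class stayed absent after {max_resample} resamples"
            )
        fit = reml_fit(train, order=order)
        priors = GroupPriors.from_labels(p.group for p in train)
        results = score_profiles(test, fit, priors)
        post = [r.posterior for r in results]
        labels = [p.group for p in test]
        roc = roc_curve(post, labels)
        conf = confusion_at_threshold(post, labels, max(min(roc.optimal_threshold, 1 - 1e-12), 1e-12))
        rows.append(
            {
                "split": s,
                "auroc": roc.auroc,
                "sensitivity": conf["sensitivity"],
                "specificity": conf["specificity"],
                "threshold": roc.optimal_threshold,
            }
        )
    per_split = pd.DataFrame(rows)
    summary = {}
    for metric in ("auroc", "sensitivity", "specificity"):
        col = per_split[metric]
        summary[metric] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            "min": float(col.min()),
            "max": float(col.max()),
        }
    return SplitEvaluation(per_split=per_split, summary=summary)


# ---------------------------------------------------------------------------
# screening yield
# ---------------------------------------------------------------------------


def screening_projection(
    population: int, prevalence: float, sensitivity: float, specificity: float
) -> dict:
    """Projected screening yield in a population.

    Rounds to the nearest person at each stage: detected cases are
    ``round(sensitivity * prevalence * population)``; referrals add the
    false positives ``round((1 - specificity) * (1 - prevalence) * population)``.
    """
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    cases = int(round(prevalence * population))
    true_positives = int(round(sensitivity * prevalence * population))
    false_positives = int(round((1.0 - specificity) * (1.0 - prevalence) * population))
    referred = true_positives + false_positives
    return {
        "cases": cases,
        "true_positives": true_positives,
        "false_negatives": cases - true_positives,
        "referred": referred,
        "spared": population - referred,
    }
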