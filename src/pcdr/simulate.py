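"""Synthetic cup-to-disc-ratio data with the model's statistical structure.

The generator is the generative reading of the spatial model: a group
harmonic mean curve, a per-eye Gaussian random intercept (SD
``sigma_d``), and iid within-eye Gaussian error (SD ``sigma_e``), with
optional MCAR missingness.  Default mean curves follow the qualitative
shapes seen in segmented fundus datasets — a healthy profile with two
maxima 180 degrees apart at the horizontal directions (peak 0.45, trough
0.30) and a flatter, uniformly higher glaucomatous profile (level 0.65,
harmonic amplitude 0.02) — with the default variance components
``sigma_d = 0.0892`` and ``sigma_e = 0.0414``.

Profiles whose 24 values do not all fall in (0, 1) are redrawn (not
clipped), so the retained sample is exactly Gaussian conditional on
landing in range; the redraw count is reported so unrealistic truth
settings are visible.  An ellipse-pair generator emits matching
segmentations with analytically known ground-truth profiles for the
geometry oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    N_DIRECTIONS,
    CDRProfile,
    DiscSegmentation,
    Ellipse,
    direction_vector,
    profile_angles_deg,
    _ray_distance,
)
from .model import design_rows, n_fixed_effects


class GenerationError(RuntimeError):
    """The requested configuration could not produce valid data."""


@dataclass(frozen=True)
class GenerativeTruth:
    """True parameters of the generative spatial model.

    ``beta`` follows the model column order: glaucoma intercept, healthy
    intercept, then per-group sine/cosine coefficients for harmonics
    ``k = 1..order`` (glaucoma block first).
    """

    order: int = 2
    beta: np.ndarray = field(
        default_factory=lambda: np.array(
            # glaucoma: 0.65 - 0.02 cos(4 pi d / 24)  (flat, high)
            # healthy : 0.375 - 0.075 cos(4 pi d / 24) (peaks 0.45 at d=6,18)
            [0.65, 0.375, 0.0, 0.0, 0.0, -0.02, 0.0, 0.0, 0.0, -0.075]
        )
    )
    sigma_d: float = 0.0892
    sigma_e: float = 0.0414
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != (n_fixed_effects(self.order),):
            raise GenerationError(
                f"beta must have {n_fixed_effects(self.order)} entries at order "
                f"{self.order}, got {beta.shape}"
            )
        object.__setattr__(self, "beta", beta)
        if not (self.sigma_d >= 0.0 and self.sigma_e > 0.0):
            raise GenerationError("require sigma_d >= 0 and sigma_e > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise GenerationError("missing_rate must lie in [0, 1)")
        for group in ("healthy", "glaucoma"):
            mu = self.mean_profile(group)
            if np.any((mu <= 0.0) | (mu >= 1.0)):
                raise GenerationError(
                    f"truth implies a {group} mean CDR outside (0, 1)"
                )

    def mean_profile(self, group: str) -> np.ndarray:
        return design_rows(np.arange(1, N_DIRECTIONS + 1), group, self.order) @ self.beta

    def delta_squared(self) -> float:
        """Squared Mahalanobis separation of the two group means under V."""
        delta = self.mean_profile("glaucoma") - self.mean_profile("healthy")
        se2, sd2 = self.sigma_e**2, self.sigma_d**2
        coef = sd2 / (se2 * (se2 + N_DIRECTIONS * sd2))
        return float(delta @ delta / se2 - coef * delta.sum() ** 2)

    def analytic_auroc(self) -> float:
        """Population AUROC of the log-odds score on complete profiles: Phi(Delta / sqrt 2)."""
        from scipy.stats import norm

        return float(norm.cdf(math.sqrt(self.delta_squared()) / math.sqrt(2.0)))

    @classmethod
    def overlapping(cls, seed: int = 0, missing_rate: float = 0.0) -> "GenerativeTruth":
        """A moderate-separation variant (analytic AUROC about 0.84).

        Useful when a check needs classification error to actually occur;
        the default truth separates the groups almost perfectly.
        """
        return cls(
            beta=np.array(
                [0.475, 0.375, 0.0, 0.0, 0.0, -0.065, 0.0, 0.0, 0.0, -0.075]
            ),
            seed=seed,
            missing_rate=missing_rate,
        )


# ---------------------------------------------------------------------------
# profile simulation
# ---------------------------------------------------------------------------


def simulate_profiles(
    truth: GenerativeTruth,
    n_healthy: int,
    n_glaucoma: int,
    rng: np.random.Generator | None = None,
    max_redraws: int = 10_000,
) -> tuple[list[CDRProfile], int]:
    """Draw labelled profiles from the generative model.

    Returns the profiles and the number of per-eye redraws needed to keep
    every value inside (0, 1).  Laterality alternates right/left (profiles
    are generated directly in the canonical orientation; laterality is
    carried as metadata).
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    profiles: list[CDRProfile] = []
    redraws = 0
    specs = [("healthy", n_healthy), ("glaucoma", n_glaucoma)]
    counter = 0
    for group, n in specs:
        mu = truth.mean_profile(group)
        for _ in range(n):
            for attempt in range(max_redraws):
                eye_level = rng.normal(0.0, truth.sigma_d)
                noise = rng.normal(0.0, truth.sigma_e, N_DIRECTIONS)
                values = mu + eye_level + noise
                if np.all((values > 0.0) & (values < 1.0)):
                    break
                redraws += 1
            else:
                raise GenerationError(
                    "could not draw an in-range profile; the truth parameters "
                    "are unrealistic for CDR data"
                )
            if truth.missing_rate > 0.0:
                values = _mask_one(values, truth.missing_rate, rng)
            laterality = "right" if counter % 2 == 0 else "left"
            profiles.append(
                CDRProfile(
                    eye_id=f"sim-{group[0]}{counter:05d}",
                    laterality=laterality,
                    group=group,
                    values=values,
                )
            )
            counter += 1
    return profiles, redraws


def _mask_one(values: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    for _ in range(1000):
        mask = rng.random(N_DIRECTIONS) < rate
        if not mask.all():
            out = values.copy()
            out[mask] = np.nan
            return out
    raise GenerationError("missingness redraw failed to keep one observed value")


def inject_missingness(
    profiles: list[CDRProfile], rate: float, seed: int = 0, mechanism: str = "MCAR"
) -> list[CDRProfile]:
    """Mask observed values independently with probability ``rate`` (MCAR).

    Each eye is guaranteed to keep at least one observed value (the mask
    is redrawn otherwise).
    """
    if mechanism != "MCAR":
        raise GenerationError(f"unsupported missingness mechanism {mechanism!r}")
    if not 0.0 <= rate <= 0.9:
        raise GenerationError(f"rate must lie in [0, 0.9], got {rate}")
    if rate == 0.0:
        return list(profiles)
    rng = np.random.default_rng(seed)
    out = []
    for p in profiles:
        values = p.values.copy()
        obs_idx = np.nonzero(p.observed_mask)[0]
        for _ in range(1000):
            mask = rng.random(obs_idx.size) < rate
            if not mask.all():
                break
        else:
            raise GenerationError("missingness redraw failed to keep one observed value")
        values[obs_idx[mask]] = np.nan
        out.append(replace(p, values=values))
    return out


# ---------------------------------------------------------------------------
# segmentation simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentationTruth:
    """A generated segmentation together with its analytic ground-truth pCDR."""

    segmentation: DiscSegmentation
    pcdr: np.ndarray  # 24 canonical CDR values, computed analytically


def simulate_segmentations(
    n: int,
    seed: int = 0,
    group_mix: float = 0.5,
    disc_radius_range: tuple[float, float] = (80.0, 120.0),
    healthy_cup_scale: tuple[float, float] = (0.30, 0.50),
    glaucoma_cup_scale: tuple[float, float] = (0.60, 0.80),
    max_retries: int = 200,
) -> list[SegmentationTruth]:
    """Random labelled cup/disc ellipse pairs with analytic ground truth.

    Disc ellipses have random size, eccentricity and rotation; cup axes
    are the disc axes times a group-dependent scale (with a small
    independent per-axis jitter) and the cup centre is offset randomly,
    constrained so the cup stays strictly inside the disc.
    """
    if n < 1:
        raise GenerationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[SegmentationTruth] = []
    angles = profile_angles_deg()
    for i in range(n):
        group = "glaucoma" if rng.random() < group_mix else "healthy"
        lo, hi = glaucoma_cup_scale if group == "glaucoma" else healthy_cup_scale
        laterality = "right" if i % 2 == 0 else "left"
        for _ in range(max_retries):
            a_disc = rng.uniform(*disc_radius_range)
            b_disc = a_disc * rng.uniform(0.8, 1.0)
            rot = rng.uniform(0.0, math.pi)
            cx, cy = rng.uniform(200.0, 400.0, size=2)
            disc = Ellipse(cx, cy, a_disc, b_disc, rot)
            s = rng.uniform(lo, hi)
            jitter = rng.uniform(0.95, 1.05, size=2)
            axes = np.sort(np.array([s * a_disc * jitter[0], s * b_disc * jitter[1]]))[::-1]
            offset = rng.uniform(-0.1, 0.1, size=2) * b_disc
            try:
                cup = Ellipse(cx + offset[0], cy + offset[1], axes[0], axes[1], rot)
            except ValueError:  # pragma: no cover - axes always positive here
                continue
            if not disc.contains((cup.center_x, cup.center_y)):
                continue
            pcdr = _analytic_pcdr(cup, disc, laterality, angles)
            if pcdr is None:
                continue
            seg = DiscSegmentation(
                eye_id=f"seg-{group[0]}{i:05d}",
                laterality=laterality,
                cup=cup,
                disc=disc,
                group=group,
            )
            out.append(SegmentationTruth(segmentation=seg, pcdr=pcdr))
            break
        else:
            raise GenerationError(
                f"could not place cup inside disc after {max_retries} retries"
            )
    return out


def _analytic_pcdr(cup, disc, laterality, angles) -> np.ndarray | None:
    origin = cup.center
    values = np.empty(N_DIRECTIONS)
    for j, angle in enumerate(angles):
        u = direction_vector(angle, laterality)
        t_cup = _ray_distance(cup, origin, u)
        t_disc = _ray_distance(disc, origin, u)
        if t_cup >= t_disc:
            return None  # cup pokes out of the disc; reject and retry
        values[j] = t_cup / t_disc
    return values
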