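"""File formats and run configuration.

Plain-text interchange formats:

* Landmarks CSV: ``eye_id, laterality, structure, x, y`` — one boundary
  point per row (pixels, 0-based, y down).
* Segmentation CSV: ``eye_id, laterality, structure, center_x, center_y,
  semi_major, semi_minor, rotation_rad`` — one ellipse per row.
* Profile CSV: ``eye_id, laterality, group, d01..d24`` — empty cells are
  missing directions.
* Model JSON: fitted parameters plus the angle-convention block, so a
  model can refuse profiles extracted under a different convention.

Header names are authoritative: readers select columns by name and reject
files whose schema does not match, naming the offending line where a row
is malformed.  Writers accept a metadata mapping (seed, config hash)
emitted as leading ``#`` comment lines; readers skip comments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    CONVENTION,
    N_DIRECTIONS,
    CDRProfile,
    DiscSegmentation,
    Ellipse,
    LandmarkSet,
)
from .model import SpatialModelFit, design_labels

DIRECTION_COLUMNS = [f"d{d:02d}" for d in range(1, N_DIRECTIONS + 1)]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared across pipeline commands."""

    angle_zero: str = "superior"
    mirror: str = "left"
    y_down: bool = True
    order: int | str = 2  # integer harmonic order or "auto"
    estimation: str = "REML"
    priors_mode: str = "proportions"  # or "fixed"
    prior_glaucoma: float | None = None  # used when priors_mode == "fixed"
    threshold_mode: str = "fixed"  # or "optimal-roc"
    threshold: float = 0.9
    seed: int = 0

    def convention(self) -> dict:
        return {"angle_zero": self.angle_zero, "mirror": self.mirror, "y_down": self.y_down}

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def metadata(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path, metadata: dict | None) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, comment="#", dtype={"eye_id": str}, float_precision="round_trip"
        )
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _line_lookup(path) -> dict[int, int]:
    """Map dataframe row index -> 1-based physical line, skipping comments."""
    lines = {}
    row = 0
    with open(path) as fh:
        header_seen = False
        for lineno, text in enumerate(fh, start=1):
            if text.lstrip().startswith("#") or not text.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            lines[row] = lineno
            row += 1
    return lines


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def write_profiles(profiles: list[CDRProfile], path, metadata: dict | None = None) -> None:
    rows = []
    for p in profiles:
        row = {"eye_id": p.eye_id, "laterality": p.laterality, "group": p.group}
        for j, col in enumerate(DIRECTION_COLUMNS):
            v = p.values[j]
            row[col] = "" if np.isnan(v) else repr(float(v))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["eye_id", "laterality", "group"] + DIRECTION_COLUMNS)
    _write_csv(df, path, metadata)


def read_profiles(path) -> list[CDRProfile]:
    df = _read_csv(path, ["eye_id", "laterality", "group"] + DIRECTION_COLUMNS)
    lines = _line_lookup(path)
    seen: set[str] = set()
    out = []
    for i, row in df.iterrows():
        where = f"{path}:{lines.get(i, '?')}"
        eye = str(row["eye_id"])
        if eye in seen:
            raise SchemaError(f"{where}: duplicate eye_id {eye!r}")
        seen.add(eye)
        values = np.full(N_DIRECTIONS, np.nan)
        for j, col in enumerate(DIRECTION_COLUMNS):
            cell = row[col]
            if pd.isna(cell) or (isinstance(cell, str) and cell.strip() == ""):
                continue
            try:
                values[j] = float(cell)
            except (TypeError, ValueError):
                raise SchemaError(f"{where}: non-numeric value {cell!r} in {col}") from None
        try:
            out.append(
                CDRProfile(eye, str(row["laterality"]), str(row["group"]), values)
            )
        except ValueError as exc:
            raise SchemaError(f"{where}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# segmentations and landmarks
# ---------------------------------------------------------------------------

_SEG_COLUMNS = [
    "eye_id", "laterality", "structure",
    "center_x", "center_y", "semi_major", "semi_minor", "rotation_rad",
]


def write_segmentations(
    segs: list[DiscSegmentation], path, metadata: dict | None = None
) -> None:
    rows = []
    for s in segs:
        for structure, e in (("cup", s.cup), ("disc", s.disc)):
            rows.append(
                {
                    "eye_id": s.eye_id, "laterality": s.laterality,
                    "structure": structure, "group": s.group,
                    "center_x": e.center_x, "center_y": e.center_y,
                    "semi_major": e.semi_major, "semi_minor": e.semi_minor,
                    "rotation_rad": e.rotation,
                }
            )
    _write_csv(pd.DataFrame(rows), path, metadata)


def read_segmentations(path) -> list[DiscSegmentation]:
    df = _read_csv(path, _SEG_COLUMNS)
    lines = _line_lookup(path)
    have_group = "group" in df.columns
    parts: dict[str, dict] = {}
    for i, row in df.iterrows():
        where = f"{path}:{lines.get(i, '?')}"
        eye = str(row["eye_id"])
        structure = str(row["structure"])
        if structure not in ("cup", "disc"):
            raise SchemaError(f"{where}: structure must be cup|disc, got {structure!r}")
        entry = parts.setdefault(eye, {"laterality": str(row["laterality"])})
        if have_group and not pd.isna(row["group"]):
            entry["group"] = str(row["group"])
        if structure in entry:
            raise SchemaError(f"{where}: duplicate ({eye!r}, {structure!r})")
        try:
            entry[structure] = Ellipse(
                float(row["center_x"]), float(row["center_y"]),
                float(row["semi_major"]), float(row["semi_minor"]),
                float(row["rotation_rad"]),
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{where}: {exc}") from None
    out = []
    for eye, entry in parts.items():
        if "cup" not in entry or "disc" not in entry:
            raise SchemaError(f"{path}: eye {eye!r} lacks a cup or disc row")
        out.append(
            DiscSegmentation(
                eye_id=eye,
                laterality=entry["laterality"],
                cup=entry["cup"],
                disc=entry["disc"],
                group=entry.get("group", "unknown"),
            )
        )
    return out


def read_landmarks(path) -> tuple[dict[tuple[str, str], LandmarkSet], dict[str, str]]:
    """Landmark sets keyed by (eye_id, structure), plus eye laterality map."""
    df = _read_csv(path, ["eye_id", "laterality", "structure", "x", "y"])
    lines = _line_lookup(path)
    points: dict[tuple[str, str], list] = {}
    laterality: dict[str, str] = {}
    seen_rows: set[tuple] = set()
    for i, row in df.iterrows():
        where = f"{path}:{lines.get(i, '?')}"
        eye, structure = str(row["eye_id"]), str(row["structure"])
        if structure not in ("cup", "disc"):
            raise SchemaError(f"{where}: structure must be cup|disc, got {structure!r}")
        try:
            x, y = float(row["x"]), float(row["y"])
        except (TypeError, ValueError):
            raise SchemaError(f"{where}: non-numeric coordinate") from None
        key = (eye, structure, x, y)
        if key in seen_rows:
            raise SchemaError(f"{where}: duplicate landmark for ({eye!r}, {structure!r})")
        seen_rows.add(key)
        laterality.setdefault(eye, str(row["laterality"]))
        points.setdefault((eye, structure), []).append((x, y))
    sets = {
        key: LandmarkSet(eye_id=key[0], structure=key[1], points=np.array(pts))
        for key, pts in points.items()
    }
    return sets, laterality


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------


def write_predictions(results, decisions, p_th: float, path, metadata=None) -> None:
    rows = [
        {
            "eye_id": r.eye_id, "n_used": r.n_used, "D_H": r.D_H, "D_G": r.D_G,
            "ddi": r.ddi, "log_odds": r.log_odds, "posterior": r.posterior,
            "decision": d, "threshold": p_th,
        }
        for r, d in zip(results, decisions)
    ]
    _write_csv(pd.DataFrame(rows), path, metadata)


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------


def write_model_json(
    fit: SpatialModelFit, path, priors=None, metadata: dict | None = None
) -> None:
    payload = {
        "order": fit.order,
        "parametrization": "group-specific",
        "beta": {label: float(b) for label, b in zip(fit.beta_labels, fit.beta)},
        "sigma_d": fit.sigma_d,
        "sigma_e": fit.sigma_e,
        "estimation": fit.estimation,
        "loglik": fit.log_likelihood,
        "aic": fit.aic,
        "bic": fit.bic,
        "n_eyes": fit.n_eyes,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "boundary_sigma_d": fit.boundary_sigma_d,
        "information_criteria_note": "k = q + 2 parameters; BIC sample size = n_obs",
        "convention": dict(fit.convention),
    }
    if priors is not None:
        payload["priors"] = {"p_G": priors.p_G, "p_H": priors.p_H}
    if metadata:
        payload["metadata"] = dict(metadata)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_json(path, expected_convention: dict | None = None) -> tuple[SpatialModelFit, dict | None]:
    with open(path) as fh:
        payload = json.load(fh)
    convention = payload.get("convention", dict(CONVENTION))
    if expected_convention is not None and convention != expected_convention:
        raise SchemaError(
            f"{path}: model convention {convention} does not match the configured "
            f"convention {expected_convention}; refusing to apply the model"
        )
    order = int(payload["order"])
    labels = design_labels(order)
    beta_map = payload["beta"]
    missing = [l for l in labels if l not in beta_map]
    if missing:
        raise SchemaError(f"{path}: model JSON lacks coefficients {missing}")
    q = len(labels)
    fit = SpatialModelFit(
        order=order,
        estimation=str(payload.get("estimation", "REML")),
        beta=np.array([float(beta_map[l]) for l in labels]),
        beta_labels=labels,
        beta_cov=np.full((q, q), np.nan),  # not serialised; tests/reports refit
        sigma_d=float(payload["sigma_d"]),
        sigma_e=float(payload["sigma_e"]),
        log_likelihood=float(payload.get("loglik", np.nan)),
        aic=float(payload.get("aic", np.nan)),
        bic=float(payload.get("bic", np.nan)),
        n_eyes=int(payload.get("n_eyes", 0)),
        n_obs=int(payload.get("n_obs", 0)),
        converged=bool(payload.get("converged", True)),
        boundary_sigma_d=bool(payload.get("boundary_sigma_d", False)),
        convention=convention,
    )
    priors = payload.get("priors")
    return fit, priors


def write_fit_report(fit: SpatialModelFit, tests, path) -> None:
    """Plain-text fit report: term table, variance SDs, spatial correlation."""
    from .model import icc

    lines = [
        "Spatial model of the cup-to-disc-ratio profile",
        f"harmonic order {fit.order} (q = {fit.q} fixed effects), "
        f"estimation {fit.estimation}",
        f"n_eyes = {fit.n_eyes}, n_obs = {fit.n_obs}",
        "",
        f"{'term':<20}{'num df':>8}{'den df':>8}{'F':>14}{'p':>12}",
    ]
    for t in tests:
        p = "<0.001" if t.p_value < 0.001 else f"{t.p_value:.3f}"
        lines.append(
            f"{t.term:<20}{t.num_df:>8}{t.den_df:>8}{t.F_statistic:>14.3f}{p:>12}"
        )
    lines += [
        "",
        f"Between-eye variation, SD   {fit.sigma_d:.4f}",
        f"Within-subject variation, SD {fit.sigma_e:.4f}",
        f"Spatial correlation          {icc(fit):.4f}",
        f"loglik {fit.log_likelihood:.3f}  AIC {fit.aic:.3f}  BIC {fit.bic:.3f}",
        "",
    ]
    Path(path).write_text("\n".join(lines))
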