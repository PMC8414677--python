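"""Synthetic bilateral cohorts of Meckel-cave-like masks with known truth.

The study's MRI segmentations are not publicly deposited, so every
downstream stage is exercised on phantoms: solid rotated ellipsoids whose
flatness is set exactly through the semi-axis ratio ``c/a`` (in the
continuum, flatness of a uniform solid ellipsoid is ``c/a``) and whose
volume is set through ``abc`` scaling.  Real Meckel caves are closer to an
open three-fingered glove than an ellipsoid, but only the size/flatness
statistics matter downstream, so ellipsoids with matched feature envelopes
suffice.

Cohort defaults reproduce the published study design: 115 patients with
primary trigeminal neuralgia (PTN) and 46 healthy controls (HC), right side
affected with probability 77/115, left/right flatness means 0.41/0.39, an
affected-side flatness deficit, neurovascular-contact (NVC) pattern
frequencies per affected side, volumes log-uniform over the observed
94.23-1589.90 mm^3 envelope, and flatness draws truncated to the observed
0.25-0.54 envelope.  Each subject consumes an independent counter-based
random substream, so enlarging a cohort never perturbs earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from .io import MANIFEST_COLUMNS, VoxelMask, write_manifest, write_mask

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
    "null_cohort_spec",
    "SyntheticCohort",
]

#: NVC (affected-side, unaffected-side) pattern frequencies per affected
#: side, as reported for the 38 left- and 77 right-affected patients.
NVC_PATTERNS = [("yes", "no"), ("no", "yes"), ("yes", "yes"), ("no", "no")]
DEFAULT_NVC_PROBABILITIES = {
    "left": (12 / 38, 4 / 38, 13 / 38, 9 / 38),
    "right": (34 / 77, 9 / 77, 25 / 77, 9 / 77),
}


@dataclass(frozen=True)
class PhantomSpec:
    """One solid-ellipsoid phantom: semi-axes a >= b >= c in mm, Euler
    rotation in rad, grid spacing in mm, optional radial boundary jitter."""

    semi_axes: tuple[float, float, float]
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    boundary_noise_sd: float = 0.0
    seed: int = 0
    margin_voxels: int = 2
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.boundary_noise_sd < 0:
            raise ValueError("boundary_noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of one synthetic bilateral cohort."""

    n_ptn: int = 115
    n_hc: int = 46
    p_right_affected: float = 77 / 115
    flatness_mean_left: float = 0.41
    flatness_mean_right: float = 0.39
    affected_flatness_delta: float = 0.02
    between_subject_sd: float = 0.06
    left_right_correlation: float = 0.5
    nvc_probabilities: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_NVC_PROBABILITIES.items()}
    )
    volume_range: tuple[float, float] = (94.23, 1589.90)
    flatness_range: tuple[float, float] = (0.25, 0.54)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    boundary_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_right_affected <= 1:
            raise ValueError("p_right_affected must be in [0, 1]")
        if not 0 <= self.left_right_correlation <= 1:
            raise ValueError("left_right_correlation must be in [0, 1]")
        for side, probs in self.nvc_probabilities.items():
            if side not in ("left", "right"):
                raise ValueError(f"nvc_probabilities keys must be sides, got {side!r}")
            if len(probs) != len(NVC_PATTERNS) or any(p < 0 for p in probs):
                raise ValueError("nvc pattern probabilities must be 4 nonnegative values")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"nvc pattern probabilities for {side} must sum to 1")
        lo, hi = self.flatness_range
        for side_mean in (self.flatness_mean_left, self.flatness_mean_right):
            if not 0 < side_mean - self.affected_flatness_delta < 1:
                raise ValueError("flatness mean minus delta must stay in (0, 1)")
        if not 0 < lo < hi < 1:
            raise ValueError("flatness_range must be inside (0, 1)")
        if not 0 < self.volume_range[0] < self.volume_range[1]:
            raise ValueError("volume_range must be increasing and positive")


@dataclass
class SyntheticCohort:
    """Output bundle of :func:`make_cohort`."""

    manifest: pd.DataFrame
    masks: dict[tuple[str, str], VoxelMask]
    truth: pd.DataFrame
    out_dir: Path | None = None


def make_phantom(spec: PhantomSpec) -> VoxelMask:
    """Discretize a (possibly rotated, noised) solid ellipsoid onto a grid.

    The grid is sized to hold the rotated ellipsoid plus a margin of empty
    voxels (default 2) on every side; occupancy is decided at voxel centers.
    Boundary noise perturbs the implicit surface radially by a zero-mean
    Gaussian of the given mm standard deviation, independently per voxel.
    Deterministic for a fixed spec (including seed).
    """
    axes = np.asarray(spec.semi_axes, dtype=float)
    spacing = np.asarray(spec.spacing, dtype=float)
    rot = Rotation.from_euler("xyz", spec.rotation).as_matrix()
    # Support function of the rotated ellipsoid along each grid axis gives
    # the half-extent needed in mm.
    half_extent = np.sqrt(((rot * axes[None, :]) ** 2).sum(axis=1))
    need = np.ceil(2 * half_extent / spacing).astype(int) + 2 * spec.margin_voxels + 1
    if spec.grid_shape is not None:
        shape = np.asarray(spec.grid_shape, dtype=int)
        if np.any(shape < need):
            raise ValueError(
                f"grid {tuple(shape)} too small for rotated ellipsoid; "
                f"requires at least {tuple(int(n) for n in need)} voxels"
            )
    else:
        shape = need
    center = (shape - 1) / 2.0 * spacing
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij", sparse=False
    )
    coords = np.stack([g.ravel() for g in grids], axis=1) - center
    local = coords @ rot  # = rot.T applied to each row vector
    level = np.sqrt(((local / axes) ** 2).sum(axis=1))
    if spec.boundary_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        # Convert mm jitter into level-set units via the mean radius.
        mean_radius = float(np.cbrt(axes.prod()))
        level = level + rng.normal(0.0, spec.boundary_noise_sd / mean_radius, size=level.shape)
    occ = (level <= 1.0).reshape(tuple(shape))
    return VoxelMask(occ, tuple(spacing), origin=(0.0, 0.0, 0.0))


def _semi_axes_from(flatness: float, volume: float) -> tuple[float, float, float]:
    """Semi-axes (a, b, c) with c/a = flatness, b = sqrt(a c), 4/3 pi abc = volume."""
    a = (3.0 * volume / (4.0 * np.pi * flatness**1.5)) ** (1.0 / 3.0)
    return a, a * np.sqrt(flatness), a * flatness


def _correlated_pair(rng: np.random.Generator, rho: float) -> tuple[float, float]:
    z0, zl, zr = rng.standard_normal(3)
    s, t = np.sqrt(rho), np.sqrt(1.0 - rho)
    return s * z0 + t * zl, s * z0 + t * zr


def make_cohort(spec: CohortSpec, out_dir=None) -> SyntheticCohort:
    """Draw a full bilateral cohort; optionally write masks + tables to disk.

    Per subject: affected side Bernoulli(``p_right_affected``) for PTN;
    per-side target flatness = side mean - (delta if that side is affected)
    + correlated between-subject noise, redrawn (up to 100 attempts) until
    both sides fall in ``flatness_range``; per-side volumes log-uniform over
    ``volume_range`` with the same left-right correlation via a Gaussian
    copula; NVC pattern drawn from the side-specific pattern frequencies
    (HC subjects carry no NVC); age and sex drawn to match the published
    demographics.  The truth table records every drawn parameter.
    """
    rows = []
    truth_rows = []
    masks: dict[tuple[str, str], VoxelMask] = {}
    rho = spec.left_right_correlation
    log_lo, log_hi = np.log(spec.volume_range[0]), np.log(spec.volume_range[1])
    groups = ["PTN"] * spec.n_ptn + ["HC"] * spec.n_hc

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    for i, group in enumerate(groups):
        rng = np.random.default_rng([int(spec.seed), i])
        sid = f"S{i + 1:03d}"
        if group == "PTN":
            affected = "right" if rng.random() < spec.p_right_affected else "left"
        else:
            affected = "none"

        means = {"left": spec.flatness_mean_left, "right": spec.flatness_mean_right}
        target_f = None
        for _ in range(100):
            dl, dr = _correlated_pair(rng, rho)
            cand = {
                "left": means["left"]
                - (spec.affected_flatness_delta if affected == "left" else 0.0)
                + spec.between_subject_sd * dl,
                "right": means["right"]
                - (spec.affected_flatness_delta if affected == "right" else 0.0)
                + spec.between_subject_sd * dr,
            }
            lo, hi = spec.flatness_range
            if all(lo <= v <= hi for v in cand.values()):
                target_f = cand
                break
        if target_f is None:
            raise RuntimeError(
                f"subject {sid}: could not draw feasible flatness in 100 attempts; "
                "check flatness means/sd against flatness_range"
            )

        vl, vr = _correlated_pair(rng, rho)
        target_v = {
            "left": float(np.exp(log_lo + norm.cdf(vl) * (log_hi - log_lo))),
            "right": float(np.exp(log_lo + norm.cdf(vr) * (log_hi - log_lo))),
        }

        if group == "PTN":
            probs = spec.nvc_probabilities[affected]
            pattern = NVC_PATTERNS[rng.choice(len(NVC_PATTERNS), p=np.asarray(probs))]
            nvc_aff, nvc_unaff = pattern
            nvc = {affected: nvc_aff, ("left" if affected == "right" else "right"): nvc_unaff}
        else:
            nvc = {"left": "no", "right": "no"}

        if group == "PTN":
            age = rng.normal(62.89, 10.43)
            sex = "female" if rng.random() < 70 / 115 else "male"
        else:
            age = rng.normal(49.28, 10.96)
            sex = "female" if rng.random() < 31 / 46 else "male"

        paths = {}
        for side in ("left", "right"):
            rotation = tuple(rng.uniform(0, np.pi, size=3))
            phantom_seed = int(rng.integers(2**31))
            pspec = PhantomSpec(
                semi_axes=_semi_axes_from(target_f[side], target_v[side]),
                rotation=rotation,
                spacing=spec.spacing,
                boundary_noise_sd=spec.boundary_noise_sd,
                seed=phantom_seed,
            )
            mask = make_phantom(pspec)
            masks[(sid, side)] = mask
            if out_dir is not None:
                rel = Path("masks") / f"{sid}_{side}.nii.gz"
                write_mask(mask, out_dir / rel)
                paths[side] = str(rel)
            else:
                paths[side] = ""
            truth_rows.append(
                {
                    "subject_id": sid,
                    "side": side,
                    "group": group,
                    "affected_side": affected,
                    "is_affected": side == affected,
                    "target_flatness": target_f[side],
                    "target_volume_mm3": target_v[side],
                    "semi_axis_a": pspec.semi_axes[0],
                    "semi_axis_b": pspec.semi_axes[1],
                    "semi_axis_c": pspec.semi_axes[2],
                    "rotation_x": rotation[0],
                    "rotation_y": rotation[1],
                    "rotation_z": rotation[2],
                    "nvc": nvc[side],
                    "phantom_seed": phantom_seed,
                }
            )

        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "affected_side": affected,
                "nvc_left": nvc["left"],
                "nvc_right": nvc["right"],
                "mask_left": paths["left"],
                "mask_right": paths["right"],
                "age": round(float(age), 2),
                "sex": sex,
            }
        )

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS + ["age", "sex"])
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.csv")
        truth.to_csv(out_dir / "truth.csv", index=False)
    return SyntheticCohort(manifest=manifest, masks=masks, truth=truth, out_dir=out_dir)


def null_cohort_spec(**overrides) -> CohortSpec:
    """A symmetric null configuration: no affected-side deficit and equal
    side means, so the affected/unaffected paired flatness difference has
    mean zero.  Used for type-I-error calibration of the pipeline."""
    base = dict(
        affected_flatness_delta=0.0,
        flatness_mean_left=0.40,
        flatness_mean_right=0.40,
    )
    base.update(overrides)
    return CohortSpec(**base)
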