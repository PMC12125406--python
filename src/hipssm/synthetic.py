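"""Synthetic landmark cohorts with known ground truth.

Because the clinical ultrasound annotations are not publicly deposited,
every pipeline stage is exercised on simulated cohorts whose generating
parameters are known exactly. The generator emulates:

* a template ilium--acetabulum contour (straight ilium segment for
  points 0-4, circular-arc acetabular slope for points 4-12, built with
  the same placement protocol the pipeline analyzes);
* a small number of orthonormal shape modes with a decaying variance
  spectrum, constructed orthogonal to the similarity-transform subspace
  (translation/rotation/scale directions at the template) so Procrustes
  alignment cannot absorb the planted variation;
* isotropic per-landmark annotation noise, plus the isotropic "noise
  floor" implied when the planted variance proportions sum to less
  than one;
* femoral-head annotations placed by inverting the coverage formula so
  the cohort's FHC distribution matches a chosen (truncated) normal;
* binary outcomes drawn through a logistic link on the latent mode
  Z-scores, with the composite outcome split into open reduction /
  osteotomy / residual dysplasia in fixed 12:13:32 proportions;
* rater re-annotation noise for reliability studies.

All outputs are bit-reproducible given the configuration (which carries
the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import derive_point0, fhc_percent, resample_equal_spacing
from .io import AnnotatedHip, Landmark, PatientRecord
from .shape_model import N_CONTOUR, VEC_LEN, to_points, to_shape_vector

__all__ = [
    "SyntheticConfig",
    "CohortTruth",
    "default_template",
    "make_modes",
    "invert_fhc",
    "sample_cohort",
    "reannotate",
]

#: Split of the composite unfavorable outcome into open reduction /
#: pelvic osteotomy / residual-dysplasia-only, as observed clinically.
UNFAVORABLE_SPLIT = (12, 13, 32)


def default_template() -> np.ndarray:
    """Template contour: straight ilium (points 0-4) and a circular-arc
    acetabular slope (points 4-12), in pixels, built with the protocol's
    own placement rules."""
    p4 = np.array([160.0, 0.0])
    arc_center = np.array([160.0, 120.0])
    radius = 120.0
    # arc from p4 (angle -90 deg, topmost) to p12 (angle 0, deepest point)
    theta = np.linspace(-math.pi / 2, 0.0, 512)
    arc = arc_center + radius * np.column_stack([np.cos(theta), np.sin(theta)])
    p12 = arc[-1]
    p0 = derive_point0(p4, p12, np.array([-1.0, 0.0]))
    ilium = np.array([p0, p4])
    pts = np.empty((N_CONTOUR, 2))
    pts[0] = p0
    pts[1:4] = resample_equal_spacing(ilium, (p0, p4), 3)
    pts[4] = p4
    pts[5:12] = resample_equal_spacing(arc, (p4, p12), 7)
    pts[12] = p12
    return to_shape_vector(pts)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating truth for one synthetic cohort.

    ``mode_variance_proportions`` are shares of ``total_shape_variance``
    planted along each mode; any remainder (1 - sum) is spread as an
    isotropic noise floor over all 26 coordinates, on top of the
    explicit per-coordinate annotation noise ``landmark_noise_sd``.
    Outcome probabilities follow
    ``logit^-1(outcome_intercept + sum coef_m * z_m)``.
    """

    n_patients: int = 92
    seed: int = 0
    template: Optional[np.ndarray] = None
    n_modes: int = 4
    mode_variance_proportions: tuple = (0.59, 0.23, 0.10, 0.03)
    total_shape_variance: float = 320.0  # px^2, summed over all 26 coordinates
    landmark_noise_sd: float = 0.25  # px per coordinate
    rater_noise_sd: float = 1.0  # px per coordinate, re-annotation
    outcome_intercept: float = 0.489  # logit of the ~62 % unfavorable rate
    outcome_coefficients: tuple = (0.0, 0.0, 0.0, math.log(1.8))
    fhc_mean: float = 24.0  # percent
    fhc_sd: float = 15.0  # percent
    head_radius: float = 60.0  # px

    def __post_init__(self):
        p = np.asarray(self.mode_variance_proportions, dtype=float)
        if len(p) != self.n_modes:
            raise ValueError("one variance proportion per mode required")
        if np.any(p <= 0) or p.sum() > 1.0 + 1e-12:
            raise ValueError("proportions must be positive and sum to at most 1")
        if min(self.landmark_noise_sd, self.rater_noise_sd, self.fhc_sd) < 0:
            raise ValueError("noise SDs must be non-negative")

    def resolved_template(self) -> np.ndarray:
        return (
            default_template()
            if self.template is None
            else to_shape_vector(self.template)
        )


@dataclass
class CohortTruth:
    """Ground truth stored alongside a sampled cohort."""

    config: SyntheticConfig
    modes: np.ndarray  # (26, n_modes) orthonormal
    mode_sds: np.ndarray  # planted per-mode SD, px
    z: np.ndarray  # (n_patients, n_modes) latent scores
    fhc_targets: np.ndarray  # (n_patients,) planted coverage percents
    outcome_probabilities: np.ndarray  # (n_patients,)


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity-transform directions at the
    template: x/y translation, infinitesimal rotation, and scaling."""
    pts = to_points(template)
    centered = pts - pts.mean(axis=0)
    tx = np.tile([1.0, 0.0], N_CONTOUR)
    ty = np.tile([0.0, 1.0], N_CONTOUR)
    rot = np.column_stack([-centered[:, 1], centered[:, 0]]).reshape(VEC_LEN)
    scale = centered.reshape(VEC_LEN)
    basis = []
    for v in (tx, ty, rot, scale):
        for b in basis:
            v = v - np.dot(v, b) * b
        n = np.linalg.norm(v)
        if n > 1e-12:
            basis.append(v / n)
    return np.column_stack(basis)


def make_modes(template, n_modes: int, seed: int) -> np.ndarray:
    """Seeded orthonormal mode matrix orthogonal to the similarity
    subspace at the template, so the planted variation is pure shape."""
    template = to_shape_vector(template)
    if n_modes > VEC_LEN - 4:
        raise ValueError("too many modes for a 26-dimensional shape space")
    rng = np.random.default_rng(seed)
    sim = _similarity_basis(template)
    modes = []
    while len(modes) < n_modes:
        v = rng.standard_normal(VEC_LEN)
        v = v - sim @ (sim.T @ v)
        for m in modes:
            v = v - np.dot(v, m) * m
        n = np.linalg.norm(v)
        if n > 1e-8:
            modes.append(v / n)
    return np.column_stack(modes)


def invert_fhc(target_percent: float, radius: float, line, covered_side_ref) -> np.ndarray:
    """Place a femoral-head center achieving a target coverage percent.

    The center is moved along the normal of the point-0-to-point-4 line
    (through a base point just distal to point 4); its signed distance is
    found by bisection until the computed coverage matches the target to
    within 1e-6 percent (at most 60 iterations). Targets 0 and 100
    saturate at one radius on the appropriate side.
    """
    if not 0.0 <= target_percent <= 100.0:
        raise ValueError("target coverage must be in [0, 100]")
    p0 = np.asarray(line[0], dtype=float)
    p4 = np.asarray(line[1], dtype=float)
    d = p4 - p0
    length = np.linalg.norm(d)
    u = d / length
    n = np.array([-u[1], u[0]])
    ref = np.asarray(covered_side_ref, dtype=float)
    if np.dot(ref - p0, n) < 0:
        n = -n  # make +n point to the covered (acetabular) side
    base = p4 + 0.8 * radius * u  # head sits over the acetabular slope

    def coverage(s: float) -> float:
        center = base + s * n
        rim = center + radius * u
        return fhc_percent(p0, p4, center, rim, ref).percent

    if target_percent <= 0.0:
        return base - radius * n
    if target_percent >= 100.0:
        return base + radius * n
    lo, hi = -radius, radius
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c = coverage(mid)
        if abs(c - target_percent) < 1e-6:
            break
        if c < target_percent:
            lo = mid
        else:
            hi = mid
    return base + 0.5 * (lo + hi) * n


def _truncated_normal(rng, mean, sd, low, high, size):
    out = np.empty(size)
    for i in range(size):
        while True:
            v = rng.normal(mean, sd)
            if low <= v <= high:
                out[i] = v
                break
    return out


def sample_cohort(config: SyntheticConfig):
    """Draw one cohort: annotated hips, patient records, and the truth.

    Per patient: latent scores z ~ N(0, 1) per mode; the contour is
    template + sum z_m * sd_m * mode_m plus isotropic noise; head points
    are placed by :func:`invert_fhc` at a coverage target drawn from the
    truncated normal N(fhc_mean, fhc_sd) on [0, 100]; the composite
    outcome is Bernoulli through the logistic link on z, and positive
    cases are split into open reduction / osteotomy / residual dysplasia
    in the fixed 12:13:32 proportions. Acetabular indices are drawn
    consistent with the outcome (absent for surgical patients, > 21 deg
    for residual dysplasia, <= 21 deg otherwise).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    template = cfg.resolved_template()
    modes = make_modes(template, cfg.n_modes, cfg.seed)
    props = np.asarray(cfg.mode_variance_proportions, dtype=float)
    mode_sds = np.sqrt(props * cfg.total_shape_variance)
    floor_var = (1.0 - props.sum()) * cfg.total_shape_variance / VEC_LEN
    noise_sd = math.sqrt(floor_var + cfg.landmark_noise_sd**2)
    coefs = np.asarray(cfg.outcome_coefficients, dtype=float)
    if len(coefs) != cfg.n_modes:
        raise ValueError("one outcome coefficient per mode required")

    n = cfg.n_patients
    z = rng.standard_normal((n, cfg.n_modes))
    shapes = template[None, :] + z @ (modes * mode_sds).T
    shapes = shapes + rng.normal(0.0, noise_sd, size=shapes.shape)
    fhc_targets = _truncated_normal(rng, cfg.fhc_mean, cfg.fhc_sd, 0.0, 100.0, n)
    eta = cfg.outcome_intercept + z @ coefs
    prob = 1.0 / (1.0 + np.exp(-eta))
    unfavorable = rng.random(n) < prob
    split = np.asarray(UNFAVORABLE_SPLIT, dtype=float)
    split = split / split.sum()

    hips = []
    records = []
    for i in range(n):
        hip_id = f"S{i:04d}"
        pts = to_points(shapes[i])
        center = invert_fhc(
            fhc_targets[i], cfg.head_radius, (pts[0], pts[4]), pts[12]
        )
        u = (pts[4] - pts[0]) / np.linalg.norm(pts[4] - pts[0])
        rim = center + cfg.head_radius * u
        contour = tuple(Landmark(float(x), float(y)) for x, y in pts)
        side = "left" if rng.random() < 65 / 92 else "right"
        hips.append(
            AnnotatedHip(
                hip_id=hip_id,
                side=side,
                contour=contour,
                head_center=Landmark(float(center[0]), float(center[1])),
                head_rim=Landmark(float(rim[0]), float(rim[1])),
            )
        )
        open_red = osteotomy = False
        ai: Optional[float] = None
        if unfavorable[i]:
            component = rng.choice(3, p=split)
            if component == 0:
                open_red = True
            elif component == 1:
                osteotomy = True
            else:
                ai = 21.0 + 0.5 + abs(rng.normal(3.0, 2.0))
        else:
            ai = float(np.clip(rng.normal(16.0, 3.0), 5.0, 20.9))
        records.append(
            PatientRecord(
                hip_id=hip_id,
                sex="F" if rng.random() < 77 / 92 else "M",
                age_at_us=float(np.clip(rng.normal(3.4, 1.2), 0.5, 12.0)),
                graf_type="D" if rng.random() < 10 / 92 else ("III" if rng.random() < 0.5 else "IV"),
                bilateral=bool(rng.random() < 4 / 92),
                closed_reduction=True,
                open_reduction=open_red,
                pelvic_osteotomy=osteotomy,
                acetabular_index_5y=ai,
                avn=bool(rng.random() < 5 / 92),
                exclusion_flag="none",
            )
        )
    truth = CohortTruth(
        config=cfg,
        modes=modes,
        mode_sds=mode_sds,
        z=z,
        fhc_targets=fhc_targets,
        outcome_probabilities=prob,
    )
    return hips, records, truth


def reannotate(
    hips: Sequence[AnnotatedHip],
    rater_noise_sd: float,
    seed: int,
    subset_fraction: Optional[float] = None,
    rater_id: str = "r1",
    session: int = 2,
):
    """Simulate a re-annotation series.

    Adds independent isotropic Gaussian noise (``rater_noise_sd`` pixels
    per coordinate) to every landmark of every selected hip. When
    ``subset_fraction`` is given, a seeded random subset of
    round(fraction * n) hips (round-half-even, e.g. 20 % of 92 -> 18) is
    selected first. Returns ``(indices, perturbed_hips)`` with indices
    into the input sequence, sorted ascending.
    """
    rng = np.random.default_rng(seed)
    n = len(hips)
    if subset_fraction is None:
        indices = np.arange(n)
    else:
        n_sel = int(round(subset_fraction * n))
        indices = np.sort(rng.choice(n, size=n_sel, replace=False))
    out = []
    for i in indices:
        hip = hips[int(i)]
        pts = np.array([[p.x, p.y] for p in hip.all_points()])
        pts = pts + rng.normal(0.0, rater_noise_sd, size=pts.shape)
        contour = tuple(Landmark(float(x), float(y)) for x, y in pts[:13])
        head_center = head_rim = None
        if hip.has_head:
            head_center = Landmark(float(pts[13, 0]), float(pts[13, 1]))
            head_rim = Landmark(float(pts[14, 0]), float(pts[14, 1]))
        out.append(
            AnnotatedHip(
                hip_id=hip.hip_id,
                side=hip.side,
                contour=contour,
                head_center=head_center,
                head_rim=head_rim,
                rater_id=rater_id,
                session=session,
            )
        )
    return indices, out
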