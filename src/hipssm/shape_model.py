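"""Point-distribution shape model of the acetabular contour.

The model follows the classical landmark pipeline: the 13-point contours
are brought into a common frame by generalized Procrustes analysis
(GPA), the aligned configurations are decomposed by principal component
analysis, and the modes explaining a cumulative 95 % of the shape
variance are retained. Each hip is then summarized by a vector of mode
Z-scores: its projection onto mode m divided by that mode's standard
deviation sqrt(lambda_m). Shapes at chosen mode deviations (e.g.
-2.5 SD / 0 / +2.5 SD) can be synthesized for visualization.

Shapes are 26-component vectors: (x0, y0, x1, y1, ..., x12, y12) in
protocol point order. 2-D similarity alignment is carried out in the
complex plane, where the optimal rotation+scale aligning z to w is the
single complex factor <z, w> / <z, z>; this excludes reflections by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AlignmentConfig",
    "ShapeModel",
    "ShapeModelError",
    "to_shape_vector",
    "to_points",
    "procrustes_align",
    "align_to_reference",
    "fit_ssm",
    "retained_count",
    "zscores",
    "zscores_table",
    "synthesize",
    "save_model",
    "load_model",
]

N_CONTOUR = 13
VEC_LEN = 2 * N_CONTOUR

_GPA_TOL = 1e-10
_GPA_MAX_ITER = 100


class ShapeModelError(ValueError):
    """Degenerate geometry or data for shape-model construction."""


@dataclass(frozen=True)
class AlignmentConfig:
    """Which similarity transforms GPA removes (default: all three)."""

    translate: bool = True
    rotate: bool = True
    scale: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ShapeModel:
    """Mean shape plus orthonormal variation modes.

    ``modes`` has one column per mode (descending eigenvalue order);
    ``variance_proportions`` are eigenvalue shares of the total variance;
    ``n_retained`` is the smallest count reaching the retention fraction.
    """

    mean_shape: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    n_retained: int
    alignment_config: AlignmentConfig = field(default_factory=AlignmentConfig)
    retention: float = 0.95


# ---------------------------------------------------------------------------
# Shape-vector plumbing
# ---------------------------------------------------------------------------


def to_shape_vector(points) -> np.ndarray:
    """Flatten a (13, 2) point array into the interleaved 26-vector."""
    a = np.asarray(points, dtype=float)
    if a.shape == (VEC_LEN,):
        return a.copy()
    if a.shape != (N_CONTOUR, 2):
        raise ShapeModelError(f"expected (13, 2) points or 26-vector, got {a.shape}")
    return a.reshape(VEC_LEN)


def to_points(vec) -> np.ndarray:
    """Reshape a 26-vector back into (13, 2) points."""
    a = np.asarray(vec, dtype=float)
    if a.shape != (VEC_LEN,):
        raise ShapeModelError(f"expected 26-vector, got {a.shape}")
    return a.reshape(N_CONTOUR, 2)


def _to_complex(vecs: np.ndarray) -> np.ndarray:
    pts = vecs.reshape(-1, N_CONTOUR, 2)
    return pts[..., 0] + 1j * pts[..., 1]


def _from_complex(z: np.ndarray) -> np.ndarray:
    pts = np.stack([z.real, z.imag], axis=-1)
    return pts.reshape(-1, VEC_LEN)


def _align_batch(z: np.ndarray, ref: np.ndarray, cfg: AlignmentConfig) -> np.ndarray:
    """Optimally align each row of ``z`` to ``ref`` under the enabled transforms.

    Rows and ``ref`` are complex 13-vectors, already centered when
    translation is enabled.
    """
    inner = np.sum(np.conj(z) * ref[None, :], axis=1)
    den = np.sum(np.abs(z) ** 2, axis=1)
    if cfg.rotate and cfg.scale:
        f = inner / den
    elif cfg.rotate:
        mag = np.abs(inner)
        f = np.where(mag > 0, inner / np.where(mag > 0, mag, 1.0), 1.0)
    elif cfg.scale:
        f = inner.real / den
    else:
        f = np.ones(len(z))
    return z * f[:, None]


def _prepare(z: np.ndarray, cfg: AlignmentConfig):
    """Center (if enabled) and check for degenerate configurations."""
    if cfg.translate:
        z = z - z.mean(axis=1, keepdims=True)
    size = np.sqrt(np.sum(np.abs(z - z.mean(axis=1, keepdims=True)) ** 2, axis=1))
    if np.any(size == 0):
        raise ShapeModelError("a shape has all points identical (zero centroid size)")
    return z


def procrustes_align(shapes, config: AlignmentConfig = AlignmentConfig()):
    """Generalized Procrustes alignment of a set of shapes.

    Iteratively aligns every shape to the running mean under the enabled
    transforms, re-estimates the mean, and repeats until the mean moves
    by less than 1e-10 (or 100 iterations). After a final alignment pass
    the returned mean is exactly the average of the aligned shapes; with
    scaling enabled the whole configuration is rescaled so the mean has
    unit centroid size.

    Parameters
    ----------
    shapes
        Sequence of 26-vectors or (13, 2) point arrays, at least two.

    Returns
    -------
    (aligned, mean): ``aligned`` is an (n, 26) array, ``mean`` a 26-vector.
    """
    vecs = np.stack([to_shape_vector(s) for s in shapes])
    if len(vecs) < 2:
        raise ShapeModelError("need at least two shapes to align")
    z = _prepare(_to_complex(vecs), config)
    if config.scale:
        size = np.sqrt(np.sum(np.abs(z) ** 2, axis=1))
        z = z / size[:, None]

    mean = z[0]
    if config.scale:
        mean = mean / np.sqrt(np.sum(np.abs(mean) ** 2))
    for _ in range(_GPA_MAX_ITER):
        z = _align_batch(z, mean, config)
        new_mean = z.mean(axis=0)
        if config.scale:
            norm = np.sqrt(np.sum(np.abs(new_mean) ** 2))
            if norm == 0:
                raise ShapeModelError("degenerate mean during alignment")
            new_mean = new_mean / norm
        delta = np.sqrt(np.sum(np.abs(new_mean - mean) ** 2))
        mean = new_mean
        if delta < _GPA_TOL:
            break

    # Final pass: make the stored mean the exact average of the output.
    z = _align_batch(z, mean, config)
    mean = z.mean(axis=0)
    if config.scale:
        factor = 1.0 / np.sqrt(np.sum(np.abs(mean) ** 2))
        z = z * factor
        mean = mean * factor
    if config.rotate:
        # Pin the rotational gauge (GPA is otherwise defined only up to a
        # common rotation): orient the mean's point-0-to-point-4 ilium
        # direction along +x, so results do not depend on the pose of the
        # input cohort.
        w = mean[4] - mean[0]
        if np.abs(w) > 0:
            rot = np.conj(w) / np.abs(w)
            z = z * rot
            mean = mean * rot
    return _from_complex(z), _from_complex(mean[None, :])[0]


def align_to_reference(shape, reference, config: AlignmentConfig = AlignmentConfig()):
    """Similarity-align one shape to a reference shape (model frame)."""
    z = _prepare(_to_complex(to_shape_vector(shape)[None, :]), config)
    ref = _to_complex(to_shape_vector(reference)[None, :])[0]
    ref_centroid = ref.mean()
    if config.translate:
        ref = ref - ref_centroid
    out = _align_batch(z, ref, config)
    if config.translate:
        out = out + ref_centroid
    return _from_complex(out)[0]


# ---------------------------------------------------------------------------
# Principal-component decomposition
# ---------------------------------------------------------------------------


def retained_count(variance_proportions, retention: float = 0.95) -> int:
    """Smallest k whose cumulative variance proportion reaches ``retention``."""
    cum = np.cumsum(np.asarray(variance_proportions, dtype=float))
    k = int(np.searchsorted(cum, retention - 1e-12) + 1)
    return min(k, len(cum))


def fit_ssm(aligned, retention: float = 0.95) -> ShapeModel:
    """Fit the point-distribution model to aligned shapes.

    Eigendecomposition of the sample covariance (denominator n-1) of the
    aligned 26-vectors about their mean; modes are sorted by descending
    eigenvalue and each mode's sign is fixed so its largest-magnitude
    component is positive (PCA signs are otherwise arbitrary, and the
    orientation determines the sign of downstream odds ratios).
    """
    x = np.asarray(aligned, dtype=float)
    if x.ndim != 2 or x.shape[1] != VEC_LEN:
        raise ShapeModelError(f"expected (n, {VEC_LEN}) aligned shapes, got {x.shape}")
    n = x.shape[0]
    if n < 3:
        raise ShapeModelError("need at least three shapes to fit a shape model")
    mean = x.mean(axis=0)
    dev = x - mean
    cov = dev.T @ dev / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = float(eigvals.sum())
    if total <= 0.0:
        raise ShapeModelError("zero total shape variance")
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    proportions = eigvals / total
    k = retained_count(proportions, retention)
    return ShapeModel(
        mean_shape=mean,
        modes=eigvecs,
        eigenvalues=eigvals,
        variance_proportions=proportions,
        n_retained=k,
        alignment_config=AlignmentConfig(),
        retention=retention,
    )


def zscores(model: ShapeModel, shape, pre_aligned: bool = False) -> np.ndarray:
    """Mode Z-scores of one shape under the model.

    z_m = <shape - mean, mode_m> / sqrt(lambda_m) for each retained mode.
    Unless ``pre_aligned``, the shape is first similarity-aligned to the
    model mean with the model's transform family, so repeat annotations
    score in a consistent frame.
    """
    vec = to_shape_vector(shape)
    if not pre_aligned:
        vec = align_to_reference(vec, model.mean_shape, model.alignment_config)
    k = model.n_retained
    lam = model.eigenvalues[:k]
    if np.any(lam <= 0):
        raise ShapeModelError("retained mode with zero eigenvalue")
    dev = vec - model.mean_shape
    return (model.modes[:, :k].T @ dev) / np.sqrt(lam)


def zscores_table(model: ShapeModel, hips, pre_aligned_shapes=None) -> pd.DataFrame:
    """Z-scores for a list of hips as a DataFrame indexed by hip_id.

    ``pre_aligned_shapes`` (an (n, 26) array) short-circuits alignment
    for the training set; otherwise each hip's contour is aligned to the
    model mean before projection.
    """
    ids = [h.hip_id for h in hips]
    if pre_aligned_shapes is not None:
        zs = [zscores(model, s, pre_aligned=True) for s in pre_aligned_shapes]
    else:
        zs = [zscores(model, h.contour_array()) for h in hips]
    cols = [f"mode{m + 1}" for m in range(model.n_retained)]
    return pd.DataFrame(zs, index=pd.Index(ids, name="hip_id"), columns=cols)


def synthesize(model: ShapeModel, mode: int, z: float) -> np.ndarray:
    """Shape at ``z`` SD along one retained mode: mean + z sqrt(lambda) mode."""
    if not 0 <= mode < model.n_retained:
        raise ShapeModelError(f"mode index {mode} out of range (retained {model.n_retained})")
    return model.mean_shape + z * np.sqrt(model.eigenvalues[mode]) * model.modes[:, mode]


# ---------------------------------------------------------------------------
# Serialization: CSV set + YAML sidecar
# ---------------------------------------------------------------------------


def save_model(model: ShapeModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"component": np.arange(VEC_LEN), "mean": model.mean_shape}
    ).to_csv(d / "mean.csv", index=False)
    pd.DataFrame(
        model.modes, columns=[f"mode{j + 1}" for j in range(model.modes.shape[1])]
    ).to_csv(d / "modes.csv", index=False)
    pd.DataFrame(
        {
            "eigenvalue": model.eigenvalues,
            "variance_proportion": model.variance_proportions,
        }
    ).to_csv(d / "eigenvalues.csv", index=False)
    meta = {
        "alignment": model.alignment_config.as_dict(),
        "retention": float(model.retention),
        "n_retained": int(model.n_retained),
    }
    (d / "model.yaml").write_text(yaml.safe_dump(meta))


def load_model(directory) -> ShapeModel:
    d = Path(directory)
    mean = pd.read_csv(d / "mean.csv")["mean"].to_numpy()
    modes = pd.read_csv(d / "modes.csv").to_numpy()
    eig = pd.read_csv(d / "eigenvalues.csv")
    meta = yaml.safe_load((d / "model.yaml").read_text())
    return ShapeModel(
        mean_shape=mean,
        modes=modes,
        eigenvalues=eig["eigenvalue"].to_numpy(),
        variance_proportions=eig["variance_proportion"].to_numpy(),
        n_retained=int(meta["n_retained"]),
        alignment_config=AlignmentConfig(**meta["alignment"]),
        retention=float(meta["retention"]),
    )
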