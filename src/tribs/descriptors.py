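"""Frame-wise motion description features and their low-dimensional embedding.

Each frame's pose is summarized by three scalars: the spectral 2-norms of the
6x6 TPS body-segment matrix E_T and of the 4x4 Euclidean body-segment matrix
E_O, and the mean of E_O's four eigenvalues.  The eigenvalue mean is real
even when eigenvalues are complex (they occur in conjugate pairs) and equals
trace/4 by the eigenvalue-sum identity, which is how it is computed; the full
decomposition is only used for diagnostics.

The three features are z-standardized and embedded with a 2-component PCA;
classes of motion then separate into clusters whose 95% confidence ellipses,
centroid distances and leave-one-out nearest-centroid accuracy quantify how
well the descriptors tell motions apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .errors import GeometryError
from .model import LimbModel
from .tps import BodySegmentMatrices, build_matrices
from .virtual_points import build_point_set

FEATURE_COLUMNS = ("norm2_EO", "mean_eig_EO", "norm2_ET")


def frame_features(mats: BodySegmentMatrices, diagnostics: bool = False) -> dict:
    """The three description features of one frame.

    ``norm2_*`` are spectral (largest-singular-value) matrix norms;
    ``mean_eig_EO`` is trace/4.  With ``diagnostics`` the eigenvalues are
    decomposed explicitly and the mean's imaginary part asserted negligible.
    """
    e_o, e_t = mats.e_o, mats.e_t
    if not (np.all(np.isfinite(e_o)) and np.all(np.isfinite(e_t))):
        raise GeometryError("non-finite body-segment matrices")
    mean_eig = float(np.trace(e_o)) / 4.0
    if diagnostics:
        eig_mean = complex(np.mean(np.linalg.eigvals(e_o)))
        if abs(eig_mean.imag) > 1e-8 * abs(eig_mean.real) + 1e-8:
            raise GeometryError(
                f"eigenvalue mean has non-negligible imaginary part {eig_mean.imag!r}"
            )
    return {
        "norm2_EO": float(np.linalg.norm(e_o, 2)),
        "mean_eig_EO": mean_eig,
        "norm2_ET": float(np.linalg.norm(e_t, 2)),
    }


def motion_features(
    local_point_frames, model: LimbModel, label: str | None = None
) -> pd.DataFrame:
    """Feature table for a sequence of local-frame measured-point dicts."""
    rows = []
    for i, measured in enumerate(local_point_frames):
        mats = build_matrices(build_point_set(measured, model), model)
        rec = frame_features(mats)
        rec["frame"] = i
        rows.append(rec)
    df = pd.DataFrame(rows, columns=["frame", *FEATURE_COLUMNS])
    if label is not None:
        df["label"] = label
    return df


@dataclass
class EmbeddingResult:
    """2-component PCA embedding of the standardized feature triple."""

    scores: pd.DataFrame  # PC1, PC2 (+ label when provided)
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # loadings, rows = PCs, cols = kept features
    feature_names: tuple[str, ...]
    ellipses: dict = field(default_factory=dict)  # label -> (center, semi_axes, angle_deg)


def _confidence_ellipse(points: np.ndarray, level: float = 0.95):
    center = points.mean(axis=0)
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    r = chi2.ppf(level, df=2)
    semi_axes = np.sqrt(np.maximum(evals, 0.0) * r)
    angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
    # order major axis first
    return center, semi_axes[::-1], angle, evecs[:, ::-1]


def pca_embed(features: pd.DataFrame, level: float = 0.95) -> EmbeddingResult:
    """Standardize the feature triple and embed with 2-component PCA.

    Zero-variance features are dropped with a warning.  The sign of each
    component is fixed by making the loading of the first kept feature
    (norm2_EO) non-negative, so embeddings are reproducible.  When a
    ``label`` column is present, per-class 95% confidence ellipses are fitted
    from the class score covariance.
    """
    if len(features) < 3:
        raise GeometryError("pca_embed needs at least 3 frames")
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    x = features[cols].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping zero-variance feature(s): {dropped}", stacklevel=2)
        cols = [c for c, k in zip(cols, keep) if k]
        x = x[:, keep]
        sd = sd[keep]
    if x.shape[1] < 2:
        raise GeometryError("fewer than two informative features; cannot embed")
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    components = pca.components_.copy()
    for k in range(2):
        if components[k, 0] < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0
    out = pd.DataFrame(scores, columns=["PC1", "PC2"], index=features.index)
    ellipses = {}
    if "label" in features.columns:
        out["label"] = features["label"].to_numpy()
        for lab, grp in out.groupby("label", sort=True):
            pts = grp[["PC1", "PC2"]].to_numpy()
            if len(pts) >= 3:
                center, semi, ang, vecs = _confidence_ellipse(pts, level)
                ellipses[lab] = {
                    "center": center,
                    "semi_axes": semi,
                    "angle_deg": ang,
                    "axes": vecs,
                }
    return EmbeddingResult(
        scores=out,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        components=components,
        feature_names=tuple(cols),
        ellipses=ellipses,
    )


def _ellipse_boundary(ell: dict, n: int = 360) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    circle = np.column_stack([np.cos(t) * ell["semi_axes"][0], np.sin(t) * ell["semi_axes"][1]])
    return circle @ ell["axes"].T + ell["center"]


def _inside(points: np.ndarray, ell: dict) -> np.ndarray:
    rel = (points - ell["center"]) @ ell["axes"]
    semi = np.maximum(ell["semi_axes"], 1e-300)
    return (rel[:, 0] / semi[0]) ** 2 + (rel[:, 1] / semi[1]) ** 2 <= 1.0


def ellipses_intersect(ea: dict, eb: dict, n: int = 720) -> bool:
    """Whether two confidence-ellipse regions overlap (numeric boundary test)."""
    if bool(_inside(ea["center"][None, :], eb)[0]) or bool(
        _inside(eb["center"][None, :], ea)[0]
    ):
        return True
    return bool(np.any(_inside(_ellipse_boundary(ea, n), eb))) or bool(
        np.any(_inside(_ellipse_boundary(eb, n), ea))
    )


@dataclass
class SeparationReport:
    """Pairwise cluster geometry and a simple held-out classification score."""

    centroid_distances: pd.DataFrame
    ellipse_intersections: pd.DataFrame
    loo_accuracy: float
    per_class_accuracy: dict


def class_separation(embedding: EmbeddingResult) -> SeparationReport:
    """Quantify how separable the labelled classes are in the embedding.

    Reports pairwise centroid distances and confidence-ellipse intersection,
    plus leave-one-out nearest-centroid accuracy over all frames.
    """
    if "label" not in embedding.scores.columns:
        raise GeometryError("class_separation needs labelled scores")
    df = embedding.scores
    labels = sorted(df["label"].unique())
    if len(labels) < 2:
        raise GeometryError("class_separation needs at least two classes")
    pts = {lab: df.loc[df["label"] == lab, ["PC1", "PC2"]].to_numpy() for lab in labels}
    centroids = {lab: p.mean(axis=0) for lab, p in pts.items()}

    dist = pd.DataFrame(0.0, index=labels, columns=labels)
    inter = pd.DataFrame(False, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            d = float(np.linalg.norm(centroids[la] - centroids[lb]))
            dist.loc[la, lb] = dist.loc[lb, la] = d
            if la in embedding.ellipses and lb in embedding.ellipses:
                x = ellipses_intersect(embedding.ellipses[la], embedding.ellipses[lb])
                inter.loc[la, lb] = inter.loc[lb, la] = x

    # leave-one-out nearest centroid
    x = df[["PC1", "PC2"]].to_numpy()
    y = df["label"].to_numpy()
    sums = {lab: pts[lab].sum(axis=0) for lab in labels}
    counts = {lab: len(pts[lab]) for lab in labels}
    correct = 0
    per_class = {lab: [0, 0] for lab in labels}
    for xi, yi in zip(x, y):
        best, best_d = None, np.inf
        for lab in labels:
            if lab == yi:
                if counts[lab] < 2:
                    continue
                c = (sums[lab] - xi) / (counts[lab] - 1)
            else:
                c = sums[lab] / counts[lab]
            d = float(np.linalg.norm(xi - c))
            if d < best_d:
                best, best_d = lab, d
        hit = best == yi
        correct += hit
        per_class[yi][0] += hit
        per_class[yi][1] += 1
    return SeparationReport(
        centroid_distances=dist,
        ellipse_intersections=inter,
        loo_accuracy=correct / len(y),
        per_class_accuracy={
            lab: (h / n if n else float("nan")) for lab, (h, n) in per_class.items()
        },
    )
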