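"""Bead-based alignment of the two emission channels.

A dual-view optical path images the green (eGFP) and red (mCherry)
emission bands onto disjoint regions of one camera, so the two channels
are related by a small unknown planar transform (chromatic shift plus a
slight rotation/scale).  The transform is calibrated from an image pair
of broad-spectrum fluorescent beads visible in both channels: beads are
localized to sub-pixel precision, matched between channels, and a
least-squares transform is fit to the matched point set.  Droplet
*coordinates* are then mapped through the transform; images themselves
are never resampled on the quantification path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import transform as _sktransform

from .segmentation import DegenerateHistogramError, Image2D, auto_threshold

__all__ = [
    "PlanarTransform",
    "PointMatchSet",
    "InsufficientMatchesError",
    "detect_beads",
    "match_points",
    "estimate_transform",
    "apply_transform",
    "warp_image",
]


@dataclass
class PlanarTransform:
    """p -> linear @ p + translation, with points as (x, y) in nm.

    ``model`` records the family the transform was fit in:
    ``translation`` (linear = I), ``similarity`` (linear = s·R, s > 0)
    or ``affine`` (any invertible 2×2).
    """

    linear: np.ndarray
    translation: np.ndarray
    model: str = "similarity"

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.linear)) < 1e-15:
            raise ValueError("linear part must be invertible")

    @classmethod
    def identity(cls) -> "PlanarTransform":
        return cls(np.eye(2), np.zeros(2), model="translation")

    @classmethod
    def from_translation(cls, tx: float, ty: float) -> "PlanarTransform":
        return cls(np.eye(2), np.array([tx, ty]), model="translation")

    @classmethod
    def from_similarity(
        cls, scale: float, rotation_rad: float, tx: float, ty: float
    ) -> "PlanarTransform":
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        return cls(scale * np.array([[c, -s], [s, c]]), np.array([tx, ty]), model="similarity")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(self, points)

    def inverse(self) -> "PlanarTransform":
        inv = np.linalg.inv(self.linear)
        return PlanarTransform(inv, -inv @ self.translation, model=self.model)

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """Transform applying ``other`` first, then ``self``."""
        return PlanarTransform(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
            model="affine" if "affine" in (self.model, other.model) else self.model,
        )

    # -- serialization: 6-number record (a11, a12, a21, a22, tx, ty), nm --

    def to_params(self) -> list[float]:
        a = self.linear
        return [a[0, 0], a[0, 1], a[1, 0], a[1, 1], *self.translation]

    @classmethod
    def from_params(cls, params, model: str = "affine") -> "PlanarTransform":
        a11, a12, a21, a22, tx, ty = (float(v) for v in params)
        return cls(np.array([[a11, a12], [a21, a22]]), np.array([tx, ty]), model=model)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"model": self.model, "params": self.to_params(), "units": "nm"}, fh, indent=2
            )

    @classmethod
    def from_json(cls, path) -> "PlanarTransform":
        with open(path) as fh:
            obj = json.load(fh)
        return cls.from_params(obj["params"], model=obj.get("model", "affine"))


@dataclass
class PointMatchSet:
    """Matched (x, y) nm coordinate pairs between channels A and B."""

    points_a: np.ndarray
    points_b: np.ndarray
    residual_rms_nm: float = field(default=float("nan"))

    def __len__(self) -> int:
        return len(self.points_a)


class InsufficientMatchesError(ValueError):
    """Fewer matched bead pairs than the transform model requires."""


def detect_beads(
    image: Image2D,
    min_separation_nm: float,
    refine_window_px: int = 7,
) -> np.ndarray:
    """Localize point-like emitters to sub-pixel precision.

    Pixels above the automatic Otsu threshold seed candidate spots;
    each local maximum is refined by the intensity-weighted centroid of
    a ``refine_window_px`` window after local background subtraction.
    Detections closer than ``min_separation_nm`` are merged (averaged).

    Returns an (n, 2) array of (x, y) in nm; empty with a warning if
    nothing is found.
    """
    values = image.values.astype(np.float64)
    px = image.pixel_size_nm
    try:
        thr = auto_threshold(image, method="otsu")
    except DegenerateHistogramError:
        warnings.warn("bead image has no contrast; no beads detected", stacklevel=2)
        return np.empty((0, 2))
    from skimage.feature import peak_local_max

    min_dist_px = max(1, int(round(min_separation_nm / px)))
    peaks = peak_local_max(values, min_distance=min_dist_px, threshold_abs=thr, exclude_border=False)
    if len(peaks) == 0:
        warnings.warn("no beads detected above threshold", stacklevel=2)
        return np.empty((0, 2))

    half = refine_window_px // 2
    centers = []
    nrow, ncol = values.shape
    for r, c in peaks:
        r0, r1 = max(0, r - half), min(nrow, r + half + 1)
        c0, c1 = max(0, c - half), min(ncol, c + half + 1)
        win = values[r0:r1, c0:c1]
        w = win - win.min()  # local background subtraction
        total = w.sum()
        if total <= 0:
            rr, cc = float(r), float(c)
        else:
            rows, cols = np.mgrid[r0:r1, c0:c1]
            rr = float((rows * w).sum() / total)
            cc = float((cols * w).sum() / total)
        centers.append(((cc + 0.5) * px, (rr + 0.5) * px))
    centers = np.asarray(centers)

    # merge detections closer than min_separation (average the cluster)
    tree = cKDTree(centers)
    groups = tree.query_ball_tree(tree, r=min_separation_nm)
    used = np.zeros(len(centers), dtype=bool)
    merged = []
    for i, grp in enumerate(groups):
        if used[i]:
            continue
        grp = [j for j in grp if not used[j]]
        used[grp] = True
        merged.append(centers[grp].mean(axis=0))
    return np.asarray(merged)


def match_points(
    points_a: np.ndarray, points_b: np.ndarray, max_distance_nm: float
) -> PointMatchSet:
    """Pair bead detections between channels by mutual nearest neighbours.

    A pair (a, b) is kept iff b is a's nearest neighbour, a is b's
    nearest neighbour, and their distance is below ``max_distance_nm``;
    no point participates in two pairs.
    """
    points_a = np.atleast_2d(np.asarray(points_a, dtype=float))
    points_b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(points_a) == 0 or len(points_b) == 0:
        raise ValueError("both point lists must be non-empty")
    tree_a, tree_b = cKDTree(points_a), cKDTree(points_b)
    d_ab, nn_ab = tree_b.query(points_a)
    _, nn_ba = tree_a.query(points_b)
    idx_a = np.arange(len(points_a))
    mutual = (nn_ba[nn_ab] == idx_a) & (d_ab <= max_distance_nm)
    pairs_a = points_a[mutual]
    pairs_b = points_b[nn_ab[mutual]]
    if len(pairs_a) < 3:
        raise InsufficientMatchesError(
            f"only {len(pairs_a)} mutual-nearest-neighbour pairs within "
            f"{max_distance_nm} nm; at least 3 required"
        )
    rms = float(np.sqrt(np.mean(np.sum((pairs_a - pairs_b) ** 2, axis=1))))
    return PointMatchSet(pairs_a, pairs_b, residual_rms_nm=rms)


def estimate_transform(matches: PointMatchSet, model: str = "similarity") -> PlanarTransform:
    """Least-squares transform mapping channel-A points onto channel-B points.

    Parameters
    ----------
    matches : PointMatchSet
        Matched coordinates; ≥ 3 pairs for translation/similarity,
        ≥ 3 non-collinear pairs for affine.
    model : {"translation", "similarity", "affine"}

    Returns
    -------
    PlanarTransform
        With ``residual_rms_nm`` of the fit recorded on the match set.
    """
    a = np.asarray(matches.points_a, dtype=float)
    b = np.asarray(matches.points_b, dtype=float)
    if model == "translation":
        t = (b - a).mean(axis=0)
        tf = PlanarTransform(np.eye(2), t, model="translation")
    elif model in ("similarity", "affine"):
        if model == "affine":
            # collinear points leave the affine fit underdetermined
            sv = np.linalg.svd(a - a.mean(axis=0), compute_uv=False)
            if sv[-1] <= 1e-9 * max(sv[0], 1.0):
                raise ValueError("degenerate point geometry for affine estimation: collinear points")
        cls = (
            _sktransform.SimilarityTransform
            if model == "similarity"
            else _sktransform.AffineTransform
        )
        if hasattr(cls, "from_estimate"):
            est = cls.from_estimate(a, b)
            ok = bool(est)
        else:  # scikit-image < 0.26
            est = cls()
            ok = est.estimate(a, b)
        mat = np.asarray(est.params) if ok else None
        if not ok or not np.all(np.isfinite(mat)):
            raise ValueError(f"degenerate point geometry for {model} estimation")
        tf = PlanarTransform(mat[:2, :2], mat[:2, 2], model=model)
        if abs(np.linalg.det(tf.linear)) < 1e-12:
            raise ValueError(f"degenerate point geometry for {model} estimation")
    else:
        raise ValueError(f"unknown transform model: {model!r}")
    res = tf(a) - b
    matches.residual_rms_nm = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return tf


def apply_transform(transform: PlanarTransform, points: np.ndarray) -> np.ndarray:
    """Map (n, 2) or (2,) points (x, y in nm) through the transform."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ transform.linear.T + transform.translation
    return out[0] if single else out


def warp_image(image: Image2D, transform: PlanarTransform) -> Image2D:
    """Bilinearly resample an image through ``transform`` (visualization only).

    Quantification maps coordinates, never pixels; this helper exists
    for overlay figures.
    """
    px = image.pixel_size_nm
    # physical transform -> pixel-index transform (x=(col+.5)px, y=(row+.5)px)
    lin = transform.linear
    t_px = transform.translation / px + (lin @ np.full(2, 0.5)) - 0.5
    mat = np.eye(3)
    mat[:2, :2] = lin
    mat[:2, 2] = t_px
    warped = _sktransform.warp(
        image.values.astype(np.float64),
        _sktransform.AffineTransform(matrix=mat).inverse,
        order=1,
        preserve_range=True,
    )
    return Image2D(warped, px, channel=image.channel, meta=dict(image.meta))
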