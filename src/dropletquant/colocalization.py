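"""Object-based two-channel colocalization of condensates.

A droplet detected in the eGFP channel and one detected in the
(registered) mCherry channel are accepted as a single heterotypic
condensate when their center-to-center Euclidean distance is strictly
below a distance criterion, 500 nm by default.  Matched pairs count
once; unmatched detections are homotypic (channel-exclusive) droplets.
Percentages are computed per field of view and aggregated as
mean +/- sd across fields, never pooled over particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import segmentation as seg
from .segmentation import Image2D, ParticleRecord

__all__ = [
    "ColocalizationCriterion",
    "ColocalizationResult",
    "FieldAggregate",
    "extract_centers",
    "classify_droplets",
    "aggregate_fields",
]

CLASSES = ("heterotypic", "greenOnly", "redOnly")


@dataclass(frozen=True)
class ColocalizationCriterion:
    """Distance criterion for heterotypic classification.

    A green/red pair colocalizes iff distance < ``max_distance_nm``
    (strict inequality: a pair at exactly the criterion distance is two
    homotypic droplets).
    """

    max_distance_nm: float = 500.0

    def __post_init__(self) -> None:
        if self.max_distance_nm <= 0:
            raise ValueError("max_distance_nm must be positive")


@dataclass
class ColocalizationResult:
    """Classification of one registered field of view.

    ``n_total`` counts each heterotypic pair once:
    n_total = #pairs + #greenOnly + #redOnly.  Percentages are ``None``
    when the field is empty.
    """

    heterotypic_pairs: list[tuple[int, int, float]]  # (green id, red id, distance nm)
    green_only: list[int]
    red_only: list[int]

    @property
    def n_total(self) -> int:
        return len(self.heterotypic_pairs) + len(self.green_only) + len(self.red_only)

    def _pct(self, k: int) -> float | None:
        return None if self.n_total == 0 else 100.0 * k / self.n_total

    @property
    def pct_heterotypic(self) -> float | None:
        return self._pct(len(self.heterotypic_pairs))

    @property
    def pct_green_only(self) -> float | None:
        return self._pct(len(self.green_only))

    @property
    def pct_red_only(self) -> float | None:
        return self._pct(len(self.red_only))

    def percentages(self) -> dict[str, float | None]:
        return {
            "heterotypic": self.pct_heterotypic,
            "greenOnly": self.pct_green_only,
            "redOnly": self.pct_red_only,
        }


@dataclass
class FieldAggregate:
    """Mean +/- sd of class percentages across fields of view.

    Standard deviations are sample sds (ddof=1) over fields; a single
    field yields sd 0.  ``n_pooled`` is the summed particle count over
    all fields, reported separately from the field-level statistics.
    """

    per_field: list[ColocalizationResult]
    mean_pct: dict[str, float] = field(default_factory=dict)
    sd_pct: dict[str, float] = field(default_factory=dict)
    n_pooled: int = 0


def extract_centers(
    image: Image2D,
    circularity_min: float = 0.8,
    exclude_overlapping: bool = False,
    threshold_method: str = "otsu",
    min_area_px: int = 5,
) -> list[ParticleRecord]:
    """Segment an image and return droplet centers for colocalization.

    Particles are hole-filled before measurement (a droplet with smaller
    internal droplets is one entity) and fitted with a moments ellipse
    whose center is the reported position.  Deformed, non-circular
    particles are excluded by ``circularity_min``; with
    ``exclude_overlapping`` particles whose dilated masks touch another
    particle are also dropped (an automated proxy for excluding
    overlapping droplets).
    """
    try:
        particles = seg.segment_image(image, method=threshold_method, min_area_px=min_area_px)
    except seg.DegenerateHistogramError:
        return []
    if exclude_overlapping and len(particles) > 1:
        particles = _drop_touching(particles, image)
    return [p for p in particles if p.circularity >= circularity_min]


def _drop_touching(particles: list[ParticleRecord], image: Image2D) -> list[ParticleRecord]:
    """Drop particles whose 1-px-dilated bounding boxes intersect another's."""
    boxes = np.array([p.bbox for p in particles], dtype=float)
    grown = boxes + np.array([-1.0, -1.0, 1.0, 1.0])
    keep = []
    for i, p in enumerate(particles):
        a = grown[i]
        touching = False
        for j in range(len(particles)):
            if j == i:
                continue
            b = grown[j]
            if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                touching = True
                break
        if not touching:
            keep.append(p)
    return keep


def classify_droplets(
    green_centers: np.ndarray,
    red_centers: np.ndarray,
    criterion: ColocalizationCriterion = ColocalizationCriterion(),
) -> ColocalizationResult:
    """Classify registered detections into heterotypic and homotypic droplets.

    The full pairwise Euclidean distance matrix between green and red
    centers is computed; candidate pairs with distance strictly below
    the criterion are accepted greedily in ascending distance order,
    one-to-one, so each droplet joins at most one heterotypic entity.
    Unmatched green detections are green-only homotypic droplets,
    unmatched red detections red-only.

    Parameters
    ----------
    green_centers, red_centers : (n, 2) arrays
        (x, y) positions in nm, already in a common registered frame.
    """
    green = np.asarray(green_centers, dtype=float).reshape(-1, 2)
    red = np.asarray(red_centers, dtype=float).reshape(-1, 2)
    matched_g: dict[int, tuple[int, float]] = {}
    matched_r: set[int] = set()
    if len(green) and len(red):
        dist = cdist(green, red)
        gi, ri = np.nonzero(dist < criterion.max_distance_nm)
        order = np.argsort(dist[gi, ri], kind="stable")
        for k in order:
            g, r = int(gi[k]), int(ri[k])
            if g in matched_g or r in matched_r:
                continue
            matched_g[g] = (r, float(dist[g, r]))
            matched_r.add(r)
    pairs = [(g, r, d) for g, (r, d) in sorted(matched_g.items())]
    green_only = [i for i in range(len(green)) if i not in matched_g]
    red_only = [i for i in range(len(red)) if i not in matched_r]
    return ColocalizationResult(pairs, green_only, red_only)


def aggregate_fields(results: list[ColocalizationResult]) -> FieldAggregate:
    """Average class percentages across fields of view (mean +/- sample sd)."""
    non_empty = [r for r in results if r.n_total > 0]
    if not non_empty:
        raise ValueError("all fields are empty; nothing to aggregate")
    table = {
        "heterotypic": [r.pct_heterotypic for r in non_empty],
        "greenOnly": [r.pct_green_only for r in non_empty],
        "redOnly": [r.pct_red_only for r in non_empty],
    }
    mean = {k: float(np.mean(v)) for k, v in table.items()}
    sd = {
        k: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0) for k, v in table.items()
    }
    return FieldAggregate(
        per_field=list(results),
        mean_pct=mean,
        sd_pct=sd,
        n_pooled=sum(r.n_total for r in non_empty),
    )
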