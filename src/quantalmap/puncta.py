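"""Fluorescent puncta detection and morphometrics on max-projected stacks.

Mirrors the standard confocal workflow: collapse the Z-stack with a maximum
intensity projection, threshold, take 8-connected components as puncta, and
quantify centroid (intensity-weighted, um), area (um^2) and sum/mean
intensity.  Pairwise statistics (colocalization deficits, AZ-PSD opposition
pairing, density per 10 um^2 of NMJ area) operate on the resulting sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

log = logging.getLogger(__name__)


@dataclass
class Punctum:
    id: int
    channel: str
    centroid: tuple[float, float]   # (x_um, y_um)
    area: float                     # um^2
    sum_intensity: float
    mean_intensity: float


@dataclass
class PunctaSet:
    """Detected puncta for one channel of one NMJ.

    ``labels`` is the filtered label image (0 = background) aligned with the
    analysed plane; ``nmj_area`` (um^2, e.g. from an HRP mask) must be set
    before asking for a density.
    """

    nmj_id: str
    channel: str
    puncta: list[Punctum]
    threshold_used: float
    pixel_size: float
    nmj_area: float | None = None
    labels: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.puncta)

    @property
    def centroids(self) -> np.ndarray:
        if not self.puncta:
            return np.empty((0, 2))
        return np.array([p.centroid for p in self.puncta])

    @property
    def ids(self) -> np.ndarray:
        return np.array([p.id for p in self.puncta], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [p.id for p in self.puncta],
            "channel": self.channel,
            "x_um": [p.centroid[0] for p in self.puncta],
            "y_um": [p.centroid[1] for p in self.puncta],
            "area_um2": [p.area for p in self.puncta],
            "sum_intensity": [p.sum_intensity for p in self.puncta],
            "mean_intensity": [p.mean_intensity for p in self.puncta],
        })


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over planes of a (planes, rows, cols) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be 3D with at least one plane")
    return stack.max(axis=0)


def estimate_threshold(plane: np.ndarray, k: float = 3.0) -> float:
    """Background median + k robust (MAD-based) SDs.

    A reproducible stand-in for an operator-set "preset threshold": with
    puncta sparse, the median and MAD are dominated by background, so the
    threshold sits k noise SDs above it without the downward bias a
    truncated low-intensity sample would have.
    """
    plane = np.asarray(plane, dtype=float)
    med = float(np.median(plane))
    sigma = 1.4826 * float(np.median(np.abs(plane - med)))
    return med + k * sigma


def detect_puncta(
    plane: np.ndarray,
    pixel_size: float,
    threshold: float | None = None,
    min_area: int = 4,
    *,
    nmj_id: str = "nmj",
    channel: str = "",
) -> PunctaSet:
    """Find-objects style puncta detection on a single plane.

    Supra-threshold pixels are grouped by 8-connectivity; components smaller
    than ``min_area`` px are dropped.  Centroids are intensity-weighted and
    converted to um (pixel i spans [i, i+1) px with its center at i+0.5).
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    plane = np.asarray(plane, dtype=float)
    if threshold is None:
        threshold = estimate_threshold(plane)
    mask = plane > threshold
    if mask.all():
        log.warning("entire plane above threshold: one giant object "
                    "(saturated or constant image?)")
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels, intensity_image=plane)

    puncta: list[Punctum] = []
    keep = np.zeros(labels.max() + 1, dtype=int)
    next_id = 0
    for rp in props:
        if rp.area < min_area:
            continue
        cy, cx = rp.centroid_weighted
        total = float(rp.image_intensity[rp.image].sum())
        puncta.append(Punctum(
            id=next_id,
            channel=channel,
            centroid=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size),
            area=float(rp.area) * pixel_size ** 2,
            sum_intensity=total,
            mean_intensity=total / float(rp.area),
        ))
        keep[rp.label] = next_id + 1
        next_id += 1
    return PunctaSet(nmj_id=nmj_id, channel=channel, puncta=puncta,
                     threshold_used=float(threshold), pixel_size=pixel_size,
                     labels=keep[labels])


def nmj_mask_area(plane: np.ndarray, pixel_size: float, k: float = 1.0) -> float:
    """NMJ area (um^2) from a loose intensity mask (HRP-channel analog)."""
    thr = estimate_threshold(plane, k=k)
    return float((np.asarray(plane) > thr).sum()) * pixel_size ** 2


def colocalize_fraction(set_a: PunctaSet, set_b: PunctaSet,
                        max_dist: float) -> tuple[float, float]:
    """Percent of A puncta lacking any B within ``max_dist`` um, and reverse.

    An empty query set yields NaN ("undefined"), never 0.
    """
    def lacking(query: PunctaSet, ref: PunctaSet) -> float:
        if len(query) == 0:
            log.warning("colocalize_fraction: empty query set %s/%s",
                        query.nmj_id, query.channel)
            return math.nan
        if len(ref) == 0:
            return 100.0
        d, _ = cKDTree(ref.centroids).query(query.centroids)
        return 100.0 * float(np.mean(d > max_dist))

    return lacking(set_a, set_b), lacking(set_b, set_a)


def opposition_pairs(az: PunctaSet, psd: PunctaSet,
                     max_dist: float = 0.8) -> pd.DataFrame:
    """Greedy mutual-nearest AZ-PSD pairing within ``max_dist`` um.

    Candidate pairs are taken shortest-distance first (ties broken by the
    smaller AZ id, then PSD id); each punctum pairs at most once.  Unpaired
    entries are retained with a missing partner, so
    paired + unpaired == len(az) + len(psd) - paired.
    """
    a_ids, b_ids = az.ids, psd.ids
    pairs: list[tuple[float, int, int]] = []
    if len(az) and len(psd):
        d = np.linalg.norm(az.centroids[:, None, :] - psd.centroids[None, :, :],
                           axis=2)
        ii, jj = np.nonzero(d <= max_dist)
        pairs = sorted(zip(d[ii, jj], a_ids[ii], b_ids[jj]),
                       key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for dist, ai, bi in pairs:
        if ai in used_a or bi in used_b:
            continue
        used_a.add(ai)
        used_b.add(bi)
        rows.append((ai, bi, float(dist)))
    for ai in a_ids:
        if ai not in used_a:
            rows.append((ai, pd.NA, math.nan))
    for bi in b_ids:
        if bi not in used_b:
            rows.append((pd.NA, bi, math.nan))
    return pd.DataFrame(rows, columns=["az_id", "psd_id", "distance_um"])


def density(pset: PunctaSet) -> float:
    """Puncta count per 10 um^2 of NMJ area."""
    if pset.nmj_area is None or pset.nmj_area <= 0:
        raise ValueError("nmj_area must be set and > 0 to compute a density")
    return 10.0 * len(pset) / pset.nmj_area
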