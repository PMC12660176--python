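"""Synapse age classification from two-color photoconversion labels.

After photoconversion (PC), receptor pools present at the time of the pulse
are red ("old") while receptors delivered afterwards are green ("new").  A
PSD is classified old when its red sum intensity exceeds a threshold; red
sums are normalized per NMJ with the brightest PSD set to 1.0 before pooling
across animals, and related to per-ROI release output and bouton position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .puncta import PunctaSet, detect_puncta, estimate_threshold, max_project

log = logging.getLogger(__name__)


def measure_psd_channels(
    red_stack: np.ndarray,
    green_stack: np.ndarray,
    pixel_size: float,
    threshold: float | None = None,
    min_area: int = 4,
    *,
    nmj_id: str = "nmj",
) -> tuple[pd.DataFrame, PunctaSet]:
    """Measure red and green sums over shared PSD masks.

    PSDs are detected on the summed (red + green) max projection so masks are
    identical for both channels; per-channel background (median outside all
    masks) is subtracted before summing.  Returns the measurement table
    (psd_id, x_um, y_um, area_px, red_sum, green_sum, red_sum_threshold) and
    the detection PunctaSet.  ``red_sum_threshold`` is a per-PSD integrated
    detection floor, 3 * red noise SD * sqrt(mask area).
    """
    red = max_project(red_stack).astype(float)
    green = max_project(green_stack).astype(float)
    combined = red + green
    pset = detect_puncta(combined, pixel_size, threshold=threshold,
                         min_area=min_area, nmj_id=nmj_id, channel="psd")
    labels = pset.labels
    outside = labels == 0
    red_bg = float(np.median(red[outside])) if outside.any() else 0.0
    green_bg = float(np.median(green[outside])) if outside.any() else 0.0
    red_noise_sd = float(1.4826 * np.median(np.abs(red[outside] - red_bg))) \
        if outside.any() else 0.0

    rows = []
    for p in pset.puncta:
        mask = labels == p.id + 1
        area = int(mask.sum())
        rows.append((
            p.id, p.centroid[0], p.centroid[1], area,
            float((red[mask] - red_bg).sum()),
            float((green[mask] - green_bg).sum()),
            3.0 * red_noise_sd * np.sqrt(area),
        ))
    df = pd.DataFrame(rows, columns=["psd_id", "x_um", "y_um", "area_px",
                                     "red_sum", "green_sum",
                                     "red_sum_threshold"])
    return df, pset


def classify_age(psd_table: pd.DataFrame,
                 red_threshold: float | np.ndarray | None = None
                 ) -> pd.DataFrame:
    """Old/new classification and per-NMJ normalized red intensity.

    A PSD is old iff ``red_sum > red_threshold`` (scalar, per-row array, or
    the table's own ``red_sum_threshold`` column when None).  ``norm_red`` is
    red_sum divided by the NMJ's maximum red_sum (brightest PSD = 1.0);
    invariant to global rescaling of the red channel.
    """
    if len(psd_table) == 0:
        return psd_table.assign(norm_red=pd.Series(dtype=float),
                                age_class=pd.Series(dtype=object))
    if red_threshold is None:
        if "red_sum_threshold" not in psd_table:
            raise ValueError("red_threshold not given and table has no "
                             "red_sum_threshold column")
        red_threshold = psd_table["red_sum_threshold"].to_numpy()
    red = psd_table["red_sum"].to_numpy(dtype=float)
    max_red = red.max()
    norm = red / max_red if max_red > 0 else np.zeros_like(red)
    out = psd_table.copy()
    out["norm_red"] = norm
    out["age_class"] = np.where(red > red_threshold, "old", "new")
    return out


@dataclass
class AgeOutputStats:
    """Correlation and group contrasts between PSD age and release output."""

    n: int
    r_pr: float                 # Pearson r, norm_red vs evoked Pr
    p_pr: float
    r_spont: float              # Pearson r, norm_red vs spontaneous rate
    p_spont: float
    mean_pr_old: float
    mean_pr_new: float
    pr_fold: float              # mean_pr_old / mean_pr_new
    mean_spont_old: float
    mean_spont_new: float
    spont_fold: float


def age_output_correlation(labels: pd.DataFrame, rmap_table: pd.DataFrame,
                           pairing: pd.DataFrame) -> AgeOutputStats:
    """Relate PSD age labels to the opposed ROI's Pr and spontaneous rate.

    ``pairing`` maps psd_id to az_id (the ROI id); PSDs without a partner
    are dropped.  Requires >= 3 matched pairs.
    """
    pairs = pairing.dropna(subset=["az_id", "psd_id"])
    merged = (labels.merge(pairs[["az_id", "psd_id"]], on="psd_id")
              .merge(rmap_table, left_on="az_id", right_on="roi_id"))
    if len(merged) < 3:
        raise ValueError("need at least 3 PSD-ROI pairs for a correlation")
    def _safe_pearson(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), float("nan")
        return pearsonr(x, y)

    r_pr, p_pr = _safe_pearson(merged["norm_red"], merged["pr"])
    r_sp, p_sp = _safe_pearson(merged["norm_red"], merged["spont_rate"])
    old = merged[merged["age_class"] == "old"]
    new = merged[merged["age_class"] == "new"]
    mean = lambda s: float(s.mean()) if len(s) else float("nan")
    m_pr_old, m_pr_new = mean(old["pr"]), mean(new["pr"])
    m_sp_old, m_sp_new = mean(old["spont_rate"]), mean(new["spont_rate"])
    return AgeOutputStats(
        n=len(merged), r_pr=float(r_pr), p_pr=float(p_pr),
        r_spont=float(r_sp), p_spont=float(p_sp),
        mean_pr_old=m_pr_old, mean_pr_new=m_pr_new,
        pr_fold=m_pr_old / m_pr_new if m_pr_new else float("nan"),
        mean_spont_old=m_sp_old, mean_spont_new=m_sp_new,
        spont_fold=m_sp_old / m_sp_new if m_sp_new else float("nan"))


def bouton_position_fraction(labels: pd.DataFrame) -> pd.DataFrame:
    """Percent of old PSDs among all PSDs per bouton.

    ``labels`` needs ``age_class`` and ``bouton_index`` columns (terminal
    bouton = 0, second from the end = 1, ...).  Boutons with no PSDs cannot
    appear; an all-empty input yields an empty table with a warning.
    """
    if len(labels) == 0:
        log.warning("bouton_position_fraction: no PSDs")
        return pd.DataFrame(columns=["bouton_index", "n_psd", "pct_old"])
    grp = labels.groupby("bouton_index")["age_class"]
    out = pd.DataFrame({
        "bouton_index": grp.count().index,
        "n_psd": grp.count().to_numpy(),
        "pct_old": 100.0 * grp.apply(lambda s: (s == "old").mean()).to_numpy(),
    }).reset_index(drop=True)
    return out


def count_old_psd_stability(n_old_t1: int, n_old_t2: int) -> float:
    """Ratio of old-PSD counts between two sessions, as a percentage.

    100% means the photoconverted pool neither seeds new PSDs nor disappears
    (no lateral receptor movement between synapses).
    """
    if n_old_t1 <= 0:
        raise ValueError("no old PSDs at the first timepoint")
    return 100.0 * n_old_t2 / n_old_t1
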