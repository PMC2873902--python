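"""Stimulus-dependent salience from low-level image features.

Two features are computed on the full-field source images: luminance
contrast (LC), the Gaussian-windowed local standard deviation of luminance
normalized by the mean luminance over all images of a task, and texture
contrast (TC), the Gaussian-windowed local standard deviation of an inner
LC map (computed with a quarter-size window) normalized by the task-mean of
that inner map.  The outer window equals the bubble envelope (sd 1 degree).

A free-viewing baseline dataset calibrates, per feature, the conditional
probability of fixating a location given its feature value, over 20
equal-population bins via Bayes' rule with an inverse-central-bias
correction.  The stimulus-dependent salience of a bubble is the product of
the two per-feature fixation probabilities read off at the bubble's center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stimulus import BUBBLE_SIGMA_DEG, Bubble, ScreenGeometry, Trial

logger = logging.getLogger(__name__)

N_BINS = 20
PROB_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# contrast maps
# ---------------------------------------------------------------------------


def _windowed_sd(img: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian-weighted local standard deviation."""
    mean = ndimage.gaussian_filter(img, sigma_px, mode="nearest")
    mean_sq = ndimage.gaussian_filter(img * img, sigma_px, mode="nearest")
    return np.sqrt(np.maximum(mean_sq - mean * mean, 0.0))


@dataclass
class FeatureMaps:
    """Per-pixel LC and TC maps of one image plus the task normalizers."""

    LC: np.ndarray
    TC: np.ndarray
    task_mean_luminance: float
    task_mean_inner_LC: float
    geometry: ScreenGeometry

    def value_at(self, feature: str, x_deg: float, y_deg: float) -> float:
        grid = self.LC if feature == "LC" else self.TC
        ppd = self.geometry.px_per_deg
        iy = int(np.clip(round(y_deg * ppd), 0, grid.shape[0] - 1))
        ix = int(np.clip(round(x_deg * ppd), 0, grid.shape[1] - 1))
        return float(grid[iy, ix])


def contrast_maps(
    image: np.ndarray,
    task_images: list[np.ndarray],
    geometry: ScreenGeometry | None = None,
    sigma_outer_deg: float = BUBBLE_SIGMA_DEG,
    sigma_inner_deg: float | None = None,
) -> FeatureMaps:
    """Compute LC and TC maps of ``image`` with task-level normalization.

    LC(x) = windowed_sd(I; sigma_outer) / mean luminance over the task's
    images.  An inner LC map with ``sigma_inner`` (default a quarter of the
    bubble sd) feeds TC(x) = windowed_sd(innerLC; sigma_outer) / mean inner
    LC over the task's images.  Scaling all task images by a constant
    leaves both maps unchanged.
    """
    geometry = geometry or ScreenGeometry()
    if not task_images:
        raise ValueError("empty task image set: cannot normalize contrasts")
    if sigma_inner_deg is None:
        sigma_inner_deg = sigma_outer_deg / 4.0
    ppd = geometry.px_per_deg
    s_out, s_in = sigma_outer_deg * ppd, sigma_inner_deg * ppd

    mean_lum = float(np.mean([im.mean() for im in task_images]))
    if mean_lum <= 0:
        raise ValueError("task images have non-positive mean luminance")
    LC = _windowed_sd(np.asarray(image, float), s_out) / mean_lum

    inner = _windowed_sd(np.asarray(image, float), s_in)
    mean_inner = float(
        np.mean([_windowed_sd(np.asarray(im, float), s_in).mean() for im in task_images])
    )
    if mean_inner <= 0:
        # perfectly flat task set: TC is identically zero, keep it defined
        mean_inner = 1.0
    TC = _windowed_sd(inner, s_out) / mean_inner
    return FeatureMaps(LC, TC, mean_lum, mean_inner, geometry)


# ---------------------------------------------------------------------------
# equal-population binning
# ---------------------------------------------------------------------------


@dataclass
class BinMapping:
    """Feature-value bins and the fixation probability of each bin."""

    edges: np.ndarray  # length k + 1, edges[0] = -inf-ish min, edges[-1] = max
    probability: np.ndarray  # length k, positive, sums to 1
    feature: str = ""
    equal_populations: bool = True

    def bin_of(self, value: float) -> int:
        k = len(self.probability)
        return int(np.clip(np.searchsorted(self.edges, value, side="right") - 1, 0, k - 1))

    def prob_of(self, value: float) -> float:
        return float(self.probability[self.bin_of(value)])


def equal_population_bins(values: np.ndarray, k: int = N_BINS) -> np.ndarray:
    """Bin edges at order statistics so each bin holds the same number of
    locations (within one).  Massive ties spanning an edge cannot be split;
    the edge then sits after the tie block and a warning is logged."""
    values = np.asarray(values, float).ravel()
    if np.unique(values).size < k:
        raise ValueError(
            f"need at least {k} distinct values for {k} equal-population bins"
        )
    edges = np.quantile(values, np.linspace(0.0, 1.0, k + 1))
    if np.any(np.diff(edges) <= 0):
        logger.warning("ties force unequal bin populations; merging tied edges")
        edges = np.maximum.accumulate(edges + np.arange(k + 1) * 1e-12)
    counts = np.histogram(values, bins=edges)[0]
    if counts.max() - counts.min() > max(2, 0.01 * values.size):
        logger.warning("bin populations unequal (range %d-%d)", counts.min(), counts.max())
    return edges


# ---------------------------------------------------------------------------
# baseline calibration: Bayes mapping from feature bin to fixation probability
# ---------------------------------------------------------------------------


def feature_fixation_mapping(
    baseline_trials: list[Trial],
    baseline_maps: dict[str, FeatureMaps],
    feature: str,
    central_bias: np.ndarray | None = None,
    geometry: ScreenGeometry | None = None,
    k: int = N_BINS,
    floor: float = PROB_FLOOR,
) -> BinMapping:
    """Calibrate P(fixation | feature bin) from free-viewing data.

    By Bayes' rule P(fix | bin) is proportional to P(bin | fix) * P(fix) /
    P(bin).  Equal-population binning over all image locations makes
    P(bin) constant, and P(fix) is constant over locations, so the mapping
    reduces to the (bias-corrected) distribution of fixated feature bins.
    The spatial-bias correction weights each fixation inversely by the
    central-bias density at its location, removing the component of feature
    selection that is explained by *where* people look rather than *what*
    they look at.

    ``baseline_maps`` maps stimulus_id -> FeatureMaps of the viewed image.
    ``central_bias`` is a density grid over the screen (same raster).
    """
    geometry = geometry or ScreenGeometry()
    all_values = np.concatenate(
        [
            (m.LC if feature == "LC" else m.TC).ravel()
            for m in baseline_maps.values()
        ]
    )
    edges = equal_population_bins(all_values, k)

    weights = np.zeros(k)
    ppd = geometry.px_per_deg
    for t in baseline_trials:
        maps = baseline_maps.get(t.stimulus_id)
        if maps is None:
            continue
        for f in t.analysis_fixations():
            v = maps.value_at(feature, f.x_deg, f.y_deg)
            b = int(np.clip(np.searchsorted(edges, v, side="right") - 1, 0, k - 1))
            w = 1.0
            if central_bias is not None:
                iy = int(np.clip(round(f.y_deg * ppd), 0, central_bias.shape[0] - 1))
                ix = int(np.clip(round(f.x_deg * ppd), 0, central_bias.shape[1] - 1))
                dens = central_bias[iy, ix]
                w = 1.0 / max(dens, floor)
            weights[b] += w
    if weights.sum() <= 0:
        raise ValueError("no baseline fixations fell on calibrated images")
    prob = np.maximum(weights / weights.sum(), floor)
    prob /= prob.sum()
    return BinMapping(edges, prob, feature=feature)


# ---------------------------------------------------------------------------
# per-bubble stimulus-dependent salience
# ---------------------------------------------------------------------------


def stimulus_dependent_salience(
    bubble: Bubble,
    mapping_lc: BinMapping,
    mapping_tc: BinMapping,
    source_maps: FeatureMaps,
) -> float:
    """Product of the two per-feature fixation probabilities at the bubble's
    center, read from the full-field source image's maps.  Values outside
    the calibrated range use the nearest bin."""
    lc = source_maps.value_at("LC", bubble.center_x_deg, bubble.center_y_deg)
    tc = source_maps.value_at("TC", bubble.center_x_deg, bubble.center_y_deg)
    for name, val, mp in (("LC", lc, mapping_lc), ("TC", tc, mapping_tc)):
        if val < mp.edges[0] or val > mp.edges[-1]:
            logger.info("%s value %.4g outside calibrated range; nearest bin used", name, val)
    return mapping_lc.prob_of(lc) * mapping_tc.prob_of(tc)


def salience_table(
    bubbles: list[Bubble],
    mapping_lc: BinMapping,
    mapping_tc: BinMapping,
    maps_by_image: dict[str, FeatureMaps],
):
    """Stimulus-dependent salience for every bubble, keyed by bubble_id."""
    import pandas as pd

    vals = {
        b.bubble_id: stimulus_dependent_salience(
            b, mapping_lc, mapping_tc, maps_by_image[b.source_image_id]
        )
        for b in bubbles
    }
    return pd.Series(vals, name="feature_salience").rename_axis("bubble_id")
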