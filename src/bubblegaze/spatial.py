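"""Spatial-bias salience from a generative scanpath model.

Two empirical densities are estimated from free-viewing baseline data: the
*central-bias map* (fixation positions in screen coordinates) and the
*saccade map* (fixation-to-fixation displacement vectors).  Both are
per-trial histograms smoothed with a 0.5-degree Gaussian kernel, normalized
to unit mass, and averaged with equal weight per trial.

The generative model then simulates gaze on a bubble stimulus: the central
bias is multiplied point-wise with the stimulus's bubble-position map (the
point-wise maximum of the Gaussian bubble envelopes); each next fixation is
drawn from that intermediate map multiplied by the saccade map centered on
the current fixation (the screen center before the first fixation) and
renormalized.  The model is first-order: no inhibition of return.

Simulated fixation counts per bubble are converted to a global salience
with the same fraction-averaging and least-squares machinery as the
empirical salience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import empirical
from .stimulus import (
    Fixation,
    ScreenGeometry,
    Stimulus,
    Trial,
    assign_fixations,
)

logger = logging.getLogger(__name__)

SMOOTHING_SD_DEG = 0.5
#: default raster of the bias/sampling grids, degrees per cell
DEFAULT_GRID_STEP_DEG = 0.25


@dataclass
class BiasMaps:
    """Central-bias and saccade-displacement densities on a screen raster."""

    central: np.ndarray  # (ny, nx), sums to 1
    saccade: np.ndarray  # (2*ny - 1, 2*nx - 1), sums to 1
    grid_step_deg: float
    geometry: ScreenGeometry
    smoothing_sd_deg: float = SMOOTHING_SD_DEG

    @property
    def shape(self) -> tuple[int, int]:
        return self.central.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.central.shape
        xs = (np.arange(nx) + 0.5) * self.grid_step_deg
        ys = (np.arange(ny) + 0.5) * self.grid_step_deg
        return xs, ys


def _grid_shape(geometry: ScreenGeometry, step: float) -> tuple[int, int]:
    return (
        int(np.ceil(geometry.height_deg / step)),
        int(np.ceil(geometry.width_deg / step)),
    )


def _cell_of(x: float, y: float, step: float, shape: tuple[int, int]) -> tuple[int, int]:
    iy = int(np.clip(np.floor(y / step), 0, shape[0] - 1))
    ix = int(np.clip(np.floor(x / step), 0, shape[1] - 1))
    return iy, ix


def estimate_bias_maps(
    baseline_trials: list[Trial],
    geometry: ScreenGeometry | None = None,
    grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
    smoothing_sd_deg: float = SMOOTHING_SD_DEG,
) -> BiasMaps:
    """Estimate central-bias and saccade maps from free-viewing trials.

    Every trial contributes one smoothed, unit-mass fixation histogram and
    (if it has at least two analysis fixations) one smoothed, unit-mass
    displacement histogram; the maps are the equal-weight trial averages,
    so a 100-fixation trial counts exactly as much as a 2-fixation one.
    """
    geometry = geometry or ScreenGeometry()
    if not baseline_trials:
        raise ValueError("no baseline trials")
    ny, nx = _grid_shape(geometry, grid_step_deg)
    sshape = (2 * ny - 1, 2 * nx - 1)
    sig = smoothing_sd_deg / grid_step_deg

    central = np.zeros((ny, nx))
    saccade = np.zeros(sshape)
    n_c = n_s = 0
    for t in baseline_trials:
        fixes = t.analysis_fixations()
        if not fixes:
            continue
        h = np.zeros((ny, nx))
        for f in fixes:
            iy, ix = _cell_of(f.x_deg, f.y_deg, grid_step_deg, (ny, nx))
            h[iy, ix] += 1
        h = ndimage.gaussian_filter(h, sig, mode="constant")
        central += h / h.sum()
        n_c += 1
        if len(fixes) >= 2:
            hs = np.zeros(sshape)
            for a, b in zip(fixes[:-1], fixes[1:]):
                dy = int(np.clip(round((b.y_deg - a.y_deg) / grid_step_deg) + ny - 1, 0, sshape[0] - 1))
                dx = int(np.clip(round((b.x_deg - a.x_deg) / grid_step_deg) + nx - 1, 0, sshape[1] - 1))
                hs[dy, dx] += 1
            hs = ndimage.gaussian_filter(hs, sig, mode="constant")
            saccade += hs / hs.sum()
            n_s += 1
    if n_c == 0:
        raise ValueError("no trial contained analysis fixations")
    central /= central.sum()
    if n_s == 0:
        logger.warning("no trial had >= 2 fixations; saccade map left flat")
        saccade = np.full(sshape, 1.0 / (sshape[0] * sshape[1]))
    else:
        saccade /= saccade.sum()
    return BiasMaps(central, saccade, grid_step_deg, geometry, smoothing_sd_deg)


def flat_bias_maps(
    geometry: ScreenGeometry | None = None,
    grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
) -> BiasMaps:
    """Uniform central and saccade maps (the model's neutral reference)."""
    geometry = geometry or ScreenGeometry()
    ny, nx = _grid_shape(geometry, grid_step_deg)
    central = np.full((ny, nx), 1.0 / (ny * nx))
    ss = (2 * ny - 1, 2 * nx - 1)
    return BiasMaps(central, np.full(ss, 1.0 / (ss[0] * ss[1])), grid_step_deg, geometry)


def bubble_position_map(stimulus: Stimulus, maps: BiasMaps) -> np.ndarray:
    """Point-wise maximum of the stimulus's Gaussian bubble envelopes
    (value 1 at each bubble center); the max avoids double-counting where
    envelope tails meet."""
    xs, ys = maps.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    out = np.zeros_like(xx)
    for b in stimulus.bubbles:
        r2 = (xx - b.center_x_deg) ** 2 + (yy - b.center_y_deg) ** 2
        np.maximum(out, np.exp(-r2 / (2.0 * b.sigma_deg**2)), out=out)
    return out


def next_fixation_map(
    intermediate: np.ndarray,
    maps: BiasMaps,
    current_cell: tuple[int, int],
) -> np.ndarray:
    """Sampling density for the next fixation: the intermediate map times
    the saccade map aligned to the current fixation, renormalized.  Falls
    back to the intermediate map when the product has no mass."""
    ny, nx = intermediate.shape
    iy, ix = current_cell
    win = maps.saccade[ny - 1 - iy : 2 * ny - 1 - iy, nx - 1 - ix : 2 * nx - 1 - ix]
    prod = intermediate * win
    total = prod.sum()
    if total <= 0:
        logger.warning("all-zero product map; falling back to intermediate map")
        prod, total = intermediate, intermediate.sum()
    return prod / total


def simulate_trajectories(
    stimuli: list[Stimulus],
    maps: BiasMaps,
    trial_lengths: list[tuple[str, str, int]],
    seed: int | np.random.Generator = 0,
) -> list[Trial]:
    """Simulate one gaze trajectory per entry of ``trial_lengths``.

    ``trial_lengths`` holds (participant_id, stimulus_id, n_fixations)
    matched to the corresponding original trials, so the simulation makes
    exactly as many fixations per trial as the subject did.  The first
    fixation of each simulated trial (saccade map aligned to the screen
    center) is emitted with order_index 0 and hence excluded from analysis,
    mirroring the convention for recorded data.  Fixation coordinates are
    jittered uniformly within their grid cell.
    """
    rng = np.random.default_rng(seed)
    by_id = {s.stimulus_id: s for s in stimuli}
    step = maps.grid_step_deg
    ny, nx = maps.central.shape
    center_cell = _cell_of(*maps.geometry.center, step, (ny, nx))

    inter_cache: dict[str, np.ndarray] = {}
    trials: list[Trial] = []
    for pid, sid, n_fix in trial_lengths:
        s = by_id[sid]
        inter = inter_cache.get(sid)
        if inter is None:
            if s.is_fullfield:
                inter = maps.central.copy()
            else:
                inter = maps.central * bubble_position_map(s, maps)
                if inter.sum() <= 0:
                    logger.warning(
                        "bubbles of %s outside bias support; using central map", sid
                    )
                    inter = maps.central.copy()
            inter = inter / inter.sum()
            inter_cache[sid] = inter
        cell = center_cell
        fixes = []
        for i in range(n_fix):
            dens = next_fixation_map(inter, maps, cell)
            flat = np.cumsum(dens.ravel())
            j = int(np.searchsorted(flat, rng.random() * flat[-1]))
            iy, ix = divmod(min(j, dens.size - 1), nx)
            x = (ix + rng.random()) * step
            y = (iy + rng.random()) * step
            fixes.append(Fixation(x, y, i))
            cell = (iy, ix)
        trials.append(Trial(pid, sid, tuple(fixes), response=""))
    return trials


def spatial_bias_salience(
    simulated_trials: list[Trial],
    stimuli: list[Stimulus] | dict[str, Stimulus],
    geometry: ScreenGeometry | None = None,
) -> empirical.SalienceSolution:
    """Global spatial-bias salience: the simulated fixation counts are put
    through the same fraction-averaging and constrained least-squares
    transform as the real data's empirical salience; the result sums to 1."""
    fractions = empirical.observed_fractions(simulated_trials, stimuli, geometry)
    return empirical.solve_salience(fractions, stimuli)


def per_bubble_probabilities(
    simulated_trials: list[Trial],
    stimuli: list[Stimulus] | dict[str, Stimulus],
    geometry: ScreenGeometry | None = None,
) -> dict[str, float]:
    """Overall fraction of simulated bubble-assigned fixations per bubble
    (pooled over trials); used for the flat-map reduction checks."""
    if not isinstance(stimuli, dict):
        stimuli = {s.stimulus_id: s for s in stimuli}
    counts: dict[str, int] = {}
    for t in simulated_trials:
        asg = assign_fixations(t, stimuli[t.stimulus_id], geometry)
        for bid, c in asg.bubble_counts.items():
            counts[bid] = counts.get(bid, 0) + c
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()} if total else {}
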