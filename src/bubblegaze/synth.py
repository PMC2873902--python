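"""Synthetic bubble experiments with known ground truth.

This module generates complete studies — bubble pools, stimulus sets,
free-viewing baseline data, fixation trajectories and classification
responses — whose statistical structure matches the assumptions of the
analysis pipeline: every bubble owns a latent response distribution and a
latent global salience; fixations target bubbles in proportion to that
salience with central-bias structure, Gaussian landing scatter and small
corrective saccades; responses are sampled from the probabilistic
integration of the member bubbles' distributions.  Because the generating
parameters are retained, every downstream estimator can be checked for
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .info import integrate_pmodel, stimulus_information
from .stimulus import (
    BUBBLE_SIGMA_DEG,
    TASK_CLASSES,
    Bubble,
    Fixation,
    ScreenGeometry,
    Stimulus,
    StimulusDesign,
    Trial,
    build_stimulus_set,
)

SALIENCE_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentDesign:
    """Scale and behavioral parameters of a synthetic study.

    Defaults reproduce the scale of the recorded study: 75 participants at
    280 trials each (21000 trials), a mean of 6.2 analysis fixations per
    trial, and corrective saccades that bring within-bubble refixations on
    average 0.16 degrees closer to the bubble center.
    """

    n_participants: int = 75
    trials_per_participant: int = 280
    mean_fixations: float = 6.2
    landing_scatter_sd_deg: float = 0.45
    corrective_approach_deg: float = 0.16
    #: probabilities that a fixation targets the screen center / is scattered
    p_center: float = 0.03
    p_scattered: float = 0.03
    central_fix_sd_deg: float = 0.5
    fullfield_accuracy: float = 0.94

    def __post_init__(self):
        if self.n_participants <= 0 or self.trials_per_participant <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.p_center + self.p_scattered < 1:
            raise ValueError("off-bubble probabilities must sum below 1")

    @property
    def subsequent_shrink(self) -> float:
        """Scatter shrink factor for within-bubble refixations, calibrated
        so the mean radial approach equals ``corrective_approach_deg``
        (mean radial distance of isotropic scatter sd s is s*sqrt(pi/2))."""
        mean_r = self.landing_scatter_sd_deg * math.sqrt(math.pi / 2.0)
        return max(0.0, 1.0 - self.corrective_approach_deg / mean_r)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Latent per-bubble state of a synthetic world.

    ``true_salience`` follows the same multiplicative structure the final
    regression assumes: exp of a weighted sum of the log feature, log
    information and log spatial components plus Gaussian log-noise,
    normalized to sum 1.
    """

    bubble_ids: list[str]
    response_dists: np.ndarray  # (n_bubbles, C)
    information: np.ndarray  # bits
    log_feature: np.ndarray
    log_info: np.ndarray  # log of floored information
    log_spatial: np.ndarray
    weights: tuple[float, float, float]  # (w_feature, w_info, w_spatial)
    log_noise_sd: float
    true_salience: np.ndarray  # positive, sums to 1

    def dist_of(self, bubble_id: str) -> np.ndarray:
        return self.response_dists[self.bubble_ids.index(bubble_id)]

    def salience_series(self) -> pd.Series:
        return pd.Series(
            self.true_salience, index=pd.Index(self.bubble_ids, name="bubble_id")
        )

    def info_series(self) -> pd.Series:
        return pd.Series(
            self.information, index=pd.Index(self.bubble_ids, name="bubble_id")
        )


def sample_ground_truth(
    n_bubbles: int,
    n_classes: int,
    concentration: float = 0.5,
    weights: tuple[float, float, float] = (0.3, 0.5, 0.7),
    log_noise_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
    bubble_ids: list[str] | None = None,
    log_feature: np.ndarray | None = None,
    log_spatial: np.ndarray | None = None,
    floor: float = SALIENCE_FLOOR,
) -> GroundTruth:
    """Draw the latent state of a synthetic world.

    Response distributions come from a symmetric Dirichlet with the given
    ``concentration``: small values yield near-deterministic (informative)
    bubbles, large values flat (uninformative) ones; the default 0.5 makes
    bubble information span its whole possible range.  Feature and spatial
    log-components default to standard-normal draws but can be supplied
    (e.g. the log central-bias density at each bubble's position) so the
    full pipeline sees coherent structure.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    ids = bubble_ids or [f"bub_{i:04d}" for i in range(n_bubbles)]
    if len(ids) != n_bubbles:
        raise ValueError("bubble_ids length mismatch")

    dists = rng.dirichlet(np.full(n_classes, concentration), size=n_bubbles)
    info = np.array([stimulus_information(p) for p in dists])

    lf = rng.standard_normal(n_bubbles) if log_feature is None else np.asarray(log_feature, float)
    ls = rng.standard_normal(n_bubbles) if log_spatial is None else np.asarray(log_spatial, float)
    li = np.log(np.maximum(info, floor))

    wf, wi, ws = weights
    log_sal = wf * lf + wi * li + ws * ls
    if log_noise_sd > 0:
        log_sal = log_sal + rng.normal(0.0, log_noise_sd, n_bubbles)
    sal = np.exp(log_sal - log_sal.max())
    sal = np.maximum(sal, floor)
    sal /= sal.sum()
    return GroundTruth(ids, dists, info, lf, li, ls, weights, log_noise_sd, sal)


def make_bubble_pool(
    n_bubbles: int,
    task: str,
    geometry: ScreenGeometry | None = None,
    seed: int | np.random.Generator = 0,
    n_images: int | None = None,
    min_separation_deg: float = 4.0,
    margin_deg: float = 3.0,
) -> list[Bubble]:
    """Scatter a pool of bubbles over registered source images.

    Bubble centers are drawn on a common position grid shared across
    images (mirroring the registered geometry of the source photographs),
    keeping within-image pairwise separations above the overlap threshold.
    Each image carries enough bubbles (at least six by default) that
    five-bubble single-image stimuli remain constructible.
    """
    geometry = geometry or ScreenGeometry()
    rng = np.random.default_rng(seed)
    classes = TASK_CLASSES[task]
    if n_images is None:
        n_images = max(2, n_bubbles // 6)
    per_image = int(np.ceil(n_bubbles / n_images))

    # shared candidate positions so different images have bubbles at the
    # same locations (needed for the permuted/congruent conditions)
    positions: list[tuple[float, float]] = []
    tries = 0
    while len(positions) < per_image * 3 and tries < 10000:
        tries += 1
        x = rng.uniform(margin_deg, geometry.width_deg - margin_deg)
        y = rng.uniform(margin_deg, geometry.height_deg - margin_deg)
        if all(math.dist((x, y), p) >= min_separation_deg for p in positions):
            positions.append((x, y))

    pool: list[Bubble] = []
    for im in range(n_images):
        cls = classes[im % len(classes)]
        sel = rng.choice(len(positions), size=per_image, replace=False)
        for j in sel:
            if len(pool) >= n_bubbles:
                break
            x, y = positions[j]
            pool.append(
                Bubble(
                    bubble_id=f"bub_{len(pool):04d}",
                    task=task,
                    source_image_id=f"img_{im:03d}",
                    source_class=cls,
                    center_x_deg=x,
                    center_y_deg=y,
                )
            )
    return pool


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------


def generate_images(
    geometry: ScreenGeometry,
    contrast_field,
    n_images: int = 1,
    mean_luminance: float = 0.5,
    cutoff_deg: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Band-limited noise textures with a prescribed local-contrast profile.

    ``contrast_field`` is either an array matching the pixel raster or a
    callable (x_deg, y_deg) -> nonnegative contrast; the local luminance sd
    of the output tracks it.  A zero field yields a constant image at
    ``mean_luminance``; the image mean is held at ``mean_luminance``.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    h, w = geometry.height_px, geometry.width_px
    if callable(contrast_field):
        xs = (np.arange(w) + 0.5) / geometry.px_per_deg
        ys = (np.arange(h) + 0.5) / geometry.px_per_deg
        xx, yy = np.meshgrid(xs, ys)
        field = np.asarray(contrast_field(xx, yy), dtype=float)
    else:
        field = np.asarray(contrast_field, dtype=float)
        if field.shape != (h, w):
            raise ValueError(f"contrast field shape {field.shape} != {(h, w)}")
    if np.any(field < 0):
        raise ValueError("contrast field must be nonnegative")

    out = []
    sig = cutoff_deg * geometry.px_per_deg
    for _ in range(n_images):
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), sig)
        sd = noise.std()
        noise = noise / sd if sd > 0 else noise
        img = mean_luminance + field * noise
        img = img - img.mean() + mean_luminance
        out.append(np.clip(img, 0.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# main experiment generator
# ---------------------------------------------------------------------------


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson truncated to >= 1 whose expectation equals ``mean``.

    Solves lam / (1 - exp(-lam)) = mean for the underlying rate so the
    reported mean fixation count is matched exactly in expectation.
    """
    from scipy import optimize

    lam = optimize.brentq(
        lambda L: L / (1.0 - math.exp(-L)) - mean, 1e-9, mean * 2 + 10
    )
    draws = rng.poisson(lam, size)
    while np.any(draws == 0):  # resample zeros (truncation)
        z = draws == 0
        draws[z] = rng.poisson(lam, int(z.sum()))
    return draws


def generate_experiment(
    design: ExperimentDesign,
    stimuli: list[Stimulus],
    truth: GroundTruth,
    seed: int | np.random.Generator = 0,
    geometry: ScreenGeometry | None = None,
) -> list[Trial]:
    """Simulate every trial of a synthetic study.

    Each participant runs through a shuffled assignment of stimuli.  Per
    trial the number of analysis fixations is truncated-Poisson with the
    design mean; an additional order-0 fixation near the screen center is
    emitted first and flagged excluded.  Each analysis fixation targets a
    bubble with probability proportional to the bubble's true salience
    (renormalized within the stimulus), lands with isotropic Gaussian
    scatter around the center, and within-bubble refixations shrink toward
    the center by the design's corrective factor.  The classification
    response is drawn from the p-model integration of the member bubbles'
    true response distributions.  Full-field stimuli get central-bias
    fixations and a class-dominant response.
    """
    rng = np.random.default_rng(seed)
    geometry = geometry or ScreenGeometry()
    scx, scy = geometry.center
    sal = truth.salience_series()
    shrink = design.subsequent_shrink
    task = stimuli[0].task
    classes = TASK_CLASSES[task]

    trials: list[Trial] = []
    order = np.arange(len(stimuli))
    for p in range(design.n_participants):
        pid = f"p{p:03d}"
        rng.shuffle(order)
        chosen = [stimuli[order[i % len(stimuli)]] for i in range(design.trials_per_participant)]
        n_fix = _truncated_poisson(rng, design.mean_fixations, len(chosen))
        for s, nf in zip(chosen, n_fix):
            fixes = [
                Fixation(
                    scx + rng.normal(0, design.central_fix_sd_deg),
                    scy + rng.normal(0, design.central_fix_sd_deg),
                    0,
                )
            ]
            if s.is_fullfield:
                for i in range(nf):
                    fixes.append(
                        Fixation(
                            float(np.clip(scx + rng.normal(0, 5.0), 0, geometry.width_deg)),
                            float(np.clip(scy + rng.normal(0, 5.0), 0, geometry.height_deg)),
                            i + 1,
                        )
                    )
                cls = rng.integers(len(classes))
                probs = np.full(
                    len(classes),
                    (1 - design.fullfield_accuracy) / (len(classes) - 1),
                )
                probs[cls] = design.fullfield_accuracy
                resp = classes[rng.choice(len(classes), p=probs)]
            else:
                w = sal.loc[list(s.bubble_ids())].to_numpy()
                w = w / w.sum()
                prev_bubble = None
                for i in range(nf):
                    u = rng.random()
                    if u < design.p_center:
                        fixes.append(
                            Fixation(
                                scx + rng.normal(0, design.central_fix_sd_deg / 2),
                                scy + rng.normal(0, design.central_fix_sd_deg / 2),
                                i + 1,
                            )
                        )
                        prev_bubble = None
                        continue
                    if u < design.p_center + design.p_scattered:
                        fixes.append(
                            Fixation(
                                rng.uniform(0, geometry.width_deg),
                                rng.uniform(0, geometry.height_deg),
                                i + 1,
                            )
                        )
                        prev_bubble = None
                        continue
                    j = int(rng.choice(len(w), p=w))
                    b = s.bubbles[j]
                    sd = design.landing_scatter_sd_deg
                    if b.bubble_id == prev_bubble:
                        sd *= shrink  # corrective saccade toward the center
                    fixes.append(
                        Fixation(
                            b.center_x_deg + rng.normal(0, sd),
                            b.center_y_deg + rng.normal(0, sd),
                            i + 1,
                        )
                    )
                    prev_bubble = b.bubble_id
                z = integrate_pmodel([truth.dist_of(b) for b in s.bubble_ids()])
                resp = classes[int(rng.choice(len(z), p=z))]
            trials.append(Trial(pid, s.stimulus_id, tuple(fixes), resp))
    return trials


def responses_table(trials: list[Trial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "stimulus_id": [t.stimulus_id for t in trials],
            "response": [t.response for t in trials],
        }
    )


def generate_responses_only(
    design: ExperimentDesign,
    stimuli: list[Stimulus],
    truth: GroundTruth,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Fast path: classification responses without fixation simulation,
    for fit-recovery studies that do not need gaze data."""
    rng = np.random.default_rng(seed)
    task = stimuli[0].task
    classes = TASK_CLASSES[task]
    bubbled = [s for s in stimuli if not s.is_fullfield]
    zs = {
        s.stimulus_id: integrate_pmodel([truth.dist_of(b) for b in s.bubble_ids()])
        for s in bubbled
    }
    n_total = design.n_participants * design.trials_per_participant
    idx = rng.integers(0, len(bubbled), size=n_total)
    rows = []
    for k, i in enumerate(idx):
        s = bubbled[i]
        z = zs[s.stimulus_id]
        rows.append(
            (
                f"p{k // design.trials_per_participant:03d}",
                s.stimulus_id,
                classes[int(rng.choice(len(z), p=z))],
            )
        )
    return pd.DataFrame(rows, columns=["participant_id", "stimulus_id", "response"])


# ---------------------------------------------------------------------------
# free-viewing baseline generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaselineSpec:
    """Generating densities of the free-viewing baseline.

    ``central_bias_sd_deg`` None means a flat (uniform) positional bias;
    ``saccade_sd_deg`` None means displacement proposals uniform over the
    screen.  ``feature_gain`` > 0 additionally weights fixation positions
    by exp(gain * normalized feature value) of the viewed image, giving the
    calibration module a known monotone target to recover.
    """

    central_bias_sd_deg: float | None = 5.0
    saccade_sd_deg: float | None = 4.0
    mean_fixations: float = 8.0
    feature_gain: float = 0.0


def generate_baseline(
    geometry: ScreenGeometry,
    spec: BaselineSpec,
    n_participants: int = 27,
    trials_per_participant: int = 40,
    seed: int | np.random.Generator = 0,
    images: dict[str, np.ndarray] | None = None,
    feature_maps: dict[str, np.ndarray] | None = None,
) -> list[Trial]:
    """Simulate free-viewing scanpaths on full-field images.

    Each next fixation is drawn from the product of the positional bias
    (central Gaussian or flat) and the saccade-displacement density
    (Gaussian around the current fixation or flat), by rejection sampling;
    an optional feature map modulates acceptance monotonically.  Trial ids
    cycle through the provided image ids (or synthetic ids).
    """
    rng = np.random.default_rng(seed)
    scx, scy = geometry.center
    image_ids = list(images) if images else [f"base_{i:03d}" for i in range(20)]
    fmaps = feature_maps or {}

    fnorm = {}
    for sid, fm in fmaps.items():
        lo, hi = float(fm.min()), float(fm.max())
        fnorm[sid] = (fm - lo) / (hi - lo) if hi > lo else np.zeros_like(fm)

    def accept_weight(x: float, y: float, sid: str) -> float:
        w = 1.0
        if spec.central_bias_sd_deg is not None:
            r2 = (x - scx) ** 2 + (y - scy) ** 2
            w *= math.exp(-r2 / (2 * spec.central_bias_sd_deg**2))
        if spec.feature_gain > 0 and sid in fnorm:
            fm = fnorm[sid]
            iy = int(np.clip(round(y * geometry.px_per_deg), 0, fm.shape[0] - 1))
            ix = int(np.clip(round(x * geometry.px_per_deg), 0, fm.shape[1] - 1))
            w *= math.exp(spec.feature_gain * (fm[iy, ix] - 1.0))
        return w

    trials: list[Trial] = []
    for p in range(n_participants):
        pid = f"base_p{p:03d}"
        for tr in range(trials_per_participant):
            sid = image_ids[(p * trials_per_participant + tr) % len(image_ids)]
            nf = int(_truncated_poisson(rng, spec.mean_fixations, 1)[0])
            fixes = []
            cur = (scx, scy)
            for i in range(nf + 1):  # +1: excluded first fixation
                for _ in range(500):
                    if i == 0 or spec.saccade_sd_deg is None:
                        x = rng.uniform(0, geometry.width_deg)
                        y = rng.uniform(0, geometry.height_deg)
                    else:
                        x = cur[0] + rng.normal(0, spec.saccade_sd_deg)
                        y = cur[1] + rng.normal(0, spec.saccade_sd_deg)
                        if not geometry.contains(x, y):
                            continue
                    if rng.random() <= accept_weight(x, y, sid):
                        break
                fixes.append(Fixation(float(x), float(y), i))
                cur = (x, y)
            trials.append(Trial(pid, sid, tuple(fixes), response=""))
    return trials


# ---------------------------------------------------------------------------
# one-call synthetic world
# ---------------------------------------------------------------------------


@dataclass
class SyntheticWorld:
    """Everything one seeded call produces: design, truth, stimuli, data."""

    design: ExperimentDesign
    truth: GroundTruth
    bubbles: list[Bubble]
    stimuli: list[Stimulus]
    trials: list[Trial]
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)

    def manifest(self) -> dict:
        return {
            "n_participants": self.design.n_participants,
            "trials_per_participant": self.design.trials_per_participant,
            "n_bubbles": len(self.bubbles),
            "n_stimuli": len(self.stimuli),
            "n_trials": len(self.trials),
            "weights": list(self.truth.weights),
            "log_noise_sd": self.truth.log_noise_sd,
        }


def make_world(
    task: str = "gender",
    n_bubbles: int = 94,
    n_stimuli: int = 300,
    design: ExperimentDesign | None = None,
    weights: tuple[float, float, float] = (0.3, 0.5, 0.7),
    concentration: float = 0.5,
    log_noise_sd: float = 0.3,
    seed: int = 0,
    central_bias_sd_deg: float = 5.0,
) -> SyntheticWorld:
    """Build a complete seeded synthetic study for one task.

    The spatial log-component of the planted salience is the log of the
    central-bias Gaussian density at each bubble's position, so the
    generative spatial structure and the planted regression structure
    agree.
    """
    rng = np.random.default_rng(seed)
    design = design or ExperimentDesign()
    geometry = ScreenGeometry()
    pool = make_bubble_pool(n_bubbles, task, geometry, seed=rng)
    scx, scy = geometry.center
    log_spatial = np.array(
        [
            -((b.center_x_deg - scx) ** 2 + (b.center_y_deg - scy) ** 2)
            / (2 * central_bias_sd_deg**2)
            for b in pool
        ]
    )
    truth = sample_ground_truth(
        n_bubbles=len(pool),
        n_classes=len(TASK_CLASSES[task]),
        concentration=concentration,
        weights=weights,
        log_noise_sd=log_noise_sd,
        seed=rng,
        bubble_ids=[b.bubble_id for b in pool],
        log_spatial=log_spatial,
    )
    stimuli = build_stimulus_set(StimulusDesign(n_stimuli), pool, seed=rng)
    trials = generate_experiment(design, stimuli, truth, seed=rng, geometry=geometry)
    return SyntheticWorld(design, truth, pool, stimuli, trials, geometry)
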