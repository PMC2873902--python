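"""Bubble stimulus geometry, rendering and fixation bookkeeping.

A *bubble* is a square gray-scale image patch that has been space-variant
low-pass filtered (imitating the fall-off of retinal acuity away from the
patch center) and masked by an isotropic Gaussian envelope so that it blends
into a uniform gray background.  Stimuli are sets of non-overlapping bubbles
shown during a classification task while eye movements are recorded.

All coordinates are degrees of visual angle, origin at the screen top-left,
x rightward, y downward.  Distances are Euclidean in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

# ---------------------------------------------------------------------------
# constants of the experimental setup
# ---------------------------------------------------------------------------

#: screen pixels per degree of visual angle of the recording setup
PX_PER_DEG = 33.0
#: screen size in pixels of the recording setup
SCREEN_PX = (1024, 786)

#: standard deviation of the Gaussian bubble envelope, degrees
BUBBLE_SIGMA_DEG = 1.0
#: side length of the square source patch of a bubble, degrees
BUBBLE_PATCH_DEG = 6.0

#: fixations farther than this from every bubble center are not "on" a bubble
BUBBLE_ASSIGN_RADIUS_DEG = 3.0
#: fixations within this radius of the screen center count as center fixations
CENTER_ASSIGN_RADIUS_DEG = 1.5
#: minimal center-to-center distance between bubbles of one stimulus
MIN_BUBBLE_SEPARATION_DEG = 4.0

#: class labels per task; `expression` is 4-alternative, the rest are binary
TASK_CLASSES = {
    "expression": ("happy", "sad", "fearful", "disgusted"),
    "gender": ("male", "female"),
    "influence": ("present", "absent"),
    "space": ("close", "open"),
}

#: stimulus-condition mix of the experimental design (fractions of stimuli)
CONDITION_MIX = {
    "same": 0.50,  # includes all single-bubble stimuli
    "congruent": 0.15,
    "incongruent": 0.15,
    "permuted": 0.16,
    "fullfield": 0.04,
}

#: bubble-count mix (fractions of stimuli; the remaining 4% are full fields)
BUBBLE_COUNT_MIX = {1: 0.12, 2: 0.42, 3: 0.26, 4: 0.14, 5: 0.02}


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen extent in visual degrees and the pixel raster on it."""

    width_deg: float = SCREEN_PX[0] / PX_PER_DEG
    height_deg: float = SCREEN_PX[1] / PX_PER_DEG
    px_per_deg: float = PX_PER_DEG

    def __post_init__(self):
        if self.width_deg <= 0 or self.height_deg <= 0 or self.px_per_deg <= 0:
            raise ValueError("screen geometry fields must be positive")

    @property
    def width_px(self) -> int:
        return int(round(self.width_deg * self.px_per_deg))

    @property
    def height_px(self) -> int:
        return int(round(self.height_deg * self.px_per_deg))

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_deg / 2.0, self.height_deg / 2.0)

    def contains(self, x_deg: float, y_deg: float) -> bool:
        return 0.0 <= x_deg <= self.width_deg and 0.0 <= y_deg <= self.height_deg


@dataclass(frozen=True)
class Bubble:
    """One Gaussian-masked image patch, the experiment's perceptual unit."""

    bubble_id: str
    task: str
    source_image_id: str
    source_class: str
    center_x_deg: float
    center_y_deg: float
    sigma_deg: float = BUBBLE_SIGMA_DEG
    patch_size_deg: float = BUBBLE_PATCH_DEG

    def __post_init__(self):
        if self.task not in TASK_CLASSES:
            raise ValueError(f"unknown task {self.task!r}")
        if self.source_class not in TASK_CLASSES[self.task]:
            raise ValueError(
                f"class {self.source_class!r} not valid for task {self.task!r}"
            )
        if self.sigma_deg <= 0 or self.patch_size_deg <= 0:
            raise ValueError("sigma_deg and patch_size_deg must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_x_deg, self.center_y_deg)


@dataclass(frozen=True)
class Stimulus:
    """One presented display: an ordered set of bubbles, or a full field."""

    stimulus_id: str
    task: str
    bubbles: tuple[Bubble, ...]
    condition: str

    def __post_init__(self):
        if self.condition not in CONDITION_MIX:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "fullfield":
            if self.bubbles:
                raise ValueError("full-field stimuli carry no bubbles")
            return
        if not 1 <= len(self.bubbles) <= 5:
            raise ValueError("bubble stimuli carry 1-5 bubbles")
        for b in self.bubbles:
            if b.task != self.task:
                raise ValueError("bubble task does not match stimulus task")
        if self.condition == "same":
            srcs = {b.source_image_id for b in self.bubbles}
            if len(srcs) > 1:
                raise ValueError("'same' stimuli draw all bubbles from one image")
        if self.condition == "congruent":
            if len({b.source_class for b in self.bubbles}) > 1:
                raise ValueError("'congruent' stimuli draw from one class")

    @property
    def is_fullfield(self) -> bool:
        return self.condition == "fullfield"

    def bubble_ids(self) -> tuple[str, ...]:
        return tuple(b.bubble_id for b in self.bubbles)


@dataclass(frozen=True)
class Fixation:
    x_deg: float
    y_deg: float
    order_index: int

    @property
    def excluded(self) -> bool:
        """The very first fixation of a trial reflects the preceding
        fixation cross and is excluded from all analyses."""
        return self.order_index == 0


@dataclass(frozen=True)
class Trial:
    participant_id: str
    stimulus_id: str
    fixations: tuple[Fixation, ...]
    response: str

    def analysis_fixations(self) -> tuple[Fixation, ...]:
        return tuple(f for f in self.fixations if not f.excluded)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

MEAN_GRAY = 0.5  # background luminance on the [0, 1] scale


def gaussian_envelope(size_px: int, sigma_px: float) -> np.ndarray:
    """Isotropic Gaussian mask, value 1 at the patch center."""
    half = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    r2 = (xx - half) ** 2 + (yy - half) ** 2
    return np.exp(-r2 / (2.0 * sigma_px**2))


def render_bubble(
    patch: np.ndarray,
    geometry: ScreenGeometry | None = None,
    sigma_deg: float = BUBBLE_SIGMA_DEG,
    blur_slope: float = 0.1,
    background: float = MEAN_GRAY,
) -> np.ndarray:
    """Render a square patch into a bubble.

    The patch is space-variant low-pass filtered — the blur standard
    deviation grows linearly with eccentricity from the patch center
    (``blur_slope`` degrees of blur per degree of eccentricity, zero at the
    center) — then multiplied by the Gaussian envelope and alpha-blended
    onto the mean-gray background.  This imitates the retinal resolution of
    an observer fixating the bubble center, so one central fixation captures
    all of the bubble's content.

    Parameters
    ----------
    patch:
        Square gray-scale array with values in ``[0, 1]``.
    """
    geometry = geometry or ScreenGeometry()
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square, got shape {patch.shape}")
    n = patch.shape[0]
    ppd = geometry.px_per_deg
    sigma_px = sigma_deg * ppd

    half = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    ecc_deg = np.hypot(xx - half, yy - half) / ppd

    # discretize eccentricity into a few blur zones; blend linearly between
    # pre-blurred copies so the filter scale varies smoothly with eccentricity
    max_blur_px = blur_slope * float(ecc_deg.max()) * ppd
    n_levels = max(2, int(np.ceil(max_blur_px / (0.25 * ppd))) + 1)
    levels = np.linspace(0.0, max_blur_px, n_levels)
    blurred = np.stack(
        [patch if s == 0 else ndimage.gaussian_filter(patch, s, mode="nearest")
         for s in levels]
    )
    want = blur_slope * ecc_deg * ppd
    idx = np.clip(np.searchsorted(levels, want) - 1, 0, n_levels - 2)
    lo, hi = levels[idx], levels[idx + 1]
    frac = np.where(hi > lo, (want - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0)
    filtered = (1 - frac) * blurred[idx, yy, xx] + frac * blurred[idx + 1, yy, xx]

    envelope = gaussian_envelope(n, sigma_px)
    return envelope * filtered + (1.0 - envelope) * background


def render_stimulus(
    stimulus: Stimulus,
    patches: dict[str, np.ndarray],
    geometry: ScreenGeometry | None = None,
    background: float = MEAN_GRAY,
) -> np.ndarray:
    """Compose rendered bubbles onto a full-screen mean-gray canvas."""
    geometry = geometry or ScreenGeometry()
    canvas = np.full((geometry.height_px, geometry.width_px), background)
    for b in stimulus.bubbles:
        rendered = render_bubble(patches[b.bubble_id], geometry, b.sigma_deg)
        n = rendered.shape[0]
        cx = int(round(b.center_x_deg * geometry.px_per_deg))
        cy = int(round(b.center_y_deg * geometry.px_per_deg))
        x0, y0 = cx - n // 2, cy - n // 2
        xs0, ys0 = max(0, x0), max(0, y0)
        xs1 = min(geometry.width_px, x0 + n)
        ys1 = min(geometry.height_px, y0 + n)
        sub = rendered[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0]
        region = canvas[ys0:ys1, xs0:xs1]
        # additive deviations from background so overlapping tails just sum
        canvas[ys0:ys1, xs0:xs1] = region + (sub - background)
    return np.clip(canvas, 0.0, 1.0)


# ---------------------------------------------------------------------------
# stimulus-set construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusDesign:
    """Composition of a stimulus set: how many stimuli, which mixes."""

    n_stimuli: int = 100
    condition_mix: dict = field(default_factory=lambda: dict(CONDITION_MIX))
    bubble_count_mix: dict = field(default_factory=lambda: dict(BUBBLE_COUNT_MIX))

    def counts(self) -> tuple[dict[str, int], dict[int, int]]:
        """Integer per-condition and per-bubble-count targets.

        Largest-remainder rounding; exact for set sizes divisible by 100
        under the default mixes.
        """
        cond = _apportion(self.condition_mix, self.n_stimuli)
        n_bubbled = self.n_stimuli - cond.get("fullfield", 0)
        mix = {k: v for k, v in self.bubble_count_mix.items()}
        total = sum(mix.values())
        size = _apportion({k: v / total for k, v in mix.items()}, n_bubbled)
        return cond, size


def _apportion(fractions: dict, n: int) -> dict:
    """Largest-remainder apportionment of n items to the given fractions."""
    quotas = {k: f * n for k, f in fractions.items()}
    out = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(out.values())
    order = sorted(quotas, key=lambda k: quotas[k] - out[k], reverse=True)
    for k in order[:short]:
        out[k] += 1
    return out


def build_stimulus_set(
    design: StimulusDesign,
    bubbles: list[Bubble],
    seed: int | np.random.Generator = 0,
    min_separation_deg: float = MIN_BUBBLE_SEPARATION_DEG,
    max_tries: int = 200,
) -> list[Stimulus]:
    """Assemble a stimulus set matching the design mixes.

    Single-bubble stimuli all belong to condition ``same``.  Bubbles are
    drawn with inverse-usage weighting so each bubble appears in roughly the
    same number of stimuli.  Bubble positions are the bubbles' own centers
    (they were cut from registered full-field images), so non-overlap is
    enforced by rejecting combinations with any pairwise center distance
    below ``min_separation_deg``.  Permuted stimuli shuffle the positions of
    a valid 'same' combination among its bubbles.
    """
    rng = np.random.default_rng(seed)
    if not bubbles:
        raise ValueError("empty bubble pool")
    task = bubbles[0].task
    if any(b.task != task for b in bubbles):
        raise ValueError("bubble pool mixes tasks")
    classes = sorted({b.source_class for b in bubbles})

    by_image: dict[str, list[Bubble]] = {}
    by_class: dict[str, list[Bubble]] = {}
    for b in bubbles:
        by_image.setdefault(b.source_image_id, []).append(b)
        by_class.setdefault(b.source_class, []).append(b)

    cond_counts, size_counts = design.counts()
    usage = {b.bubble_id: 0 for b in bubbles}

    # queue of bubble counts: singles first (they must be 'same'), then the
    # multi-bubble sizes interleaved across conditions
    sizes = []
    for k in sorted(size_counts):
        sizes += [k] * size_counts[k]
    n_single = size_counts.get(1, 0)
    if cond_counts.get("same", 0) < n_single:
        raise ValueError(
            "infeasible design: single-bubble stimuli (condition 'same') "
            f"exceed the 'same' quota ({n_single} > {cond_counts.get('same', 0)})"
        )

    multi_conditions = (
        ["same"] * (cond_counts.get("same", 0) - n_single)
        + ["congruent"] * cond_counts.get("congruent", 0)
        + ["incongruent"] * cond_counts.get("incongruent", 0)
        + ["permuted"] * cond_counts.get("permuted", 0)
    )
    rng.shuffle(multi_conditions)
    multi_sizes = [k for k in sizes if k > 1]
    rng.shuffle(multi_sizes)
    if len(multi_sizes) != len(multi_conditions):
        raise ValueError(
            "infeasible design: bubble-count and condition quotas disagree "
            f"({len(multi_sizes)} multi-bubble stimuli vs {len(multi_conditions)} slots)"
        )

    def weighted_pick(pool: list[Bubble], k: int) -> list[Bubble]:
        w = np.array([1.0 / (1 + usage[b.bubble_id]) ** 2 for b in pool])
        idx = rng.choice(len(pool), size=k, replace=False, p=w / w.sum())
        return [pool[i] for i in idx]

    def separated(chosen: list[Bubble]) -> bool:
        for i, a in enumerate(chosen):
            for b in chosen[i + 1 :]:
                if math.dist(a.center, b.center) < min_separation_deg:
                    return False
        return True

    def pick_combo(k: int, condition: str) -> list[Bubble]:
        for _ in range(max_tries):
            if condition in ("same", "permuted"):
                images = [im for im, bs in by_image.items() if len(bs) >= k]
                if not images:
                    break
                pool = by_image[images[rng.integers(len(images))]]
            elif condition == "congruent":
                cls = classes[rng.integers(len(classes))]
                pool = by_class[cls]
            else:  # incongruent: force >= 2 classes
                pool = bubbles
            if len(pool) < k:
                continue
            chosen = weighted_pick(pool, k)
            if condition == "incongruent" and len(
                {b.source_class for b in chosen}
            ) < min(2, k):
                continue
            if separated(chosen):
                return chosen
        raise ValueError(
            f"infeasible constraints: no non-overlapping {k}-bubble combination "
            f"found for condition {condition!r} (pool too small or too dense)"
        )

    stimuli: list[Stimulus] = []
    counter = 0

    def emit(chosen: list[Bubble], condition: str):
        nonlocal counter
        for b in chosen:
            usage[b.bubble_id] += 1
        stimuli.append(
            Stimulus(f"stim_{counter:05d}", task, tuple(chosen), condition)
        )
        counter += 1

    for _ in range(n_single):
        emit(pick_combo(1, "same"), "same")
    for k, condition in zip(multi_sizes, multi_conditions):
        chosen = pick_combo(k, condition)
        if condition == "permuted":
            # shuffle the positions among the chosen bubbles
            centers = [(b.center_x_deg, b.center_y_deg) for b in chosen]
            perm = rng.permutation(len(chosen))
            chosen = [
                replace(b, center_x_deg=centers[j][0], center_y_deg=centers[j][1])
                for b, j in zip(chosen, perm)
            ]
        emit(chosen, condition)
    for _ in range(cond_counts.get("fullfield", 0)):
        stimuli.append(Stimulus(f"stim_{counter:05d}", task, (), "fullfield"))
        counter += 1
    rng.shuffle(stimuli)
    return stimuli


# ---------------------------------------------------------------------------
# fixation assignment
# ---------------------------------------------------------------------------


@dataclass
class FixationAssignment:
    """Per-trial outcome of snapping fixations to bubbles."""

    bubble_counts: dict[str, int]
    center_count: int
    scattered_count: int
    #: per non-excluded fixation: (label, distance to its bubble center or nan)
    labels: list[tuple[str, float]]

    @property
    def n_assigned(self) -> int:
        return sum(self.bubble_counts.values())

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.center_count + self.scattered_count


def assign_fixations(
    trial: Trial,
    stimulus: Stimulus,
    geometry: ScreenGeometry | None = None,
    bubble_radius_deg: float = BUBBLE_ASSIGN_RADIUS_DEG,
    center_radius_deg: float = CENTER_ASSIGN_RADIUS_DEG,
) -> FixationAssignment:
    """Assign each non-excluded fixation to its nearest bubble center.

    Fixations farther than ``bubble_radius_deg`` from every center fall to
    the screen center (within ``center_radius_deg``) or count as scattered.
    Distance ties go to the lexicographically smallest bubble id.
    """
    if trial.stimulus_id != stimulus.stimulus_id:
        raise ValueError(
            f"trial refers to {trial.stimulus_id!r}, not {stimulus.stimulus_id!r}"
        )
    geometry = geometry or ScreenGeometry()
    scx, scy = geometry.center
    order = sorted(stimulus.bubbles, key=lambda b: b.bubble_id)
    counts = {b.bubble_id: 0 for b in order}
    center = scattered = 0
    labels: list[tuple[str, float]] = []
    for f in trial.analysis_fixations():
        best_id, best_d = None, np.inf
        for b in order:  # sorted order makes ties land on the smallest id
            d = math.dist((f.x_deg, f.y_deg), b.center)
            if d < best_d - 1e-12:
                best_id, best_d = b.bubble_id, d
        if best_id is not None and best_d <= bubble_radius_deg:
            counts[best_id] += 1
            labels.append((best_id, best_d))
        elif math.dist((f.x_deg, f.y_deg), (scx, scy)) <= center_radius_deg:
            center += 1
            labels.append(("<center>", np.nan))
        else:
            scattered += 1
            labels.append(("<scattered>", np.nan))
    return FixationAssignment(counts, center, scattered, labels)


# ---------------------------------------------------------------------------
# first vs subsequent fixation distances
# ---------------------------------------------------------------------------


def gaussian_radial_median(sigma_deg: float = BUBBLE_SIGMA_DEG) -> float:
    """Median radial distance of samples from an isotropic bivariate
    Gaussian with per-axis sd ``sigma_deg``: the Rayleigh median
    sigma * sqrt(2 ln 2)."""
    return sigma_deg * math.sqrt(2.0 * math.log(2.0))


@dataclass
class DistanceStats:
    """First- vs subsequent-fixation distances to the nearest bubble center.

    A fixation entering a bubble from outside it is "first"; consecutive
    fixations assigned to the same bubble are "subsequent".
    """

    first_distances: np.ndarray
    subsequent_distances: np.ndarray
    reference_median: float
    first_median: float = np.nan
    subsequent_median: float = np.nan
    ks_first_vs_subsequent: tuple[float, float] | None = None
    ks_first_vs_reference: tuple[float, float] | None = None
    ks_subsequent_vs_reference: tuple[float, float] | None = None


def fixation_distance_stats(
    trials: list[Trial],
    stimuli: dict[str, Stimulus] | list[Stimulus],
    geometry: ScreenGeometry | None = None,
    sigma_deg: float = BUBBLE_SIGMA_DEG,
    n_reference: int = 20000,
    seed: int = 0,
) -> DistanceStats:
    """Split bubble-assigned fixation distances into first/subsequent groups
    and compare them (two-sample Kolmogorov-Smirnov) against each other and
    against the distance distribution of samples from the bubble envelope."""
    if not isinstance(stimuli, dict):
        stimuli = {s.stimulus_id: s for s in stimuli}
    first, subseq = [], []
    for t in trials:
        s = stimuli[t.stimulus_id]
        if s.is_fullfield:
            continue
        asg = assign_fixations(t, s, geometry)
        prev = None
        for label, dist in asg.labels:
            if label.startswith("<"):
                prev = None
                continue
            (subseq if label == prev else first).append(dist)
            prev = label
    ref_median = gaussian_radial_median(sigma_deg)
    stats_out = DistanceStats(
        np.asarray(first), np.asarray(subseq), ref_median
    )
    rng = np.random.default_rng(seed)
    ref = sigma_deg * np.hypot(
        rng.standard_normal(n_reference), rng.standard_normal(n_reference)
    )
    if first:
        stats_out.first_median = float(np.median(first))
        ks = stats.ks_2samp(first, ref)
        stats_out.ks_first_vs_reference = (ks.statistic, ks.pvalue)
    if subseq:
        stats_out.subsequent_median = float(np.median(subseq))
        ks = stats.ks_2samp(subseq, ref)
        stats_out.ks_subsequent_vs_reference = (ks.statistic, ks.pvalue)
    if first and subseq:
        ks = stats.ks_2samp(first, subseq)
        stats_out.ks_first_vs_subsequent = (ks.statistic, ks.pvalue)
    return stats_out
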