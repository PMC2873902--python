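"""Geometry, rendering, stimulus assembly and fixation bookkeeping."""

import collections
import math

import numpy as np
import pytest

from bubblegaze.stimulus import (
    MEAN_GRAY,
    Bubble,
    Fixation,
    ScreenGeometry,
    Stimulus,
    StimulusDesign,
    Trial,
    assign_fixations,
    build_stimulus_set,
    fixation_distance_stats,
    gaussian_envelope,
    gaussian_radial_median,
    render_bubble,
)
from bubblegaze.synth import make_bubble_pool

from conftest import make_bubble, make_trial


class TestGeometry:
    def test_default_raster_matches_recording_setup(self, geometry):
        assert geometry.width_px == 1024
        assert geometry.height_px == 786
        assert geometry.center == pytest.approx((1024 / 33 / 2, 786 / 33 / 2))

    @pytest.mark.parametrize("field", ["width_deg", "height_deg", "px_per_deg"])
    def test_rejects_nonpositive_dimensions(self, field):
        with pytest.raises(ValueError):
            ScreenGeometry(**{field: -1.0})

    def test_bubble_rejects_wrong_class(self):
        with pytest.raises(ValueError):
            Bubble("b", "gender", "i", "happy", 5.0, 5.0)

    def test_stimulus_condition_consistency(self):
        b1 = make_bubble("b1", 5, 5, image="img_a")
        b2 = make_bubble("b2", 15, 5, image="img_b")
        with pytest.raises(ValueError):
            Stimulus("s", "gender", (b1, b2), "same")
        Stimulus("s", "gender", (b1, b2), "congruent")  # same class: fine


class TestRenderBubble:
    def test_uniform_midgray_patch_is_invisible(self, geometry):
        n = int(6.0 * geometry.px_per_deg)
        patch = np.full((n, n), MEAN_GRAY)
        out = render_bubble(patch, geometry)
        assert np.allclose(out, MEAN_GRAY)

    def test_center_pixel_unchanged_for_smooth_patch(self, geometry):
        # low-frequency patch: blur is zero at eccentricity 0 and the
        # envelope is 1 there, so the center intensity passes through
        n = 199
        yy, xx = np.mgrid[0:n, 0:n] / n
        patch = 0.4 + 0.2 * np.sin(2 * np.pi * xx)
        out = render_bubble(patch, geometry)
        c = n // 2
        assert out[c, c] == pytest.approx(patch[c, c], abs=1e-6)

    def test_difference_mass_confined_to_envelope(self, geometry):
        # the Gaussian envelope confines the visible deviation from the
        # background; numerically integrating the envelope puts less than
        # 1.2% of its mass beyond radius 3 sigma
        n = int(6.0 * geometry.px_per_deg)
        rng = np.random.default_rng(0)
        patch = np.clip(0.5 + 0.3 * rng.standard_normal((n, n)), 0, 1)
        out = render_bubble(patch, geometry)
        diff = np.abs(out - MEAN_GRAY)
        half = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        r_deg = np.hypot(xx - half, yy - half) / geometry.px_per_deg
        frac = diff[r_deg > 3.0].sum() / diff.sum()
        env = gaussian_envelope(n, geometry.px_per_deg)
        env_frac = env[r_deg > 3.0].sum() / env.sum()
        assert frac < 0.012
        assert env_frac < 0.012  # oracle: the envelope itself

    def test_rejects_non_square_patch(self):
        with pytest.raises(ValueError, match="square"):
            render_bubble(np.zeros((10, 12)))


@pytest.fixture(scope="module")
def pool_and_set():
    pool = make_bubble_pool(30, "gender", seed=0)
    return pool, build_stimulus_set(StimulusDesign(100), pool, seed=0)


class TestBuildStimulusSet:

    def test_condition_proportions_exact_at_100(self, pool_and_set):
        _, stims = pool_and_set
        conds = collections.Counter(s.condition for s in stims)
        assert conds == {
            "same": 50,
            "congruent": 15,
            "incongruent": 15,
            "permuted": 16,
            "fullfield": 4,
        }

    def test_bubble_count_proportions(self, pool_and_set):
        _, stims = pool_and_set
        sizes = collections.Counter(len(s.bubbles) for s in stims if s.bubbles)
        assert sizes == {1: 12, 2: 42, 3: 26, 4: 14, 5: 2}

    def test_no_two_bubbles_overlap(self, pool_and_set):
        _, stims = pool_and_set
        for s in stims:
            for i, a in enumerate(s.bubbles):
                for b in s.bubbles[i + 1 :]:
                    assert math.dist(a.center, b.center) >= 4.0

    def test_bubble_usage_balanced(self, pool_and_set):
        _, stims = pool_and_set
        usage = collections.Counter(
            b.bubble_id for s in stims for b in s.bubbles
        )
        assert len(usage) == 30  # every bubble used
        assert max(usage.values()) / min(usage.values()) <= 2.0

    def test_singles_are_condition_same(self, pool_and_set):
        _, stims = pool_and_set
        assert all(
            s.condition == "same" for s in stims if len(s.bubbles) == 1
        )

    def test_infeasible_pool_raises(self):
        pool = make_bubble_pool(4, "gender", n_images=2, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            build_stimulus_set(StimulusDesign(200), pool, seed=0)


class TestAssignFixations:
    @pytest.fixture()
    def stimulus(self):
        return Stimulus(
            "s1",
            "gender",
            (
                make_bubble("bA", 10.0, 10.0),
                make_bubble("bB", 20.0, 10.0),
            ),
            "same",
        )

    def test_fixation_at_center_goes_to_that_bubble(self, stimulus):
        t = make_trial([(10.0, 10.0)])
        asg = assign_fixations(t, stimulus)
        assert asg.bubble_counts == {"bA": 1, "bB": 0}

    def test_far_fixation_is_scattered(self, stimulus, geometry):
        t = make_trial([(2.0, 20.0)])  # >3 deg from bubbles, >1.5 from center
        asg = assign_fixations(t, stimulus, geometry)
        assert asg.scattered_count == 1 and asg.n_assigned == 0

    def test_near_screen_center_counts_as_center(self, stimulus, geometry):
        cx, cy = geometry.center
        t = make_trial([(cx + 0.5, cy)])
        asg = assign_fixations(t, stimulus, geometry)
        assert asg.center_count == 1

    def test_equidistant_tie_goes_to_smallest_id(self):
        close = Stimulus(
            "s1",
            "gender",
            (make_bubble("bA", 10.0, 10.0), make_bubble("bB", 14.0, 10.0)),
            "same",
        )
        t = make_trial([(12.0, 10.0)])  # exactly 2 deg from both centers
        asg = assign_fixations(t, close)
        assert asg.bubble_counts["bA"] == 1 and asg.bubble_counts["bB"] == 0

    def test_first_fixation_excluded(self, stimulus):
        t = Trial("p", "s1", (Fixation(10.0, 10.0, 0),), "male")
        asg = assign_fixations(t, stimulus)
        assert asg.n_total == 0

    def test_counts_conservation(self, stimulus, small_world):
        by_id = {s.stimulus_id: s for s in small_world.stimuli}
        for t in small_world.trials[:200]:
            s = by_id[t.stimulus_id]
            if s.is_fullfield:
                continue
            asg = assign_fixations(t, s)
            assert asg.n_total == len(t.analysis_fixations())

    def test_id_mismatch_rejected(self, stimulus):
        t = make_trial([(10.0, 10.0)], stimulus_id="other")
        with pytest.raises(ValueError):
            assign_fixations(t, stimulus)


class TestDistanceStats:
    def test_reference_median_closed_form(self):
        # Rayleigh median of the unit bubble envelope: sigma*sqrt(2 ln 2)
        assert gaussian_radial_median(1.0) == pytest.approx(1.18, abs=0.005)
        assert gaussian_radial_median(2.0) == pytest.approx(
            2 * math.sqrt(2 * math.log(2))
        )

    def test_single_visit_counts_as_first(self):
        s = Stimulus("s1", "gender", (make_bubble("bA", 10.0, 10.0),), "same")
        t = make_trial([(10.2, 10.0)])
        st = fixation_distance_stats([t], [s])
        assert len(st.first_distances) == 1
        assert len(st.subsequent_distances) == 0

    def test_refixation_counts_as_subsequent(self):
        s = Stimulus("s1", "gender", (make_bubble("bA", 10.0, 10.0),), "same")
        t = make_trial([(10.5, 10.0), (10.2, 10.0), (10.1, 10.0)])
        st = fixation_distance_stats([t], [s])
        assert len(st.first_distances) == 1
        assert len(st.subsequent_distances) == 2

    def test_corrective_saccades_visible_in_generated_data(self, small_world):
        # the generator shrinks within-bubble refixations so they land on
        # average 0.16 degrees closer to the bubble center
        st = fixation_distance_stats(
            small_world.trials, small_world.stimuli, seed=0
        )
        approach = st.first_distances.mean() - st.subsequent_distances.mean()
        assert approach == pytest.approx(0.16, abs=0.04)
        assert st.subsequent_median < st.first_median
        # both groups are tighter than envelope sampling would produce
        assert st.first_median < st.reference_median
        assert st.ks_first_vs_subsequent[1] < 0.01

    def test_empty_groups_leave_comparison_unavailable(self):
        s = Stimulus("s1", "gender", (make_bubble("bA", 10.0, 10.0),), "same")
        st = fixation_distance_stats([make_trial([])], [s])
        assert st.ks_first_vs_subsequent is None
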