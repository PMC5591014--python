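"""Isotonic decay fit, robust z-scores, BH adjustment, consensus calls."""

import numpy as np
import pandas as pd
import pytest

from contactscape import ViewpointSpec, bh_adjust, fit_decay, score_contacts
from contactscape.capture_profile import CaptureProfile
from contactscape.contact_stats import _isotonic_decreasing, replicate_scores

from _oracles import brute_force_isotonic_decreasing, suffix_min_bh


def profile_from_frequencies(f_up, f_down, replicate="rep1"):
    """CaptureProfile with explicit per-window frequencies each side of the viewpoint."""
    n_up, n_down = len(f_up), len(f_down)
    rows = []
    for i, f in enumerate(f_up):
        d = -(n_up - i) * 1000.0
        rows.append({"window": i, "chrom": "chr1", "start": 0, "end": 0,
                     "midpoint": 5e6 + d, "n_fragments": 30, "c": f * 60, "f": f,
                     "distance": d, "excluded": False, "truncated": False})
    for i, f in enumerate(f_down):
        d = (i + 1) * 1000.0
        rows.append({"window": n_up + i, "chrom": "chr1", "start": 0, "end": 0,
                     "midpoint": 5e6 + d, "n_fragments": 30, "c": f * 60, "f": f,
                     "distance": d, "excluded": False, "truncated": False})
    vp = ViewpointSpec("vp", "chr1", int(5e6), 0, 0)
    return CaptureProfile(vp, replicate, 30, np.array([]), np.array([]),
                          pd.DataFrame(rows))


class TestIsotonic:
    @pytest.mark.parametrize("seed", range(15))
    def test_pava_matches_level_set_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=int(rng.integers(2, 13)))
        assert np.allclose(_isotonic_decreasing(y), brute_force_isotonic_decreasing(y),
                           atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_level_set_residual_means_are_zero(self, seed):
        rng = np.random.default_rng(100 + seed)
        y = rng.normal(size=12)
        fit = _isotonic_decreasing(y)
        resid = y - fit
        for level in np.unique(fit):
            assert abs(resid[fit == level].mean()) < 1e-12


class TestFitDecay:
    def test_monotone_input_is_interpolated_exactly(self):
        f = np.linspace(0.9, 0.1, 10)
        fits = fit_decay(profile_from_frequencies(f[::-1], f))
        for side in ("upstream", "downstream"):
            tab = fits[side].table
            assert np.allclose(tab["yhat"], tab["f"])
            assert np.allclose(tab["z"], 0.0)

    def test_constant_input_gives_zero_z(self):
        f = np.full(8, 0.4)
        fits = fit_decay(profile_from_frequencies(f, f))
        assert np.allclose(fits["downstream"].table["z"], 0.0)

    def test_fitted_decay_is_non_increasing_with_distance(self):
        rng = np.random.default_rng(3)
        f = np.clip(0.5 * np.exp(-np.arange(40) / 10) + rng.normal(0, 0.02, 40), 0, 1)
        fits = fit_decay(profile_from_frequencies(f[:1][::-1].repeat(5), f))
        tab = fits["downstream"].table.sort_values("distance")
        assert (np.diff(tab["yhat"]) <= 1e-12).all()

    def test_spiked_window_has_dominant_z_above_threshold(self):
        rng = np.random.default_rng(42)
        d = np.arange(1, 41, dtype=float)
        base = 0.5 * d ** -1.0
        noise = rng.normal(0, 0.005, size=40)
        f = np.clip(base + noise, 0, 1)
        f_spiked = f.copy()
        f_spiked[25] = min(f[25] * 10, 1.0)
        fits = fit_decay(profile_from_frequencies(f_spiked[:5][::-1], f_spiked))
        tab = fits["downstream"].table.reset_index(drop=True)
        assert tab["z"].idxmax() == 25
        assert tab["z"].max() > 2
        # removing the spike leaves residual noise small
        fits0 = fit_decay(profile_from_frequencies(f[:5][::-1], f))
        assert fits0["downstream"].sigma <= 0.01

    def test_all_zero_side_yields_zero_z_with_warning(self, caplog):
        f = np.zeros(6)
        with caplog.at_level("WARNING"):
            fits = fit_decay(profile_from_frequencies(f, f))
        assert np.allclose(fits["downstream"].table["z"], 0.0)
        assert "all-zero" in caplog.text

    def test_too_few_windows_is_an_error(self):
        f = np.full(4, 0.2)
        with pytest.raises(ValueError, match="insufficient windows"):
            fit_decay(profile_from_frequencies(f, np.full(8, 0.2)))

    def test_symmetric_mode_pools_sides(self):
        f = np.linspace(0.8, 0.2, 7)
        fits = fit_decay(profile_from_frequencies(f[::-1], f), symmetric=True)
        assert set(fits) == {"pooled"}
        assert len(fits["pooled"].table) == 14


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_of_one(self):
        assert bh_adjust([1.0]).tolist() == [1.0]

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_suffix_min_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40)))
        assert np.allclose(bh_adjust(p), suffix_min_bh(p), atol=1e-12)

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-6, 1, 50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    def test_q_bounds_and_rank_monotonicity_hold_generally(self, p):
        q = bh_adjust(p)
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1 + 1e-12)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestScoreContacts:
    def _two_rep_profiles(self, spike_reps=(True, True), seed=0):
        rng = np.random.default_rng(seed)
        profs = []
        for r, spike in enumerate(spike_reps):
            d = np.arange(1, 61, dtype=float)
            f = np.clip(0.5 * d ** -1.0 + rng.normal(0, 0.004, 60), 0, 1)
            if spike:
                f[40] = min(f[40] + 0.2, 1.0)
            profs.append(profile_from_frequencies(f[:6][::-1], f, replicate=f"rep{r+1}"))
        return profs

    def test_consensus_requires_z_in_all_replicates(self):
        calls_both = score_contacts(self._two_rep_profiles((True, True)))
        sig = calls_both.significant_windows()
        assert 46 in sig["window"].tolist()  # spiked downstream window (6 upstream first)
        calls_one = score_contacts(self._two_rep_profiles((True, False)))
        assert 46 not in calls_one.significant_windows()["window"].tolist()

    def test_rule_on_explicit_z_q_combinations(self):
        # z=(2.5,2.6), q=(0.01,0.2) -> significant; z fails one rep -> not;
        # q fails both reps -> not.  Checked through the boolean rule itself.
        from contactscape.contact_stats import ContactCallSet  # noqa: F401
        tab = pd.DataFrame({
            "z_a": [2.5, 2.5, 3.0], "z_b": [2.6, 1.9, 3.0],
            "q_a": [0.01, 0.001, 0.2], "q_b": [0.2, 0.001, 0.2],
        })
        consensus = ((tab[["z_a", "z_b"]] > 2).all(axis=1)
                     & (tab[["q_a", "q_b"]] < 0.05).any(axis=1))
        assert consensus.tolist() == [True, False, False]

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="requires >=2 replicates"):
            score_contacts(self._two_rep_profiles()[:1])

    def test_mismatched_grids_rejected(self):
        a, b = self._two_rep_profiles()
        b.windows = b.windows.iloc[:-1]
        with pytest.raises(ValueError, match="mismatched"):
            score_contacts([a, b])

    def test_replicate_scores_include_bh_q_over_all_windows(self):
        prof = self._two_rep_profiles()[0]
        sc = replicate_scores(prof)
        assert {"z", "p", "q"} <= set(sc.columns)
        assert (sc["q"] >= sc["p"] - 1e-12).all()
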