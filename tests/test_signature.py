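import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ohp.signature import (
    BLOCKS,
    ConditionStats,
    DYNAMIC_PARAMETERS,
    RATIO_PARAMETER,
    SignatureError,
    antero_retro_ratio,
    assemble_signature,
    zscore,
)

META = {"project": "P", "experiment": "E", "treatment": "Mock", "line": "L1"}


def _stats(mean, sd=1.0, n=100, name="x"):
    return ConditionStats(parameter=name, mean=mean, sd=sd, n=n)


class TestZscore:
    def test_equal_means_give_zero_regardless_of_sds(self):
        assert zscore(_stats(2.0, sd=5.0), _stats(2.0, sd=0.1)) == 0.0
        assert zscore(_stats(2.0, sd=0.0), _stats(2.0, sd=0.0)) == 0.0

    def test_hand_computed_case(self):
        # Unit mean difference, unit SDs, N = 100 in both pools:
        # z = 1 / (1/10 + 1/10) = 5.
        assert zscore(_stats(1.0), _stats(0.0)) == pytest.approx(5.0)

    @given(
        m1=st.floats(-10, 10),
        m2=st.floats(-10, 10),
        sd1=st.floats(0.1, 5),
        sd2=st.floats(0.1, 5),
        n1=st.integers(2, 500),
        n2=st.integers(2, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_pool_swap(self, m1, m2, sd1, sd2, n1, n2):
        a = _stats(m1, sd1, n1)
        b = _stats(m2, sd2, n2)
        assert zscore(a, b) == pytest.approx(-zscore(b, a), rel=1e-12, abs=1e-12)

    def test_grows_as_sqrt_n_with_fixed_moments(self):
        z1 = zscore(_stats(1.0, n=100), _stats(0.0, n=100))
        z4 = zscore(_stats(1.0, n=400), _stats(0.0, n=400))
        assert z4 == pytest.approx(2 * z1)

    def test_small_pool_is_an_error(self):
        with pytest.raises(SignatureError, match="n = 1"):
            zscore(_stats(1.0, n=1), _stats(0.0))

    def test_zero_denominator_with_unequal_means_is_an_error(self):
        with pytest.raises(SignatureError, match="SDs are zero"):
            zscore(_stats(1.0, sd=0.0), _stats(0.0, sd=0.0))

    def test_parameter_mismatch_rejected(self):
        with pytest.raises(SignatureError):
            zscore(_stats(1.0, name="a"), _stats(0.0, name="b"))

    def test_welch_denominator_option(self):
        a, b = _stats(1.0), _stats(0.0)
        welch = zscore(a, b, welch=True)
        assert welch == pytest.approx(1.0 / np.sqrt(0.01 + 0.01))
        assert welch > zscore(a, b)  # sum of SEs >= Welch SE


class TestAnteroRetroRatio:
    def test_examples(self):
        assert antero_retro_ratio(["anterograde"] * 6 + ["retrograde"] * 3) == 2.0
        assert antero_retro_ratio(["retrograde"] * 5) == 0.0
        assert antero_retro_ratio(["anterograde"] * 5) is None
        assert antero_retro_ratio([]) is None


def make_tables(rng, diseases, n_movies=3, n_tracks=40, n_particles=30,
                distal_speed=None):
    """Synthetic mined tables: per (disease, marker, readout), n_movies
    movies of n_tracks tracks and n_particles organelles, all pools drawn
    from the same distributions unless distal_speed[disease] rescales
    the speed family at the distal readout."""
    track_rows, morph_rows = [], []
    for disease in diseases:
        for marker in ("Mitotracker", "Lysotracker"):
            for readout in ("Distal", "Proximal"):
                factor = 1.0
                if distal_speed and readout == "Distal":
                    factor = distal_speed.get(disease, 1.0)
                for m in range(n_movies):
                    fname = f"{disease}_{marker}_{readout}_m{m}"
                    speeds = rng.normal(0.8 * factor, 0.2 * factor, n_tracks).clip(0.05)
                    for i in range(n_tracks):
                        track_rows.append(
                            {
                                **META,
                                "marker": marker,
                                "readout_position": readout,
                                "disease": disease,
                                "Filename": fname,
                                "TrackID": i,
                                "duration_s": rng.uniform(3, 15),
                                "displacement_um": rng.uniform(1.2, 10),
                                "length_um": rng.uniform(1.2, 12),
                                "mean_speed_um_s": speeds[i],
                                "max_speed_um_s": speeds[i] * 1.3,
                                "min_speed_um_s": speeds[i] * 0.7,
                                "median_speed_um_s": speeds[i],
                                "sd_speed_um_s": 0.1,
                                "angle_rad": 0.0,
                                "direction": "anterograde" if rng.random() < 0.5 else "retrograde",
                            }
                        )
                    for i in range(n_particles):
                        morph_rows.append(
                            {
                                **META,
                                "marker": marker,
                                "readout_position": readout,
                                "disease": disease,
                                "Filename": fname,
                                "particle_id": i,
                                "area_um2": rng.uniform(0.2, 1.5),
                                "feret_max_um": rng.normal(1.0, 0.2),
                                "feret_min_um": rng.normal(0.6, 0.1),
                                "aspect_ratio": max(rng.normal(2.0, 0.4), 1.0),
                                "circularity": rng.uniform(0.5, 1.0),
                                "integrated_intensity": rng.uniform(1e4, 1e5),
                            }
                        )
    return pd.DataFrame(track_rows), pd.DataFrame(morph_rows)


@pytest.fixture(scope="module")
def tables():
    rng = np.random.default_rng(42)
    return make_tables(rng, ["Ctrl", "FUS"], distal_speed={"FUS": 0.5})


class TestAssembleSignature:

    def test_forty_ordered_entries_with_block_structure(self, tables):
        tracks, morph = tables
        sig = assemble_signature(
            tracks, morph, condition={"disease": "FUS"}, baseline={"disease": "Ctrl"}
        )
        assert len(sig) == 40
        assert [e.index for e in sig.entries] == list(range(1, 41))
        for b, (label, _, _) in enumerate(BLOCKS):
            block_entries = sig.entries[10 * b : 10 * (b + 1)]
            assert all(e.block == label for e in block_entries)
            names = [e.parameter for e in block_entries]
            assert names[:8] == [n for n, _ in DYNAMIC_PARAMETERS]
            assert names[8] == RATIO_PARAMETER
        # marker-specific shape parameter at positions 10/20 vs 30/40
        assert sig.entries[9].parameter == "Mitochondrial Aspect Ratio"
        assert sig.entries[29].parameter == "Lysosomal Feret Diameter"

    def test_baseline_condition_is_all_zero_proximally(self, tables):
        tracks, morph = tables
        sig = assemble_signature(
            tracks, morph, condition={"disease": "Ctrl"}, baseline={"disease": "Ctrl"}
        )
        z = sig.z_values
        proximal = sig.subset_indices("proximal")
        distal = sig.subset_indices("distal")
        np.testing.assert_allclose(z[proximal], 0.0)
        assert np.all(np.abs(z[distal]) < 2.0)  # same distribution, noise only

    def test_distal_slowdown_detected_with_correct_sign(self, tables):
        tracks, morph = tables
        sig = assemble_signature(
            tracks, morph, condition={"disease": "FUS"}, baseline={"disease": "Ctrl"}
        )
        for e in sig.entries:
            if e.parameter == "Track Mean Speed":
                if e.block.endswith("Distal"):
                    assert e.z <= -5.0
                else:
                    assert abs(e.z) < 2.0

    def test_missing_pool_is_an_error(self, tables):
        tracks, morph = tables
        with pytest.raises(SignatureError, match="marker=Mitotracker"):
            assemble_signature(
                tracks[tracks.marker != "Mitotracker"],
                morph,
                condition={"disease": "FUS"},
                baseline={"disease": "Ctrl"},
            )

    def test_ratio_parameter_uses_per_movie_n(self, tables):
        tracks, morph = tables
        sig = assemble_signature(
            tracks, morph, condition={"disease": "FUS"}, baseline={"disease": "Ctrl"}
        )
        ratio_entries = [e for e in sig.entries if e.parameter == RATIO_PARAMETER]
        assert all(e.n == 3 for e in ratio_entries)  # 3 movies per pool
        track_entries = [e for e in sig.entries if e.parameter == "Track Duration"]
        assert all(e.n == 3 * 40 for e in track_entries)

    def test_significance_flag_band(self, tables):
        tracks, morph = tables
        sig = assemble_signature(
            tracks, morph, condition={"disease": "FUS"}, baseline={"disease": "Ctrl"}
        )
        for e in sig.entries:
            assert e.significant(sig.significance_band) == (abs(e.z) >= 5.0)
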