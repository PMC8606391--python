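import numpy as np
import pandas as pd
import pytest

from sleevesim import (
    BougieSpec,
    DEFAULT_FLARE,
    DEFAULT_STACK,
    band_coverage,
    band_envelope,
    build_sleeve,
    group_difference,
    inflate,
    mean_over_sizes,
    simulate_volumes,
    size_ratio,
    volume_table,
)
from sleevesim.datasets import CORRECTED_CELLS


class TestFixtures:
    def test_table1_shape_and_monotonicity(self, table1):
        assert len(table1) == 55
        for _, g in table1.groupby("bougie_fr"):
            assert g.sort_values("pressure_mmhg")["volume_ml"].is_monotonic_increasing
        for _, g in table1.groupby("pressure_mmhg"):
            assert g.sort_values("bougie_fr")["volume_ml"].is_monotonic_increasing

    def test_table2_shape(self, table2):
        assert len(table2) == 11 * 4 * 5
        assert set(table2["grouping"]) == {"whole", "antrum", "corpus", "mucosa", "muscularis"}
        assert (table2["sd_percent"] >= 0).all()

    def test_corrected_cell_substitution(self, table2, table2_corrected):
        (fr, p, g), val = next(iter(CORRECTED_CELLS.items()))
        sel = lambda df: float(
            df[(df.bougie_fr == fr) & (df.pressure_mmhg == p) & (df.grouping == g)][
                "mean_percent"
            ].iloc[0]
        )
        assert sel(table2) == 4.12  # as printed
        assert sel(table2_corrected) == val

    def test_corrected_cell_consistent_with_mean_row(self, table2_corrected):
        """The corrected antrum cell restores the table's own cross-size mean."""
        assert mean_over_sizes(table2_corrected, "antrum", 22.5) == pytest.approx(
            38.45, abs=0.02
        )


class TestMeanOverSizes:
    @pytest.mark.parametrize(
        "grouping,pressure,printed",
        [
            ("whole", 7.5, 14.34),
            ("whole", 15, 23.23),
            ("whole", 22.5, 29.85),
            ("whole", 37.5, 39.24),
            ("antrum", 7.5, 18.16),
            ("antrum", 37.5, 50.19),
            ("corpus", 22.5, 26.95),
            ("mucosa", 22.5, 34.12),
            ("muscularis", 37.5, 36.38),
        ],
    )
    def test_reproduces_printed_mean_rows(self, table2_corrected, grouping, pressure, printed):
        """Averaging the 11 per-size cells reproduces the table's Mean row."""
        assert mean_over_sizes(table2_corrected, grouping, pressure) == pytest.approx(
            printed, abs=0.02
        )

    def test_constant_input(self):
        df = pd.DataFrame(
            {
                "bougie_fr": np.arange(11),
                "pressure_mmhg": 7.5,
                "grouping": "whole",
                "mean_percent": 5.0,
                "sd_percent": 1.0,
            }
        )
        assert mean_over_sizes(df, "whole", 7.5) == 5.0

    def test_incomplete_size_set_rejected(self, table2):
        with pytest.raises(ValueError):
            mean_over_sizes(table2[table2.bougie_fr != 40], "whole", 7.5)


class TestSizeRatio:
    def test_printed_six_fold_claim(self, table1):
        """54 vs 27 Fr at 22.5 mmHg: 57.92/9.70 = 5.97, quoted as 6x."""
        assert size_ratio(table1, 22.5, 54, 27) == pytest.approx(5.9711, abs=1e-4)
        assert size_ratio(table1, 22.5, 54, 27, "int") == 6

    def test_printed_five_and_half_claim(self, table1):
        """54 vs 27 Fr at 75 mmHg: 150.84/27.30 = 5.525, quoted as 5.5x."""
        assert size_ratio(table1, 75, 54, 27, "half") == 5.5

    def test_identity_ratio(self, table1):
        assert size_ratio(table1, 37.5, 40, 40) == 1.0

    def test_missing_cell(self, table1):
        with pytest.raises(KeyError):
            size_ratio(table1, 22.5, 44, 27)


class TestGroupDifference:
    @pytest.mark.parametrize(
        "pressure,expected", [(7.5, 3.0), (22.5, 7.0), (37.5, 8.0)]
    )
    def test_layer_differences_match_quoted_integers(
        self, table2_corrected, pressure, expected
    ):
        """Mucosa minus muscularis cross-size means: 3/7/8 points."""
        d = group_difference(table2_corrected, pressure, "mucosa", "muscularis", "round")
        assert d == expected

    def test_antrum_corpus_difference(self, table2_corrected):
        """Antrum minus corpus at 22.5 mmHg: 11.50, truncated to 11 points."""
        raw = group_difference(table2_corrected, 22.5, "antrum", "corpus")
        assert raw == pytest.approx(11.50, abs=0.02)
        assert group_difference(table2_corrected, 22.5, "antrum", "corpus", "truncate") == 11

    def test_self_difference_zero(self, table2_corrected):
        assert group_difference(table2_corrected, 15, "whole", "whole") == 0.0

    def test_unknown_group(self, table2_corrected):
        with pytest.raises(ValueError):
            group_difference(table2_corrected, 15, "whole", "fundus")


class TestVolumeTable:
    def test_single_cell(self, stack):
        res = inflate(build_sleeve(BougieSpec(40)), stack, [22.5])
        vt = volume_table({40: res}, [22.5])
        assert len(vt) == 1
        assert vt["volume_ml"].iloc[0] == pytest.approx(res.volume_at(22.5))

    def test_monotone_in_size_and_pressure(self, stack):
        results = {
            fr: inflate(build_sleeve(BougieSpec(fr)), stack, [7.5, 37.5])
            for fr in (27, 40, 54)
        }
        vt = volume_table(results, [7.5, 37.5])
        for p, g in vt.groupby("pressure_mmhg"):
            assert g.sort_values("bougie_fr")["volume_ml"].is_monotonic_increasing
        for fr, g in vt.groupby("bougie_fr"):
            assert g.sort_values("pressure_mmhg")["volume_ml"].is_monotonic_increasing


@pytest.fixture(scope="module")
def family():
    pressures = [7.5, 15.0, 22.5, 37.5, 75.0]
    curves = {}
    for fr in (27, 40, 54):
        geom = build_sleeve(BougieSpec(fr), flare=DEFAULT_FLARE)
        curves[fr] = (np.asarray(pressures), simulate_volumes(geom, DEFAULT_STACK, pressures))
    return curves


class TestBand:
    def test_duplicate_curve_degenerate_band(self, family):
        p, v = family[40]
        band = band_envelope([(p, v), (p, v.copy())])
        assert np.allclose(band.volume_min_ml, band.volume_max_ml)

    def test_extreme_sizes_are_the_edges(self, family):
        band = band_envelope(family.values())
        assert np.allclose(band.volume_min_ml, family[27][1])
        assert np.allclose(band.volume_max_ml, family[54][1])

    def test_envelope_idempotent_under_interior_curve(self, family):
        with_mid = band_envelope(family.values())
        without_mid = band_envelope([family[27], family[54]])
        assert np.allclose(with_mid.volume_min_ml, without_mid.volume_min_ml)
        assert np.allclose(with_mid.volume_max_ml, without_mid.volume_max_ml)

    def test_mismatched_grids_rejected(self, family):
        p, v = family[27]
        with pytest.raises(ValueError):
            band_envelope([(p, v), (p + 1.0, v)])


class TestBandCoverage:
    def test_boundary_points_count_inside(self, family):
        band = band_envelope(family.values())
        obs = pd.DataFrame(
            {"pressure_mmhg": band.pressures_mmhg, "volume_ml": band.volume_min_ml}
        )
        assert band_coverage(band, obs) == 1.0

    def test_mid_band_curve_fully_covered(self, family):
        band = band_envelope(family.values())
        p, v = family[40]
        obs = pd.DataFrame({"pressure_mmhg": p, "volume_ml": v})
        assert band_coverage(band, obs) == 1.0

    def test_matches_brute_force_recount(self, family):
        """Vectorised coverage equals a point-by-point recount on a noisy set."""
        band = band_envelope(family.values())
        rng = np.random.default_rng(42)
        n = 200
        p_obs = rng.choice(band.pressures_mmhg, size=n)
        lo, hi = band.edges_at(p_obs)
        width = hi - lo
        v_obs = 0.5 * (lo + hi) + rng.normal(scale=1.5 * width)
        obs = pd.DataFrame({"pressure_mmhg": p_obs, "volume_ml": v_obs})

        count = 0
        for pi, vi in zip(p_obs, v_obs):
            li = np.interp(pi, band.pressures_mmhg, band.volume_min_ml)
            hi_i = np.interp(pi, band.pressures_mmhg, band.volume_max_ml)
            if li <= vi <= hi_i:
                count += 1
        assert band_coverage(band, obs) == pytest.approx(count / n, abs=0.05)

    def test_invariant_under_reordering(self, family):
        band = band_envelope(family.values())
        rng = np.random.default_rng(3)
        obs = pd.DataFrame(
            {
                "pressure_mmhg": rng.uniform(7.5, 75.0, 50),
                "volume_ml": rng.uniform(0.0, 150.0, 50),
            }
        )
        shuffled = obs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert band_coverage(band, obs) == band_coverage(band, shuffled)
        band_rev = band_envelope(list(family.values())[::-1])
        assert band_coverage(band_rev, obs) == band_coverage(band, obs)

    def test_empty_observations_rejected(self, family):
        band = band_envelope(family.values())
        with pytest.raises(ValueError):
            band_coverage(band, pd.DataFrame(columns=["pressure_mmhg", "volume_ml"]))
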