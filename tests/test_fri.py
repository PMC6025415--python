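"""Regional integration, partition properties and source indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdompae.dataio import EEMGrid
from cdompae.exceptions import UncorrectedEEMError, ValidationError
from cdompae.fri import (
    DEFAULT_REGIONS,
    RegionDef,
    classify_source,
    fluorescence_index,
    fri_components,
    integrate_region,
)
from cdompae.synthetic import GaussianPeak, generate_eem

# counted-cell volumes of a uniform I=1 EEM on the default grid
# (ex 220–450 @5 nm, em 250–600 @1 nm, half-open region bounds)
UNIFORM_VOLUMES = {1: 1500.0, 2: 1500.0, 3: 5100.0, 4: 15000.0, 5: 25500.0}


def oracle_region_volume(eem, region):
    """Brute-force double loop applying the half-open convention."""
    dex = eem.excitation_nm[1] - eem.excitation_nm[0]
    dem = eem.emission_nm[1] - eem.emission_nm[0]
    total = 0.0
    for i, x in enumerate(eem.excitation_nm):
        for j, y in enumerate(eem.emission_nm):
            if (region.ex_range_nm[0] <= x < region.ex_range_nm[1]
                    and region.em_range_nm[0] <= y < region.em_range_nm[1]):
                total += eem.intensity[i, j] * dex * dem
    return total


class TestIntegrateRegion:
    def test_uniform_volumes_equal_counted_cells(self, uniform_eem):
        for region in DEFAULT_REGIONS:
            vol = integrate_region(uniform_eem, region, force=True)
            assert vol == pytest.approx(UNIFORM_VOLUMES[region.region_id])
            assert vol == pytest.approx(oracle_region_volume(uniform_eem, region))

    def test_zero_eem(self, default_axes):
        ex, em = default_axes
        eem = EEMGrid(ex, em, np.zeros((ex.size, em.size)))
        assert all(integrate_region(eem, r, force=True) == 0.0 for r in DEFAULT_REGIONS)

    def test_linearity(self, default_axes):
        ex, em = default_axes
        rng = np.random.default_rng(3)
        base = rng.uniform(size=(ex.size, em.size))
        eem = EEMGrid(ex, em, base)
        scaled = EEMGrid(ex, em, 3.5 * base)
        for region in DEFAULT_REGIONS:
            assert integrate_region(scaled, region, force=True) == pytest.approx(
                3.5 * integrate_region(eem, region, force=True))

    def test_random_eem_matches_oracle(self):
        rng = np.random.default_rng(11)
        ex = np.arange(220.0, 321.0, 5.0)
        em = np.arange(250.0, 451.0, 5.0)
        eem = EEMGrid(ex, em, rng.uniform(size=(ex.size, em.size)))
        for region in DEFAULT_REGIONS:
            assert integrate_region(eem, region, force=True) == pytest.approx(
                oracle_region_volume(eem, region), rel=1e-12)

    def test_irregular_axis_rejected(self):
        eem = EEMGrid([220.0, 225.0, 235.0], [250.0, 251.0], np.ones((3, 2)))
        with pytest.raises(ValidationError, match="resampl"):
            integrate_region(eem, DEFAULT_REGIONS[0], force=True)

    def test_uncorrected_eem_refused_without_force(self, uniform_eem):
        with pytest.raises(UncorrectedEEMError, match="blank"):
            integrate_region(uniform_eem, DEFAULT_REGIONS[0])
        marked = uniform_eem.with_intensity(
            uniform_eem.intensity, add_corrections={"blank", "scatter"})
        integrate_region(marked, DEFAULT_REGIONS[0])  # no raise


class TestPartition:
    def test_half_open_assignment_is_exclusive_on_default_grid(self, default_axes):
        ex, em = default_axes
        for x in ex:
            for y in em:
                owners = [r.region_id for r in DEFAULT_REGIONS if r.contains(x, y)]
                assert len(owners) <= 1

    def test_shares_sum_to_one_and_sources_partition(self, uniform_eem):
        res = fri_components(uniform_eem, force=True)
        assert sum(res.p.values()) == pytest.approx(1.0)
        assert res.f_allo + res.f_auto == pytest.approx(res.phi_total)
        expected_total = sum(UNIFORM_VOLUMES.values())
        assert res.phi_total == pytest.approx(expected_total)
        # emission 550–600 nm and excitation >400 nm fall outside all regions
        grid_volume = 47 * 351 * 5.0
        assert res.unassigned == pytest.approx(grid_volume - expected_total)
        for region in DEFAULT_REGIONS:
            assert res.p[region.region_id] == pytest.approx(
                UNIFORM_VOLUMES[region.region_id] / expected_total)

    def test_volume_invariant_to_zero_padding_outside_regions(self, default_axes):
        ex, em = default_axes
        rng = np.random.default_rng(5)
        intensity = rng.uniform(size=(ex.size, em.size))
        base = fri_components(EEMGrid(ex, em, intensity), force=True)
        em_ext = np.concatenate([em, np.arange(601.0, 651.0)])
        padded = np.concatenate(
            [intensity, np.zeros((ex.size, em_ext.size - em.size))], axis=1)
        ext = fri_components(EEMGrid(ex, em_ext, padded), force=True)
        for rid in range(1, 6):
            assert ext.phi[rid] == pytest.approx(base.phi[rid], rel=1e-12)

    def test_single_region_signal(self, default_axes):
        ex, em = default_axes
        intensity = np.zeros((ex.size, em.size))
        sel = np.ix_((ex >= 250) & (ex < 400), (em >= 380) & (em < 550))
        intensity[sel] = 2.0
        res = fri_components(EEMGrid(ex, em, intensity), force=True)
        assert res.p[5] == pytest.approx(1.0)
        assert res.f_allo == pytest.approx(res.phi_total)

    def test_zero_total_volume_warns(self, default_axes):
        ex, em = default_axes
        eem = EEMGrid(ex, em, np.zeros((ex.size, em.size)))
        with pytest.warns(UserWarning, match="zero"):
            res = fri_components(eem, force=True)
        assert res.p is None

    def test_overlapping_regions_rejected(self, uniform_eem):
        bad = (RegionDef(1, (200, 260), (280, 330)), RegionDef(2, (250, 300), (300, 340)))
        with pytest.raises(ValidationError, match="overlap"):
            fri_components(uniform_eem, regions=bad, force=True)

    def test_multiplication_factors_equalise_uniform_volumes(self, uniform_eem):
        res = fri_components(uniform_eem, force=True, multiplication_factors=True)
        values = np.array([res.phi[r] for r in range(1, 6)])
        # on a uniform EEM area-normalised volumes agree up to grid discretisation
        assert values.std() / values.mean() < 0.05

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=15)
    def test_total_equals_region_sums_plus_unassigned(self, seed):
        rng = np.random.default_rng(seed)
        ex = np.arange(220.0, 451.0, 5.0)
        em = np.arange(250.0, 601.0, 5.0)
        eem = EEMGrid(ex, em, rng.uniform(size=(ex.size, em.size)))
        res = fri_components(eem, force=True)
        total = eem.intensity.sum() * 5.0 * 5.0
        assert sum(res.phi.values()) + res.unassigned == pytest.approx(total, rel=1e-9)


class TestGaussianMasses:
    def test_riemann_sum_matches_analytic_truncated_mass(self):
        """One Gaussian per region: Φ_i within 2% of its erf closed form."""
        peaks = {  # centred ≥3σ from every region edge so truncation is mild
            1: GaussianPeak(235.0, 305.0, 5.0, 8.0),
            2: GaussianPeak(235.0, 355.0, 5.0, 8.0),
            3: GaussianPeak(235.0, 460.0, 5.0, 25.0),
            4: GaussianPeak(325.0, 330.0, 25.0, 16.0),
            5: GaussianPeak(325.0, 465.0, 25.0, 25.0),
        }
        amps = {1: 50.0, 2: 60.0, 3: 200.0, 4: 40.0, 5: 150.0}
        for rid, region in zip(sorted(amps), DEFAULT_REGIONS):
            eem, truth = generate_eem({rid: amps[rid]}, peaks)
            vol = integrate_region(eem, region, force=True)
            assert vol == pytest.approx(truth[rid], rel=0.02)


class TestFluorescenceIndex:
    def base(self, i370_450=1.0, i370_500=1.0, i310_380=1.0, i310_430=1.0):
        ex, em = np.arange(220.0, 451.0, 5.0), np.arange(250.0, 601.0, 1.0)
        intensity = np.ones((ex.size, em.size))
        grid = EEMGrid(ex, em, intensity)
        for (x, y), v in {(370.0, 450.0): i370_450, (370.0, 500.0): i370_500,
                          (310.0, 380.0): i310_380, (310.0, 430.0): i310_430}.items():
            i, j = grid.index_of(x, y)
            intensity[i, j] = v
        return EEMGrid(ex, em, intensity)

    def test_equal_cells_give_unity(self):
        assert fluorescence_index(self.base(), "FI370") == pytest.approx(1.0)

    def test_direct_ratio(self):
        eem = self.base(i370_450=2.0, i370_500=1.0)
        assert fluorescence_index(eem, "FI370") == pytest.approx(2.0)

    def test_fi310_cells(self):
        eem = self.base(i310_380=1.3, i310_430=2.6)
        assert fluorescence_index(eem, "FI310") == pytest.approx(0.5)

    def test_nonpositive_denominator_warns_nan(self):
        eem = self.base(i370_500=0.0)
        with pytest.warns(UserWarning, match="interpolate"):
            assert np.isnan(fluorescence_index(eem, "FI370"))

    def test_missing_grid_point_rejected(self):
        ex, em = np.arange(220.0, 301.0, 5.0), np.arange(250.0, 401.0, 1.0)
        eem = EEMGrid(ex, em, np.ones((ex.size, em.size)))
        with pytest.raises(ValidationError, match="grid point"):
            fluorescence_index(eem, "FI370")

    def test_unknown_index_rejected(self, uniform_eem):
        with pytest.raises(ValidationError):
            fluorescence_index(uniform_eem, "FI999")


class TestClassifySource:
    @pytest.mark.parametrize("fi370,fi310,expected", [
        ((1.14), 0.81, ("terrestrial", "autochthonous-high")),
        (2.0, 0.5, ("microbial", "autochthonous-low")),
        (1.4, 0.7, ("intermediate", "autochthonous-intermediate")),
        (1.39, 0.8, ("terrestrial", "autochthonous-intermediate")),
        (1.9, 0.75, ("intermediate", "autochthonous-intermediate")),
    ])
    def test_threshold_rules(self, fi370, fi310, expected):
        assert classify_source(fi370, fi310) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            classify_source(float("nan"), 0.8)
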