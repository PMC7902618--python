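"""Reconstruction arithmetic, masking rules and the synthetic round trip."""

import numpy as np
import pytest

from forest_vuln import biomass_recon as br
from forest_vuln import synth
from forest_vuln.errors import ReconstructionError


def layers_1px(tc2000=80.0, loss_year=0, gain=False, tc2012_gain=np.nan):
    return br.TreeCoverLayers(
        np.full((1, 1), tc2000),
        np.full((1, 1), loss_year, dtype=int),
        np.full((1, 1), gain, dtype=bool),
        np.full((1, 1), tc2012_gain),
    )


class TestTc2010:
    @pytest.mark.parametrize("loss_year,expected", [
        (2005, 0.0),   # loss before 2010 masks the pixel
        (0, 80.0),     # never lost
        (2015, 80.0),  # loss after 2010 does not mask
        (2010, 0.0),   # boundary year belongs to the masked period
    ])
    def test_masking_rule(self, loss_year, expected):
        assert br.tc2010(layers_1px(loss_year=loss_year))[0, 0] == expected


class TestTc2010Gain:
    @pytest.mark.parametrize("tc2012,expected", [
        (60.0, 50.0),          # 10/12 of the 2000-2012 ramp
        (0.0, 0.0),
        (100.0, 100.0 * 10 / 12),
    ])
    def test_linear_ramp_factor(self, tc2012, expected):
        layers = layers_1px(tc2000=0.0, gain=True, tc2012_gain=tc2012)
        out = br.tc2010_gain(layers)
        assert out[0, 0] == pytest.approx(expected)

    def test_non_gain_pixels_undefined(self):
        out = br.tc2010_gain(layers_1px(gain=False, tc2012_gain=50.0))
        assert np.isnan(out[0, 0])

    def test_missing_tc2012_rejected(self):
        layers = br.TreeCoverLayers(np.zeros((1, 1)),
                                    np.zeros((1, 1), dtype=int),
                                    np.ones((1, 1), dtype=bool))
        with pytest.raises(ValueError, match="tc2012_gain"):
            br.tc2010_gain(layers)

    def test_window_maximum_statistic(self):
        tc = np.zeros((5, 5))
        tc[0, 0] = 90.0
        gain = np.zeros((5, 5), dtype=bool)
        gain[4, 4] = True
        out = br.tc2012_gain_window(tc, gain, radius_px=25)
        assert out[4, 4] == 90.0
        assert np.isnan(out[0, 0])


class TestDensities:
    def test_ratio_arithmetic(self):
        # B=100 over 50% cover lost after 2010 -> 2 t/ha per %
        layers = layers_1px(tc2000=50.0, loss_year=2014)
        dens = br.densities(np.full((1, 1), 100.0), layers, coarse_block=1)
        assert dens.rho_loss[0, 0] == pytest.approx(2.0)

    def test_zero_cover_pixels_excluded(self):
        tc = np.array([[50.0, 0.0]])
        ly = np.array([[2014, 2014]], dtype=int)
        layers = br.TreeCoverLayers(tc, ly, np.zeros((1, 2), dtype=bool),
                                    np.full((1, 2), np.nan))
        dens = br.densities(np.full((1, 2), 100.0), layers, coarse_block=2)
        # only the 50%-cover pixel defines the ratio
        assert np.allclose(dens.rho_loss, 2.0)

    def test_coarse_cell_median(self):
        tc = np.array([[100.0, 50.0, 100.0 / 9]])
        ly = np.array([[2012, 2013, 2014]], dtype=int)
        layers = br.TreeCoverLayers(tc, ly, np.zeros((1, 3), dtype=bool),
                                    np.full((1, 3), np.nan))
        dens = br.densities(np.full((1, 3), 100.0), layers, coarse_block=4)
        # pixel ratios {1, 2, 9} -> median 2
        assert np.allclose(dens.rho_loss, 2.0)

    def test_empty_cells_nearest_filled(self):
        tc = np.full((4, 8), 50.0)
        ly = np.zeros((4, 8), dtype=int)
        ly[0, 0] = 2014  # only the left block has a defined ratio
        layers = br.TreeCoverLayers(tc, ly, np.zeros((4, 8), dtype=bool),
                                    np.full((4, 8), np.nan))
        dens = br.densities(np.full((4, 8), 75.0), layers, coarse_block=4)
        assert np.allclose(dens.rho_loss, 1.5)

    def test_loss_pixels_without_estimable_ratio(self):
        # losses exist but all pre-2011: the loss density cannot be derived
        layers = layers_1px(loss_year=2005)
        with pytest.raises(ReconstructionError, match="loss-density"):
            br.densities(np.full((1, 1), 100.0), layers, coarse_block=1)

    def test_change_free_domain_needs_no_density(self):
        layers = layers_1px(loss_year=0)
        dens = br.densities(np.full((1, 1), 100.0), layers, coarse_block=1)
        assert np.allclose(dens.rho_loss, 0.0)
        assert np.allclose(dens.rho_gain, 0.0)


class TestAnnualBiomass:
    def make(self, rho_loss=2.0, rho_gain=1.0, shape=(1, 1)):
        return br.DensityGrids(np.full(shape, rho_loss),
                               np.full(shape, rho_gain))

    def test_reference_year_identity(self):
        layers = layers_1px(loss_year=0)
        out = br.annual_biomass(np.full((1, 1), 100.0), self.make(), layers, 2010)
        assert out[0, 0] == 100.0

    def test_post2010_loss_subtracted(self):
        # 10% cover lost in 2013, rho=2: 100 - 2*10 = 80 at t=2015
        layers = layers_1px(tc2000=10.0, loss_year=2013)
        out = br.annual_biomass(np.full((1, 1), 100.0), self.make(), layers, 2015)
        assert out[0, 0] == pytest.approx(80.0)

    def test_gain_ramp_at_2000(self):
        # gain pixel with TC_2010,gain = 12 and rho_gain = 1:
        # B_2000 = B_2010 - 1 * 12 * (10/10)
        layers = layers_1px(tc2000=0.0, gain=True, tc2012_gain=14.4)
        out = br.annual_biomass(np.full((1, 1), 100.0), self.make(), layers, 2000)
        assert out[0, 0] == pytest.approx(88.0)

    @pytest.mark.parametrize("t", [1999, 2018])
    def test_year_out_of_range(self, t):
        layers = layers_1px()
        with pytest.raises(ValueError, match="outside"):
            br.annual_biomass(np.full((1, 1), 100.0), self.make(), layers, t)

    def test_negative_reconstruction_clipped(self):
        layers = layers_1px(tc2000=90.0, loss_year=2012)
        out = br.annual_biomass(np.full((1, 1), 10.0), self.make(), layers, 2017)
        assert out[0, 0] == 0.0

    def test_alpha_boundary_configurable(self):
        # loss in 2010: t=2009 sits on the negative side by default
        layers = layers_1px(tc2000=10.0, loss_year=2010)
        b = np.full((1, 1), 100.0)
        default = br.annual_biomass(b, self.make(), layers, 2009)
        literal2010 = br.annual_biomass(b, self.make(), layers, 2009,
                                        alpha_boundary_year=2010)
        assert default[0, 0] == pytest.approx(80.0)   # alpha = -1
        assert literal2010[0, 0] == pytest.approx(120.0)  # alpha = +1

    def test_per_year_gain_mode_double_scales(self):
        layers = layers_1px(tc2000=0.0, gain=True, tc2012_gain=24.0)
        b = np.full((1, 1), 100.0)
        static = br.annual_biomass(b, self.make(), layers, 2006)
        peryear = br.annual_biomass(b, self.make(), layers, 2006,
                                    gain_mode="per-year")
        # static: 24*(10/12) = 20 vs per-year ramp: 24*(6/12) = 12,
        # both times the (2010-2006)/10 factor and rho_gain = 1
        assert static[0, 0] == pytest.approx(100.0 - 20.0 * 0.4)
        assert peryear[0, 0] == pytest.approx(100.0 - 12.0 * 0.4)

    def test_loss_monotonicity_after_2010(self):
        """More post-2010 cover loss never increases reconstructed biomass."""
        b = np.full((1, 1), 100.0)
        low = layers_1px(tc2000=5.0, loss_year=2013)
        high = layers_1px(tc2000=20.0, loss_year=2013)
        out_low = br.annual_biomass(b, self.make(), low, 2015)
        out_high = br.annual_biomass(b, self.make(), high, 2015)
        assert out_high[0, 0] <= out_low[0, 0]


def _oracle_stack(landscape, years, alpha_boundary=2009):
    """Brute-force per-pixel evaluation of the reconstruction rule with the
    generator's true (constant) densities."""
    tc2000 = landscape["tc2000"].values
    loss_year = landscape["loss_year"].values
    gain = landscape["gain_mask"].values
    tc2012g = landscape["tc2012_gain"].values
    b2010 = landscape["b2010"].values
    rl = landscape.attrs["rho_loss_true"]
    rg = landscape.attrs["rho_gain_true"]
    ny, nx = tc2000.shape
    out = np.zeros((len(years), ny, nx))
    for k, t in enumerate(years):
        for i in range(ny):
            for j in range(nx):
                alpha = 1.0 if t < alpha_boundary else -1.0
                ly = loss_year[i, j]
                if t < 2010:
                    tcl = tc2000[i, j] if t < ly <= 2010 else 0.0
                else:
                    tcl = tc2000[i, j] if 2010 < ly <= t else 0.0
                gain_term = 0.0
                if gain[i, j]:
                    gain_term = rg * (10 / 12) * tc2012g[i, j] * (2010 - t) / 10
                val = b2010[i, j] + alpha * rl * tcl - gain_term
                out[k, i, j] = max(val, 0.0)
    return out


class TestRoundTrip:
    def test_reconstruction_matches_per_pixel_oracle(self):
        """On a landscape whose 2010 biomass is consistent with constant
        true densities, the full estimate-then-reconstruct chain recovers
        the direct per-pixel evaluation exactly."""
        ls = synth.generate_landscape(21, 16, 16)
        layers = synth.landscape_layers(ls)
        years = list(range(2000, 2018))
        stack = br.reconstruct_stack(ls["b2010"].values, layers, years=years)
        oracle = _oracle_stack(ls, years)
        assert np.max(np.abs(stack.biomass - oracle)) < 1e-9

    def test_estimated_densities_recover_truth(self):
        ls = synth.generate_landscape(22, 24, 24)
        layers = synth.landscape_layers(ls)
        dens = br.densities(ls["b2010"].values, layers)
        assert np.allclose(dens.rho_loss, ls.attrs["rho_loss_true"])
        assert np.allclose(dens.rho_gain, ls.attrs["rho_gain_true"])

    def test_loss_density_exceeds_gain_density(self):
        """Old forests carry more biomass per percent cover than regrowth."""
        ls = synth.generate_landscape(23, 24, 24)
        layers = synth.landscape_layers(ls)
        dens = br.densities(ls["b2010"].values, layers)
        assert np.median(dens.rho_loss) > np.median(dens.rho_gain)
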