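"""Gas conversion, two-pool mixing and priming arithmetic."""

import numpy as np
import pandas as pd
import pytest

from soilprime.isotopes import (GasSample, IsotopeMeasurement,
                                atom_fraction_to_delta,
                                delta_to_atom_fraction, headspace_to_carbon,
                                net_effect, partition_respiration,
                                substrate_fraction)


class TestHeadspaceToCarbon:
    def test_ideal_gas_hand_value(self):
        # 400 ppm in 25 ml at 101 kPa, 298 K: n = 101000*25e-6*400e-6/(R*298)
        n = headspace_to_carbon(GasSample(ppm=400))
        assert n == pytest.approx(0.4077, rel=1e-3)

    def test_zero_ppm_gives_zero(self):
        assert headspace_to_carbon(GasSample(ppm=0)) == 0.0

    def test_linearity_in_ppm(self):
        n1 = headspace_to_carbon(GasSample(ppm=500))
        n2 = headspace_to_carbon(GasSample(ppm=1000))
        assert n2 == pytest.approx(2 * n1, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"headspace_volume_ml": 0}, {"pressure_kpa": -1},
        {"temperature_k": 0}])
    def test_nonpositive_conditions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GasSample(ppm=400, **kwargs)


class TestSubstrateFraction:
    def test_endmember_limits(self):
        m0 = IsotopeMeasurement(delta_c=-25, delta_t=-25, delta_l=975)
        assert substrate_fraction(m0) == 0.0
        m1 = IsotopeMeasurement(delta_c=-25, delta_t=975, delta_l=975)
        assert substrate_fraction(m1) == pytest.approx(1.0)

    def test_halfway_mixture_in_atom_fraction(self):
        # the delta-scale midpoint corresponds to the atom-fraction scale
        # only approximately; the atom-fraction formulation is exact
        a_c = delta_to_atom_fraction(-25.0)
        a_l = delta_to_atom_fraction(975.0)
        a_t = 0.5 * (a_c + a_l)
        m = IsotopeMeasurement(a_c, a_t, a_l, as_atom_fraction=True)
        assert substrate_fraction(m) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_mixture_value(self):
        a_c, a_l = 0.011, 0.75
        fracs = [substrate_fraction(IsotopeMeasurement(
            a_c, a_t, a_l, as_atom_fraction=True))
            for a_t in np.linspace(a_c, a_l, 25)]
        assert np.all(np.diff(fracs) > 0)

    def test_equal_endmembers_rejected(self):
        with pytest.raises(ValueError):
            substrate_fraction(IsotopeMeasurement(-25, 0, -25))

    def test_outside_unit_interval_clamped_with_warning(self):
        m = IsotopeMeasurement(0.011, 0.010, 0.75, as_atom_fraction=True)
        with pytest.warns(UserWarning):
            assert substrate_fraction(m) == 0.0

    def test_delta_atom_roundtrip(self):
        d = np.array([-25.0, 0.0, 500.0, 975.0])
        assert np.allclose(atom_fraction_to_delta(delta_to_atom_fraction(d)),
                           d, atol=1e-9)


class TestPartitionRespiration:
    @staticmethod
    def _series(total_straw, total_basal, frac_c13=0.5):
        rows = []
        days = np.arange(1, len(total_straw) + 1)
        for day, t in zip(days, total_straw):
            rows.append(dict(treatment="control", straw_group="c13",
                             replicate="r1", day=day, total_ugC_g=t,
                             c13_ugC_g=t * frac_c13))
        for day, t in zip(days, total_basal):
            rows.append(dict(treatment="control", straw_group="none",
                             replicate="r1", day=day, total_ugC_g=t,
                             c13_ugC_g=t * 0.011))
        return pd.DataFrame(rows)

    def test_stated_arithmetic(self):
        # total 500, substrate-derived 300, basal 80 -> primed 120
        series = self._series([250, 250], [40, 40])
        res = partition_respiration(series, fractions={1: 0.6, 2: 0.6})
        row = res.table.iloc[0]
        assert row.total_respiration == 500
        assert row.substrate_derived == pytest.approx(300)
        assert row.primed == pytest.approx(120)

    def test_zero_fraction_identical_series_gives_zero_priming(self):
        series = self._series([40, 40], [40, 40])
        res = partition_respiration(series, fractions={1: 0.0, 2: 0.0})
        assert res.table.iloc[0].primed == pytest.approx(0.0)

    def test_fraction_one_gives_negative_basal(self):
        series = self._series([100, 100], [30, 30])
        res = partition_respiration(series, fractions={1: 1.0, 2: 1.0})
        assert res.table.iloc[0].primed == pytest.approx(-60.0)

    def test_partition_is_exact_decomposition(self):
        series = self._series([120, 90, 60], [30, 25, 20])
        res = partition_respiration(series, fractions={1: .4, 2: .3, 3: .2})
        row = res.table.iloc[0]
        native = row.total_respiration - row.substrate_derived
        assert native == pytest.approx(row.basal + row.primed, rel=1e-12)

    def test_missing_basal_group_rejected(self):
        series = self._series([100], [30])
        series = series[series.straw_group != "none"]
        with pytest.raises(ValueError, match="basal"):
            partition_respiration(series, fractions={1: 0.5})

    def test_both_fraction_sources_rejected(self):
        series = self._series([100], [30])
        with pytest.raises(ValueError):
            partition_respiration(series, straw_atom13=0.75,
                                  fractions={1: 0.5})


class TestNetEffect:
    def test_stated_convention(self):
        rep, net = net_effect(1000, 400, 120)
        assert (rep, net) == (600, 480)

    def test_zero_priming_net_equals_replenishment(self):
        rep, net = net_effect(1000, 400, 0)
        assert net == rep == 600

    def test_full_respiration_gives_zero_replenishment(self):
        rep, _ = net_effect(1000, 1000, 50)
        assert rep == 0

    def test_mass_balance_violation_rejected(self):
        with pytest.raises(ValueError):
            net_effect(100, 150, 0)

    def test_gain_convention_flips_sign(self):
        _, net_loss = net_effect(1000, 400, 120, "loss")
        _, net_gain = net_effect(1000, 400, 120, "gain")
        assert net_gain - net_loss == 240
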