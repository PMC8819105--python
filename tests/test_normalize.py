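import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from abcscreen import RunConfig, SignalModelParams, ViabilityRecord, cell_viability, generate_timecourse, min_max_scale
from abcscreen.errors import DegenerateScaleError, DenominatorError
from abcscreen.io import ROLE_BACKGROUND, ROLE_VEHICLE_BFGF, VEHICLE
from abcscreen.normalize import compute_rlu, fold_change


class TestComputeRlu:
    def test_self_normalization(self, noiseless_plate):
        """Background wells divided by their own mean give RLU 1."""
        rlu = compute_rlu(noiseless_plate)
        bg = rlu[rlu["role"] == ROLE_BACKGROUND]
        np.testing.assert_allclose(bg["rlu"], 1.0)

    def test_scaling(self, noiseless_plate):
        plate3 = noiseless_plate
        df = plate3.df.copy()
        chem = df["role"] == "chemical_bfgf"
        bg_mean = df[df["role"] == ROLE_BACKGROUND].groupby("time_h")["luminescence"].mean()
        df.loc[chem, "luminescence"] = 3.0 * bg_mean.reindex(df.loc[chem, "time_h"]).to_numpy()
        from abcscreen import PlateTimeSeries

        rlu = compute_rlu(PlateTimeSeries(df))
        np.testing.assert_allclose(rlu.loc[chem, "rlu"], 3.0)

    def test_vehicle_rlu_at_peak(self, config, design):
        """sigma = 0: vehicle RLU at the peak equals 1 + A by the generator model."""
        params = SignalModelParams(noise_sd=0.0, amplitude=7.0, peak_time_h=5.0)
        plate = generate_timecourse(params, design, config, seed=0)
        rlu = compute_rlu(plate)
        veh_peak = rlu[(rlu["role"] == ROLE_VEHICLE_BFGF) & (rlu["time_h"] == 5.0)]
        np.testing.assert_allclose(veh_peak["rlu"], 8.0)

    def test_missing_background_rejected(self, noiseless_plate):
        df = noiseless_plate.df
        trimmed = df[df["role"] != ROLE_BACKGROUND]
        from abcscreen import PlateTimeSeries

        with pytest.raises(DenominatorError):
            compute_rlu(PlateTimeSeries(trimmed))


class TestMinMaxScale:
    def test_linear_map(self):
        np.testing.assert_allclose(min_max_scale([0.0, 5.0, 10.0]), [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        x = np.array([0.0, 0.3, 0.8, 1.0])
        np.testing.assert_allclose(min_max_scale(x), x)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateScaleError):
            min_max_scale([5.0, 5.0, 5.0])

    @given(
        x=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30).filter(
            lambda v: max(v) - min(v) > 1e-3
        ),
        alpha=st.floats(1e-3, 1e3),
        beta=st.floats(-1e6, 1e6),
    )
    @settings(derandomize=True, max_examples=60)
    def test_affine_invariance_and_bounds(self, x, alpha, beta):
        """Scaling is invariant to x -> alpha x + beta and attains both bounds."""
        arr = np.asarray(x)
        s = min_max_scale(arr)
        assert s.min() == 0.0 and s.max() == 1.0
        s2 = min_max_scale(alpha * arr + beta)
        np.testing.assert_allclose(s, s2, atol=1e-9)


def _scaled_frame(times, chem_vals, veh_reps):
    rows = []
    for rep, vals in enumerate(veh_reps, start=1):
        for t, v in zip(times, vals):
            rows.append((VEHICLE, 0.0, rep, ROLE_VEHICLE_BFGF, t, v))
    for t, v in zip(times, chem_vals):
        rows.append(("X", 1.0, 1, "chemical_bfgf", t, v))
    return pd.DataFrame(
        rows, columns=["chemical", "concentration_ug_ml", "replicate", "role", "time_h", "scaled"]
    )


class TestFoldChange:
    times = [0.0, 1.0, 2.0]

    def test_identity(self):
        df = _scaled_frame(self.times, [0.4, 0.5, 0.6], [[0.4, 0.5, 0.6]])
        out = fold_change(df, RunConfig(epsilon_ratio_floor=0.0))
        chem = out[out["chemical"] == "X"]
        np.testing.assert_allclose(chem["fold_change"], 1.0)
        np.testing.assert_allclose(chem["log_fc"], 0.0)

    def test_ratio_two(self):
        df = _scaled_frame(self.times, [0.4, 0.6, 0.8], [[0.2, 0.3, 0.4]])
        out = fold_change(df, RunConfig(epsilon_ratio_floor=0.0))
        chem = out[out["chemical"] == "X"]
        np.testing.assert_allclose(chem["fold_change"], 2.0)

    def test_floor_keeps_ratio_finite(self):
        """A zero vehicle mean at one time point stays finite with the floor."""
        df = _scaled_frame(self.times, [0.5, 0.5, 0.5], [[0.0, 0.5, 0.5]])
        out = fold_change(df, RunConfig(epsilon_ratio_floor=1e-3))
        chem = out[out["chemical"] == "X"].set_index("time_h")
        assert np.isfinite(chem.loc[0.0, "fold_change"])
        # limit computation: (0.5 + eps) / (0 + eps)
        assert chem.loc[0.0, "fold_change"] == pytest.approx(0.501 / 0.001)

    def test_vehicle_fold_change_mean_one(self, rng):
        """Vehicle wells against their own mean average to fc = 1 at every t (eps = 0).

        Holds wherever the scaled vehicle mean is positive; the shared
        minimum at the stimulus time (scaled value exactly 0) is the
        0/0 case the epsilon floor exists for.
        """
        reps = rng.uniform(0.05, 1.0, size=(3, len(self.times)))
        df = _scaled_frame(self.times, reps[0], list(reps))
        out = fold_change(df, RunConfig(epsilon_ratio_floor=0.0))
        veh = out[out["chemical"] == VEHICLE]
        means = veh.groupby("time_h")["fold_change"].mean()
        np.testing.assert_allclose(means, 1.0, atol=1e-12)


class TestCellViability:
    @pytest.mark.parametrize(
        "sample,blank,vehicle,expected",
        [(1.1, 0.1, 1.1, 1.0), (0.1, 0.1, 1.1, 0.0), (0.6, 0.1, 1.1, 0.5)],
    )
    def test_quotient(self, sample, blank, vehicle, expected):
        rec = ViabilityRecord("X", 1.0, abs_sample=sample, abs_blank=blank, abs_vehicle=vehicle)
        assert cell_viability(rec) == pytest.approx(expected)

    def test_denominator_error(self):
        rec = ViabilityRecord("X", 1.0, abs_sample=0.5, abs_blank=0.2, abs_vehicle=0.1)
        with pytest.raises(DenominatorError):
            cell_viability(rec)
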