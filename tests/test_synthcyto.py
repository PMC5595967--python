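"""Generator contracts: distribution moments, determinism, plate plumbing."""

import numpy as np
import pytest

from cycleprof.errors import MissingCompoundError, ValidationError
from cycleprof.synthcyto import (
    DEFAULT_DOSES_UM,
    DMSO_TRUTH,
    PhaseFractions,
    PlateMap,
    PopulationModel,
    make_screen_truth,
    read_events_long,
    simulate_dose_response,
    simulate_plate,
    simulate_viability_plate,
    simulate_well,
    well_seed,
    write_events_long,
)


class TestPhaseFractions:
    def test_rejects_non_normalized(self):
        with pytest.raises(ValidationError):
            PhaseFractions(0.5, 0.5, 0.5, 0.5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            PhaseFractions(1.2, -0.2, 0.0, 0.0)

    def test_accepts_exact_partition(self):
        f = PhaseFractions(0.54, 0.10, 0.31, 0.05)
        assert f.as_array().sum() == pytest.approx(1.0, abs=1e-12)


class TestSimulateWell:
    @pytest.mark.parametrize(
        "fractions, mean_lo, mean_hi, sd_lo, sd_hi",
        [
            # pure 2N population: Normal(100, 5) moments at n = 10000
            ((1, 0, 0, 0), 99.0, 101.0, 4.5, 5.5),
            # pure 4N population: Normal(200, 10)
            ((0, 0, 1, 0), 198.0, 202.0, 9.0, 11.0),
        ],
    )
    def test_peak_moments(self, default_model, fractions, mean_lo, mean_hi, sd_lo, sd_hi):
        ev = simulate_well(PhaseFractions(*fractions), default_model)
        assert mean_lo <= ev.intensities.mean() <= mean_hi
        assert sd_lo <= ev.intensities.std(ddof=1) <= sd_hi

    def test_same_seed_identical(self, default_model):
        a = simulate_well(DMSO_TRUTH, default_model)
        b = simulate_well(DMSO_TRUTH, default_model)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_all_positive(self, default_model):
        ev = simulate_well(PhaseFractions(0.1, 0.1, 0.1, 0.7), default_model)
        assert (ev.intensities > 0).all()

    def test_labels_match_counts(self, default_model):
        ev = simulate_well(DMSO_TRUTH, default_model)
        assert len(ev.labels) == len(ev.intensities) == default_model.n_events

    def test_multinomial_phase_counts_calibrated(self):
        """Generated label proportions track the multinomial model: within
        3*sqrt(p(1-p)/n) of truth in >= 95% of 200 seeded wells."""
        p = DMSO_TRUTH.as_array()
        n = 5000
        tol = 3.0 * np.sqrt(p * (1 - p) / n)
        ok = 0
        for seed in range(200):
            ev = simulate_well(DMSO_TRUTH, PopulationModel(seed=seed, n_events=n))
            props = np.array([
                (ev.labels == ph).mean() for ph in ("g1", "s", "g2m", "subg1")
            ])
            ok += int((np.abs(props - p) <= tol).all())
        assert ok >= 0.95 * 200


class TestPlate:
    def test_plate_counts_and_truth_rows(self):
        pm = PlateMap.build(["drugA", "drugB"], n_dmso=2, rows=2, cols=3)
        truth = {"drugA": PhaseFractions(0.1, 0.1, 0.7, 0.1),
                 "drugB": DMSO_TRUTH}
        events, table = simulate_plate(pm, truth, PopulationModel(n_events=50))
        assert len(events) == 4
        assert (table["role"] == "compound").sum() == 2

    def test_missing_truth_raises_named_error(self):
        pm = PlateMap.build(["mystery"], n_dmso=1, rows=1, cols=4)
        with pytest.raises(MissingCompoundError, match="mystery"):
            simulate_plate(pm, {}, PopulationModel(n_events=10))

    def test_same_seed_identical_plates(self):
        pm = PlateMap.build(["a"], n_dmso=2, rows=1, cols=4)
        truth = {"a": DMSO_TRUTH}
        m = PopulationModel(n_events=100, seed=11)
        ev1, _ = simulate_plate(pm, truth, m)
        ev2, _ = simulate_plate(pm, truth, m)
        for wid in ev1:
            np.testing.assert_array_equal(ev1[wid].intensities, ev2[wid].intensities)

    def test_well_seed_stable_and_31bit(self):
        s = well_seed(42, "A01")
        assert s == well_seed(42, "A01")
        assert 0 <= s < 2**31
        assert s != well_seed(42, "A02")

    def test_map_requires_dmso_reference_well(self):
        with pytest.raises(ValidationError):
            PlateMap.build(["a"], n_dmso=0, rows=1, cols=2)

    def test_events_roundtrip(self, tmp_path):
        pm = PlateMap.build(["a"], n_dmso=1, rows=1, cols=3)
        ev, _ = simulate_plate(pm, {"a": DMSO_TRUTH}, PopulationModel(n_events=100))
        path = tmp_path / "events.csv"
        write_events_long(ev, path)
        back = read_events_long(path)
        assert set(back) == set(ev)
        for wid in ev:
            np.testing.assert_allclose(back[wid].intensities, ev[wid].intensities)


class TestViabilityPlate:
    def test_mean_tracks_truth(self):
        pm = PlateMap.build([f"c{i}" for i in range(100)], n_dmso=4)
        via = {f"c{i}": 0.5 for i in range(100)}
        df = simulate_viability_plate(pm, via, signal_mean=1000.0, cv=0.02, seed=5)
        comp = df[df["role"] == "compound"]["reading"]
        assert 490 <= comp.mean() <= 510

    def test_zero_viability_near_zero(self):
        pm = PlateMap.build(["dead"], n_dmso=2, rows=1, cols=4)
        df = simulate_viability_plate(pm, {"dead": 0.0}, cv=0.05, seed=1)
        assert (df[df["compound"] == "dead"]["reading"] == 0).all()

    def test_dmso_near_signal_mean(self):
        pm = PlateMap.build([], n_dmso=50, rows=16, cols=24)
        df = simulate_viability_plate(pm, {}, signal_mean=1000.0, cv=0.02, seed=2)
        assert df["reading"].mean() == pytest.approx(1000.0, rel=0.02)

    def test_rejects_bad_cv(self):
        pm = PlateMap.build([], n_dmso=2, rows=1, cols=2)
        with pytest.raises(ValidationError):
            simulate_viability_plate(pm, {}, cv=0.0)


class TestDoseResponse:
    def test_midpoint_identity(self):
        df = simulate_dose_response(ec50=1.0, hill=1.0, doses=[1.0], cv=0.0, replicates=1)
        assert df["response"].iloc[0] == pytest.approx(50.0)

    def test_asymptotes(self):
        df = simulate_dose_response(ec50=1.0, hill=2.0, doses=[1e-6, 1e6], cv=0.0, replicates=1)
        assert df["response"].iloc[0] == pytest.approx(100.0, abs=1e-6)
        assert df["response"].iloc[1] == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_point(self):
        # bottom + (top-bottom)/(1 + (6/2)^2) = 0 + 100/10 = 10
        df = simulate_dose_response(ec50=2.0, hill=2.0, doses=[6.0], cv=0.0, replicates=1)
        assert df["response"].iloc[0] == pytest.approx(10.0)

    def test_noiseless_monotone_on_default_grid(self):
        df = simulate_dose_response(ec50=0.5, hill=1.3, cv=0.0, replicates=1)
        ordered = df.sort_values("dose_uM")["response"].to_numpy()
        assert (np.diff(ordered) < 0).all()
        assert len(DEFAULT_DOSES_UM) == 8

    def test_rejects_nonpositive_dose(self):
        with pytest.raises(ValidationError):
            simulate_dose_response(ec50=1.0, doses=[1.0, 0.0])


def test_make_screen_truth_contracts():
    truth, shift = make_screen_truth(n_shifted=10, n_dmso_like=5, n_moderate=5, seed=3)
    assert len(truth) == 20
    for name, dist in shift.items():
        if name.startswith("shifted"):
            assert dist >= 15.0
        elif name.startswith("inactive"):
            assert dist == 0.0
        else:
            assert 2.0 <= dist <= 6.0
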