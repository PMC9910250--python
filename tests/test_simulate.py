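"""Generator tests: planted coupling structure, determinism, spectral content,
trial-table shapes and Monte-Carlo recovery of planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import welch

from sleepfbn import (
    CouplingModel,
    TrialDesign,
    simulate_eeg,
    simulate_scales,
    simulate_volumes,
)
from sleepfbn.errors import (
    InvalidArgumentError,
    InvalidDesignError,
    InvalidModelError,
    InvalidRegionError,
)
from sleepfbn.reference import AAL_REGIONS


def pair_coupling(i, j, value, n=8):
    c = np.zeros((n, n))
    c[i, j] = c[j, i] = value
    return c


class TestSimulateEEG:
    def test_shared_source_identity(self):
        """A fully shared source with no noise gives r = 1 between the pair."""
        model = CouplingModel(coupling=pair_coupling(0, 1, 1.0), noise_sd=0.0, seed=3)
        rec = simulate_eeg(model, duration=20)
        r = np.corrcoef(rec.signal[0], rec.signal[1])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_uncoupled_channels_are_near_independent(self):
        """All-zero coupling: mean |off-diagonal r| < 0.15 over 20 seeds."""
        model_kw = dict(coupling=np.zeros((8, 8)), noise_sd=0.5)
        iu = np.triu_indices(8, 1)
        vals = []
        for seed in range(20):
            rec = simulate_eeg(CouplingModel(seed=seed, **model_kw), duration=60)
            vals.append(np.abs(np.corrcoef(rec.signal)[iu]).mean())
        assert np.mean(vals) < 0.15

    def test_seed_determinism_bit_identical(self):
        model = CouplingModel(coupling=pair_coupling(2, 5, 0.4), noise_sd=1.0, seed=11)
        a = simulate_eeg(model, duration=30)
        b = simulate_eeg(model, duration=30)
        assert np.array_equal(a.signal, b.signal)

    def test_channel_labels_and_metadata(self):
        rec = simulate_eeg(CouplingModel(seed=0), duration=5)
        assert rec.channel_labels == ("C3", "C4", "P3", "P4", "O1", "O2", "P7", "P8")
        assert rec.fs == 128.0
        assert rec.n_samples == 5 * 128

    @pytest.mark.parametrize(
        "bad",
        [
            dict(coupling=np.triu(np.full((8, 8), 0.5), 1)),  # asymmetric
            dict(coupling=np.full((8, 8), 0.5)),  # nonzero diagonal
            dict(coupling=pair_coupling(0, 1, 1.5)),  # out of range
            dict(noise_sd=-0.1),
            dict(band_profile=(((0.1, 4.0), 1.0),)),  # band below 0.3 Hz
        ],
    )
    def test_invalid_models_rejected(self, bad):
        with pytest.raises(InvalidModelError):
            CouplingModel(**bad)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_eeg(CouplingModel(seed=0), duration=0)

    def test_spectral_fidelity(self):
        """>= 90% of pre-filter power lies inside the 0.3-30 Hz band."""
        model = CouplingModel(coupling=pair_coupling(0, 1, 0.5), noise_sd=1.0, seed=8)
        rec = simulate_eeg(model, duration=120)
        f, p = welch(rec.signal, fs=rec.fs, nperseg=1024, axis=1)
        inband = p[:, (f >= 0.3) & (f <= 30)].sum(axis=1) / p.sum(axis=1)
        assert inband.min() >= 0.90

    def test_coupling_correlation_monotone(self):
        """Expected |PCC| increases with the planted coupling (5-value grid x 50 seeds)."""
        grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        means = []
        for c in grid:
            vals = []
            for seed in range(50):
                model = CouplingModel(coupling=pair_coupling(0, 1, c), noise_sd=1.0, seed=seed)
                rec = simulate_eeg(model, duration=30)
                vals.append(abs(np.corrcoef(rec.signal[0], rec.signal[1])[0, 1]))
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestSimulateScales:
    def test_row_count(self):
        design = TrialDesign(n_treatment=15, n_control=10, seed=0)
        table = simulate_scales(design)
        assert len(table) == 25 * len(design.timepoints) * len(design.measures)
        assert set(table.columns) == {"subject_id", "arm", "timepoint", "measure", "value"}

    def test_determinism(self):
        a = simulate_scales(TrialDesign(seed=5))
        b = simulate_scales(TrialDesign(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_null_arm_difference_centred(self):
        """No planted effect: arm difference at 24M averages ~0 over 500 seeds."""
        diffs = []
        for seed in range(500):
            t = simulate_scales(TrialDesign(seed=seed, measures=("ADL",)))
            sub = t[t.timepoint == "24M"]
            diffs.append(
                sub.loc[sub.arm == "treatment", "value"].mean()
                - sub.loc[sub.arm == "control", "value"].mean()
            )
        design = TrialDesign()
        assert abs(np.mean(diffs)) < 0.1 * design.between_subject_sd

    def test_planted_effect_separates_arms(self):
        """A 2-SD shift at 24M puts the treatment mean above control in >= 95% of seeds."""
        wins = 0
        for seed in range(500):
            t = simulate_scales(TrialDesign(
                seed=seed, measures=("ADL",),
                effect_sizes={("ADL", "24M", "treatment"): 2.0},
            ))
            sub = t[t.timepoint == "24M"]
            wins += (
                sub.loc[sub.arm == "treatment", "value"].mean()
                > sub.loc[sub.arm == "control", "value"].mean()
            )
        assert wins / 500 >= 0.95

    @pytest.mark.parametrize(
        "kw",
        [
            dict(effect_sizes={("ADL", "36M", "treatment"): 1.0}),  # unknown timepoint
            dict(effect_sizes={("ADL", "baseline", "treatment"): 1.0}),  # baseline shift
            dict(effect_sizes={("XYZ", "24M", "treatment"): 1.0}),  # unknown measure
            dict(n_treatment=1),
            dict(between_subject_sd=0.0),
            dict(timepoints=("baseline", "baseline", "24M")),
        ],
    )
    def test_invalid_designs_rejected(self, kw):
        with pytest.raises(InvalidDesignError):
            TrialDesign(**kw)


class TestSimulateVolumes:
    def test_paired_records_per_region(self):
        table = simulate_volumes(n_subjects=9, seed=1)
        counts = table.groupby(["region", "timepoint"]).size()
        assert (counts == 9).all()
        # 9 AAL regions + TOTAL pseudo-region, 2 timepoints
        assert len(table) == 9 * (len(AAL_REGIONS) + 1) * 2

    def test_total_is_sum_of_regions_plus_remainder(self):
        """TOTAL minus the regional sum is constant within subject across timepoints."""
        table = simulate_volumes(n_subjects=5, seed=3)
        wide = table.pivot_table(index=["subject_id", "timepoint"], columns="region",
                                 values="volume")
        regions = [c for c in wide.columns if c != "TOTAL"]
        remainder = wide["TOTAL"] - wide[regions].sum(axis=1)
        per_subject = remainder.groupby("subject_id").agg(["min", "max"])
        assert np.allclose(per_subject["min"], per_subject["max"], rtol=1e-9)

    def test_null_percent_change_centred(self):
        """Zero effect: mean paired percent change within 0.2 pp of 0 (500 seeds)."""
        changes = []
        for seed in range(500):
            t = simulate_volumes(n_subjects=9, seed=seed)
            wide = t[t.region == "SOG.L"].pivot_table(
                index="subject_id", columns="timepoint", values="volume")
            changes.append((100 * (wide["6M"] - wide["baseline"]) / wide["baseline"]).mean())
        assert abs(np.mean(changes)) < 0.2

    def test_planted_effect_recovered(self):
        """+5% on one region is recovered within [4%, 6%] at 2% measurement noise."""
        changes = []
        for seed in range(500):
            t = simulate_volumes(n_subjects=9, seed=seed, effect={"SOG.L": 0.05},
                                 noise_sd=0.02)
            wide = t[t.region == "SOG.L"].pivot_table(
                index="subject_id", columns="timepoint", values="volume")
            changes.append((100 * (wide["6M"] - wide["baseline"]) / wide["baseline"]).mean())
        assert 4.0 <= np.mean(changes) <= 6.0

    def test_unknown_region_rejected(self):
        with pytest.raises(InvalidRegionError):
            simulate_volumes(effect={"NOPE.L": 0.05}, seed=0)
        with pytest.raises(InvalidRegionError):
            simulate_volumes(regions=("SOG.L", "NOPE.R"), seed=0)
        with pytest.raises(InvalidRegionError):
            simulate_volumes(effect={"SOG.L": -1.0}, seed=0)
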