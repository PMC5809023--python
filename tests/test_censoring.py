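"""Record validation and the death/EoE/crowding/drug-delay censoring stages."""

import numpy as np
import pytest

from ddtcycle import (
    CellRecord,
    CensorConfig,
    CensorReport,
    DDTModel,
    CheckpointParams,
    SyntheticConfig,
    censor_crowding,
    censor_death,
    censor_drug_delay,
    censor_eoe,
    censor_pipeline,
    generate_dataset,
)
from ddtcycle.censoring import IMTDataset


def rec(i, birth, division=None, death=None, end=200.0):
    return CellRecord(
        cell_id=f"c{i}", birth_time=birth, division_time=division,
        death_time=death, observed_end=end,
    )


class TestCellRecord:
    def test_divide_and_die_rejected(self):
        with pytest.raises(ValueError, match="divide and die"):
            CellRecord("x", 0.0, division_time=10.0, death_time=8.0)

    def test_division_before_birth_rejected(self):
        with pytest.raises(ValueError):
            CellRecord("x", 5.0, division_time=4.0)

    def test_fucci_outside_cycle_rejected(self):
        with pytest.raises(ValueError):
            CellRecord("x", 0.0, division_time=10.0, fucci_onset=11.0)

    def test_derived_durations(self):
        r = CellRecord("x", 2.0, division_time=14.0, fucci_onset=9.0)
        assert r.imt == pytest.approx(12.0)
        assert r.g1_duration == pytest.approx(7.0)
        assert r.sgm_duration == pytest.approx(5.0)


class TestCensorDeath:
    def test_no_deaths_is_identity(self):
        ds = IMTDataset([rec(i, i, division=i + 10) for i in range(10)])
        out, n = censor_death(ds)
        assert n == 0 and len(out) == 10

    def test_counts(self):
        recs = [rec(i, i, division=i + 10) for i in range(7)]
        recs += [rec(100 + i, float(i), death=i + 3.0) for i in range(3)]
        out, n = censor_death(IMTDataset(recs))
        assert n == 3 and len(out) == 7
        assert all(not r.died for r in out)


def brute_force_eoe_cutoff(records, frac):
    """Independent oracle: enumerate every birth-time prefix."""
    recs = sorted(records, key=lambda r: r.birth_time)
    births = sorted({r.birth_time for r in recs})
    best = None
    for b in births:
        prefix = [r for r in recs if r.birth_time <= b]
        if sum(r.divided for r in prefix) / len(prefix) > frac:
            best = b
    return best


class TestCensorEoE:
    def test_all_divide_keeps_everything(self):
        ds = IMTDataset([rec(i, float(i), division=i + 10.0) for i in range(20)])
        out, cutoff, n = censor_eoe(ds)
        assert n == 0
        assert cutoff == 19.0
        assert len(out) == 20

    def test_truncated_tail_against_brute_force(self):
        # 75 early dividers, 25 late-born cells that never divide
        recs = [rec(i, float(i) * 0.5, division=i * 0.5 + 12.0) for i in range(75)]
        recs += [rec(100 + i, 40.0 + i, division=None, end=60.0) for i in range(25)]
        ds = IMTDataset(recs)
        out, cutoff, n = censor_eoe(ds, frac=0.96)
        assert cutoff == brute_force_eoe_cutoff(recs, 0.96)
        assert all(r.divided and r.birth_time <= cutoff for r in out)
        assert n == len(recs) - len(out)

    def test_boundary_fraction_not_strictly_exceeded(self):
        # every prefix has dividing fraction exactly 1/2 <= frac
        recs = []
        for i in range(10):
            recs.append(rec(2 * i, float(i), division=float(i) + 5.0))
            recs.append(rec(2 * i + 1, float(i), division=None, end=50.0))
        with pytest.raises(ValueError, match="too short|truncated"):
            censor_eoe(IMTDataset(recs), frac=0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            censor_eoe(IMTDataset([]))


class TestCensorCrowding:
    @staticmethod
    def _null_dataset(seed, n=200):
        rng = np.random.default_rng(seed)
        births = rng.uniform(0, 24, n)
        imts = rng.gamma(20, 0.7, n)
        return IMTDataset(
            [rec(i, b, division=b + t) for i, (b, t) in enumerate(zip(births, imts))]
        )

    def test_null_rarely_removes(self):
        removals = 0
        for seed in range(20):
            _, cutoff, n = censor_crowding(self._null_dataset(seed), alpha=0.01)
            removals += int(n > 0)
        # alpha = 0.01 => expected ~0.2 spurious removals in 20 runs
        assert removals <= 2

    def test_crowding_changepoint_detected(self, cp_slow):
        config = SyntheticConfig(
            model=DDTModel([cp_slow, cp_slow]), n_cells=400, birth_window=40.0,
            frame_interval=None, eoe_time=np.inf, crowding_onset=20.0,
            crowding_slope=0.8, seed=2,
        )
        ds = generate_dataset(config)
        out, cutoff, n = censor_crowding(ds, alpha=0.01)
        assert n > 0
        assert cutoff is not None
        # the scan should land near or before the true onset (sampling noise)
        assert cutoff <= 28.0

    def test_constant_imts_noop_with_warning(self):
        ds = IMTDataset([rec(i, float(i), division=float(i) + 10.0) for i in range(50)])
        with pytest.warns(UserWarning, match="undefined|constant"):
            out, cutoff, n = censor_crowding(ds)
        assert n == 0 and cutoff is None

    def test_too_few_records_noop_with_warning(self):
        ds = IMTDataset([rec(i, float(i), division=float(i) + 10 + i) for i in range(4)])
        with pytest.warns(UserWarning, match="fewer than 5"):
            out, cutoff, n = censor_crowding(ds)
        assert n == 0

    def test_small_sample_permutation_path(self):
        rng = np.random.default_rng(0)
        births = np.linspace(0, 10, 20)
        imts = 10 + 1.5 * births + rng.normal(0, 0.5, 20)  # strong trend, n <= 30
        ds = IMTDataset(
            [rec(i, b, division=b + t) for i, (b, t) in enumerate(zip(births, imts))]
        )
        out, cutoff, n = censor_crowding(ds, alpha=0.01, seed=1)
        assert n > 0


class TestCensorDrugDelay:
    def test_strict_boundary(self):
        ds = IMTDataset([rec(0, 9.9, division=25.0), rec(1, 10.0, division=26.0)])
        out, n = censor_drug_delay(ds, t_min=10.0)
        assert n == 1
        assert out.records[0].birth_time == 10.0

    def test_zero_threshold_is_noop(self):
        ds = IMTDataset([rec(i, float(i), division=float(i) + 12) for i in range(5)])
        out, n = censor_drug_delay(ds, t_min=0.0)
        assert n == 0

    def test_all_removed_warns(self):
        ds = IMTDataset([rec(0, 1.0, division=10.0)])
        with pytest.warns(UserWarning, match="every record"):
            out, n = censor_drug_delay(ds, t_min=5.0)
        assert len(out) == 0 and n == 1


class TestPipeline:
    def test_clean_dataset_passes_through(self, ddt2_hl):
        config = SyntheticConfig(
            model=ddt2_hl, n_cells=150, birth_window=24.0, frame_interval=None,
            eoe_time=np.inf, seed=3,
        )
        ds = generate_dataset(config)
        imts, report = censor_pipeline(ds)
        assert report.n_retained == 150
        assert imts.size == 150

    def test_report_conservation(self, ddt2_hl):
        config = SyntheticConfig(
            model=ddt2_hl, n_cells=300, birth_window=30.0, frame_interval=0.25,
            death_rate=0.01, eoe_time=60.0, seed=8,
        )
        ds = generate_dataset(config)
        imts, report = censor_pipeline(ds)
        removed = (report.removed_death + report.removed_eoe
                   + report.removed_crowding + report.removed_drug_delay)
        assert report.n_input - removed == report.n_retained
        assert imts.size == report.n_retained

    def test_idempotent_on_own_output(self, ddt2_hl):
        config = SyntheticConfig(
            model=ddt2_hl, n_cells=300, birth_window=30.0, frame_interval=0.25,
            death_rate=0.01, eoe_time=60.0, seed=8,
        )
        ds = generate_dataset(config)
        ds1, _ = censor_death(ds)
        ds1, _, _ = censor_eoe(ds1)
        ds1, _, _ = censor_crowding(ds1)
        _, report2 = censor_pipeline(ds1)
        assert report2.removed_death == 0
        assert report2.removed_eoe == 0
        assert report2.removed_crowding == 0

    def test_empty_retained_raises(self):
        ds = IMTDataset([rec(0, 1.0, death=5.0), rec(1, 2.0, death=6.0),
                         rec(2, 0.5, division=12.0)])
        imts, report = censor_pipeline(ds)
        assert report.n_retained == 1

    def test_report_invariant_enforced(self):
        with pytest.raises(ValueError, match="balance"):
            CensorReport(
                n_input=10, removed_death=1, removed_eoe=1, eoe_birth_cutoff=5.0,
                removed_crowding=1, crowding_birth_cutoff=None,
                removed_drug_delay=0, n_retained=9,
            )
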