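"""Ground-truth generator: determinism, planted coupling, behavior log."""

import numpy as np
import pytest
from scipy import stats as sst

from nirsplv import (
    BehaviorEffectSpec,
    CouplingSpec,
    NoiseSpec,
    ResponseSpec,
    plv_matrix,
    simulate_behavior,
    simulate_hemodynamics,
)
from nirsplv.errors import InvalidArgumentError
from nirsplv.preprocess import preprocess

SILENT = NoiseSpec(
    cardiac_uM=0.0, respiratory_uM=0.0, mayer_uM=0.0,
    white_sd_uM=0.0, drift_slope_uM_per_s=0.0, band_sd_uM=0.0,
)


def test_all_zero_spec_gives_flat_series(schedule, layout):
    s = simulate_hemodynamics(
        schedule, layout, noise=SILENT, response=ResponseSpec(amplitude_uM=0.0), seed=0
    )
    assert np.all(s.hbo == 0.0)
    assert np.all(s.hbr == 0.0)


def test_seed_determinism(schedule, layout):
    a = simulate_hemodynamics(schedule, layout, seed=7)
    b = simulate_hemodynamics(schedule, layout, seed=7)
    c = simulate_hemodynamics(schedule, layout, seed=8)
    assert np.array_equal(a.hbo, b.hbo) and np.array_equal(a.hbr, b.hbr)
    assert not np.array_equal(a.hbo, c.hbo)


def test_full_coupling_yields_unit_plv_downstream(schedule, layout):
    """Strength-1 shared oscillator on (Ch01, Ch02), no other noise:
    the preprocessed PLV of the pair is 1 within 1e-3."""
    noise = NoiseSpec(
        cardiac_uM=0.0, respiratory_uM=0.0, mayer_uM=0.0,
        white_sd_uM=0.0, drift_slope_uM_per_s=0.0, band_sd_uM=0.1,
    )
    s = simulate_hemodynamics(
        schedule,
        layout,
        coupling=CouplingSpec(pairs=(("Ch01", "Ch02"),), frequency_hz=0.02, strength=1.0),
        noise=noise,
        response=ResponseSpec(amplitude_uM=0.0),
        seed=3,
    )
    f = preprocess(s, schedule)
    m = plv_matrix(f, schedule.condition_segment(schedule.condition_order[0]))
    assert m.loc("Ch01", "Ch02") == pytest.approx(1.0, abs=1e-3)


def test_hbr_is_scaled_inverted_companion(schedule, layout):
    s = simulate_hemodynamics(
        schedule, layout, noise=SILENT, response=ResponseSpec(amplitude_uM=0.4), seed=0
    )
    assert np.allclose(s.hbr, -s.hbo / 3.0)


def test_coupling_frequency_outside_nyquist_rejected(schedule, layout):
    bad = CouplingSpec(pairs=(("Ch01", "Ch02"),), frequency_hz=6.0, strength=0.5)
    with pytest.raises(InvalidArgumentError):
        simulate_hemodynamics(schedule, layout, coupling=bad, seed=0)


def test_planted_coupling_recovery_across_replicates(schedule, layout):
    """Strength 0.9 on 3 designated pairs, defaults elsewhere: designated
    pairs beat non-designated pairs in mean PLV in >= 95/100 replicates."""
    pairs = (("Ch01", "Ch02"), ("Ch05", "Ch09"), ("Ch10", "Ch13"))
    idx = [(0, 1), (4, 8), (9, 12)]
    wins = 0
    for r in range(100):
        s = simulate_hemodynamics(
            schedule,
            layout,
            coupling=CouplingSpec(pairs=pairs, strength=0.9),
            seed=10_000 + r,
        )
        f = preprocess(s, schedule)
        m = plv_matrix(f, schedule.condition_segment(schedule.condition_order[0]))
        designated = np.mean([m.values[i, j] for i, j in idx])
        mask = np.ones((15, 15), dtype=bool)
        np.fill_diagonal(mask, False)
        for i, j in idx:
            mask[i, j] = mask[j, i] = False
        assert designated <= 1.0
        wins += designated > m.values[mask].mean()
    assert wins >= 95


# --------------------------------------------------------------------------
# behavior


def test_behavior_log_counts_and_truncation(schedule):
    log = simulate_behavior(schedule, seed=0)
    for cond in ("OOC", "SOC"):
        assert (log["condition"] == cond).sum() == 30
    assert ((log["rt_ms"] > 0) & (log["rt_ms"] <= 8000)).all()
    again = simulate_behavior(schedule, seed=0)
    assert log.equals(again)


def test_behavior_low_price_probability_one(schedule):
    eff = BehaviorEffectSpec(low_price_prob={"OOC": 0.0, "SOC": 1.0})
    log = simulate_behavior(schedule, eff, seed=1)
    soc = log[log["condition"] == "SOC"]
    assert (soc["price_tier"] == "low").sum() == 30
    ooc = log[log["condition"] == "OOC"]
    assert (ooc["price_tier"] == "low").sum() == 0


def test_identical_rt_distributions_mostly_non_significant(schedule):
    """Null Monte-Carlo: equal RT specs in both conditions leave the
    per-subject 30-vs-30 t-test non-significant in >= 90/100 replicates."""
    eff = BehaviorEffectSpec(
        rt_mean_ms={"OOC": 3500.0, "SOC": 3500.0},
        rt_sd_ms={"OOC": 800.0, "SOC": 800.0},
    )
    non_sig = 0
    for r in range(100):
        log = simulate_behavior(schedule, eff, seed=20_000 + r)
        rts = {c: log.loc[log["condition"] == c, "rt_ms"] for c in ("OOC", "SOC")}
        _, p = sst.ttest_ind(rts["OOC"], rts["SOC"])
        non_sig += p >= 0.05
    assert non_sig >= 90
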