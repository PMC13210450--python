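"""Paired inference, BH-FDR, contrast families and power analysis."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from nirsplv import (
    bh_fdr,
    channel_activation_contrast,
    connectivity_contrast,
    paired_ttest,
    required_n_paired,
)
from nirsplv.containers import EpochSet
from nirsplv.errors import DegenerateInputError, InvalidArgumentError
from nirsplv.stats import paired_power, seed_profile_contrast


def test_paired_ttest_hand_computation():
    r = paired_ttest(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
    assert r.t == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), abs=1e-12)  # 3.464
    assert r.df == 2
    assert r.dz == pytest.approx(2.0)


def test_paired_equals_one_sample_on_differences():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=(2, 30))
    r = paired_ttest(x, y)
    t1, p1 = sst.ttest_1samp(x - y, 0.0)
    assert r.t == pytest.approx(t1, abs=1e-12)
    assert r.p_raw == pytest.approx(p1, abs=1e-12)


def test_paired_df_convention_for_44_subjects():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=(2, 44))
    assert paired_ttest(x, y).df == 43


def test_degenerate_zero_variance_convention():
    x = np.array([1.0, 2.0, 3.0])
    with pytest.warns(UserWarning, match="zero-variance"):
        r = paired_ttest(x, x)
    assert (r.t, r.p_raw, r.dz) == (0.0, 1.0, 0.0)
    with pytest.raises(DegenerateInputError):
        paired_ttest(np.array([1.0]), np.array([2.0]))


def test_bh_hand_step_up():
    p = np.array([0.005, 0.01, 0.03, 0.04])
    adj, rej = bh_fdr(p, 0.05)
    assert rej.all()  # k = 4: 0.04 <= 4*0.05/4
    assert np.allclose(adj, [0.02, 0.02, 0.04, 0.04])

    adj, rej = bh_fdr(np.array([0.04]), 0.05)
    assert adj[0] == pytest.approx(0.04) and rej[0]

    adj, rej = bh_fdr(np.ones(10), 0.05)
    assert not rej.any()

    with pytest.raises(InvalidArgumentError):
        bh_fdr(np.array([0.5, 1.2]))


def test_bh_matches_statsmodels_and_is_monotone():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(2)
    for _ in range(50):
        m = rng.integers(1, 106)
        p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
        adj, rej = bh_fdr(p, 0.05)
        rej_sm, adj_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, adj_sm, atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


def _epochs_from_subject_means(means, layout, n_trials=1):
    """EpochSet whose task-window mean per epoch equals ``means``
    (subjects x conditions x channels)."""
    S, n_cond, C = means.shape
    data, rows = [], []
    times = -1.0 + np.arange(124) / 2.0
    for s in range(S):
        for ci, cond in enumerate(("OOC", "SOC")):
            for k in range(n_trials):
                ep = np.zeros((C, 124))
                ep[:, (times >= 0) & (times <= 24)] = means[s, ci][:, None]
                data.append(ep)
                rows.append({"subject": s + 1, "condition": cond, "trial": k + 1})
    return EpochSet(
        data=np.stack(data), index=pd.DataFrame(rows), times=times,
        rate_hz=2.0, layout=layout,
    )


def test_channel_activation_contrast_detects_planted_channel(layout):
    rng = np.random.default_rng(3)
    S, C = 44, 15
    means = rng.normal(0.3, 0.08, size=(S, 2, C))
    k = layout.index("Ch06")
    means[:, 0, k] += rng.normal(0.15, 0.1, size=S)  # strong OOC-only boost
    table = channel_activation_contrast(_epochs_from_subject_means(means, layout))
    assert len(table) == 15
    assert table["Ch06"].p_adj < 0.05
    assert table["Ch06"].df == 43
    others = [r for r in table.results if r.unit != "Ch06"]
    assert sum(r.p_adj < 0.05 for r in others) <= 2


def test_channel_activation_requires_two_complete_subjects(layout):
    means = np.zeros((1, 2, 15))
    with pytest.raises(DegenerateInputError):
        channel_activation_contrast(_epochs_from_subject_means(means, layout))


def test_connectivity_contrast_family_sizes(layout, roi_map):
    rng = np.random.default_rng(4)

    def stack(n_nodes, S=10):
        v = rng.uniform(0.2, 0.8, size=(S, n_nodes, n_nodes))
        v = (v + v.transpose(0, 2, 1)) / 2
        return v

    chan = connectivity_contrast(
        stack(15), stack(15), level="channel-pair", labels=layout.channels
    )
    assert len(chan) == 105
    rois = tuple(roi_map.roi_names)
    roi = connectivity_contrast(stack(7), stack(7), level="roi-pair", labels=rois)
    assert len(roi) == 21
    seed = connectivity_contrast(stack(7), stack(7), level="seed", labels=rois)
    assert len(seed) == 6
    assert [r.unit for r in seed.results] == ["S1", "S2", "S3", "S4", "S5", "S6"]
    with pytest.raises(InvalidArgumentError):
        connectivity_contrast(stack(7), stack(6), level="roi-pair", labels=rois)


def test_identical_condition_matrices_reject_nothing(layout):
    rng = np.random.default_rng(5)
    v = rng.uniform(0.2, 0.8, size=(8, 15, 15))
    v = (v + v.transpose(0, 2, 1)) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        table = connectivity_contrast(v, v.copy(), level="channel-pair",
                                      labels=layout.channels)
    assert not table.significant.any()
    assert all(r.p_raw == 1.0 for r in table.results)


def test_seed_profile_contrast_validates_shape():
    with pytest.raises(InvalidArgumentError):
        seed_profile_contrast(np.zeros((5, 4)), np.zeros((5, 4)))


# --------------------------------------------------------------------------
# power analysis


def brute_force_required_n(dz, alpha, power, n_max=5000):
    for n in range(2, n_max):
        df = n - 1
        tcrit = sst.t.isf(alpha / 2, df)
        ncp = dz * np.sqrt(n)
        p = sst.nct.sf(tcrit, df, ncp) + sst.nct.cdf(-tcrit, df, ncp)
        if p >= power:
            return n
    raise AssertionError("not reached")


def test_a_priori_sample_size_matches_study():
    assert required_n_paired(0.5, 0.05, 0.90) == 44


def test_required_n_matches_brute_force_oracle():
    for dz, power in [(1.0, 0.90), (0.8, 0.95), (0.3, 0.80)]:
        assert required_n_paired(dz, 0.05, power) == brute_force_required_n(
            dz, 0.05, power
        )


def test_required_n_floor_and_monotonicity():
    assert required_n_paired(2.0, 0.05, 0.0001) == 2
    ns_dz = [required_n_paired(d, 0.05, 0.9) for d in (0.3, 0.5, 0.8, 1.2)]
    assert ns_dz == sorted(ns_dz, reverse=True)
    ns_power = [required_n_paired(0.5, 0.05, p) for p in (0.5, 0.8, 0.9, 0.99)]
    assert ns_power == sorted(ns_power)
    with pytest.raises(InvalidArgumentError):
        required_n_paired(0.0)
    with pytest.raises(InvalidArgumentError):
        required_n_paired(0.001, 0.05, 0.999, n_max=50)


def test_paired_power_increases_with_n():
    p = [paired_power(0.5, n) for n in (5, 10, 20, 44)]
    assert p == sorted(p)
    assert p[-1] >= 0.90
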