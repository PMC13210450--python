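"""Group-level inference: paired contrasts with FDR control.

Every contrast is a two-tailed paired t-test across subjects with the
paired effect size dz = mean(diff) / sd(diff), corrected within an
explicitly declared family by the Benjamini–Hochberg step-up procedure
at level q (adjusted p_(k) = min_{j ≥ k} m·p_(j)/j, capped at 1;
reject iff adjusted p < q). Families used by the pipeline: 15 channels
(activation), 105 channel pairs, 21 ROI pairs, 6 seed connections, and
21 nodal-metric tests.

Zero-variance differences are degenerate: they report t = 0, p = 1,
dz = 0 with a warning (deterministic and conservative) rather than
propagating NaNs.

The a-priori sample-size operation inverts the power of the
noncentral-t paired test: the smallest n whose two-tailed test at
level α reaches the requested power when the noncentrality is dz·√n
with n−1 degrees of freedom.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .connectivity import ConnectivityMatrix, seed_profile
from .containers import EpochSet
from .errors import DegenerateInputError, InvalidArgumentError
from .layout import SEED_LABELS

DEFAULT_Q = 0.05


@dataclass(frozen=True)
class StatResult:
    """Paired-test outcome for one unit of a contrast family."""

    unit: str
    t: float
    df: int
    p_raw: float
    dz: float
    mean_diff: float
    p_adj: float | None = None
    family: str | None = None
    family_size: int | None = None

    @property
    def significant(self) -> bool | None:
        return None if self.p_adj is None else bool(self.p_adj < DEFAULT_Q)


class ContrastTable:
    """Results container for one family of paired contrasts.

    Indexable by unit label; ``to_frame()`` gives the long-format
    results table and ``summary()`` a printable report.
    """

    def __init__(self, results: list[StatResult], family: str, q: float = DEFAULT_Q):
        self.family = family
        self.q = q
        self.results = results

    def __getitem__(self, unit: str) -> StatResult:
        for r in self.results:
            if r.unit == unit:
                return r
        raise KeyError(unit)

    def __len__(self) -> int:
        return len(self.results)

    @property
    def significant(self) -> pd.Series:
        return self.to_frame()["significant"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "analysis": self.family,
                "unit": [r.unit for r in self.results],
                "t": [r.t for r in self.results],
                "df": [r.df for r in self.results],
                "p_raw": [r.p_raw for r in self.results],
                "p_adj": [r.p_adj for r in self.results],
                "dz": [r.dz for r in self.results],
                "mean_diff": [r.mean_diff for r in self.results],
            }
        )
        df["significant"] = df["p_adj"] < self.q
        return df

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Paired contrasts — family '{self.family}' "
            f"(m = {len(df)}, BH-FDR q = {self.q})",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
                columns=["unit", "t", "df", "p_raw", "p_adj", "dz", "significant"],
            ),
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# primitives


def paired_ttest(x: np.ndarray, y: np.ndarray, unit: str = "") -> StatResult:
    """Two-tailed paired t-test (equivalently one-sample t on x − y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("paired samples must be 1-d arrays of equal length")
    n = len(x)
    if n < 2:
        raise DegenerateInputError("paired t-test requires at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        warnings.warn(
            f"zero-variance differences for {unit or 'contrast'}; "
            "reporting t=0, p=1 by convention",
            stacklevel=2,
        )
        return StatResult(unit=unit, t=0.0, df=df, p_raw=1.0, dz=0.0, mean_diff=float(d.mean()))
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sst.t.sf(abs(t), df)
    return StatResult(
        unit=unit,
        t=float(t),
        df=df,
        p_raw=float(p),
        dz=float(d.mean() / sd),
        mean_diff=float(d.mean()),
    )


def bh_fdr(pvals: np.ndarray, q: float = DEFAULT_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("p-values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj < q


def _family(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]], family: str, q: float
) -> ContrastTable:
    results = [paired_ttest(x, y, unit) for unit, (x, y) in pairs.items()]
    adj, _ = bh_fdr(np.array([r.p_raw for r in results]), q)
    results = [
        StatResult(
            unit=r.unit, t=r.t, df=r.df, p_raw=r.p_raw, dz=r.dz,
            mean_diff=r.mean_diff, p_adj=float(a), family=family,
            family_size=len(results),
        )
        for r, a in zip(results, adj)
    ]
    return ContrastTable(results, family, q)


# --------------------------------------------------------------------------
# pipeline-level contrasts


def channel_activation_contrast(
    epochs: EpochSet,
    summary_window_s: tuple[float, float] = (0.0, 24.0),
    conditions: tuple[str, str] = ("OOC", "SOC"),
    q: float = DEFAULT_Q,
) -> ContrastTable:
    """Channel-wise activation contrast across subjects.

    Per subject, channel and condition the statistic is the mean ΔHbO
    over the summary window (default: the 24 s task period) averaged
    across trials; channels form one BH family. Subjects missing either
    condition are excluded pairwise.
    """
    win = (epochs.times >= summary_window_s[0] - 1e-9) & (
        epochs.times <= summary_window_s[1] + 1e-9
    )
    if not win.any():
        raise InvalidArgumentError("summary window contains no samples")
    per_epoch = epochs.data[:, :, win].mean(axis=2)  # (epochs, channels)
    idx = epochs.index
    means: dict[tuple[int, str], np.ndarray] = {}
    for (subject, cond), grp in idx.groupby(["subject", "condition"], sort=True):
        means[(subject, cond)] = per_epoch[grp.index.to_numpy()].mean(axis=0)
    subjects = sorted({s for s, _ in means})
    complete = [s for s in subjects if all((s, c) in means for c in conditions)]
    if len(complete) < len(subjects):
        warnings.warn(
            f"excluding {len(subjects) - len(complete)} subject(s) missing a condition",
            stacklevel=2,
        )
    if len(complete) < 2:
        raise DegenerateInputError("need at least 2 subjects with both conditions")
    a = np.stack([means[(s, conditions[0])] for s in complete])  # (subjects, channels)
    b = np.stack([means[(s, conditions[1])] for s in complete])
    pairs = {
        ch: (a[:, k], b[:, k]) for k, ch in enumerate(epochs.layout.channels)
    }
    return _family(pairs, family="channel_activation", q=q)


def connectivity_contrast(
    matrices_a: list[ConnectivityMatrix] | np.ndarray,
    matrices_b: list[ConnectivityMatrix] | np.ndarray,
    level: str = "channel-pair",
    labels: tuple[str, ...] | None = None,
    seed: str = "ROI4",
    q: float = DEFAULT_Q,
) -> ContrastTable:
    """Edge-wise paired contrast of per-subject connectivity matrices.

    ``level`` selects the family: ``channel-pair`` (all off-diagonal
    pairs of a channel matrix, 105 for 15 channels), ``roi-pair`` (21
    for 7 ROIs) or ``seed`` (the 6 seed connections S1..S6 of an ROI
    matrix). Matrices must share node labels across subjects and
    conditions.
    """
    def unpack(ms):
        if isinstance(ms, np.ndarray):
            return ms, None
        labs = tuple(ms[0].labels)
        for m in ms:
            if tuple(m.labels) != labs:
                raise InvalidArgumentError("node labels differ across subjects")
        return np.stack([m.values for m in ms]), labs

    va, la = unpack(matrices_a)
    vb, lb = unpack(matrices_b)
    if va.shape != vb.shape:
        raise InvalidArgumentError("conditions have different numbers of subjects/nodes")
    labels = labels or la or lb
    if labels is None:
        raise InvalidArgumentError("node labels are required")
    if la and lb and la != lb:
        raise InvalidArgumentError("node labels differ between conditions")
    n_nodes = va.shape[1]
    if len(labels) != n_nodes:
        raise InvalidArgumentError("label count does not match matrix size")

    if level in ("channel-pair", "roi-pair"):
        pairs = {
            f"{labels[i]}-{labels[j]}": (va[:, i, j], vb[:, i, j])
            for i, j in itertools.combinations(range(n_nodes), 2)
        }
        family = "channel_pair_plv" if level == "channel-pair" else "roi_pair_plv"
    elif level == "seed":
        prof_a = np.stack(
            [seed_profile(ConnectivityMatrix(v, labels), seed).to_numpy() for v in va]
        )
        prof_b = np.stack(
            [seed_profile(ConnectivityMatrix(v, labels), seed).to_numpy() for v in vb]
        )
        return seed_profile_contrast(prof_a, prof_b, q)
    else:
        raise InvalidArgumentError(f"unknown level {level!r}")
    return _family(pairs, family=family, q=q)


def seed_profile_contrast(
    profiles_a: np.ndarray, profiles_b: np.ndarray, q: float = DEFAULT_Q
) -> ContrastTable:
    """Paired contrast of per-subject seed profiles (subjects × 6),
    BH-corrected within the 6 seed connections S1..S6."""
    profiles_a = np.asarray(profiles_a, dtype=float)
    profiles_b = np.asarray(profiles_b, dtype=float)
    if profiles_a.shape != profiles_b.shape or profiles_a.shape[1] != len(SEED_LABELS):
        raise InvalidArgumentError("seed profiles must be (subjects, 6) in both conditions")
    pairs = {
        lab: (profiles_a[:, k], profiles_b[:, k]) for k, lab in enumerate(SEED_LABELS)
    }
    return _family(pairs, family="seed_plv", q=q)


def metric_contrast(
    metrics_a: pd.DataFrame, metrics_b: pd.DataFrame, q: float = DEFAULT_Q
) -> tuple[StatResult, ContrastTable]:
    """Contrast network metrics between conditions.

    ``metrics_a/b`` are per-subject tables indexed by subject with a
    ``global_efficiency`` column and per-node ``strength_*``,
    ``clustering_*``, ``local_efficiency_*`` columns. Returns the
    (uncorrected, single-test) global-efficiency result and one BH
    family over all nodal-metric columns.
    """
    ge = paired_ttest(
        metrics_a["global_efficiency"].to_numpy(),
        metrics_b["global_efficiency"].to_numpy(),
        unit="global_efficiency",
    )
    nodal_cols = [c for c in metrics_a.columns if c != "global_efficiency"]
    pairs = {
        c: (metrics_a[c].to_numpy(), metrics_b[c].to_numpy()) for c in nodal_cols
    }
    return ge, _family(pairs, family="nodal_metrics", q=q)


# --------------------------------------------------------------------------
# a-priori power analysis


def paired_power(dz: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-tailed paired t-test at effect size dz."""
    df = n - 1
    ncp = dz * np.sqrt(n)
    tcrit = sst.t.isf(alpha / 2, df)
    return float(sst.nct.sf(tcrit, df, ncp) + sst.nct.cdf(-tcrit, df, ncp))


def required_n_paired(
    dz: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.90,
    n_max: int = 100_000,
) -> int:
    """Smallest n whose paired t-test attains the requested power.

    Matches the a-priori "difference between two dependent means"
    computation of standard power software (noncentral-t, two-tailed).
    """
    if dz <= 0:
        raise InvalidArgumentError("dz must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise InvalidArgumentError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if paired_power(dz, n, alpha) >= power:
            return n
    raise InvalidArgumentError(
        f"requested power {power} not reached by n = {n_max}; effect size too small"
    )
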