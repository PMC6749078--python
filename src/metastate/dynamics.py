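"""Metastate dynamics and test-retest reliability.

Dwell time is the number of windows a label sequence spends in each state
(or that count times the TR, in seconds); transition time is the count of
consecutive-window switches from one state to another. Reliability across
two sessions is the intra-class correlation coefficient

    ICC = sum_i (x1i - xbar)(x2i - xbar) / ((n - 1) * s_x^2),

where xbar and s_x are the mean and standard deviation of all 2n
observations. The pooled variance uses divisor 2(n - 1), so a perfectly
reproduced measurement yields ICC = 1 exactly. Values are reported raw
(they can be negative); the conventional cutoffs are < 0.4 poor and
> 0.75 good reliability. Bartlett (equal variances) and Kolmogorov-Smirnov
(normality of the pooled z-scores) diagnostics accompany each value.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

POOR_RELIABILITY = 0.4
GOOD_RELIABILITY = 0.75


@dataclasses.dataclass
class StateDynamics:
    """Dwell and transition features of one subject-session label sequence."""

    dwell_windows: np.ndarray  # per-state window counts
    dwell_seconds: np.ndarray
    transitions: np.ndarray  # K x K counts, zero diagonal
    n_windows: int


@dataclasses.dataclass
class IccResult:
    value: float
    n: int
    feature_id: str = ""
    bartlett_p: float = float("nan")
    ks_p: float = float("nan")


def dwell_time(labels: np.ndarray, tr_s: float, k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-state occupancy in windows and in seconds (windows x TR)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if k is None:
        k = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=k).astype(float)
    return counts, counts * tr_s


def transition_matrix(labels: np.ndarray, k: int | None = None) -> np.ndarray:
    """K x K counts of consecutive a -> b label changes; zero diagonal."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if k is None:
        k = int(labels.max()) + 1
    T = np.zeros((k, k))
    a, b = labels[:-1], labels[1:]
    moved = a != b
    np.add.at(T, (a[moved], b[moved]), 1.0)
    return T


def state_dynamics(labels: np.ndarray, tr_s: float, k: int) -> StateDynamics:
    dw, ds = dwell_time(labels, tr_s, k)
    return StateDynamics(
        dwell_windows=dw,
        dwell_seconds=ds,
        transitions=transition_matrix(labels, k),
        n_windows=int(np.asarray(labels).size),
    )


def icc(x1: np.ndarray, x2: np.ndarray, feature_id: str = "") -> IccResult:
    """Test-retest ICC of one feature measured twice on n subjects.

    Pooled mean over all 2n observations; pooled variance with divisor
    2(n - 1). Raises when the pooled variance is zero (a constant feature
    has no reliability to estimate).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be equal-length 1-D vectors")
    n = x1.size
    if n < 3:
        raise ValueError("ICC needs n >= 3 subjects")
    allx = np.concatenate([x1, x2])
    xbar = allx.mean()
    ss = ((allx - xbar) ** 2).sum()
    if ss == 0:
        raise ValueError("reliability undefined for constant feature")
    s2 = ss / (2 * (n - 1))
    value = float(((x1 - xbar) * (x2 - xbar)).sum() / ((n - 1) * s2))
    try:
        with np.errstate(divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bartlett_p = float(stats.bartlett(x1, x2).pvalue)
    except ValueError:
        bartlett_p = float("nan")
    z = (allx - xbar) / allx.std(ddof=1)
    ks_p = float(stats.kstest(z, "norm").pvalue)
    return IccResult(value=value, n=n, feature_id=feature_id,
                     bartlett_p=bartlett_p, ks_p=ks_p)


def icc_matrix(
    dynamics_a: list[StateDynamics], dynamics_b: list[StateDynamics]
) -> np.ndarray:
    """K x K reliability matrix: diagonal (s, s) = ICC of state-s dwell
    windows, off-diagonal (a, b) = ICC of the a -> b transition count.

    States must be matched across sessions beforehand. Entries whose
    feature is constant across subjects are NaN (skipped, logged).
    """
    if len(dynamics_a) != len(dynamics_b):
        raise ValueError("sessions have different subject counts")
    k = dynamics_a[0].dwell_windows.size
    dwell_a = np.stack([d.dwell_windows for d in dynamics_a])
    dwell_b = np.stack([d.dwell_windows for d in dynamics_b])
    trans_a = np.stack([d.transitions for d in dynamics_a])
    trans_b = np.stack([d.transitions for d in dynamics_b])
    out = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            if a == b:
                x1, x2 = dwell_a[:, a], dwell_b[:, a]
                name = f"dwell[{a}]"
            else:
                x1, x2 = trans_a[:, a, b], trans_b[:, a, b]
                name = f"transition[{a}->{b}]"
            try:
                out[a, b] = icc(x1, x2, feature_id=name).value
            except ValueError:
                logger.info("ICC undefined for %s (constant feature)", name)
    return out


@dataclasses.dataclass
class GroupDifferenceReport:
    paired_t_p: np.ndarray  # per-state, session A vs B
    paired_t_p_fdr: np.ndarray
    anova_p_a: float  # across states within session A
    anova_p_b: float


def group_difference_test(
    dwell_a: np.ndarray, dwell_b: np.ndarray
) -> GroupDifferenceReport:
    """Paired t-test per state between sessions and one-way ANOVA across
    states within each session, with BH-FDR over the per-state p-values.

    Identical sessions give p = 1 by convention (a zero-difference vector
    carries no evidence of a difference).
    """
    A = np.asarray(dwell_a, dtype=float)
    B = np.asarray(dwell_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("dwell tables must be equal-shape (subjects x states)")
    if A.shape[0] < 3:
        raise ValueError("group tests need >= 3 subjects")
    k = A.shape[1]
    pvals = np.empty(k)
    for s in range(k):
        diff = A[:, s] - B[:, s]
        if np.all(diff == 0):
            pvals[s] = 1.0
        else:
            pvals[s] = stats.ttest_rel(A[:, s], B[:, s]).pvalue
    _, p_fdr, _, _ = multipletests(pvals, method="fdr_bh")
    anova_a = float(stats.f_oneway(*[A[:, s] for s in range(k)]).pvalue)
    anova_b = float(stats.f_oneway(*[B[:, s] for s in range(k)]).pvalue)
    return GroupDifferenceReport(
        paired_t_p=pvals, paired_t_p_fdr=p_fdr, anova_p_a=anova_a, anova_p_b=anova_b
    )
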