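"""Functional connectivity network construction.

Static and sliding-window Pearson correlation with Fisher z-transform,
framewise-displacement volume censoring, and proportional (density)
thresholding that retains a fixed fraction of the strongest edges.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import LabeledMatrix

logger = logging.getLogger(__name__)

#: |r| is capped here before atanh so degenerate (perfectly correlated)
#: windows give large finite z-values instead of inf.
R_CLAMP = 1.0 - 1e-7


@dataclasses.dataclass
class RoiTimeSeries:
    """A time x region BOLD signal matrix with repetition time and labels."""

    signal: np.ndarray
    tr_s: float
    labels: list[str]
    censor_mask: np.ndarray | None = None  # True = volume kept

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (volumes x regions) array")
        if len(self.labels) != self.signal.shape[1]:
            raise ValueError("label count does not match region count")
        if np.isnan(self.signal).any():
            raise ValueError("signal contains NaN")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_regions(self) -> int:
        return self.signal.shape[1]


@dataclasses.dataclass
class WindowedNetworkSequence:
    """Ordered symmetric Fisher-z connectivity matrices, one per window."""

    matrices: list[np.ndarray]
    width_volumes: int
    step_volumes: int
    window_start_indices: list[int]
    labels: list[str]

    @property
    def n_windows(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)


@dataclasses.dataclass
class CensorResult:
    timeseries: RoiTimeSeries
    n_removed: int
    excluded: bool


def censor_volumes(
    ts: RoiTimeSeries,
    fd: np.ndarray,
    fd_threshold: float = 0.3,
    min_volumes: int = 200,
) -> CensorResult:
    """Drop volumes whose framewise displacement exceeds ``fd_threshold`` (mm).

    Volumes with FD strictly above the threshold are deleted (not
    interpolated); a subject left with fewer than ``min_volumes`` usable
    volumes is flagged excluded.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (ts.n_volumes,):
        raise ValueError(
            f"FD length {fd.shape[0] if fd.ndim == 1 else fd.shape} does not "
            f"match {ts.n_volumes} volumes"
        )
    keep = fd <= fd_threshold
    censored = RoiTimeSeries(
        signal=ts.signal[keep], tr_s=ts.tr_s, labels=list(ts.labels), censor_mask=keep
    )
    n_removed = int((~keep).sum())
    excluded = censored.n_volumes < min_volumes
    if excluded:
        logger.warning(
            "subject excluded: %d volumes remain after censoring (< %d)",
            censored.n_volumes,
            min_volumes,
        )
    return CensorResult(censored, n_removed, excluded)


def _fisher_z_corr(segment: np.ndarray, labels: list[str]) -> np.ndarray:
    sd = segment.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance region(s): {[labels[i] for i in zero]}"
        )
    r = np.corrcoef(segment, rowvar=False)
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0


def static_fc(ts: RoiTimeSeries) -> LabeledMatrix:
    """Fisher-z transformed Pearson FC over the full (censored) series."""
    if ts.n_volumes < 3:
        raise ValueError("static FC needs at least 3 volumes")
    return LabeledMatrix(_fisher_z_corr(ts.signal, ts.labels), list(ts.labels), list(ts.labels))


def window_count(n_volumes: int, width: int, step: int) -> int:
    return (n_volumes - width) // step + 1


def sliding_window_fc(
    ts: RoiTimeSeries, width_volumes: int, step_volumes: int = 1
) -> WindowedNetworkSequence:
    """Fisher-z FC in rectangular windows of ``width_volumes``, stepped by
    ``step_volumes``. Window w covers volumes [start, start + width)."""
    T = ts.n_volumes
    if width_volumes < 2:
        raise ValueError("window width must be >= 2 volumes")
    if width_volumes > T:
        raise ValueError(f"window width {width_volumes} exceeds {T} usable volumes")
    if step_volumes < 1:
        raise ValueError("step must be >= 1")
    starts = [w * step_volumes for w in range(window_count(T, width_volumes, step_volumes))]
    matrices = [
        _fisher_z_corr(ts.signal[s : s + width_volumes], ts.labels) for s in starts
    ]
    return WindowedNetworkSequence(
        matrices=matrices,
        width_volumes=width_volumes,
        step_volumes=step_volumes,
        window_start_indices=starts,
        labels=list(ts.labels),
    )


def _threshold_values(values: np.ndarray, density: float) -> np.ndarray:
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    m = w.size
    # round half away from zero; 0.40 * 4005 = 1602 is exact
    n_keep = int(np.floor(density * m + 0.5))
    if n_keep >= m:
        return values.copy()
    # signed weight descending, ties by (row, col) lexicographic order
    order = np.lexsort((ju, iu, -w))
    if n_keep > 0 and w[order[n_keep - 1]] == w[order[n_keep]]:
        warnings.warn(
            "tied edge weights cross the density cut; retained set broken "
            "by (row, col) order",
            RuntimeWarning,
            stacklevel=3,
        )
    out = np.zeros_like(values)
    kept = order[:n_keep]
    out[iu[kept], ju[kept]] = w[kept]
    return out + out.T


def proportional_threshold(fc: LabeledMatrix, density: float) -> LabeledMatrix:
    """Retain exactly round(density * N(N-1)/2) strongest edges by signed
    weight; all other off-diagonal entries are zeroed, weights are kept."""
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    fc.require_square_symmetric(atol=1e-9)
    return LabeledMatrix(
        _threshold_values(fc.values, density), list(fc.row_labels), list(fc.col_labels)
    )


def group_positive_mask(
    static_fcs: list[LabeledMatrix], q: float = 0.05
) -> tuple[LabeledMatrix, float]:
    """Edges whose Fisher-z values are significantly > 0 across subjects.

    One-sided one-sample t-test per edge, Benjamini-Hochberg over all
    N(N-1)/2 edges at level ``q``. Returns the binary mask and its edge
    density — guidance for choosing the proportional threshold.
    """
    if len(static_fcs) < 3:
        raise ValueError("group mask needs >= 3 subjects")
    labels = static_fcs[0].row_labels
    n = len(labels)
    for m in static_fcs:
        if m.row_labels != labels:
            raise ValueError("mismatched region labels across subjects")
    iu, ju = np.triu_indices(n, k=1)
    stack = np.stack([m.values[iu, ju] for m in static_fcs])  # subjects x edges
    res = stats.ttest_1samp(stack, 0.0, axis=0, alternative="greater")
    reject, _, _, _ = multipletests(res.pvalue, alpha=q, method="fdr_bh")
    mask = np.zeros((n, n))
    mask[iu[reject], ju[reject]] = 1.0
    mask = mask + mask.T
    density = reject.mean()
    return LabeledMatrix(mask, list(labels), list(labels)), float(density)


class SlidingWindowConnectivity(BaseEstimator, TransformerMixin):
    """Transformer from an ROI time series to windowed, thresholded FC.

    Parameters
    ----------
    width_volumes : window width in volumes (24 at the 60 s / 2.5 s default).
    step_volumes : window step in volumes.
    density : fraction of strongest edges retained per window; 1.0 disables
        thresholding.
    """

    def __init__(self, width_volumes: int = 24, step_volumes: int = 1, density: float = 0.40):
        self.width_volumes = width_volumes
        self.step_volumes = step_volumes
        self.density = density

    def fit(self, X, y=None):
        return self

    def transform(self, X: RoiTimeSeries) -> WindowedNetworkSequence:
        seq = sliding_window_fc(X, self.width_volumes, self.step_volumes)
        if self.density < 1.0:
            seq = WindowedNetworkSequence(
                matrices=[_threshold_values(m, self.density) for m in seq.matrices],
                width_volumes=seq.width_volumes,
                step_volumes=seq.step_volumes,
                window_start_indices=seq.window_start_indices,
                labels=seq.labels,
            )
        return seq
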