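"""Synthetic multi-subject, two-session datasets with planted ground truth.

Every pipeline stage has a generator here that plants a recoverable truth:

* ``generate_state_sequence`` — per-subject-session metastate label
  sequences from a Markov chain with geometric dwell times; a per-subject
  Gaussian latent shared between sessions at correlation ``retest_rho``
  modulates state propensities, giving controllable test-retest
  reliability of dwell/transition features.
* ``generate_centrality_series`` — windowed z-normalized centrality
  vectors: a zero-mean, unit-SD state template (hub regions high,
  non-hubs uniformly low) plus Gaussian noise of SD 1/snr.
* ``generate_roi_timeseries`` — BOLD-like region time series built from
  per-window latent-factor draws in which the active state's hub regions
  carry elevated shared-factor loadings, so windowed correlation networks
  re-expose the planted states.
* ``generate_core_periphery_network`` — a weighted structural network
  with a dense high-weight core, for exercising rich-club analysis.

All generators are pure functions of (spec, seed); the single seed is
expanded into independent substreams per subject/session/component.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import LabeledMatrix
from .netbuild import RoiTimeSeries

#: strength of the entry-propensity modulation that carries test-retest identity
PROPENSITY_SCALE = 0.6
#: lognormal scale of the per-subject-state dwell modulation (mean-calibrated)
DWELL_SCALE = 0.5


def default_hub_sets(n_states: int, n_regions: int, hubs_per_state: int | None = None) -> list[list[int]]:
    """Disjoint, contiguous hub index sets, one per state."""
    if hubs_per_state is None:
        hubs_per_state = max(2, n_regions // (n_states + 1))
    if hubs_per_state * n_states > n_regions:
        raise ValueError("hub sets cannot be disjoint with these sizes")
    return [
        list(range(s * hubs_per_state, (s + 1) * hubs_per_state))
        for s in range(n_states)
    ]


@dataclasses.dataclass
class SyntheticSpec:
    """Study-scale defaults: 23 subjects scanned twice, 5 metastates over
    90 regions, 227 windows per session at TR 2.5 s."""

    n_subjects: int = 23
    n_states: int = 5
    n_regions: int = 90
    hub_sets: list[list[int]] | None = None
    windows_per_session: int = 227
    mean_dwell: float = 10.0  # windows
    snr: float = 5.0
    retest_rho: float = 0.8
    tr_s: float = 2.5
    window_width_volumes: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hub_sets is None:
            self.hub_sets = default_hub_sets(self.n_states, self.n_regions)
        if len(self.hub_sets) != self.n_states:
            raise ValueError("one hub set per state required")
        seen: set[frozenset] = set()
        for h in self.hub_sets:
            fs = frozenset(h)
            if not fs or fs in seen:
                raise ValueError("hub sets must be nonempty and pairwise distinct")
            seen.add(fs)
        if self.mean_dwell < 1:
            raise ValueError("mean_dwell must be >= 1 window")
        if not (0.0 <= self.retest_rho <= 1.0):
            raise ValueError("retest_rho must lie in [0, 1]")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")

    @property
    def region_labels(self) -> list[str]:
        return [f"R{i + 1:03d}" for i in range(self.n_regions)]


import zlib


def _session_streams(spec: SyntheticSpec, component: str) -> np.random.SeedSequence:
    # one deterministic substream root per generator component
    # (crc32 is stable across processes, unlike hash())
    return np.random.SeedSequence(spec.seed, spawn_key=(zlib.crc32(component.encode()),))


def state_templates(spec: SyntheticSpec) -> np.ndarray:
    """K x N zero-mean, unit-sample-SD centrality templates: hub regions at
    a common positive value, all others at a common negative value."""
    K, N = spec.n_states, spec.n_regions
    out = np.empty((K, N))
    for s, hubs in enumerate(spec.hub_sets):
        m = len(hubs)
        hi = np.sqrt((N - m) * (N - 1) / (m * N))
        lo = -hi * m / (N - m)
        row = np.full(N, lo)
        row[list(hubs)] = hi
        out[s] = row
    return out


def subject_propensity_latents(spec: SyntheticSpec) -> np.ndarray:
    """Per-subject-state Gaussian latents, shape (subjects, 2 sessions, K).

    Session II's latent is rho * (session I) + sqrt(1 - rho^2) * fresh noise,
    so at retest_rho = 1 the two sessions share identical state propensities.
    """
    rng = np.random.default_rng(_session_streams(spec, "latents"))
    K = spec.n_states
    rho = spec.retest_rho
    out = np.empty((spec.n_subjects, 2, K))
    for s in range(spec.n_subjects):
        g1 = rng.standard_normal(K)
        fresh = rng.standard_normal(K)
        out[s, 0] = g1
        out[s, 1] = rho * g1 + np.sqrt(1.0 - rho**2) * fresh
    return out


def generate_state_sequence(spec: SyntheticSpec) -> list[list[np.ndarray]]:
    """Label sequences, indexed [subject][session] (two sessions).

    A Markov chain dwells geometrically in each state; a per-subject-state
    Gaussian latent g modulates both the state's entry propensity
    (proportional to exp(PROPENSITY_SCALE * g)) and its mean dwell
    (mean_dwell * exp(DWELL_SCALE * g - DWELL_SCALE^2 / 2), the lognormal
    correction keeping the expected dwell at mean_dwell). Session II reuses
    session I's latent at weight rho, mixed with fresh noise at weight
    sqrt(1 - rho^2), so dwell/occupancy propensities correlate at
    retest_rho across sessions.
    """
    ss = _session_streams(spec, "labels")
    rng = np.random.default_rng(ss)
    K = spec.n_states
    out: list[list[np.ndarray]] = []
    all_latents = subject_propensity_latents(spec)
    for latents in all_latents:
        sessions = []
        for g in latents:
            prop = np.exp(PROPENSITY_SCALE * g)
            dwell = np.maximum(
                spec.mean_dwell * np.exp(DWELL_SCALE * g - DWELL_SCALE**2 / 2.0),
                1.0,
            )
            stay = 1.0 - 1.0 / dwell
            labels = np.empty(spec.windows_per_session, dtype=int)
            labels[0] = rng.choice(K, p=prop / prop.sum())
            for t in range(1, spec.windows_per_session):
                cur = labels[t - 1]
                if rng.random() < stay[cur]:
                    labels[t] = cur
                else:
                    p = prop.copy()
                    p[cur] = 0.0
                    labels[t] = rng.choice(K, p=p / p.sum())
            sessions.append(labels)
        out.append(sessions)
    return out


def generate_centrality_series(
    spec: SyntheticSpec, labels: np.ndarray, stream: np.random.Generator | None = None
) -> np.ndarray:
    """Windows x regions matrix: state template + N(0, 1/snr) noise per
    entry, then row z-normalized. ``snr = 0`` yields pure (unrecoverable)
    noise."""
    if stream is None:
        stream = np.random.default_rng(_session_streams(spec, "centrality"))
    labels = np.asarray(labels, dtype=int)
    templates = state_templates(spec)
    base = templates[labels]
    noise = stream.standard_normal(base.shape)
    if spec.snr == 0:
        raw = noise
    else:
        raw = base + noise / spec.snr
    from .centrality import z_normalize_rows

    scores, _ = z_normalize_rows(raw)
    return scores


def generate_centrality_dataset(spec: SyntheticSpec) -> tuple[list[list[np.ndarray]], list[list[np.ndarray]]]:
    """Convenience: (label sequences, matching centrality series), both
    indexed [subject][session]."""
    labels = generate_state_sequence(spec)
    stream = np.random.default_rng(_session_streams(spec, "centrality"))
    series = [
        [generate_centrality_series(spec, sess, stream) for sess in subj]
        for subj in labels
    ]
    return labels, series


#: factor loadings for the BOLD-like forward model
HUB_LOADING = 0.9
BG_LOADING = 0.25
NOISE_SD = 0.6


def generate_roi_timeseries(
    spec: SyntheticSpec, labels: np.ndarray, stream: np.random.Generator | None = None
) -> RoiTimeSeries:
    """Concatenated per-window blocks of ``window_width_volumes`` volumes.

    Within a window in state s, every region loads on a shared latent
    factor — hub regions of s at HUB_LOADING, the rest at BG_LOADING — plus
    independent Gaussian noise, so the window's correlation matrix has a
    high-strength block on the planted hubs. Windowing the result at the
    generator's width with step = width re-exposes the planted labels.
    """
    if stream is None:
        stream = np.random.default_rng(_session_streams(spec, "timeseries"))
    labels = np.asarray(labels, dtype=int)
    width = spec.window_width_volumes
    N = spec.n_regions
    blocks = []
    for s in labels:
        loadings = np.full(N, BG_LOADING)
        loadings[list(spec.hub_sets[s])] = HUB_LOADING
        factor = stream.standard_normal(width)
        noise = stream.standard_normal((width, N)) * NOISE_SD
        blocks.append(factor[:, None] * loadings[None, :] + noise)
    return RoiTimeSeries(
        signal=np.vstack(blocks), tr_s=spec.tr_s, labels=spec.region_labels
    )


def generate_core_periphery_network(
    n: int = 30, core_size: int = 6, seed: int | None = None
) -> LabeledMatrix:
    """Weighted network with a complete high-weight core (U(0.8, 1.0)) and
    a sparse low-weight periphery (density 0.15, U(0.05, 0.2)); every
    peripheral node attaches to at least one core node."""
    if core_size >= n:
        raise ValueError("core_size must be < n")
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n))
    core = range(core_size)
    for i in core:
        for j in range(i + 1, core_size):
            A[i, j] = rng.uniform(0.8, 1.0)
    for i in range(core_size, n):
        # guaranteed feeder edge into the core
        j = int(rng.integers(core_size))
        A[j, i] = rng.uniform(0.05, 0.2)
        for j2 in range(i + 1, n):
            if rng.random() < 0.15:
                A[i, j2] = rng.uniform(0.05, 0.2)
    A = A + A.T
    labels = [f"N{i + 1:02d}" for i in range(n)]
    return LabeledMatrix(A, labels, labels)
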