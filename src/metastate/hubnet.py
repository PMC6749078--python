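"""Hub detection and weighted rich-club analysis.

A hub is a region whose centrality exceeds the pattern mean by a multiple
(default one) of the sample standard deviation. The weighted rich-club
coefficient at rank r,

    phi_w(r) = W_{>r} / sum_{l=1}^{E_{>r}} w_l^rank,

is the total edge weight among the top-r strength-ranked nodes divided by
the sum of the E_{>r} globally strongest edge weights; it is normalized by
its mean over degree-preserving randomized networks (Maslov-Sneppen double
edge swaps with the original weight multiset reassigned at random), and
phi_norm(r) > 1 signals a rich-club effect.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from importlib import resources

import numpy as np

from .io import LabeledMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class HubSet:
    members: list[str]
    threshold_value: float
    source: str = ""

    def __len__(self) -> int:
        return len(self.members)


def detect_hubs(
    pattern: np.ndarray,
    labels: list[str] | None = None,
    multiplier: float = 1.0,
    source: str = "",
) -> HubSet:
    """Regions whose score exceeds mean + multiplier x sample SD."""
    x = np.asarray(pattern, dtype=float)
    if x.size < 2:
        raise ValueError("hub detection needs >= 2 regions")
    if labels is None:
        labels = [str(i) for i in range(x.size)]
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant pattern: no hubs", RuntimeWarning, stacklevel=2)
        return HubSet(members=[], threshold_value=float(x.mean()), source=source)
    thr = float(x.mean() + multiplier * sd)
    members = [labels[i] for i in np.flatnonzero(x > thr)]
    return HubSet(members=members, threshold_value=thr, source=source)


def overlap_rate(hubs: HubSet, region_set: set[str] | list[str]) -> tuple[float, str]:
    """|hubs ∩ region_set| / |hubs|, with the raw counts as "x/y"."""
    if len(hubs) == 0:
        raise ValueError("overlap undefined for an empty hub set")
    region_set = set(region_set)
    x = sum(1 for m in hubs.members if m in region_set)
    y = len(hubs)
    return x / y, f"{x}/{y}"


def load_reference_hub_lists() -> dict[str, list[str]]:
    """The packaged reference hub lists: AAL-90 region names per metastate
    (keys "state1".."state5") plus the structural-network hub list."""
    path = resources.files("metastate").joinpath("data/reference_hubs.json")
    with path.open() as f:
        return json.load(f)


# -- rich club -------------------------------------------------------------


def _strength_ranking(W: np.ndarray, labels: list[str]) -> np.ndarray:
    """Node indices ordered by weighted degree (strength), descending;
    ties broken by label order."""
    strength = W.sum(axis=1)
    order = sorted(range(W.shape[0]), key=lambda i: (-strength[i], labels[i]))
    return np.asarray(order, dtype=int)


def _as_weighted(W) -> tuple[np.ndarray, list[str]]:
    if isinstance(W, LabeledMatrix):
        W.require_square_symmetric(atol=1e-9)
        return W.values.copy(), list(W.row_labels)
    A = np.asarray(W, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("weighted network must be square")
    if not np.allclose(A, A.T, atol=1e-9):
        raise ValueError("weighted network must be symmetric")
    return A.copy(), [str(i) for i in range(A.shape[0])]


def rich_club_coefficient(W, r: int) -> float:
    """phi_w(r) for the subgraph of the top-r strength-ranked nodes.

    Returns NaN when that subgraph has no edges.
    """
    A, labels = _as_weighted(W)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    if not (1 <= r <= n):
        raise ValueError(f"rank r={r} outside 1..{n}")
    top = _strength_ranking(A, labels)[:r]
    sub = A[np.ix_(top, top)]
    iu = np.triu_indices(r, k=1)
    sub_w = sub[iu]
    edges = sub_w[sub_w != 0]
    e_gt = edges.size
    if e_gt == 0:
        return float("nan")
    w_gt = float(edges.sum())
    all_w = A[np.triu_indices(n, k=1)]
    all_w = all_w[all_w != 0]
    denom = float(np.sort(all_w)[::-1][:e_gt].sum())
    return w_gt / denom


@dataclasses.dataclass
class RichClubCurve:
    r_grid: np.ndarray
    phi: np.ndarray
    phi_rand_mean: np.ndarray
    phi_norm: np.ndarray
    n_null: int
    seed: int | None


def degree_preserving_null(W, seed=None) -> LabeledMatrix | np.ndarray:
    """Maslov-Sneppen randomization: 10 x edge-count attempted double-edge
    swaps on the topology, exactly preserving every node's degree, then the
    original weight multiset reassigned to the surviving edges uniformly at
    random. A graph admitting no valid swap is returned unchanged (warned).
    """
    A, labels = _as_weighted(W)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    present = A[iu, ju] != 0
    edges = list(zip(iu[present].tolist(), ju[present].tolist()))
    weights = A[iu, ju][present]
    m = len(edges)
    if m < 2:
        raise ValueError("null model needs >= 2 edges")
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    n_success = 0
    for _ in range(10 * m):
        e1, e2 = rng.integers(m), rng.integers(m)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.integers(2):
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1], edges[e2] = new1, new2
        n_success += 1
    if n_success == 0:
        warnings.warn(
            "no valid degree-preserving swap found; topology unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.zeros_like(A)
    perm = rng.permutation(m)
    for (i, j), w in zip(edges, weights[perm]):
        out[i, j] = out[j, i] = w
    result = LabeledMatrix(out, labels, labels)
    return result


def normalized_rich_club(
    W, n_null: int = 1000, seed=None, r_grid: np.ndarray | None = None
) -> RichClubCurve:
    """phi_norm(r) = phi(r) / mean over ``n_null`` degree-preserving nulls.

    The grid defaults to ranks 1..N-2. Where phi is undefined for more than
    half the nulls, phi_norm is NaN.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    A, labels = _as_weighted(W)
    n = A.shape[0]
    if r_grid is None:
        r_grid = np.arange(1, n - 1)
    r_grid = np.asarray(r_grid, dtype=int)
    phi = np.array([rich_club_coefficient(LabeledMatrix(A, labels, labels), r) for r in r_grid])
    ss = np.random.SeedSequence(seed)
    null_phi = np.empty((n_null, r_grid.size))
    for i, child in enumerate(ss.spawn(n_null)):
        null = degree_preserving_null(LabeledMatrix(A, labels, labels), seed=child)
        null_phi[i] = [rich_club_coefficient(null, r) for r in r_grid]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rand_mean = np.nanmean(null_phi, axis=0)
    frac_defined = np.isfinite(null_phi).mean(axis=0)
    rand_mean[frac_defined <= 0.5] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = np.where(rand_mean > 0, phi / rand_mean, np.nan)
    return RichClubCurve(
        r_grid=r_grid,
        phi=phi,
        phi_rand_mean=rand_mean,
        phi_norm=phi_norm,
        n_null=n_null,
        seed=seed if isinstance(seed, (int, type(None))) else None,
    )
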