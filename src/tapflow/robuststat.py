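"""Robust mass-univariate statistics with cluster correction.

Cell-wise inference over channel x time (x frequency) grids uses 20%
trimmed means and the Tukey-McLaughlin one-sample statistic (winsorized
variance, df = h - 1 with h the number of retained observations); paired
designs test the trimmed mean of the differences.  Multiple comparisons
are controlled by spatiotemporal clustering: cells with p below the
cluster-forming threshold are grouped by temporal/spectral adjacency
within a channel and by montage adjacency across channels (positive and
negative statistics separately), each cluster is scored by the sum of
|t| (its mass), and observed masses are compared with the bootstrap null
distribution of the maximum cluster mass obtained by resampling units
of mean-centered data with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


# ---------------------------------------------------------------------------
# trimmed-mean statistics


def trimmed_mean(x, trim: float = 0.2, axis: int = 0):
    """Mean after dropping ``g = floor(trim * n)`` values at each tail."""
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    g = int(np.floor(trim * n))
    if n - 2 * g < 3:
        raise ValueError(f"only {n - 2 * g} values left after trimming {n}")
    xs = np.sort(x, axis=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(g, n - g)
    return xs[tuple(sl)].mean(axis=axis)


def _winsorized_var(x, g, axis=0):
    xs = np.sort(x, axis=axis)
    lo = np.take(xs, g, axis=axis)
    hi = np.take(xs, x.shape[axis] - g - 1, axis=axis)
    w = np.clip(x, np.expand_dims(lo, axis), np.expand_dims(hi, axis))
    return w.var(axis=axis, ddof=1)


def yuen_one_sample(x, trim: float = 0.2, mu0: float = 0.0, axis: int = 0,
                    errors: str = "raise"):
    """Tukey-McLaughlin trimmed-mean one-sample test.

    ``T = (trimmed mean - mu0) / SE`` with ``SE = s_w / ((1 - 2g/n) sqrt(n))``
    from the winsorized variance ``s_w^2``; two-sided p from Student's t
    with ``df = h - 1``, ``h = n - 2g``.  With ``errors="mask"`` (used on
    dense maps) degenerate zero-variance cells do not raise: a cell whose
    values are all equal to ``mu0`` gets T = 0, p = 1, while a constant
    cell away from ``mu0`` gets a capped extreme statistic and p = 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 5:
        raise ValueError("need at least 5 observations")
    g = int(np.floor(trim * n))
    h = n - 2 * g
    tm = trimmed_mean(x, trim, axis)
    sw2 = _winsorized_var(x, g, axis)
    bad = sw2 <= 0
    if np.any(bad):
        if errors == "raise":
            raise ValueError("zero winsorized variance; statistic undefined")
        sw2 = np.where(bad, 1.0, sw2)
    se = np.sqrt(sw2) / ((1.0 - 2.0 * g / n) * np.sqrt(n))
    T = (tm - mu0) / se
    df = h - 1
    p = 2.0 * _st.t.sf(np.abs(T), df)
    if np.any(bad):
        shifted = bad & (np.abs(tm - mu0) > 0)
        T = np.where(bad, np.where(shifted, np.sign(tm - mu0) * 1e6, 0.0), T)
        p = np.where(bad, np.where(shifted, 0.0, 1.0), p)
    return T, df, p


def yuen_paired(a, b, trim: float = 0.2, axis: int = 0, errors: str = "raise"):
    """Paired trimmed-mean test: one-sample Yuen on the differences."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal shapes")
    return yuen_one_sample(a - b, trim=trim, axis=axis, errors=errors)


# ---------------------------------------------------------------------------
# adjacency and clustering


@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive channel neighbor relation."""

    names: list[str]
    matrix: np.ndarray  # (n, n) bool
    radius: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=bool)
        if not np.array_equal(m, m.T) or m.diagonal().any():
            raise ValueError("adjacency must be symmetric and irreflexive")
        self.matrix = m

    @property
    def isolated(self) -> list[str]:
        return [n for n, row in zip(self.names, self.matrix) if not row.any()]

    def pairs(self) -> np.ndarray:
        i, j = np.nonzero(np.triu(self.matrix, 1))
        return np.column_stack([i, j])


def build_adjacency(positions: np.ndarray, radius: float | None = None,
                    names: list[str] | None = None,
                    radius_factor: float = 1.3) -> AdjacencyGraph:
    """Neighbors = channels within ``radius`` (default 1.3 x median
    nearest-neighbor distance)."""
    pos = np.asarray(positions, dtype=float)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if radius is None:
        radius = radius_factor * float(np.median(d.min(axis=1)))
    if radius <= 0:
        raise ValueError("radius must be positive")
    if names is None:
        names = [f"ch{i + 1:02d}" for i in range(len(pos))]
    return AdjacencyGraph(list(names), d <= radius, float(radius))


@dataclass
class Cluster:
    sign: int
    cells: tuple  # arrays of indices per map axis
    mass: float
    p_value: float = np.nan


def find_clusters(stat_map: np.ndarray, p_map: np.ndarray, alpha: float,
                  adjacency: AdjacencyGraph):
    """Group supra-threshold cells into signed spatiotemporal clusters.

    Maps are (channels, times) or (channels, freqs, times).  Cells are
    connected when adjacent along time (or frequency) within a channel,
    or at the same grid point on neighboring channels.  Positive and
    negative statistics never join.  Returns ``(clusters, labels)`` with
    ``labels`` an integer map (0 = background, cluster ids from 1).
    """
    stat = np.asarray(stat_map, dtype=float)
    p = np.asarray(p_map, dtype=float)
    if stat.shape != p.shape:
        raise ValueError("stat and p maps must share a shape")
    if stat.shape[0] != len(adjacency.names):
        raise ValueError("first map axis must be channels")
    labels = np.zeros(stat.shape, dtype=int)
    clusters: list[Cluster] = []
    next_id = 1
    for sign in (1, -1):
        active = (p < alpha) & (np.sign(stat) == sign)
        if not active.any():
            continue
        comp_labels = _connected_components(active, adjacency)
        for cid in range(comp_labels.max() + 1):
            cells = np.nonzero(comp_labels == cid)
            if len(cells[0]) == 0:
                continue
            mass = float(np.abs(stat[cells]).sum())
            labels[cells] = next_id
            clusters.append(Cluster(sign, cells, mass))
            next_id += 1
    return clusters, labels


def _connected_components(active: np.ndarray, adjacency: AdjacencyGraph
                          ) -> np.ndarray:
    """Label map of connected components over active cells (-1 = inactive)."""
    idx_map = np.full(active.shape, -1, dtype=int)
    coords = np.nonzero(active)
    n_active = len(coords[0])
    idx_map[coords] = np.arange(n_active)
    rows, cols = [], []

    def link(mask_a, mask_b, shift_axis=None):
        a = idx_map[mask_a]
        b = idx_map[mask_b]
        ok = (a >= 0) & (b >= 0)
        rows.append(a[ok])
        cols.append(b[ok])

    # adjacency along each grid axis (time, and frequency if present)
    for ax in range(1, active.ndim):
        sl_a = [slice(None)] * active.ndim
        sl_b = [slice(None)] * active.ndim
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        link(tuple(sl_a), tuple(sl_b))
    # channel adjacency at identical grid points
    for i, j in adjacency.pairs():
        a, b = idx_map[i].ravel(), idx_map[j].ravel()
        ok = (a >= 0) & (b >= 0)
        rows.append(a[ok])
        cols.append(b[ok])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=int)
    graph = coo_matrix((np.ones(len(r)), (r, c)), shape=(n_active, n_active))
    _, comp = connected_components(graph, directed=False)
    out = np.full(active.shape, -1, dtype=int)
    out[coords] = comp
    return out


# ---------------------------------------------------------------------------
# cluster-corrected inference


@dataclass
class StatResult:
    stat_map: np.ndarray
    df: int
    p_map: np.ndarray
    cluster_labels: np.ndarray
    clusters: list[Cluster] = field(default_factory=list)
    mask: np.ndarray | None = None
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    boot_max_mass: np.ndarray | None = None

    @property
    def cluster_masses(self) -> np.ndarray:
        return np.asarray([c.mass for c in self.clusters])

    @property
    def cluster_pvalues(self) -> np.ndarray:
        return np.asarray([c.p_value for c in self.clusters])


def cluster_correct(data, adjacency: AdjacencyGraph, design: str = "one_sample",
                    alpha: float = 0.05, n_boot: int = 1000, seed: int = 0,
                    trim: float = 0.2, mu0: float = 0.0) -> StatResult:
    """Trimmed-mean mass-univariate test with bootstrap cluster correction.

    ``data`` is (units, channels, ...grid) for ``design="one_sample"`` or
    a pair of such tensors for ``design="paired"``.  The null reference
    is built by resampling units with replacement from data centered to
    satisfy H0 (the per-cell trimmed mean subtracted; differences for
    paired designs), recording the maximum cluster mass of each of the
    ``n_boot`` resamples.  A cluster is significant when the fraction of
    bootstrap maxima at or above its mass falls below ``alpha``.
    """
    if design == "paired":
        a, b = data
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    elif design == "one_sample":
        d = np.asarray(data, dtype=float) - mu0
    else:
        raise ValueError(f"unknown design {design!r}")
    n = d.shape[0]
    if n < 10:
        raise ValueError("need at least 10 units on the first axis")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse null distribution")

    T, df, p = yuen_one_sample(d, trim=trim, axis=0, errors="mask")
    clusters, labels = find_clusters(T, p, alpha, adjacency)

    centered = d - trimmed_mean(d, trim, axis=0)
    rng = np.random.default_rng(seed)
    boot_max = np.empty(n_boot)
    for bi in range(n_boot):
        idx = rng.integers(0, n, n)
        Tb, _, pb = yuen_one_sample(centered[idx], trim=trim, axis=0,
                                    errors="mask")
        bc, _ = find_clusters(Tb, pb, alpha, adjacency)
        boot_max[bi] = max((c.mass for c in bc), default=0.0)

    mask = np.zeros(T.shape, dtype=bool)
    for c in clusters:
        c.p_value = float((1 + np.sum(boot_max >= c.mass)) / (n_boot + 1))
        if c.p_value < alpha:
            mask[c.cells] = True
    return StatResult(T, df, p, labels, clusters, mask, alpha, n_boot, seed,
                      boot_max)


# ---------------------------------------------------------------------------
# hierarchical (per-subject covariate) modeling


def first_level_covariate(epochs: np.ndarray, condition: np.ndarray,
                          covariate: np.ndarray) -> dict[str, np.ndarray]:
    """Per-cell OLS with a condition indicator and a trial covariate.

    ``epochs`` is (trials, channels, ...grid); returns coefficient maps
    for the intercept, the condition contrast, and the covariate slope.
    """
    y = np.asarray(epochs, dtype=float)
    cond = np.asarray(condition, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    X = np.column_stack([np.ones(len(cond)), cond, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient "
                         "(covariate confounded with condition?)")
    beta = np.linalg.pinv(X) @ y.reshape(len(cond), -1)
    shape = y.shape[1:]
    return {
        "intercept": beta[0].reshape(shape),
        "condition": beta[1].reshape(shape),
        "covariate": beta[2].reshape(shape),
    }


def second_level(coefficient_maps: np.ndarray, adjacency: AdjacencyGraph,
                 alpha: float = 0.05, n_boot: int = 1000, seed: int = 0,
                 trim: float = 0.2) -> StatResult:
    """Population-level one-sample test on per-subject coefficient maps."""
    maps = np.asarray(coefficient_maps, dtype=float)
    if maps.shape[0] < 10:
        raise ValueError("need at least 10 subjects")
    return cluster_correct(maps, adjacency, design="one_sample", alpha=alpha,
                           n_boot=n_boot, seed=seed, trim=trim)
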