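"""Cellular-resolution ensemble analysis.

From per-neuron dF/F traces this module derives: a nonnegative deconvolved
activity matrix (ddF/F) by inverting the indicator's AR(1) decay kernel; per
neuron event metrics using a noise floor estimated from the bottom 20th
percentile of the deconvolved values; a weighted, undirected functional
network from pairwise Pearson correlations; potentially overlapping coactive
clusters of at least three neurons found by greedy cohesiveness optimization;
and the Onnela-style weighted clustering coefficient of each neuron.  A
two-stage seeded subsampling utility assembles equal-weighted comparison
groups across recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import defaults

__all__ = [
    "CorrelationGraph",
    "ClusterSet",
    "deconvolve",
    "deconvolve_matrix",
    "extract_neuron_events",
    "neuron_metrics_table",
    "correlation_graph",
    "cohesiveness",
    "detect_clusters",
    "clustering_coefficient",
    "assemble_groups",
]


# --------------------------------------------------------------------------
# deconvolution
# --------------------------------------------------------------------------

def deconvolve(dff: np.ndarray, gamma: float, noise_sd: float = 0.0,
               penalty: float | None = None) -> np.ndarray:
    """Nonnegative AR(1) deconvolution of a single dF/F trace (OASIS-style).

    Solves ``min 1/2 ||c - y||^2 + penalty * sum(s)`` subject to
    ``s_t = c_t - gamma * c_{t-1} >= 0`` with an online pool-adjacent-
    violators pass.  ``penalty`` defaults to ``noise_sd`` (an L1 pressure on
    the order of one noise SD); with ``noise_sd = 0`` the inversion is exact
    and recovers the spike support of a noiseless trace.

    Returns the nonnegative activity ``s`` (same length as the input).
    """
    y = np.asarray(dff, dtype=float)
    if y.ndim != 1:
        raise ValueError("trace must be 1-D")
    if not np.all(np.isfinite(y)):
        raise ValueError("trace must be finite")
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must be in (0, 1)")
    lam = float(noise_sd) if penalty is None else float(penalty)
    t_len = len(y)
    if t_len == 0:
        return np.zeros(0)

    # L1 penalty folds into the target: mu_t = lam * (1 - gamma), last frame lam
    mu = np.full(t_len, lam * (1.0 - gamma))
    if t_len:
        mu[-1] = lam
    ytil = y - mu

    # pools: [value, weight, start, length]
    pools: list[list[float]] = []
    for t in range(t_len):
        pools.append([ytil[t], 1.0, t, 1])
        while len(pools) > 1:
            v_prev, w_prev, t_prev, l_prev = pools[-2]
            v_cur, w_cur, _, l_cur = pools[-1]
            if v_prev * gamma ** l_prev <= v_cur:
                break
            g = gamma ** l_prev
            g2 = gamma ** (2 * l_prev)
            new_w = w_prev + w_cur * g2
            new_v = (w_prev * v_prev + w_cur * v_cur * g) / new_w
            pools[-2] = [new_v, new_w, t_prev, l_prev + l_cur]
            pools.pop()

    c = np.zeros(t_len)
    for v, _, start, length in pools:
        v = max(v, 0.0)
        c[start:start + length] = v * gamma ** np.arange(length)
    s = np.empty(t_len)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    s[s < 1e-12] = 0.0
    return s


def deconvolve_matrix(dff: np.ndarray, gamma: float,
                      noise_sd: float | np.ndarray = 0.0) -> np.ndarray:
    """Row-wise :func:`deconvolve` of an N x T dF/F matrix."""
    dff = np.asarray(dff, dtype=float)
    sds = np.broadcast_to(np.asarray(noise_sd, dtype=float), (dff.shape[0],))
    return np.stack([deconvolve(row, gamma, sd) for row, sd in zip(dff, sds)])


def default_gamma(frame_rate: float, decay_s: float = 1.0) -> float:
    """AR(1) frame decay for an indicator with the given decay time constant."""
    return float(np.exp(-1.0 / (frame_rate * decay_s)))


# --------------------------------------------------------------------------
# per-neuron events and metrics
# --------------------------------------------------------------------------

def _noise_floor(row: np.ndarray, k: float) -> float:
    """Event threshold for a nonnegative deconvolved trace.

    Primary rule: median + ``k`` * SD of the values at or below the trace's
    20th percentile (the sub-percentile mass is taken to be random noise).
    When the deconvolution's sparsity pressure has compressed that mass to
    exactly zero (SD 0, the common case for an L1-penalized AR(1) inversion),
    the residual noise instead shows up as a low mode of small positive
    bins; an Otsu split of the log positive values separates it from the
    spike mode, and is accepted only when the two modes are well apart
    (median ratio > 4) so that clean traces keep every positive bin.
    """
    from skimage.filters import threshold_otsu

    cutoff = np.percentile(row, 20.0)
    noise = row[row <= cutoff]
    if noise.std(ddof=0) > 0:
        return float(np.median(noise) + k * noise.std(ddof=0))
    pos = row[row > 0]
    if pos.size < 3 or pos.min() == pos.max():
        return 0.0
    split = threshold_otsu(np.log(pos))
    low, high = pos[np.log(pos) <= split], pos[np.log(pos) > split]
    if low.size and high.size and np.median(high) > 4.0 * np.median(low):
        return float(np.exp(split))
    return 0.0


def extract_neuron_events(ddff: np.ndarray, frame_rate: float,
                          k: float = defaults.EVENT_K_SD):
    """Detect deconvolved transients and summarize one neuron.

    The noise floor is the median + ``k`` * SD of the bottom-20th-percentile
    values of the deconvolved trace (see :func:`_noise_floor` for the
    fallback used when that mass is exactly zero); contiguous supra-threshold
    runs are events.  Returns ``(events, metrics)`` where ``events`` is a DataFrame
    (onset, offset, peak, duration_s) and ``metrics`` a dict with
    ``ddff_per_min`` (summed ddF/F per minute), ``events_per_sec`` and
    ``mean_amplitude`` (mean of per-event peaks; 0.0 when no events).
    """
    row = np.asarray(ddff, dtype=float)
    if row.ndim != 1:
        raise ValueError("ddff row must be 1-D")
    if np.any(row < 0):
        raise ValueError("ddff must be nonnegative")
    duration_s = len(row) / frame_rate
    metrics = {"ddff_per_min": float(row.sum() / (duration_s / 60.0)),
               "events_per_sec": 0.0, "mean_amplitude": 0.0}
    if not row.any():
        empty = pd.DataFrame(columns=["onset", "offset", "peak", "duration_s"])
        return empty, metrics

    thr = _noise_floor(row, k)
    above = row > thr
    idx = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(np.int8), [0]])))
    starts, stops = idx[::2], idx[1::2] - 1
    rows = [(int(a), int(b), float(row[a:b + 1].max()), (b - a + 1) / frame_rate)
            for a, b in zip(starts, stops)]
    events = pd.DataFrame(rows, columns=["onset", "offset", "peak", "duration_s"])
    metrics["events_per_sec"] = len(events) / duration_s
    if len(events):
        metrics["mean_amplitude"] = float(events["peak"].mean())
    return events, metrics


def neuron_metrics_table(ddff_matrix: np.ndarray, frame_rate: float,
                         k: float = defaults.EVENT_K_SD,
                         graph: "CorrelationGraph | None" = None) -> pd.DataFrame:
    """Per-neuron metric table (one row per neuron) for an N x T ddF/F matrix.

    When ``graph`` is supplied the table includes each neuron's weighted
    clustering coefficient.
    """
    rows = []
    for i, row in enumerate(np.asarray(ddff_matrix, dtype=float)):
        _, m = extract_neuron_events(row, frame_rate, k)
        m["neuron"] = i
        rows.append(m)
    table = pd.DataFrame(rows).set_index("neuron")
    if graph is not None:
        table["clustering_coefficient"] = clustering_coefficient(graph)
    return table


# --------------------------------------------------------------------------
# functional network
# --------------------------------------------------------------------------

@dataclass
class CorrelationGraph:
    """Weighted undirected functional network (nonnegative Pearson weights)."""

    weights: np.ndarray    # N x N symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def correlation_graph(ddff: np.ndarray, quiet_mask: np.ndarray | None = None
                      ) -> CorrelationGraph:
    """Pairwise Pearson correlation network on quiet frames.

    Negative correlations are clipped to 0 (the cohesiveness objective and
    the weighted clustering coefficient require nonnegative weights); a
    zero-variance neuron keeps zero-weight edges, with a warning.
    """
    x = np.asarray(ddff, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need an N x T matrix with at least 3 neurons")
    if quiet_mask is not None:
        x = x[:, np.asarray(quiet_mask, dtype=bool)]
    if x.shape[1] < 100:
        raise ValueError("need at least 100 (quiet) frames")
    sd = x.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance neuron(s): edges set to 0")
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ xc.T) / np.where(denom > 0, denom, np.nan)
    r[np.isnan(r)] = 0.0
    r = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return CorrelationGraph(weights=r)


# --------------------------------------------------------------------------
# overlapping cluster detection (cohesiveness-based)
# --------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Potentially overlapping groups of >= 3 associated neurons."""

    clusters: list          # list of frozensets of node indices

    def __post_init__(self) -> None:
        self.clusters = [frozenset(c) for c in self.clusters]
        if any(len(c) < 3 for c in self.clusters):
            raise ValueError("clusters must have at least 3 members")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def membership(self, n_nodes: int) -> np.ndarray:
        """Boolean membership matrix (n_clusters x n_nodes)."""
        m = np.zeros((len(self.clusters), n_nodes), dtype=bool)
        for i, c in enumerate(self.clusters):
            m[i, sorted(c)] = True
        return m


def cohesiveness(weights: np.ndarray, nodes, penalty: float = defaults.CLUSTER_PENALTY
                 ) -> float:
    """f(V) = W_in(V) / (W_in(V) + W_bound(V) + penalty * |V|)."""
    idx = np.asarray(sorted(nodes), dtype=int)
    if idx.size == 0:
        return 0.0
    sub = weights[np.ix_(idx, idx)]
    w_in = sub.sum() / 2.0
    w_bound = weights[idx].sum() - sub.sum()
    denom = w_in + w_bound + penalty * idx.size
    return float(w_in / denom) if denom > 0 else 0.0


def _grow_cluster(weights: np.ndarray, seed_node: int, penalty: float) -> set:
    """Greedy cohesiveness optimization: add or remove one node per step."""
    n = weights.shape[0]
    members = {seed_node}
    best = cohesiveness(weights, members, penalty)
    while True:
        best_action, best_f = None, best
        outside = [v for v in range(n) if v not in members]
        for v in outside:
            if weights[v, sorted(members)].sum() == 0:
                continue
            f = cohesiveness(weights, members | {v}, penalty)
            if f > best_f + 1e-12:
                best_f, best_action = f, ("add", v)
        if len(members) > 1:
            for v in list(members):
                f = cohesiveness(weights, members - {v}, penalty)
                if f > best_f + 1e-12:
                    best_f, best_action = f, ("remove", v)
        if best_action is None:
            return members
        op, v = best_action
        members = members | {v} if op == "add" else members - {v}
        best = best_f


def _overlap_score(a: frozenset, b: frozenset) -> float:
    """Match coefficient omega(A, B) = |A & B|^2 / (|A| * |B|)."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _density(weights: np.ndarray, nodes: frozenset) -> float:
    idx = np.asarray(sorted(nodes), dtype=int)
    if idx.size < 2:
        return 0.0
    sub = weights[np.ix_(idx, idx)]
    return float(sub.sum() / (idx.size * (idx.size - 1)))


def detect_clusters(graph: CorrelationGraph,
                    min_size: int = defaults.CLUSTER_MIN_SIZE,
                    density_threshold: float = defaults.CLUSTER_DENSITY_THRESHOLD,
                    overlap_threshold: float = defaults.CLUSTER_OVERLAP_THRESHOLD,
                    penalty: float = defaults.CLUSTER_PENALTY) -> ClusterSet:
    """Greedy cohesiveness-based overlapping cluster detection.

    Seeds are taken in decreasing weighted-degree order among nodes not yet
    claimed by a cluster; each seed grows (or shrinks) one node at a time
    while the cohesiveness ``W_in / (W_in + W_bound + penalty * |V|)``
    increases.  Candidate groups whose pairwise match coefficient reaches
    ``overlap_threshold`` are merged, and groups smaller than ``min_size`` or
    with mean pairwise weight density below ``density_threshold`` are
    discarded.
    """
    w = graph.weights
    n = w.shape[0]
    if n == 0:
        return ClusterSet(clusters=[])
    degree = w.sum(axis=1)
    order = np.argsort(-degree, kind="stable")
    claimed = np.zeros(n, dtype=bool)
    candidates: list[frozenset] = []
    for seed_node in order:
        if claimed[seed_node] or degree[seed_node] == 0:
            continue
        members = frozenset(_grow_cluster(w, int(seed_node), penalty))
        claimed[sorted(members)] = True
        if members not in candidates:
            candidates.append(members)

    # merge highly overlapping candidates (transitively)
    merged = True
    while merged:
        merged = False
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                if _overlap_score(candidates[i], candidates[j]) >= overlap_threshold:
                    union = candidates[i] | candidates[j]
                    candidates = [c for k, c in enumerate(candidates)
                                  if k not in (i, j)] + [union]
                    merged = True
                    break
            if merged:
                break

    final = [c for c in candidates
             if len(c) >= min_size and _density(w, c) >= density_threshold]
    return ClusterSet(clusters=final)


# --------------------------------------------------------------------------
# weighted clustering coefficient
# --------------------------------------------------------------------------

def clustering_coefficient(graph: CorrelationGraph) -> np.ndarray:
    """Onnela-style weighted clustering coefficient per node.

    With weights normalized by the network maximum (``w_hat = w / max(w)``),
    ``CC_i = sum_{j,k} (w_hat_ij w_hat_jk w_hat_ik)^(1/3) / (k_i (k_i - 1))``
    where ``k_i`` counts nonzero-weight neighbors; nodes with fewer than two
    neighbors get CC 0.
    """
    w = graph.weights
    n = w.shape[0]
    if n == 0:
        return np.zeros(0)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    w_hat = np.cbrt(w / wmax)
    triangles = np.diagonal(w_hat @ w_hat @ w_hat)
    k = np.count_nonzero(w > 0, axis=1)
    cc = np.zeros(n)
    ok = k >= 2
    cc[ok] = triangles[ok] / (k[ok] * (k[ok] - 1))
    return cc


# --------------------------------------------------------------------------
# group assembly
# --------------------------------------------------------------------------

def assemble_groups(tables: dict, n_per_group: int, seed: int = 0) -> pd.DataFrame:
    """Two-stage seeded subsampling into equal-weighted comparison groups.

    ``tables`` maps a group label to a list of per-recording metric tables
    (DataFrames, one row per neuron).  Within each group, an equal number of
    neurons (the size of the smallest recording in that group) is drawn
    without replacement from every recording; ``n_per_group`` neurons are
    then drawn from the pooled rows.  If the pool is smaller than
    ``n_per_group`` the whole pool is returned with a warning.  The result is
    a tidy frame with ``group`` and ``recording`` columns, reproducible for a
    given seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for group in sorted(tables):
        recs = tables[group]
        if not recs:
            warnings.warn(f"group {group!r} has no recordings; omitted")
            continue
        per_rec = min(len(t) for t in recs)
        pooled = []
        for r, table in enumerate(recs):
            take = rng.choice(len(table), size=per_rec, replace=False)
            sub = table.iloc[np.sort(take)].copy()
            sub["recording"] = r
            pooled.append(sub)
        pool = pd.concat(pooled, ignore_index=True)
        if len(pool) < n_per_group:
            warnings.warn(
                f"group {group!r} pool ({len(pool)}) smaller than requested "
                f"{n_per_group}; using all")
            chosen = pool
        else:
            take = rng.choice(len(pool), size=n_per_group, replace=False)
            chosen = pool.iloc[np.sort(take)]
        chosen = chosen.copy()
        chosen["group"] = group
        out.append(chosen)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)
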