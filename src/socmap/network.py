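"""ROI functional connectivity and map-equation community detection.

Per subject, ROI mean time series are correlated pairwise; the group matrix is
the Fisher-z average (atanh -> mean -> tanh). The significance threshold comes
from a circular-shift permutation null: in each permutation, every subject
independently gets a random seed ROI whose time course is circularly shifted
by at least ``min_shift`` samples (destroying cross-correlations while
preserving the autocorrelation), correlated with all other ROIs; the
seed-to-target correlations are Fisher-z averaged across subjects, and the
threshold is the maximum |pooled value| over the whole null. Edges require
|mean r| strictly above the threshold.

Community structure is found by minimizing the two-level map equation on the
undirected weighted graph (visit rates proportional to node strength, no
teleportation) with a greedy local-move + module-agglomeration search run from
many random restarts; the partition with the lowest description length wins,
and the modal fraction of restarts returning it is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import (DegenerateDataError, SaturationError, ValidationError)

_PERM_CHUNK = 65536  # fixed so identical seeds give identical draw streams


@dataclass
class ConnectivityGraph:
    node_names: list[str]
    subject_r: list[np.ndarray]
    mean_r: np.ndarray
    threshold: float
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    degree: dict[str, int] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_names)
        for a, b, r in self.edges:
            g.add_edge(a, b, weight=abs(r), r=r)
        return g


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    description_length: float
    n_restarts: int
    modal_fraction: float

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


# ---------------------------------------------------------------------------
# Correlations

def subject_connectivity(roi_series: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of per-ROI time series (rows = ROIs)."""
    x = np.asarray(roi_series, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValidationError("need a 2-D (roi, time) array with >= 3 samples")
    if np.any(x.std(axis=1) == 0):
        raise DegenerateDataError("zero-variance ROI series")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return r


def group_mean_connectivity(subject_r: list[np.ndarray]) -> np.ndarray:
    """Entrywise atanh -> mean over subjects -> tanh; diagonal stays 1."""
    mats = [np.asarray(m, dtype=float) for m in subject_r]
    off = ~np.eye(mats[0].shape[0], dtype=bool)
    for m in mats:
        if np.any(np.abs(m[off]) >= 1.0):
            raise SaturationError("|r| = 1 off-diagonal; Fisher mean undefined")
    z = np.mean([np.arctanh(np.where(off, m, 0.0)) for m in mats], axis=0)
    out = np.tanh(z)
    np.fill_diagonal(out, 1.0)
    return out


def circular_shift(series: np.ndarray, k: int, min_shift: int = 1,
                   ) -> np.ndarray:
    """Circularly rotate a series by ``k`` samples; ``k`` must keep at least
    ``min_shift`` samples away from the identity in both directions."""
    series = np.asarray(series)
    T = series.size
    if not (min_shift <= k <= T - min_shift):
        raise ValidationError(
            f"shift {k} outside [{min_shift}, {T - min_shift}]")
    return np.roll(series, k)


# ---------------------------------------------------------------------------
# Permutation null

def _circular_corr_tensor(roi_series: np.ndarray) -> np.ndarray:
    """C[s, j, k] = Pearson r between the seed series s circularly shifted by
    k samples and the unshifted series j, for all lags at once (via FFT)."""
    x = np.asarray(roi_series, dtype=float)
    R, T = x.shape
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise DegenerateDataError("zero-variance ROI series")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    F = np.fft.rfft(z, axis=1)
    cross = np.conj(F)[:, None, :] * F[None, :, :]
    return np.fft.irfft(cross, n=T, axis=2) / T


def permutation_threshold(roi_series_per_subject: list[np.ndarray],
                          n_perm: int, min_shift: int = 10,
                          seed: int = 0, pooling: str = "group_mean",
                          ) -> tuple[float, dict]:
    """Maximum-statistic threshold from the circular-shift permutation null.

    ``pooling='group_mean'`` (default) thresholds the statistic actually
    reported — the Fisher-z group-mean correlation: per permutation the
    per-subject seed-to-target r values are atanh-averaged over subjects
    (excluding a subject when the target is its own seed) and the maximum
    |tanh(mean)| over targets and permutations is the threshold.
    ``pooling='per_subject'`` instead pools every subject-level |r|.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    series = [np.asarray(s, dtype=float) for s in roi_series_per_subject]
    S = len(series)
    R, T = series[0].shape
    if R < 2:
        raise ValidationError("need at least 2 ROIs")
    if T < 2 * min_shift:
        raise ValidationError("series shorter than twice the minimum shift")
    if pooling not in ("group_mean", "per_subject"):
        raise ValidationError(f"unknown pooling {pooling!r}")

    tensors = [_circular_corr_tensor(s) for s in series]
    # independent child streams for seed-ROI and shift draws so the null for
    # n_perm permutations is a prefix of the null for any larger count
    ss = np.random.SeedSequence(seed).spawn(2)
    seed_rng = np.random.default_rng(ss[0])
    shift_rng = np.random.default_rng(ss[1])

    threshold = 0.0
    null_max_per_chunk = []
    done = 0
    while done < n_perm:
        nc = min(_PERM_CHUNK, n_perm - done)
        seeds = seed_rng.integers(0, R, size=(nc, S))
        shifts = shift_rng.integers(min_shift, T - min_shift + 1,
                                    size=(nc, S))
        if pooling == "group_mean":
            zsum = np.zeros((nc, R))
            count = np.zeros((nc, R))
            for i in range(S):
                vals = tensors[i][seeds[:, i], :, shifts[:, i]]   # (nc, R)
                include = np.ones((nc, R), dtype=bool)
                include[np.arange(nc), seeds[:, i]] = False
                z = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
                zsum += np.where(include, z, 0.0)
                count += include
            pooled = np.abs(np.tanh(zsum / np.maximum(count, 1)))
            pooled[count == 0] = 0.0
            chunk_max = float(pooled.max())
        else:
            chunk_max = 0.0
            for i in range(S):
                vals = tensors[i][seeds[:, i], :, shifts[:, i]]
                include = np.ones((nc, R), dtype=bool)
                include[np.arange(nc), seeds[:, i]] = False
                chunk_max = max(chunk_max, float(np.abs(vals[include]).max()))
        null_max_per_chunk.append(chunk_max)
        threshold = max(threshold, chunk_max)
        done += nc

    summary = {"n_perm": n_perm, "min_shift": min_shift, "pooling": pooling,
               "threshold": threshold, "n_subjects": S, "n_rois": R}
    return threshold, summary


# ---------------------------------------------------------------------------
# Graph construction

def build_graph(mean_r: np.ndarray, threshold: float,
                node_names: list[str],
                subject_r: list[np.ndarray] | None = None,
                ) -> ConnectivityGraph:
    """Edges wherever |mean r| strictly exceeds the permutation threshold."""
    mean_r = np.asarray(mean_r, dtype=float)
    if not np.allclose(mean_r, mean_r.T):
        raise ValidationError("mean_r must be symmetric")
    n = mean_r.shape[0]
    edges = []
    degree = {name: 0 for name in node_names}
    for i in range(n):
        for j in range(i + 1, n):
            if abs(mean_r[i, j]) > threshold:
                edges.append((node_names[i], node_names[j],
                              float(mean_r[i, j])))
                degree[node_names[i]] += 1
                degree[node_names[j]] += 1
    return ConnectivityGraph(node_names=list(node_names),
                             subject_r=list(subject_r or []),
                             mean_r=mean_r, threshold=float(threshold),
                             edges=edges, degree=degree)


# ---------------------------------------------------------------------------
# Map equation

def _plogp(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def map_equation(graph: nx.Graph, assignment: dict[str, int]) -> float:
    """Two-level map-equation description length (bits per step) of a random
    walk on the undirected weighted graph under the given node-to-module
    assignment; visit rates are proportional to node strength."""
    nodes = list(graph.nodes())
    if set(assignment) < set(nodes):
        raise ValidationError("every node must be assigned to a module")
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    if np.any(A < 0):
        raise ValidationError("edge weights must be non-negative")
    strength = A.sum(axis=1)
    total = strength.sum()
    if total == 0:
        raise ValidationError("graph has no edges")
    p = strength / total                      # node visit rates

    modules = sorted({assignment[v] for v in nodes})
    mod_index = {m: i for i, m in enumerate(modules)}
    member = np.array([mod_index[assignment[v]] for v in nodes])

    q = np.zeros(len(modules))                # module exit probabilities
    p_mod = np.zeros(len(modules))            # sum of visit rates per module
    for mi in range(len(modules)):
        in_m = member == mi
        q[mi] = A[np.ix_(in_m, ~in_m)].sum() / total
        p_mod[mi] = p[in_m].sum()

    q_total = q.sum()
    # index codebook
    L = -np.sum(_plogp(q / q_total)) * q_total if q_total > 0 else 0.0
    # module codebooks (exit word + node visit words)
    for mi in range(len(modules)):
        denom = q[mi] + p_mod[mi]
        if denom == 0:
            continue
        probs = np.concatenate(([q[mi]], p[member == mi])) / denom
        L += -np.sum(_plogp(probs)) * denom
    return float(L)


# ---------------------------------------------------------------------------
# Community search

def _partition_L(A: np.ndarray, p: np.ndarray, total: float,
                 member: np.ndarray) -> float:
    """Map equation on precomputed arrays (labels need not be contiguous)."""
    L = 0.0
    q_list = []
    for m in np.unique(member):
        in_m = member == m
        q_m = A[np.ix_(in_m, ~in_m)].sum() / total
        q_list.append(q_m)
        denom = q_m + p[in_m].sum()
        if denom > 0:
            probs = np.concatenate(([q_m], p[in_m])) / denom
            L += -np.sum(_plogp(probs)) * denom
    q = np.asarray(q_list)
    q_total = q.sum()
    if q_total > 0:
        L += -np.sum(_plogp(q / q_total)) * q_total
    return float(L)


def _greedy_once(A: np.ndarray, p: np.ndarray, total: float,
                 rng: np.random.Generator) -> np.ndarray:
    n = A.shape[0]
    member = np.arange(n)
    L = _partition_L(A, p, total, member)
    improved = True
    while improved:
        improved = False
        # local node moves
        moved = True
        while moved:
            moved = False
            for v in rng.permutation(n):
                neigh_mods = sorted({member[u] for u in np.flatnonzero(A[v] > 0)}
                                    - {member[v]})
                best_L, best_m = L, member[v]
                for m in neigh_mods:
                    old = member[v]
                    member[v] = m
                    cand = _partition_L(A, p, total, member)
                    member[v] = old
                    if cand < best_L - 1e-12:
                        best_L, best_m = cand, m
                if best_m != member[v]:
                    member[v] = best_m
                    L = best_L
                    moved = improved = True
        # module agglomeration
        merged = True
        while merged:
            merged = False
            mods = np.unique(member)
            best_L, best_pair = L, None
            for i, ma in enumerate(mods):
                for mb in mods[i + 1:]:
                    if A[np.ix_(member == ma, member == mb)].sum() == 0:
                        continue
                    trial = member.copy()
                    trial[trial == mb] = ma
                    cand = _partition_L(A, p, total, trial)
                    if cand < best_L - 1e-12:
                        best_L, best_pair = cand, (ma, mb)
            if best_pair is not None:
                ma, mb = best_pair
                member[member == mb] = ma
                L = best_L
                merged = improved = True
    return member


def _canonical(member: np.ndarray) -> tuple[int, ...]:
    """Relabel modules 0,1,... in order of first appearance."""
    seen: dict[int, int] = {}
    out = []
    for m in member:
        if m not in seen:
            seen[m] = len(seen)
        out.append(seen[m])
    return tuple(out)


def detect_communities(graph: nx.Graph, n_restarts: int = 100,
                       seed: int = 0) -> CommunityPartition:
    """Greedy map-equation minimization from ``n_restarts`` random
    initializations; returns the lowest-description-length partition, with
    ties broken by the lexicographically smallest canonical labeling, and the
    fraction of restarts that returned it."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    nodes = list(graph.nodes())
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    strength = A.sum(axis=1)
    total = strength.sum()
    if total == 0:
        # no edges: every node is its own module, description length 0
        return CommunityPartition({v: i for i, v in enumerate(nodes)}, 0.0,
                                  n_restarts, 1.0)
    p = strength / total
    rng = np.random.default_rng(seed)

    results: list[tuple[float, tuple[int, ...]]] = []
    for _ in range(n_restarts):
        member = _greedy_once(A, p, total, rng)
        results.append((_partition_L(A, p, total, member),
                        _canonical(member)))
    best_L, best_canon = min(results, key=lambda it: (it[0], it[1]))
    modal = sum(1 for _, c in results if c == best_canon) / n_restarts
    assignment = {v: m for v, m in zip(nodes, best_canon)}
    return CommunityPartition(assignment=assignment,
                              description_length=best_L,
                              n_restarts=n_restarts, modal_fraction=modal)
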