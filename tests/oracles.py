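"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over definitions — no shared code
with the package under test — so agreement is meaningful.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def gip_kernel_brute(A: np.ndarray, axis: str, gamma_prime: float = 1.0) -> np.ndarray:
    """Double-loop evaluation of the Gaussian interaction-profile kernel."""
    profiles = A if axis == "circRNA" else A.T
    n = profiles.shape[0]
    mean_sq = sum(float(np.dot(p, p)) for p in profiles) / n
    gamma = gamma_prime / mean_sq
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = profiles[i] - profiles[j]
            K[i, j] = math.exp(-gamma * float(np.dot(diff, diff)))
    return K


def _bfs(adj: dict, source):
    """Distances, shortest-path counts, and predecessor lists from source."""
    dist = {source: 0}
    sigma = {source: 1}
    preds: dict = {source: []}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                preds[v] = []
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, preds


def _all_shortest_paths(preds: dict, source, target):
    """Enumerate every shortest path source->target from the BFS DAG."""
    if target == source:
        return [[source]]
    if target not in preds:
        return []
    paths = []
    for p in preds[target]:
        for sub in _all_shortest_paths(preds, source, p):
            paths.append(sub + [target])
    return paths


def centralities_brute(nodes: list, edges: list) -> dict:
    """degree/closeness/betweenness by explicit shortest-path enumeration.

    Closeness uses the within-component value scaled by
    (reachable - 1)/(n - 1); betweenness divides by (n-1)(n-2)/2.
    """
    n = len(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    between = {v: 0.0 for v in nodes}
    bfs_cache = {s: _bfs(adj, s) for s in nodes}
    for si, s in enumerate(nodes):
        dist_s, _, preds_s = bfs_cache[s]
        for t in nodes[si + 1:]:
            if t not in dist_s or t == s:
                continue
            paths = _all_shortest_paths(preds_s, s, t)
            for v in nodes:
                if v in (s, t):
                    continue
                frac = sum(1 for p in paths if v in p) / len(paths)
                between[v] += frac
    denom_b = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    for v in nodes:
        dist, _, _ = bfs_cache[v]
        reachable = len(dist) - 1
        total = sum(dist.values())
        clo = 0.0
        if reachable > 0 and total > 0:
            clo = (reachable / total) * (reachable / (n - 1))
        out[v] = {
            "n_neighbors": len(adj[v]),
            "degree": len(adj[v]) / (n - 1) if n > 1 else 0.0,
            "closeness": clo,
            "betweenness": between[v] / denom_b,
        }
    return out


def auc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def confusion_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """ACC/PRE/REC/F1 from explicit confusion-matrix counts."""
    tp = fp = tn = fn = 0
    for s, l in zip(scores, labels):
        pred = 1 if s >= threshold else 0
        if pred == 1 and l == 1:
            tp += 1
        elif pred == 1 and l == 0:
            fp += 1
        elif pred == 0 and l == 0:
            tn += 1
        else:
            fn += 1
    acc = (tp + tn) / len(labels)
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return {"ACC": acc, "PRE": pre, "REC": rec, "F1": f1}
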