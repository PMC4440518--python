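"""Hierarchical clustering of categorical copy-number profiles.

Distances are Euclidean on the numeric state encodings (-1, 0, 1, 2), with
pairwise deletion of probes missing in either profile and rescaling by
sqrt(grid / observed) so distances stay comparable under missing-at-random
probes. Linkage is Ward's minimum-variance criterion in its squared-distance
(Ward.D2-style) form via the Lance-Williams update, implemented here so that
ties merge deterministically at the pair whose clusters contain the smallest
leaf indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import StateProfile

__all__ = ["Dendrogram", "state_distance", "ward_cluster", "pair_sibling_fraction"]


def state_distance(profiles: list[StateProfile]) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean distances between encodings."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    n_grid = profiles[0].n_probes
    for p in profiles:
        if p.n_probes != n_grid:
            raise ValueError("profiles are not on a common probe grid")
    enc = np.stack([p.encoding.astype(float) for p in profiles])
    obs = ~np.stack([p.missing for p in profiles])
    m = len(profiles)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both = obs[i] & obs[j]
            n_obs = int(both.sum())
            if n_obs == 0:
                raise ValueError(f"profiles {i} and {j} share no observed probes")
            d = float(np.sqrt(np.sum((enc[i, both] - enc[j, both]) ** 2)))
            d *= np.sqrt(n_grid / n_obs)
            dist[i, j] = dist[j, i] = d
    return dist


@dataclass
class Dendrogram:
    """Agglomeration result in scipy linkage-matrix convention.

    ``merges[t] = (id_a, id_b, height, size)`` where leaves are 0..n-1 and
    the cluster formed at step t gets id n+t; heights are non-decreasing.
    """

    merges: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    def to_newick(self) -> str:
        n = self.n_leaves
        labels = self.labels or [str(i) for i in range(n)]
        height = {i: 0.0 for i in range(n)}
        node = {i: labels[i] for i in range(n)}
        for t, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + t] = f"({node[a]}:{la:.6f},{node[b]}:{lb:.6f})"
            height[n + t] = h
        return node[n + len(self.merges) - 1] + ";" if len(self.merges) else labels[0] + ";"


def ward_cluster(dist: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Agglomerative Ward linkage from a distance matrix.

    Works on squared distances with the Lance-Williams update

        d2(k, i+j) = ((n_i+n_k) d2(k,i) + (n_j+n_k) d2(k,j) - n_k d2(i,j))
                     / (n_i + n_j + n_k)

    and reports sqrt of the merge cost as the height (matching the
    convention of scipy's 'ward' linkage on Euclidean input). Ties are
    broken at the candidate pair whose (smallest-leaf, smallest-leaf) ids
    are lexicographically least.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = dist.shape[0]
    d2 = dist ** 2
    active: dict[int, dict] = {
        i: {"size": 1, "minleaf": i} for i in range(n)
    }
    cur = {i: i for i in range(n)}  # position in d2 -> cluster id (ids grow)
    # store squared distances keyed by cluster id pairs
    pair_d2: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            pair_d2[(i, j)] = d2[i, j]
    merges = np.zeros((n - 1, 4))
    next_id = n
    for t in range(n - 1):
        ids = sorted(active)
        best = None  # (v, minleaf_lo, minleaf_hi, a, b)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                v = pair_d2[(a, b)]
                la = min(active[a]["minleaf"], active[b]["minleaf"])
                lb = max(active[a]["minleaf"], active[b]["minleaf"])
                if best is None:
                    best = (v, la, lb, a, b)
                    continue
                tol = 1e-12 * max(abs(v), abs(best[0]), 1.0)
                if v < best[0] - tol or (abs(v - best[0]) <= tol
                                         and (la, lb) < (best[1], best[2])):
                    best = (v, la, lb, a, b)
        v, la, lb, a, b = best
        merges[t] = (a, b, np.sqrt(max(v, 0.0)), active[a]["size"] + active[b]["size"])
        na, nb = active[a]["size"], active[b]["size"]
        new = {"size": na + nb, "minleaf": min(active[a]["minleaf"], active[b]["minleaf"])}
        for k in active:
            if k in (a, b):
                continue
            nk = active[k]["size"]
            ka = pair_d2[(min(a, k), max(a, k))]
            kb = pair_d2[(min(b, k), max(b, k))]
            ab = pair_d2[(min(a, b), max(a, b))]
            upd = ((na + nk) * ka + (nb + nk) * kb - nk * ab) / (na + nb + nk)
            pair_d2[(min(k, next_id), max(k, next_id))] = upd
        del active[a], active[b]
        active[next_id] = new
        next_id += 1
    return Dendrogram(merges=merges, labels=list(labels) if labels else [])


def pair_sibling_fraction(dendro: Dendrogram, pairing: dict) -> float:
    """Fraction of cases whose two component leaves merge as immediate
    siblings (their lowest common ancestor covers exactly those two leaves).

    ``pairing`` maps case id -> (leaf index A, leaf index B) or, when the
    dendrogram carries labels, (label A, label B).
    """
    if not pairing:
        raise ValueError("empty pairing")
    label_idx = {lab: i for i, lab in enumerate(dendro.labels)}
    singleton_merges = {
        frozenset((int(a), int(b)))
        for a, b, _, _ in dendro.merges
        if a < dendro.n_leaves and b < dendro.n_leaves
    }
    hits = 0
    for case, (la, lb) in pairing.items():
        ia = label_idx.get(la, la)
        ib = label_idx.get(lb, lb)
        if not isinstance(ia, (int, np.integer)) or not isinstance(ib, (int, np.integer)):
            raise ValueError(f"case {case}: leaves {la!r}/{lb!r} not in dendrogram")
        if frozenset((int(ia), int(ib))) in singleton_merges:
            hits += 1
    return hits / len(pairing)
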