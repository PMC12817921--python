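"""Multi-strain analysis.

Binary feature tables from different predictions are merged, pairwise
strain similarity is computed with the Jaccard index over the 1-feature
sets, and the resulting distance matrix (1 - J) is clustered with
Ward's agglomerative method into a "phylometabolic tree": strains with
similar metabolic potential sit close together.  Clusters of
metabolically coherent strains are extracted by cutting the tree, and
per-cluster feature frequencies rank characteristic features.
Predicted tables can be scored against experimental tables with
standard confusion metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prediction import BFT


def merge_bfts(tables: list[BFT], drop_constant: bool = False,
               exclude_features: list[str] | None = None) -> BFT:
    """Row-wise concatenation of BFTs over one strain set.

    Strain sets must match (order-insensitive) and feature ids must be
    disjoint.  ``exclude_features`` removes named rows (e.g. a pathway's
    reactions); ``drop_constant`` removes rows constant across strains.
    """
    if not tables:
        raise ValueError("no tables")
    strains = sorted(tables[0].strains)
    for t in tables[1:]:
        if sorted(t.strains) != strains:
            diff = set(t.strains) ^ set(strains)
            raise ValueError(f"strain set mismatch: {sorted(diff)}")
    frames = [t.frame[strains] for t in tables]
    merged = pd.concat(frames, axis=0)
    if merged.index.has_duplicates:
        dups = merged.index[merged.index.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids: {dups}")
    if exclude_features:
        merged = merged.drop(index=[f for f in exclude_features
                                    if f in merged.index])
    if drop_constant:
        merged = merged[merged.nunique(axis=1) > 1]
    return BFT(merged)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, in [0,1]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero "
                             "diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0,1]")


def jaccard_distance_matrix(bft: BFT) -> DistanceMatrix:
    """distance(a,b) = 1 - |Fa & Fb| / |Fa | Fb| over 1-feature sets;
    two strains with no features at all are at distance 0."""
    strains = bft.strains
    if len(strains) < 2:
        raise ValueError("need >= 2 strains")
    X = bft.frame.to_numpy().astype(bool)
    n = len(strains)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.count_nonzero(X[:, i] & X[:, j])
            union = np.count_nonzero(X[:, i] | X[:, j])
            D[i, j] = D[j, i] = 0.0 if union == 0 else 1.0 - inter / union
    return DistanceMatrix(list(strains), D)


@dataclass
class Dendrogram:
    """Binary merge tree in linkage form.

    ``merges[k] = (i, j, height, size)`` joins nodes i and j (node ids:
    0..n-1 leaves in label order, n+k for the cluster made at merge k).
    Heights are non-decreasing from leaves to root.
    """
    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def to_linkage(self) -> np.ndarray:
        return np.array([[i, j, h, s] for i, j, h, s in self.merges],
                        dtype=float)

    def to_newick(self) -> str:
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        text = {i: lab for i, lab in enumerate(self.labels)}
        for k, (i, j, h, _s) in enumerate(self.merges):
            node = n + k
            bi = (h - height[i]) / 2
            bj = (h - height[j]) / 2
            text[node] = f"({text[i]}:{bi:.6g},{text[j]}:{bj:.6g})"
            height[node] = h
        return text[n + len(self.merges) - 1] + ";"


def ward_dendrogram(d: DistanceMatrix) -> Dendrogram:
    """Ward agglomeration on a precomputed distance matrix via the
    Lance-Williams recurrence.

    Among minimum-distance pairs, the pair whose (smallest member
    label, smallest member label of the partner) is lexicographically
    least is merged, making the tree deterministic.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("need >= 2 strains")
    D = d.values.astype(float).copy()
    size = {i: 1 for i in range(n)}
    tag = {i: d.labels[i] for i in range(n)}  # smallest member label
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best_key = None
        best_pair = None
        for (i, j), v in dist.items():
            key = (v, *sorted((tag[i], tag[j])))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (i, j)
        assert best_pair is not None
        s, t = best_pair
        h = dist[(s, t)]
        u = next_id
        next_id += 1
        ns, nt = size[s], size[t]
        size[u] = ns + nt
        tag[u] = min(tag[s], tag[t])
        active -= {s, t}
        for w in active:
            dsw = dist[tuple(sorted((s, w)))]
            dtw = dist[tuple(sorted((t, w)))]
            nw = size[w]
            duw = math.sqrt(((nw + ns) * dsw ** 2 + (nw + nt) * dtw ** 2
                             - nw * h ** 2) / (ns + nt + nw))
            dist[(w, u) if w < u else (u, w)] = duw
        dist = {k: v for k, v in dist.items()
                if s not in k and t not in k}
        active.add(u)
        merges.append((s, t, h, size[u]))
    return Dendrogram(list(d.labels), merges)


def extract_clusters(dendrogram: Dendrogram, k: int) -> dict[str, str]:
    """Cut the tree into exactly k groups (undo the k-1 last merges).

    Groups are labeled Cluster_1..Cluster_k by decreasing size, ties by
    smallest member label.  Returns strain -> cluster label.
    """
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n + len(dendrogram.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (i, j, _h, _s) in enumerate(dendrogram.merges[:n - k]):
        u = n + idx
        parent[find(i)] = u
        parent[find(j)] = u
    groups: dict[int, list[str]] = {}
    for leaf, label in enumerate(dendrogram.labels):
        groups.setdefault(find(leaf), []).append(label)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    return {strain: f"Cluster_{rank + 1}"
            for rank, members in enumerate(ordered) for strain in members}


def cluster_feature_frequencies(bft: BFT, assignment: dict[str, str]
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster relative feature frequencies and characteristic
    scores.

    freq(f, c) = mean of row f over cluster c's strains; the
    characteristic score of f for c is freq(f, c) minus the frequency in
    all other strains.  Returns (frequencies, scores), features x
    clusters, scores sorted per column by rank elsewhere.
    """
    missing = [s for s in bft.strains if s not in assignment]
    if missing:
        raise KeyError(f"assignment misses strains {missing}")
    clusters = sorted(set(assignment.values()))
    freq = pd.DataFrame(index=bft.frame.index, columns=clusters, dtype=float)
    score = pd.DataFrame(index=bft.frame.index, columns=clusters, dtype=float)
    for c in clusters:
        inside = [s for s in bft.strains if assignment[s] == c]
        outside = [s for s in bft.strains if assignment[s] != c]
        fin = bft.frame[inside].mean(axis=1)
        freq[c] = fin
        fout = bft.frame[outside].mean(axis=1) if outside else 0.0
        score[c] = fin - fout
    return freq, score


@dataclass
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int

    def _ratio(self, num: float, den: float) -> float:
        return num / den if den else float("nan")

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp
                           + self.fn)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)


def confusion_metrics(predicted: BFT, experimental: pd.DataFrame
                      ) -> tuple[dict[str, ConfusionMetrics], pd.DataFrame]:
    """Score predictions against an experimental table ({0,1,NaN};
    NaN = untested, excluded).

    Returns per-strain metrics over the shared feature/strain labels and
    a summary frame with the mean and standard deviation across strains.
    """
    strains = [s for s in predicted.strains if s in experimental.columns]
    features = [f for f in predicted.features if f in experimental.index]
    if not strains or not features:
        raise ValueError("no overlapping strain/feature labels")
    per_strain: dict[str, ConfusionMetrics] = {}
    for s in strains:
        tp = tn = fp = fn = 0
        for f in features:
            exp = experimental.loc[f, s]
            if pd.isna(exp):
                continue
            pred = predicted.frame.loc[f, s]
            if exp == 1 and pred == 1:
                tp += 1
            elif exp == 0 and pred == 0:
                tn += 1
            elif exp == 0 and pred == 1:
                fp += 1
            else:
                fn += 1
        per_strain[s] = ConfusionMetrics(tp, tn, fp, fn)
    table = pd.DataFrame(
        {s: {"accuracy": m.accuracy, "precision": m.precision,
             "recall": m.recall, "specificity": m.specificity}
         for s, m in per_strain.items()}).T
    summary = pd.DataFrame({"mean": table.mean(), "std": table.std()})
    return per_strain, summary
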