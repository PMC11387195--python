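"""Mononucleotide-repeat (MNR) profiling and clustering of chloroplast genomes.

Homopolymer runs of A, C, G or T with length 3-20 are counted per sequence
(maximal runs only; N breaks a run; runs longer than 20 are excluded by
default or optionally capped at 20).  Per-sequence abundances — by default
the percentage of the sequence covered by each (base, length) feature —
feed a Euclidean distance matrix, a correlation-based secondary
dissimilarity, average-linkage hierarchical clustering, and feature-bootstrap
cluster support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

MIN_RUN = 3
MAX_RUN = 20
BASES = ("A", "C", "G", "T")
FEATURES: list[str] = [f"{b}{k}" for b in BASES for k in range(MIN_RUN, MAX_RUN + 1)]
"""The 72 possible features: 4 bases x run lengths 3-20, named A3..T20."""

_BASE_ROW = {b: i for i, b in enumerate(BASES)}


def scan_mnr(sequence: str, long_run_policy: str = "exclude") -> pd.Series:
    """Count maximal homopolymer runs per (base, length) feature.

    A maximal run of length L with 3 <= L <= 20 increments feature
    ``f"{base}{L}"`` by one.  Runs longer than 20 are excluded entirely
    (``long_run_policy="exclude"``, the default) or counted as length-20
    (``"cap"``).  N breaks runs and never forms a feature.
    """
    if long_run_policy not in ("exclude", "cap"):
        raise ValueError(f"unknown long_run_policy {long_run_policy!r}")
    seq = sequence.upper()
    counts = pd.Series(0, index=FEATURES, dtype=np.int64)
    if not seq:
        return counts
    a = np.frombuffer(seq.encode("ascii"), dtype="S1")
    bad = ~np.isin(a, np.array([b"A", b"C", b"G", b"T", b"N"], dtype="S1"))
    if bad.any():
        ch = a[bad][0].decode()
        raise ValueError(f"invalid character {ch!r} in sequence")
    change = np.nonzero(a[1:] != a[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(a)]))
    run_base = a[starts]
    run_len = ends - starts
    for base, length in zip(run_base, run_len):
        if base == b"N":
            continue
        L = int(length)
        if L > MAX_RUN:
            if long_run_policy == "exclude":
                continue
            L = MAX_RUN
        if L < MIN_RUN:
            continue
        counts[f"{base.decode()}{L}"] += 1
    return counts


@dataclass
class MNRAbundanceMatrix:
    """Samples x MNR features: raw counts and percentage abundances.

    Under the default ``"coverage"`` convention the abundance of feature
    (base, L) is ``count * L / sequence_length * 100`` — the percent of the
    genome covered by such runs.  The alternative ``"count"`` convention is
    ``count / sequence_length * 100``.
    """

    counts: pd.DataFrame
    abundance: pd.DataFrame
    seq_lengths: pd.Series
    convention: str = "coverage"

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def features(self) -> list[str]:
        return list(self.counts.columns)

    def total_loci(self) -> pd.Series:
        """Total MNR locus count per sample (sum of feature counts)."""
        return self.counts.sum(axis=1)


def abundance_matrix(
    sequences: Iterable[tuple[str, str]],
    convention: str = "coverage",
    long_run_policy: str = "exclude",
) -> MNRAbundanceMatrix:
    """Scan each named sequence and assemble the abundance matrix."""
    if convention not in ("coverage", "count"):
        raise ValueError(f"unknown convention {convention!r}")
    names, rows, lengths = [], [], []
    for name, seq in sequences:
        if len(seq) == 0:
            raise ValueError(f"zero-length sequence {name!r}")
        names.append(name)
        rows.append(scan_mnr(seq, long_run_policy=long_run_policy))
        lengths.append(len(seq))
    counts = pd.DataFrame(rows, index=names)
    lens = pd.Series(lengths, index=names, dtype=np.int64)
    if convention == "coverage":
        run_len = np.array([int(f[1:]) for f in FEATURES])
        ab = counts * run_len[None, :] / lens.values[:, None] * 100.0
    else:
        ab = counts / lens.values[:, None] * 100.0
    return MNRAbundanceMatrix(
        counts=counts, abundance=ab, seq_lengths=lens, convention=convention
    )


def filter_features(m: MNRAbundanceMatrix) -> MNRAbundanceMatrix:
    """Drop features absent from every sample and features with identical
    abundance (exact equality) across all samples."""
    ab = m.abundance
    nonzero = (m.counts != 0).any(axis=0)
    varying = ab.nunique(axis=0) > 1
    keep = nonzero & varying
    if not keep.any():
        warnings.warn("no informative MNR features remain after filtering",
                      stacklevel=2)
    return MNRAbundanceMatrix(
        counts=m.counts.loc[:, keep],
        abundance=ab.loc[:, keep],
        seq_lengths=m.seq_lengths,
        convention=m.convention,
    )


def mnr_distance(m: MNRAbundanceMatrix) -> pd.DataFrame:
    """Euclidean distance between sample abundance rows."""
    if len(m.samples) < 2:
        raise ValueError("need >= 2 samples")
    if not m.features:
        raise ValueError("need >= 1 feature")
    D = squareform(pdist(m.abundance.values, metric="euclidean"))
    return pd.DataFrame(D, index=m.samples, columns=m.samples)


@dataclass
class MNRClusterResult:
    """Average-linkage dendrogram on the correlation-based dissimilarity.

    ``linkage_matrix`` is in scipy format; ``supports`` maps each internal
    cluster (as a frozenset of sample names) to its bootstrap proportion.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    secondary_dissimilarity: pd.DataFrame
    supports: dict[frozenset, float] | None = None

    def cluster_leaf_sets(self) -> list[frozenset]:
        """Leaf-name sets of every internal node, in merge order."""
        n = len(self.labels)
        members: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out: list[frozenset] = []
        for step, (a, b, _h, _c) in enumerate(self.linkage_matrix):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            out.append(merged)
        return out

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self, include_support: bool = False) -> str:
        n = len(self.labels)
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        members = self.cluster_leaf_sets()

        def fmt(idx: int) -> str:
            if idx < n:
                return self.labels[idx]
            a, b, h, _ = self.linkage_matrix[idx - n]
            la = h - height[int(a)]
            lb = h - height[int(b)]
            label = ""
            if include_support and self.supports is not None:
                s = self.supports.get(members[idx - n])
                if s is not None:
                    label = f"{s:.3g}"
            return f"({fmt(int(a))}:{la:.10g},{fmt(int(b))}:{lb:.10g}){label}"

        for step, (_a, _b, h, _c) in enumerate(self.linkage_matrix):
            height[n + step] = h
        return fmt(n + len(self.linkage_matrix) - 1) + ";"


def _secondary_dissimilarity(D: pd.DataFrame) -> pd.DataFrame:
    """d*(i, j) = 1 - Pearson correlation of rows i, j of the distance matrix,
    excluding the self-entries of the pair (columns i and j)."""
    n = D.shape[0]
    V = D.values
    out = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            xi, xj = V[i, mask], V[j, mask]
            if xi.std() == 0 or xj.std() == 0:
                raise ValueError(
                    "correlation undefined: constant distance profile for "
                    f"{D.index[i]!r} or {D.index[j]!r}"
                )
            r = np.corrcoef(xi, xj)[0, 1]
            out[i, j] = out[j, i] = 1.0 - r
    return pd.DataFrame(out, index=D.index, columns=D.columns)


def cluster_samples(D: pd.DataFrame) -> MNRClusterResult:
    """Average-linkage clustering on the correlation-based dissimilarity.

    The Euclidean distance matrix is first transformed to the secondary
    dissimilarity d* = 1 - Pearson(rows), then agglomerated with average
    linkage (heights are non-decreasing along the merge order).
    """
    if D.shape[0] < 3:
        raise ValueError("need >= 3 samples to cluster")
    dstar = _secondary_dissimilarity(D)
    Z = linkage(squareform(dstar.values, checks=False), method="average")
    return MNRClusterResult(
        labels=list(D.index),
        linkage_matrix=Z,
        secondary_dissimilarity=dstar,
    )


def bootstrap_clusters(
    m: MNRAbundanceMatrix,
    replicates: int = 1000,
    seed: int | None = None,
) -> MNRClusterResult:
    """Cluster with feature-bootstrap support values.

    Feature columns are resampled with replacement; distance, secondary
    dissimilarity and clustering are recomputed per replicate, and each
    original cluster's support is the fraction of replicates reproducing it
    as a leaf set.  Replicates where the secondary dissimilarity is undefined
    (a constant distance profile) are discarded.
    """
    if len(m.features) < 2:
        raise ValueError("need >= 2 features after filtering")
    base = cluster_samples(mnr_distance(m))
    targets = [s for s in base.cluster_leaf_sets() if len(s) < len(m.samples)]
    hits = {s: 0 for s in targets}
    rng = np.random.default_rng(seed)
    n_feat = len(m.features)
    n_used = 0
    for _ in range(replicates):
        idx = rng.integers(0, n_feat, size=n_feat)
        rep = MNRAbundanceMatrix(
            counts=m.counts.iloc[:, idx],
            abundance=m.abundance.iloc[:, idx],
            seq_lengths=m.seq_lengths,
            convention=m.convention,
        )
        try:
            res = cluster_samples(mnr_distance(rep))
        except ValueError:
            continue
        n_used += 1
        found = set(res.cluster_leaf_sets())
        for s in hits:
            if s in found:
                hits[s] += 1
    if n_used == 0:
        raise ValueError("all bootstrap replicates failed")
    base.supports = {s: hits[s] / n_used for s in hits}
    # the root cluster (all samples) is trivially always present
    base.supports[frozenset(m.samples)] = 1.0
    return base
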