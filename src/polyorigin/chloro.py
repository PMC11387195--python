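"""Chloroplast alignment polymorphisms and neighbor-joining phylogeny.

Works on an existing multiple alignment of whole chloroplast genomes
(orientation of the small single-copy region is assumed normalized upstream).
SNPs are columns with two or more distinct non-gap, non-N bases; insertion/
deletion events are maximal runs of columns whose gap pattern varies across
sequences, counted as one polymorphism per run by default.  Trees are built
with the Saitou-Nei neighbor-joining algorithm on p-distances, with column
bootstrap for branch support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_ALPHABET = frozenset(b"ACGTN-")


@dataclass
class Alignment:
    """Equal-length sequence matrix over {A, C, G, T, N, -}."""

    names: list[str]
    matrix: np.ndarray  # (n_seqs, n_cols) of single bytes

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise ValueError("matrix must be (n_seqs, n_cols) with one row per name")
        present = set(np.unique(self.matrix).tolist())
        bad = present - {bytes([c]) for c in _ALPHABET}
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    @classmethod
    def from_sequences(cls, named: Iterable[tuple[str, str]]) -> "Alignment":
        names, rows = [], []
        for name, seq in named:
            names.append(name)
            rows.append(np.frombuffer(seq.upper().encode("ascii"), dtype="S1"))
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        return cls(names=names, matrix=np.vstack(rows))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import SeqIO

        return cls.from_sequences(
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        )

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def subset(self, names: Sequence[str]) -> "Alignment":
        lookup = {n: i for i, n in enumerate(self.names)}
        try:
            rows = [lookup[n] for n in names]
        except KeyError as exc:
            raise KeyError(f"unknown sequence {exc.args[0]!r}") from None
        return Alignment(names=list(names), matrix=self.matrix[rows])


@dataclass
class VariantEvent:
    """One alignment polymorphism: a SNP column or an InDel column interval."""

    kind: str  # "SNP" | "INDEL"
    start_col: int  # 0-based
    end_col: int  # exclusive; start_col + 1 for SNPs
    states: dict[str, str]


@dataclass
class VariantCounts:
    snps: int
    indels: int

    @property
    def total(self) -> int:
        return self.snps + self.indels


def find_alignment_variants(
    aln: Alignment,
    subset: Sequence[str] | None = None,
    indel_mode: str = "run",
    n_policy: str = "exclude-state",
) -> tuple[list[VariantEvent], VariantCounts]:
    """Identify SNP and InDel polymorphisms among a subset of sequences.

    A SNP is a column with >= 2 distinct bases among non-gap, non-N states.
    An InDel is a maximal run of columns whose gap/non-gap pattern varies
    across the subset, counted as one event (``indel_mode="run"``) or one
    per column (``indel_mode="column"``).  Columns inside an InDel run may
    additionally yield SNPs on their non-gap states.  ``n_policy`` controls
    N handling: ``"exclude-state"`` ignores N when collecting column states;
    ``"drop-column"`` excludes any column containing an N entirely.
    """
    if indel_mode not in ("run", "column"):
        raise ValueError(f"indel_mode must be 'run' or 'column', got {indel_mode!r}")
    if n_policy not in ("exclude-state", "drop-column"):
        raise ValueError(f"unknown n_policy {n_policy!r}")
    sub = aln if subset is None else aln.subset(subset)
    M = sub.matrix
    gap = M == b"-"
    is_n = M == b"N"
    usable = np.ones(sub.n_cols, dtype=bool)
    if n_policy == "drop-column":
        usable = ~is_n.any(axis=0)

    # SNP columns: >=2 distinct non-gap non-N bases
    events: list[VariantEvent] = []
    base_ok = ~gap & ~is_n
    snp_cols = []
    for j in np.nonzero(usable)[0]:
        states = set(M[base_ok[:, j], j].tolist())
        if len(states) >= 2:
            snp_cols.append(int(j))
    for j in snp_cols:
        events.append(
            VariantEvent(
                kind="SNP",
                start_col=j,
                end_col=j + 1,
                states={
                    n: M[i, j].decode() for i, n in enumerate(sub.names)
                },
            )
        )

    # InDel columns: gap pattern non-constant across the subset
    varying = usable & gap.any(axis=0) & ~gap.all(axis=0)
    indel_events: list[VariantEvent] = []
    if indel_mode == "column":
        for j in np.nonzero(varying)[0]:
            indel_events.append(_indel_event(sub, int(j), int(j) + 1))
    else:
        j = 0
        cols = varying
        while j < sub.n_cols:
            if cols[j]:
                k = j
                while k < sub.n_cols and cols[k]:
                    k += 1
                indel_events.append(_indel_event(sub, j, k))
                j = k
            else:
                j += 1
    events.extend(indel_events)
    counts = VariantCounts(snps=len(snp_cols), indels=len(indel_events))
    return events, counts


def _indel_event(sub: Alignment, start: int, end: int) -> VariantEvent:
    return VariantEvent(
        kind="INDEL",
        start_col=start,
        end_col=end,
        states={
            n: sub.matrix[i, start:end].tobytes().decode()
            for i, n in enumerate(sub.names)
        },
    )


def pairwise_distance(aln: Alignment) -> np.ndarray:
    """p-distance matrix: per pair, mismatches over columns where both
    sequences have a non-gap, non-N base.  Errors on pairs with no
    comparable columns."""
    M = aln.matrix
    ok = (M != b"-") & (M != b"N")
    n = aln.n_seqs
    D = np.zeros((n, n))
    for i in range(n - 1):
        both = ok[i] & ok[i + 1 :]
        comparable = both.sum(axis=1)
        if (comparable == 0).any():
            j = i + 1 + int(np.nonzero(comparable == 0)[0][0])
            raise ValueError(
                f"no comparable columns between {aln.names[i]!r} and "
                f"{aln.names[j]!r}"
            )
        mism = ((M[i] != M[i + 1 :]) & both).sum(axis=1)
        D[i, i + 1 :] = mism / comparable
        D[i + 1 :, i] = D[i, i + 1 :]
    return D


@dataclass
class TreeNode:
    """Node of an (unrooted) phylogeny; leaves carry names."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class Tree:
    """Unrooted tree as a trifurcating (or star) root node.

    ``negative_branches_clamped`` flags NJ branch-length estimates that came
    out negative and were set to 0.
    """

    root: TreeNode
    negative_branches_clamped: int = 0

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial bipartitions keyed by canonical leaf-set (smaller side,
        ties broken by sorted name order), mapped to the subtree node."""
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                side = frozenset(child.leaf_names())
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out[canonical_bipartition(side, all_leaves)] = child
                walk(child)

        walk(self.root)
        return out

    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(c)}:{bl:.10g}" for c, bl in node.children
            )
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:.3g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def canonical_bipartition(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical key for an unrooted bipartition: the smaller side, ties
    resolved by lexicographically smaller sorted name tuple."""
    comp = all_leaves - side
    if len(side) < len(comp):
        return side
    if len(comp) < len(side):
        return comp
    return side if tuple(sorted(side)) <= tuple(sorted(comp)) else comp


def nj_tree(D: np.ndarray, names: Sequence[str]) -> Tree:
    """Saitou-Nei neighbor joining with deterministic lowest-(i, j) tie-break.

    Returns an unrooted tree (trifurcating root).  Branch lengths solving
    the NJ equations that come out negative are clamped to 0 and counted.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(names):
        raise ValueError("distance matrix must be square and match names")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=str(s)) for s in names]
    D = D.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        Q = (r - 2) * D - rowsum[:, None] - rowsum[None, :]
        iu = np.triu_indices(r, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))  # row-major scan -> lowest (i, j) on ties
        i, j = int(iu[0][k]), int(iu[1][k])
        li = D[i, j] / 2 + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        new = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        dnew = (D[i] + D[j] - D[i, j]) / 2
        keep = [x for x in range(r) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [new]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = clamp((d01 + d02 - d12) / 2)
    l1 = clamp((d01 + d12 - d02) / 2)
    l2 = clamp((d02 + d12 - d01) / 2)
    root = TreeNode(
        children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)]
    )
    return Tree(root=root, negative_branches_clamped=clamped)


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int | None = None,
    subset: Sequence[str] | None = None,
) -> Tree:
    """NJ tree with column-bootstrap support values.

    Alignment columns are resampled with replacement; the NJ tree is rebuilt
    per replicate and each original internal bipartition's support is the
    fraction of replicate trees containing it.
    """
    sub = aln if subset is None else aln.subset(subset)
    tree = nj_tree(pairwise_distance(sub), sub.names)
    parts = tree.bipartitions()
    hits = {key: 0 for key in parts}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        idx = rng.integers(0, sub.n_cols, size=sub.n_cols)
        rep = Alignment(names=list(sub.names), matrix=sub.matrix[:, idx])
        rep_tree = nj_tree(pairwise_distance(rep), rep.names)
        rep_parts = set(rep_tree.bipartitions())
        for key in hits:
            if key in rep_parts:
                hits[key] += 1
    for key, node in parts.items():
        node.support = hits[key] / replicates
    return tree
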