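"""Protein-distance phylogenetics with jackknife support.

A native re-implementation of the classic distance pipeline for protein
alignments: column-jackknife resampling, pairwise-deletion p-distances with
Kimura's divergence correction d = -ln(1 - p - p^2/5), neighbor joining
(Q-criterion agglomeration with Studier-Keppler branch lengths), greedy
majority-rule consensus of the replicate trees, and outgroup rooting.  Trees
are handled as dendropy objects (newick I/O, rerooting); the algorithms
themselves are implemented here.

The substitution model behind the published distances is not restated by the
pipeline's sources, so the Kimura-corrected p-distance is the default; the
uncorrected p-distance is available via ``model="p"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "MSA",
    "DistanceMatrix",
    "KIMURA_P_MAX",
    "KIMURA_D_CAP",
    "protein_distance",
    "neighbor_joining",
    "jackknife_msa",
    "tree_bipartitions",
    "majority_consensus",
    "root_with_outgroup",
    "run_pipeline",
]

AA_GAP_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")

#: p beyond which Kimura's correction argument 1 - p - p^2/5 is <= 0.
KIMURA_P_MAX = (np.sqrt(1.8) - 1.0) / 0.4
#: distance assigned (with a warning) when the correction leaves its domain.
KIMURA_D_CAP = 10.0


@dataclass(frozen=True)
class MSA:
    """A protein multiple alignment: unique taxon ids, equal-length rows, gap '-'."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        seqs = tuple(s.upper() for s in self.seqs)
        if len(ids) != len(seqs):
            raise ValueError("ids and sequences must match in number")
        if len(set(ids)) != len(ids):
            raise ValueError("taxon ids must be unique")
        if seqs:
            length = len(seqs[0])
            if any(len(s) != length for s in seqs):
                raise ValueError("aligned sequences must have equal length")
            bad = set("".join(seqs)) - AA_GAP_ALPHABET
            if bad:
                raise ValueError(f"invalid alignment letters: {sorted(bad)}")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "seqs", seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __len__(self) -> int:
        return len(self.ids)

    def to_fasta(self, path_or_buf) -> None:
        text = "".join(f">{i}\n{s}\n" for i, s in zip(self.ids, self.seqs))
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_fasta(cls, path_or_buf) -> "MSA":
        from Bio import SeqIO
        handle = path_or_buf if hasattr(path_or_buf, "read") else open(path_or_buf)
        try:
            records = list(SeqIO.parse(handle, "fasta"))
        finally:
            if handle is not path_or_buf:
                handle.close()
        return cls(tuple(r.id for r in records), tuple(str(r.seq) for r in records))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative taxon-by-taxon distances with zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        m = np.asarray(self.matrix, dtype=float)
        n = len(ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape must match taxon count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "matrix", m)


def protein_distance(msa: MSA, model: str = "kimura") -> DistanceMatrix:
    """Pairwise protein distances with pairwise deletion of gaps.

    ``p`` is mismatches over ungapped overlap columns; ``kimura`` applies
    d = -ln(1 - p - p^2/5), capped at ``KIMURA_D_CAP`` (with a warning) when
    p >= 0.8541 puts the correction outside its domain.  A pair with zero
    ungapped overlap is an error.
    """
    if model not in ("p", "kimura"):
        raise ValueError("model must be 'p' or 'kimura'")
    n = len(msa)
    arr = np.array([list(s) for s in msa.seqs])
    gap = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            overlap = ~gap[i] & ~gap[j]
            n_overlap = int(overlap.sum())
            if n_overlap == 0:
                raise ValueError(f"no ungapped overlap between {msa.ids[i]!r} "
                                 f"and {msa.ids[j]!r}")
            p = float(np.sum(arr[i, overlap] != arr[j, overlap])) / n_overlap
            if model == "p":
                dist = p
            else:
                arg = 1.0 - p - 0.2 * p * p
                if arg <= 0.0:
                    warnings.warn(f"p = {p:.3f} outside the Kimura correction domain; "
                                  f"capping distance at {KIMURA_D_CAP}")
                    dist = KIMURA_D_CAP
                else:
                    dist = float(-np.log(arg))
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(msa.ids, d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _quote(label: str) -> str:
    return f"'{label}'" if any(c in label for c in " (),:;'") else label


def nj_newick(dm: DistanceMatrix) -> str:
    """Neighbor joining; returns the unrooted tree as a newick string.

    Standard Saitou-Nei agglomeration on the Q criterion with Studier-Keppler
    branch lengths; ties break on the smallest (i, j) index pair.  Negative
    branch lengths are clamped to zero with the deficit shifted to the sister
    edge, so path lengths through each join are preserved.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes = [_quote(t) for t in dm.ids]

    def clamp_pair(bi: float, bj: float) -> tuple[float, float]:
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        return max(bi, 0.0), max(bj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) with i < j on ties: row-major argmin over upper triangle
        iu = np.triu_indices(m, k=1)
        k = int(np.argmin(q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        bi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = d[i, j] - bi
        bi, bj = clamp_pair(bi, bj)
        merged = f"({nodes[i]}:{bi:.12g},{nodes[j]}:{bj:.12g})"
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k2 for k2 in range(m) if k2 not in (i, j)]
        d_next = np.empty((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = dnew[keep]
        d_next[-1, -1] = 0.0
        d = d_next
        nodes = [nodes[k2] for k2 in keep] + [merged]

    b0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    b2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    b0, b1, b2 = (max(b, 0.0) for b in (b0, b1, b2))
    return f"({nodes[0]}:{b0:.12g},{nodes[1]}:{b1:.12g},{nodes[2]}:{b2:.12g});"


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining returning an unrooted dendropy tree."""
    tree = dendropy.Tree.get(data=nj_newick(dm), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# jackknife, consensus, rooting
# ---------------------------------------------------------------------------

def jackknife_msa(msa: MSA, delete_fraction: float = 0.5,
                  seed: int = 0) -> MSA:
    """A jackknife replicate: a random ordered subset of alignment columns.

    Keeps ``round((1 - f) * L)`` columns sampled without replacement, original
    order preserved.
    """
    if not (0.0 < delete_fraction < 1.0):
        raise ValueError("delete_fraction must be in (0, 1)")
    n_keep = int(round((1.0 - delete_fraction) * msa.length))
    if n_keep == 0:
        raise ValueError("jackknife would delete every column")
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(msa.length, size=n_keep, replace=False))
    return MSA(msa.ids, tuple("".join(s[c] for c in cols) for s in msa.seqs))


def tree_bipartitions(tree: dendropy.Tree,
                      taxa: Sequence[str] | None = None) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets on the side excluding the
    lexicographically first taxon (a rooting-independent normal form)."""
    labels = sorted(taxa if taxa is not None
                    else (leaf.taxon.label for leaf in tree.leaf_node_iter()))
    ref = labels[0]
    all_taxa = frozenset(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = all_taxa - below if ref in below else below
        if 2 <= len(side) <= len(all_taxa) - 2:
            splits.add(side)
    return splits


def majority_consensus(trees: Sequence[dendropy.Tree],
                       threshold: float = 0.5) -> dendropy.Tree:
    """Greedy majority-rule consensus with bipartition frequencies as support.

    Bipartitions occurring in more than ``threshold`` of the input trees are
    assembled in order of decreasing frequency, skipping any that conflict
    with those already accepted (never triggered for threshold >= 0.5, where
    majority bipartitions are mutually compatible).  Support values are stored
    as internal-node labels; the consensus carries no branch lengths.
    """
    if not trees:
        raise ValueError("need at least one tree")
    taxa_sets = [frozenset(leaf.taxon.label for leaf in t.leaf_node_iter())
                 for t in trees]
    if len(set(taxa_sets)) != 1:
        raise ValueError("all trees must share one taxon set")
    labels = sorted(taxa_sets[0])
    ref = labels[0]
    universe = frozenset(labels)

    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for split in tree_bipartitions(t, labels):
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    kept = [(c / n, s) for s, c in counts.items() if c / n > threshold]
    kept.sort(key=lambda x: (-x[0], len(x[1]), sorted(x[1])))

    def compatible(s: frozenset, t: frozenset) -> bool:
        return (not (s & t)) or s <= t or t <= s or (s | t) == universe - {ref}

    accepted: list[tuple[float, frozenset[str]]] = []
    for freq, split in kept:
        if all(compatible(split, s) for _, s in accepted):
            accepted.append((freq, split))

    # assemble newick by containment nesting on the ref-excluded clusters
    support = {split: freq for freq, split in accepted}
    clusters = sorted((s for _, s in accepted), key=len)

    def children_of(parent: frozenset[str] | None) -> tuple[list, list]:
        """Clusters and leaves whose smallest strict container is `parent`."""
        inside = universe - {ref} if parent is None else parent
        subclusters = []
        for c in clusters:
            if c == parent or not c < inside:
                continue
            container = min((o for o in clusters if c < o), key=len, default=None)
            if container == parent or (parent is None and container is None):
                subclusters.append(c)
        claimed = set().union(*subclusters) if subclusters else set()
        leaves = sorted(inside - claimed)
        return subclusters, leaves

    def render(cluster: frozenset[str]) -> str:
        subs, leaves = children_of(cluster)
        parts = [render(c) for c in sorted(subs, key=lambda s: sorted(s))]
        parts += [_quote(l) for l in leaves]
        return f"({','.join(parts)}){support[cluster]:.6g}"

    top_subs, top_leaves = children_of(None)
    parts = [_quote(ref)]
    parts += [render(c) for c in sorted(top_subs, key=lambda s: sorted(s))]
    parts += [_quote(l) for l in top_leaves]
    newick = f"({','.join(parts)});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    tree.is_rooted = False
    return tree


def root_with_outgroup(tree: dendropy.Tree, taxon_id: str) -> dendropy.Tree:
    """Root a tree at the midpoint of the outgroup's pendant edge."""
    rooted = tree.clone(depth=1)
    leaf = None
    for node in rooted.leaf_node_iter():
        if node.taxon.label == taxon_id:
            leaf = node
            break
    if leaf is None:
        raise ValueError(f"taxon {taxon_id!r} not in tree")
    root = rooted.seed_node
    if (rooted.is_rooted and len(root.child_nodes()) == 2
            and leaf in root.child_nodes()):
        return rooted  # already rooted on this pendant edge
    edge = leaf.edge
    if edge.length is None:
        rooted.reroot_at_edge(edge, update_bipartitions=False)
    else:
        half = edge.length / 2.0
        rooted.reroot_at_edge(edge, length1=half, length2=half,
                              update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def run_pipeline(msa: MSA, n_replicates: int = 100,
                 delete_fraction: float = 0.5,
                 outgroup: str | None = None,
                 seed: int = 0,
                 model: str = "kimura",
                 threshold: float = 0.5) -> dendropy.Tree:
    """Jackknife -> distances -> NJ -> majority consensus -> optional rooting.

    Deterministic for a fixed seed (replicate seeds are spawned from it);
    supports are jackknife bipartition frequencies stored as internal labels.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    trees = []
    for ss in child_seeds:
        rep = jackknife_msa(msa, delete_fraction,
                            seed=int(ss.generate_state(1)[0] % (2**31)))
        trees.append(neighbor_joining(protein_distance(rep, model=model)))
    consensus = majority_consensus(trees, threshold=threshold)
    if outgroup is not None:
        consensus = root_with_outgroup(consensus, outgroup)
    return consensus
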