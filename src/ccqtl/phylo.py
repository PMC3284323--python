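"""Distance trees for candidate regions.

Shared-ancestry regions are characterized phylogenetically by
concatenating the founders' SNP alleles across the region (het/missing
sites dropped), computing pairwise p-distances, and building a
neighbor-joining tree with site-bootstrap support values.  Distance trees
are a fully specified, fast alternative to model-based maximum likelihood;
for the qualitative pattern these regions exhibit (a tight clade of
functionally grouped founders, wild-derived strains on long branches) the
topology and supports carry the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, FounderPanel


@dataclass
class SnpAlignment:
    """Concatenated biallelic SNP alleles per founder for one region."""

    names: list[str]
    matrix: np.ndarray  # (n_taxa, n_sites) of 0/1
    positions: np.ndarray  # retained site bp positions

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise ValueError("matrix must be n_taxa x n_sites")
        if self.matrix.shape[1] == 0:
            raise ValueError("alignment has zero retained sites")

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[1])

    def to_fasta(self) -> str:
        """0/1 columns rendered as A/G characters (arbitrary but fixed)."""
        alpha = np.array(["A", "G"])
        out = []
        for name, row in zip(self.names, self.matrix):
            out.append(f">{name}\n" + "".join(alpha[row]))
        return "\n".join(out) + "\n"


@dataclass
class TreeResult:
    newick: str
    names: list[str]
    bipartitions: dict[frozenset[str], float]  # branch lengths of internal edges
    supports: dict[frozenset[str], float] = field(default_factory=dict)
    n_bootstraps: int = 0
    clamped_negative: bool = False


def build_alignment(
    panel: FounderPanel, region: tuple[str, int, int]
) -> SnpAlignment:
    """Alignment of the eight founders over a region, in SNP order.

    Sites where any founder is heterozygous or missing are omitted; an
    interval with no retained site is an error.
    """
    chrom, start, end = region
    mask = panel.region_mask(chrom, start, end)
    sites = np.flatnonzero(mask)
    keep = (panel.genotypes[:, sites] != MISSING).all(axis=0)
    sites = sites[keep]
    if sites.size == 0:
        raise ValueError(f"no fully called sites in {chrom}:{start}-{end}")
    return SnpAlignment(
        names=list(panel.founder_names),
        matrix=panel.genotypes[:, sites],
        positions=panel.pos[sites],
    )


def distance_matrix(alignment: SnpAlignment) -> np.ndarray:
    """Pairwise p-distances (mismatch fractions); symmetric, zero diagonal."""
    X = alignment.matrix.astype(np.int16)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = (X != X[i]).mean(axis=1)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("children", "name", "tipset")

    def __init__(self, name=None, children=None, tipset=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)
        self.tipset = tipset


def _nj_root(D: np.ndarray, names: list[str]) -> tuple[_Node, bool]:
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [_Node(name=nm, tipset=frozenset([nm])) for nm in names]
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n
    store: dict[int, _Node] = {i: nodes[i] for i in range(n)}
    clamped = False

    def d(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(
            children=[(store[i], li), (store[j], lj)],
            tipset=store[i].tipset | store[j].tipset,
        )
        store[next_id] = new
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = 0.5 * (
                d(i, k) + d(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # join the last three nodes at an unrooted trifurcation
    i, j, k = active
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    if min(li, lj, lk) < 0:
        clamped = True
        li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    root = _Node(
        children=[(store[i], li), (store[j], lj), (store[k], lk)],
        tipset=store[i].tipset | store[j].tipset | store[k].tipset,
    )
    return root, clamped


def _collect_bipartitions(root: _Node, all_tips: frozenset[str]):
    bipartitions: dict[frozenset[str], float] = {}

    def collect(node):
        for child, bl in node.children:
            if child.children:
                bipartitions[_canonical(child.tipset, all_tips)] = bl
            collect(child)

    collect(root)
    return bipartitions


def nj_tree(D: np.ndarray, names: list[str]) -> TreeResult:
    """Neighbor joining (Saitou-Nei with the Studier-Keppler Q criterion).

    Produces an unrooted tree written as a trifurcating newick.  Negative
    branch-length estimates are clamped to 0 and flagged.  NJ is
    consistent: if ``D`` is an additive tree metric the generating topology
    is recovered exactly.
    """
    root, clamped = _nj_root(D, names)
    return TreeResult(
        newick=_to_newick(root) + ";",
        names=list(names),
        bipartitions=_collect_bipartitions(root, frozenset(names)),
        clamped_negative=clamped,
    )


def _canonical(side: frozenset[str], all_tips: frozenset[str]) -> frozenset[str]:
    """Orient a bipartition to the side not containing the first tip name."""
    anchor = min(all_tips)
    return all_tips - side if anchor in side else side


def _to_newick(node: _Node, support: dict | None = None, all_tips=None) -> str:
    if not node.children:
        return node.name
    parts = []
    for child, bl in node.children:
        label = _to_newick(child, support, all_tips)
        if child.children and support is not None:
            key = _canonical(child.tipset, all_tips)
            label += f"{support.get(key, 0.0):.0f}"
        parts.append(f"{label}:{bl:.6g}")
    return "(" + ",".join(parts) + ")"


def tree_bipartitions(tree: TreeResult) -> set[frozenset[str]]:
    """Internal-edge bipartitions (canonical side) of a tree."""
    return set(tree.bipartitions)


def bootstrap_support(
    alignment: SnpAlignment, n: int = 100, seed: int | None = None
) -> TreeResult:
    """NJ tree with site-bootstrap supports.

    Columns are resampled with replacement ``n`` times; the support of each
    internal branch of the full-alignment tree is the percentage of
    replicate trees containing the same bipartition.  Supports are written
    into the newick as internal-node labels.
    """
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    D = distance_matrix(alignment)
    tree = nj_tree(D, alignment.names)
    counts = {bp: 0 for bp in tree.bipartitions}
    S = alignment.n_sites
    for _ in range(n):
        cols = rng.integers(0, S, size=S)
        rep = SnpAlignment(
            names=alignment.names,
            matrix=alignment.matrix[:, cols],
            positions=alignment.positions[cols],
        )
        rep_tree = nj_tree(distance_matrix(rep), rep.names)
        rep_bps = tree_bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n for bp, c in counts.items()}

    root, clamped = _nj_root(D, alignment.names)
    all_tips = frozenset(alignment.names)
    newick = _to_newick(root, support=supports, all_tips=all_tips) + ";"
    return TreeResult(
        newick=newick,
        names=list(alignment.names),
        bipartitions=dict(tree.bipartitions),
        supports=supports,
        n_bootstraps=n,
        clamped_negative=clamped,
    )
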