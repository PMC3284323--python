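"""Shared-ancestry narrowing of QTL intervals.

The core idea: if a QTL is biallelic, the founders carrying the same
functional allele should descend from a common ancestral haplotype
somewhere in the confidence interval.  Founders are first bipartitioned by
their estimated allele effects (split at the greatest gap between ordered
effects); the interval is then scanned for maximal runs of SNPs over which
the grouped founders are nearly identical (>98% by default), optionally
requiring that no out-group founder matches the group consensus.  Where no
multi-founder group exists, SNPs private to a single founder (or founder
set) serve the same purpose.  The payoff is reported as the percent
reduction from the full confidence interval to the candidate region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree
import numpy as np

from .core import MISSING, FounderPanel
from .scan import interval_size_mb


@dataclass
class Grouping:
    """Bipartition of the eight founders by allele effect."""

    group_a: frozenset[str]  # higher-effect side
    group_b: frozenset[str]
    ambiguous: frozenset[str] = frozenset()
    split_gap: float = 0.0
    tie: bool = False

    def __post_init__(self) -> None:
        self.group_a = frozenset(self.group_a)
        self.group_b = frozenset(self.group_b)
        self.ambiguous = frozenset(self.ambiguous)
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be nonempty")
        all_f = self.group_a | self.group_b | self.ambiguous
        if len(all_f) != len(self.group_a) + len(self.group_b) + len(self.ambiguous):
            raise ValueError("groups must be disjoint")


@dataclass
class SharedRegion:
    """A run of SNPs over which a founder group is nearly identical."""

    chrom: str
    start: int
    end: int
    group: frozenset[str]
    n_snps: int
    within_identity: float
    cross_identity: float
    exclusive: bool

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass
class ReductionReport:
    full_start: int
    full_end: int
    candidate_start: int
    candidate_end: int
    n_genes_before: int | None = None
    n_genes_after: int | None = None

    def __post_init__(self) -> None:
        if not (self.full_start <= self.candidate_start
                and self.candidate_end <= self.full_end):
            raise ValueError("candidate region must lie within the full interval")

    @property
    def full_size_mb(self) -> float:
        return interval_size_mb(self.full_start, self.full_end)

    @property
    def candidate_size_mb(self) -> float:
        return interval_size_mb(self.candidate_start, self.candidate_end)

    @property
    def candidate_size_kb(self) -> float:
        return float(np.floor((self.candidate_end - self.candidate_start) / 1e3 + 0.5))

    @property
    def percent_reduction(self) -> float:
        return percent_reduction(self.full_size_mb, self.candidate_size_mb)


def percent_reduction(full_size: float, candidate_size: float) -> float:
    """100 * (1 - candidate/full), rounded half-up to the nearest percent."""
    if candidate_size > full_size:
        raise ValueError("candidate larger than full interval")
    if full_size <= 0:
        raise ValueError("full interval size must be positive")
    pct = 100.0 * (1.0 - candidate_size / full_size)
    return float(np.floor(pct + 0.5))


def group_alleles(
    effects: np.ndarray,
    founder_names: list[str] | None = None,
    ambiguity_ratio: float = 0.5,
) -> Grouping:
    """Bipartition founders at the greatest gap between ordered effects.

    The eight effects are sorted and split where consecutive ordered values
    differ most; ties across the maximal gap break to the lowest-index
    split and are flagged.  A founder whose effect sits more than
    ``ambiguity_ratio * split_gap`` from the mean of *both* groups is moved
    to ``ambiguous`` (the intermediate-allele case, treated as a possible
    third allele downstream).
    """
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (8,) or not np.isfinite(effects).all():
        raise ValueError("need 8 finite allele effects")
    if founder_names is None:
        founder_names = [f"F{i}" for i in range(8)]
    order = np.argsort(effects, kind="stable")
    ordered = effects[order]
    gaps = np.diff(ordered)
    if np.allclose(gaps, 0.0):
        raise ValueError("all allele effects equal; no grouping exists")
    split = int(gaps.argmax())  # argmax takes the first maximal gap
    tie = bool((np.isclose(gaps, gaps[split]).sum()) > 1)
    low_idx, high_idx = order[: split + 1], order[split + 1 :]
    split_gap = float(gaps[split])

    mean_low = effects[low_idx].mean()
    mean_high = effects[high_idx].mean()
    ambiguous: set[int] = set()
    for side_idx, own_mean, other_mean in (
        (low_idx, mean_low, mean_high),
        (high_idx, mean_high, mean_low),
    ):
        if len(side_idx) < 2:
            continue
        for i in side_idx:
            if (
                abs(effects[i] - own_mean) > ambiguity_ratio * split_gap
                and abs(effects[i] - other_mean) > ambiguity_ratio * split_gap
            ):
                ambiguous.add(int(i))
    group_b = [founder_names[i] for i in low_idx if i not in ambiguous]
    group_a = [founder_names[i] for i in high_idx if i not in ambiguous]
    return Grouping(
        group_a=frozenset(group_a),
        group_b=frozenset(group_b),
        ambiguous=frozenset(founder_names[i] for i in ambiguous),
        split_gap=split_gap,
        tie=tie,
    )


# ---------------------------------------------------------------------------
# shared-ancestry scan


def _informative_sites(panel: FounderPanel, mask: np.ndarray, members: list[int]):
    """Site indices in ``mask`` where every group member has a homozygous
    call (het/missing positions are omitted from the analysis)."""
    called = (panel.genotypes[members][:, mask] != MISSING).all(axis=0)
    return np.flatnonzero(mask)[called]


def _qualifying_runs(
    geno: np.ndarray, threshold: float, min_snps: int
) -> list[tuple[int, int]]:
    """Maximal anchored runs of near-identity among the group rows.

    A run [i, j] (inclusive site indices into ``geno`` columns, which hold
    0/1 calls for the group members) qualifies when

    * every within-group pairwise identity over the run is >= threshold,
    * it spans at least ``min_snps`` sites, and
    * its first and last sites are full-group matches (boundary
      resolution: a region of shared ancestry cannot begin or end on a
      discordant SNP).

    Runs contained in a longer qualifying run are suppressed.  Uses prefix
    mismatch counts per pair; O(pairs * S^2) worst case, fine at the SNP
    counts a confidence interval holds.
    """
    g, S = geno.shape
    if S == 0:
        return []
    if g < 2:  # single-member group: everything matches itself
        return [(0, S - 1)] if S >= min_snps else []
    pair_mm = []
    for a in range(g):
        for b in range(a + 1, g):
            mm = np.concatenate(([0], np.cumsum(geno[a] != geno[b])))
            pair_mm.append(mm)
    pair_mm = np.vstack(pair_mm)  # (P, S+1)
    anchored = (geno == geno[0]).all(axis=0)

    best_end = np.full(S, -1)
    lengths = np.arange(1, S + 1, dtype=float)
    for i in range(S):
        if not anchored[i]:
            continue
        L = lengths[: S - i]
        mism = pair_mm[:, i + 1 :] - pair_mm[:, i : i + 1]
        ident = 1.0 - mism / L[None, :]
        ok = (ident >= threshold).all(axis=0) & anchored[i:]
        ok[: max(min_snps - 1, 0)] = False  # run length >= min_snps
        hits = np.flatnonzero(ok)
        if hits.size:
            best_end[i] = i + hits[-1]
    runs = []
    best_so_far = -1
    for i in range(S):
        if best_end[i] > best_so_far:
            runs.append((i, int(best_end[i])))
            best_so_far = int(best_end[i])
    return runs


def _min_pairwise_identity(geno: np.ndarray) -> float:
    g = geno.shape[0]
    if g < 2:
        return 1.0
    best = 1.0
    for a in range(g):
        for b in range(a + 1, g):
            best = min(best, float((geno[a] == geno[b]).mean()))
    return best


def shared_ancestry_regions(
    panel: FounderPanel,
    interval: tuple[str, int, int],
    group: frozenset[str] | set[str],
    identity_threshold: float = 0.98,
    min_snps: int = 50,
    out_group: frozenset[str] | set[str] | None = None,
) -> list[SharedRegion]:
    """Maximal regions of near-identity among a founder group.

    Sites where any group member is het/missing are omitted.  A region is a
    maximal run of retained SNPs over which every within-group pairwise
    identity is >= ``identity_threshold``, which spans at least
    ``min_snps`` informative sites, and whose first and last SNPs are
    full-group matches (regions neither begin nor end on a discordant
    site).  Each region is annotated with the
    maximum identity of any out-group founder to the group consensus
    (``cross_identity``); regions where that stays below the threshold are
    flagged ``exclusive`` — candidate regions require the causal group not
    to share ancestry with the other allele group.
    """
    chrom, start, end = interval
    mask = panel.region_mask(chrom, start, end)
    members = sorted(panel.founder_index(n) for n in group)
    if out_group is None:
        out_group = set(panel.founder_names) - set(group)
    out_members = sorted(panel.founder_index(n) for n in out_group)

    sites = _informative_sites(panel, mask, members)
    if sites.size < min_snps:
        warnings.warn(
            f"only {sites.size} informative SNPs in {chrom}:{start}-{end}",
            stacklevel=2,
        )
        return []
    geno = panel.genotypes[np.ix_(members, sites)]
    runs = _qualifying_runs(geno, identity_threshold, min_snps)

    regions = []
    for (i, j) in runs:
        sub = geno[:, i : j + 1]
        # consensus: majority allele per site within the group
        consensus = (sub.mean(axis=0) >= 0.5).astype(np.int8)
        cross = 0.0
        for m in out_members:
            og = panel.genotypes[m, sites[i : j + 1]]
            called = og != MISSING
            if called.sum() == 0:
                continue
            cross = max(cross, float((og[called] == consensus[called]).mean()))
        regions.append(
            SharedRegion(
                chrom=chrom,
                start=int(panel.pos[sites[i]]),
                end=int(panel.pos[sites[j]]),
                group=frozenset(group),
                n_snps=j - i + 1,
                within_identity=_min_pairwise_identity(sub),
                cross_identity=cross,
                exclusive=bool(cross < identity_threshold),
            )
        )
    return regions


def private_snps(
    panel: FounderPanel,
    interval: tuple[str, int, int],
    target: frozenset[str] | set[str],
) -> np.ndarray:
    """SNP indices in the interval private to ``target``.

    A SNP qualifies when every target founder carries one allele, every
    non-target founder carries the other, and no founder is het/missing
    (het/missing disqualifies the site — the conservative omission rule).
    Returns indices into the panel's SNP arrays.
    """
    if not target:
        raise ValueError("target must be nonempty")
    chrom, start, end = interval
    mask = panel.region_mask(chrom, start, end)
    t_idx = sorted(panel.founder_index(n) for n in target)
    o_idx = [i for i in range(8) if i not in t_idx]
    if not o_idx:
        return np.array([], dtype=np.int64)
    sites = np.flatnonzero(mask)
    G = panel.genotypes[:, sites]
    called = (G != MISSING).all(axis=0)
    t_same = (G[t_idx] == G[t_idx[0]]).all(axis=0)
    o_same = (G[o_idx] == G[o_idx[0]]).all(axis=0)
    differs = G[t_idx[0]] != G[o_idx[0]]
    return sites[called & t_same & o_same & differs]


def reduction_report(
    full_interval: tuple[int, int],
    candidate: tuple[int, int] | SharedRegion,
    annotation: "np.ndarray | list[tuple[int, int, str]] | None" = None,
) -> ReductionReport:
    """Summarize the interval reduction achieved by a candidate region.

    ``annotation`` (optional) is a list of (start, end, name) gene
    intervals in bp, half-open, for before/after gene counts.
    """
    if isinstance(candidate, SharedRegion):
        cand = (candidate.start, candidate.end)
    else:
        cand = candidate
    rep = ReductionReport(
        full_start=full_interval[0],
        full_end=full_interval[1],
        candidate_start=cand[0],
        candidate_end=cand[1],
    )
    if annotation is not None:
        genes = [(int(s), int(e), str(n)) for (s, e, n) in annotation]
        rep.n_genes_before = len(candidate_genes(full_interval, genes))
        rep.n_genes_after = len(candidate_genes(cand, genes))
    return rep


def candidate_genes(
    region: tuple[int, int],
    annotation: list[tuple[int, int, str]],
) -> list[str]:
    """Genes overlapping a region under half-open [start, end) semantics.

    ``annotation`` rows are (start, end, name); any overlap counts, an
    interval abutting the region end does not.
    """
    start, end = region
    tree = IntervalTree()
    for (s, e, name) in annotation:
        if e > s:
            tree[s:e] = name
    hits = tree[start:end]
    return sorted({iv.data for iv in hits})
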