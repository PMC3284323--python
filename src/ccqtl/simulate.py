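"""Synthetic eight-founder recombinant inbred data.

The generator emulates the structure of an eight-way recombinant inbred
panel sampled mid-inbreeding: a founder SNP panel with five closely related
"classical" strains and three deeply diverged "wild-derived" strains,
funnel-bred mosaic lines carrying residual heterozygosity after 5-14
generations of sib mating, and quantitative phenotypes driven by planted
biallelic QTL whose functional allele is shared identically by descent
across a subset of founders.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Phylo

from .core import (
    DEFAULT_FOUNDERS,
    MISSING,
    DosageMatrix,
    FounderPanel,
    IntervalSet,
    LineMosaic,
    PhenotypeTable,
    QtlSpec,
)

#: Default founder tree.  Branch lengths are expected substitutions per
#: site under a symmetric two-state model; the five classical strains sit
#: on short branches of one clade, the three wild-derived strains on long
#: branches, so classical-classical SNP identity exceeds classical-wild
#: identity (the genome-wide pattern in real eight-founder panels).
DEFAULT_FOUNDER_TREE = (
    "((((C57BL6J:0.05,NODShiLtJ:0.05):0.01,NZOHlLtJ:0.06):0.01,"
    "(129S1SvImJ:0.05,AJ:0.05):0.02):0.25,"
    "(WSBEiJ:0.20,(PWKPhJ:0.35,CASTEiJ:0.35):0.10):0.10);"
)


@dataclass
class GeneticMap:
    """Uniform recombination map: expected crossovers per bp per meiosis.

    A mouse-like default is ~0.5 cM/Mb, i.e. 5e-9 crossovers per bp.
    """

    rate_per_bp: float = 5e-9
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate_per_bp < 0:
            raise ValueError("recombination rate must be >= 0")


def simulate_founders(
    n_snps: int,
    tree: str = DEFAULT_FOUNDER_TREE,
    mutation_scale: float = 1.0,
    chrom_lengths: dict[str, int] | None = None,
    seed: int | None = None,
) -> FounderPanel:
    """Simulate a biallelic founder SNP panel along a fixed strain tree.

    Each site starts from a Bernoulli(1/2) root allele and flips along every
    branch with probability ``(1 - exp(-2 * mutation_scale * t)) / 2`` (the
    symmetric two-state substitution model), so divergence 0 yields identical
    founders and long branches approach 50% identity.

    Parameters
    ----------
    n_snps:
        Number of SNP sites, spread uniformly over ``chrom_lengths``.
    tree:
        Newick with branch lengths; tip labels become the founder names.
    mutation_scale:
        Global multiplier on branch lengths.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if mutation_scale < 0:
        raise ValueError("mutation_scale must be >= 0")
    if chrom_lengths is None:
        chrom_lengths = {"1": 100_000_000}
    rng = np.random.default_rng(seed)

    phylo_tree = Phylo.read(_io.StringIO(tree), "newick")
    tips = phylo_tree.get_terminals()
    if len(tips) != 8:
        raise ValueError(f"founder tree must have 8 tips, got {len(tips)}")
    for clade in phylo_tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            raise ValueError("branch lengths must be non-negative")

    # evolve alleles down the tree, vectorized over sites
    alleles: dict[int, np.ndarray] = {}
    root = phylo_tree.root
    alleles[id(root)] = rng.integers(0, 2, size=n_snps, dtype=np.int8)
    tip_alleles: dict[str, np.ndarray] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        a = alleles.pop(id(node))
        if node.is_terminal():
            tip_alleles[node.name] = a
            continue
        for child in node.clades:
            t = (child.branch_length or 0.0) * mutation_scale
            p_flip = 0.5 * (1.0 - np.exp(-2.0 * t))
            flips = rng.random(n_snps) < p_flip
            alleles[id(child)] = np.where(flips, 1 - a, a).astype(np.int8)
            stack.append(child)

    founder_names = [t.name for t in tips]
    genotypes = np.vstack([tip_alleles[n] for n in founder_names])

    # assign positions: proportional share of sites per chromosome, sorted
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    counts = {c: int(round(n_snps * chrom_lengths[c] / total)) for c in chroms}
    drift = n_snps - sum(counts.values())
    counts[chroms[0]] += drift
    chrom_col, pos_col = [], []
    for c in chroms:
        k = counts[c]
        if k == 0:
            continue
        pos = np.sort(rng.choice(chrom_lengths[c], size=k, replace=False)) + 1
        chrom_col.extend([c] * k)
        pos_col.append(pos)
    return FounderPanel(
        founder_names=founder_names,
        chrom=np.array(chrom_col, dtype=object),
        pos=np.concatenate(pos_col),
        genotypes=genotypes,
        chrom_lengths=dict(chrom_lengths),
        true_tree=tree,
    )


def plant_ibd_block(
    panel: FounderPanel,
    chrom: str,
    start: int,
    end: int,
    founders: set[str] | frozenset[str],
    source: str | None = None,
) -> FounderPanel:
    """Copy one founder's haplotype across a block to a set of founders.

    Emulates identity by descent: the returned panel has every founder in
    ``founders`` carrying ``source``'s alleles (default: the first member)
    at all SNPs in ``chrom:start-end``, so a functional allele planted on
    that group is genuinely shared ancestry, detectable downstream.
    """
    idx = [panel.founder_index(n) for n in founders]
    if source is None:
        source = sorted(founders, key=panel.founder_index)[0]
    src = panel.founder_index(source)
    mask = panel.region_mask(chrom, start, end)
    genotypes = panel.genotypes.copy()
    genotypes[np.ix_(idx, np.flatnonzero(mask))] = panel.genotypes[src, mask]
    return FounderPanel(
        founder_names=list(panel.founder_names),
        chrom=panel.chrom,
        pos=panel.pos,
        genotypes=genotypes,
        chrom_lengths=dict(panel.chrom_lengths),
        true_tree=panel.true_tree,
    )


# ---------------------------------------------------------------------------
# funnel breeding


def _meiosis(hap_a, hap_b, length, rate, rng):
    """One gamete from a pair of haplotypes (breakpoint-list representation)."""
    n_co = rng.poisson(rate * length)
    if n_co == 0:
        return list(hap_a if rng.random() < 0.5 else hap_b)
    cuts = np.sort(rng.integers(1, length, size=n_co))
    # crossovers between cut and cut+1; alternate source haplotype
    haps = (hap_a, hap_b) if rng.random() < 0.5 else (hap_b, hap_a)
    gamete = []
    prev = 1
    which = 0
    bounds = [int(c) for c in cuts] + [length]
    for bound in bounds:
        if bound >= prev:
            gamete.extend(_slice_hap(haps[which], prev, bound))
            prev = bound + 1
        which = 1 - which
    return _merge_runs(gamete)


def _slice_hap(hap, start, end):
    out = []
    for (s, e, f) in hap:
        if e < start or s > end:
            continue
        out.append((max(s, start), min(e, end), f))
    return out


def _merge_runs(segments):
    merged = [segments[0]]
    for seg in segments[1:]:
        ps, pe, pf = merged[-1]
        if seg[2] == pf and seg[0] == pe + 1:
            merged[-1] = (ps, seg[1], pf)
        else:
            merged.append(seg)
    return merged


def simulate_funnel_line(
    panel: FounderPanel,
    genetic_map: GeneticMap,
    n_inbreeding_gens: int,
    seed: int | None = None,
    line_id: str = "line",
) -> LineMosaic:
    """Breed one mosaic inbred line through a randomized eight-way funnel.

    Three generations of crossing mix the eight founders into a single
    individual's genome (four F1s, two four-way G2s, one eight-way G2:F1
    sibship), followed by ``n_inbreeding_gens`` generations of brother-sister
    mating.  Crossovers are a Poisson process on the genetic map with no
    interference.  The funnel order is shuffled per line, emulating
    independently derived lines.
    """
    if n_inbreeding_gens < 0:
        raise ValueError("n_inbreeding_gens must be >= 0")
    rng = np.random.default_rng(seed)
    chrom_lengths = {c: genetic_map.chrom_lengths.get(c, panel.chrom_lengths[c])
                     for c in panel.chrom_lengths}
    order = rng.permutation(8)

    haplotypes: dict[str, tuple[list, list]] = {}
    for chrom, length in chrom_lengths.items():
        rate = genetic_map.rate_per_bp
        # individuals are pairs of haplotypes; founders are homozygous
        founders = [[(1, length, int(f))] for f in order]
        f1 = [(founders[2 * i], founders[2 * i + 1]) for i in range(4)]
        g2 = []
        for i in range(2):
            mom, dad = f1[2 * i], f1[2 * i + 1]
            g2.append((_meiosis(*mom, length, rate, rng),
                       _meiosis(*dad, length, rate, rng)))
        # the eight-way sibship: two sibs start the inbreeding pedigree
        pair = []
        for _ in range(2):
            pair.append((_meiosis(*g2[0], length, rate, rng),
                         _meiosis(*g2[1], length, rate, rng)))
        for _ in range(n_inbreeding_gens):
            pair = [
                (_meiosis(*pair[0], length, rate, rng),
                 _meiosis(*pair[1], length, rate, rng))
                for _ in range(2)
            ]
        haplotypes[chrom] = (pair[0][0], pair[0][1])

    mosaic = LineMosaic(line_id=line_id, haplotypes=haplotypes,
                        inbreeding_generations=n_inbreeding_gens)
    mosaic.validate_tiling(chrom_lengths)
    return mosaic


def simulate_panel_lines(
    panel: FounderPanel,
    n_lines: int,
    genetic_map: GeneticMap | None = None,
    gens_range: tuple[int, int] = (5, 14),
    seed: int | None = None,
) -> list[LineMosaic]:
    """Breed ``n_lines`` funnel lines with inbreeding generations drawn
    uniformly from ``gens_range`` (the incipient-panel design: lines are
    sampled after 5-14 generations of inbreeding)."""
    if genetic_map is None:
        genetic_map = GeneticMap(chrom_lengths=dict(panel.chrom_lengths))
    rng = np.random.default_rng(seed)
    lines = []
    for i in range(n_lines):
        gens = int(rng.integers(gens_range[0], gens_range[1] + 1))
        child_seed = int(rng.integers(0, 2**31 - 1))
        lines.append(
            simulate_funnel_line(panel, genetic_map, gens, seed=child_seed,
                                 line_id=f"CC{i + 1:03d}")
        )
    return lines


# ---------------------------------------------------------------------------
# genotyping and truth extraction


def genotype_lines(
    panel: FounderPanel,
    mosaics: list[LineMosaic],
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Call line genotypes (0/1/2 alt-allele counts) from the mosaics.

    Each haplotype contributes the covering founder's allele; sites where the
    covering founder is uncalled propagate ``MISSING``.  With probability
    ``error_rate`` a call is replaced by a uniformly chosen different value,
    and with probability ``missing_rate`` it is dropped.
    """
    rng = np.random.default_rng(seed)
    M = panel.n_snps
    out = np.empty((len(mosaics), M), dtype=np.int8)
    for li, mosaic in enumerate(mosaics):
        geno = np.empty(M, dtype=np.int8)
        for chrom in panel.chromosomes:
            mask = panel.chrom == chrom
            positions = panel.pos[mask]
            tracks = mosaic.founder_tracks(chrom, positions)
            a = panel.genotypes[tracks[0], np.flatnonzero(mask)]
            b = panel.genotypes[tracks[1], np.flatnonzero(mask)]
            g = a + b
            g[(a == MISSING) | (b == MISSING)] = MISSING
            geno[mask] = g
        out[li] = geno
    if error_rate > 0:
        flip = (rng.random(out.shape) < error_rate) & (out != MISSING)
        shift = rng.integers(1, 3, size=out.shape)
        out[flip] = ((out[flip] + shift[flip]) % 3).astype(np.int8)
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = MISSING
    return out


def true_dosages(
    panel: FounderPanel, mosaics: list[LineMosaic], positions: pd.DataFrame | None = None
) -> tuple[IntervalSet, np.ndarray]:
    """Exact founder dosages from the simulated mosaics.

    Dosages are evaluated at the panel's SNPs (or at ``positions`` with
    columns chrom/pos); the returned intervals tile each chromosome with
    midpoint boundaries between adjacent loci, the convention for
    marker-based mapping intervals.  The ``(n_lines, n_loci, 8)`` array is
    the ground truth the ancestry HMM estimates.
    """
    if positions is None:
        chroms, pos = panel.chrom, panel.pos
    else:
        chroms = positions["chrom"].to_numpy(dtype=object)
        pos = positions["pos"].to_numpy()
    n_loci = len(pos)
    X = np.zeros((len(mosaics), n_loci, 8))
    starts = np.empty(n_loci, dtype=np.int64)
    ends = np.empty(n_loci, dtype=np.int64)
    for chrom in dict.fromkeys(chroms):
        mask = chroms == chrom
        idx = np.flatnonzero(mask)
        p = pos[idx]
        mid = (p[:-1] + p[1:]) // 2
        starts[idx] = np.concatenate(([1], mid + 1))
        ends[idx] = np.concatenate((mid, [panel.chrom_lengths[chrom]]))
    for li, mosaic in enumerate(mosaics):
        for chrom in dict.fromkeys(chroms):
            mask = chroms == chrom
            tracks = mosaic.founder_tracks(chrom, pos[mask])
            idx = np.flatnonzero(mask)
            for h in range(2):
                X[li, idx, tracks[h]] += 1.0
    intervals = IntervalSet(
        pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    )
    return intervals, X


def heterozygous_fraction(mosaic: LineMosaic, chrom_lengths: dict[str, int]) -> float:
    """bp fraction of the genome where the two haplotypes carry different
    founders (residual heterozygosity by descent)."""
    het = 0
    total = 0
    for chrom, length in chrom_lengths.items():
        hap_a, hap_b = mosaic.haplotypes[chrom]
        bounds = sorted({e for (_, e, _) in hap_a} | {e for (_, e, _) in hap_b})
        prev = 1
        ia = ib = 0
        for bound in bounds:
            while hap_a[ia][1] < bound:
                ia += 1
            while hap_b[ib][1] < bound:
                ib += 1
            if hap_a[ia][2] != hap_b[ib][2]:
                het += bound - prev + 1
            prev = bound + 1
        total += length
    return het / total


# ---------------------------------------------------------------------------
# phenotypes


def assign_phenotypes(
    panel: FounderPanel,
    mosaics: list[LineMosaic],
    qtl_specs: list[QtlSpec],
    noise_sd: float | None = None,
    baseline: float = 0.0,
    trait: str = "trait",
    units: str = "au",
    seed: int | None = None,
) -> PhenotypeTable:
    """Assign one trait value per line from planted QTL plus Gaussian noise.

    A line carrying 0, 1 or 2 haplotypes from a QTL's functional founder
    group is shifted by 0, ``dominance * effect`` or ``effect``.  When
    ``noise_sd`` is None the first QTL's ``h2_target`` sets it so that the
    realized genetic variance fraction matches the target; the realized
    heritability is recorded either way.
    """
    rng = np.random.default_rng(seed)
    for spec in qtl_specs:
        spec.validate_against(panel)
    genetic = np.zeros(len(mosaics))
    for spec in qtl_specs:
        group_idx = {panel.founder_index(n) for n in spec.functional_group}
        for li, mosaic in enumerate(mosaics):
            fa, fb = mosaic.founders_at(spec.chrom, spec.pos)
            copies = (fa in group_idx) + (fb in group_idx)
            if copies == 2:
                genetic[li] += spec.effect_size
            elif copies == 1:
                genetic[li] += spec.dominance * spec.effect_size
    if noise_sd is None:
        targets = [s.h2_target for s in qtl_specs if s.h2_target is not None]
        if not targets:
            raise ValueError("noise_sd not given and no QTL has h2_target")
        h2 = targets[0]
        var_g = float(np.var(genetic))
        noise_sd = float(np.sqrt(var_g * (1.0 - h2) / h2)) if h2 < 1 else 0.0
    noise = rng.normal(0.0, noise_sd, size=len(mosaics)) if noise_sd > 0 else 0.0
    values = baseline + genetic + noise
    var_g = float(np.var(genetic))
    var_tot = float(np.var(values))
    data = pd.DataFrame(
        {"line_id": [m.line_id for m in mosaics], "trait": trait, "value": values}
    )
    return PhenotypeTable(
        data=data,
        units={trait: units},
        realized_h2={trait: var_g / var_tot if var_tot > 0 else 1.0},
    )
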