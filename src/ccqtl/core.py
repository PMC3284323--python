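"""Core data containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package; BED output
is converted to 0-based half-open at write time.  Genotypes are coded as the
count of the alternate allele: founders (fully inbred) carry 0 or 1 per
haplotype, lines carry 0/1/2, and ``MISSING`` (-1) marks no-calls and
heterozygous founder calls that policy treats as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Conventional founder labels for an eight-way recombinant inbred panel:
#: five classical inbred strains followed by three wild-derived strains.
DEFAULT_FOUNDERS = (
    "C57BL6J",
    "129S1SvImJ",
    "AJ",
    "NODShiLtJ",
    "NZOHlLtJ",
    "WSBEiJ",
    "PWKPhJ",
    "CASTEiJ",
)

CLASSICAL_FOUNDERS = DEFAULT_FOUNDERS[:5]
WILD_FOUNDERS = DEFAULT_FOUNDERS[5:]


@dataclass
class FounderPanel:
    """Biallelic SNP calls for the eight founder strains.

    Attributes
    ----------
    founder_names:
        Exactly eight strain labels.
    chrom, pos:
        Per-SNP chromosome label and 1-based bp position; positions must be
        strictly increasing within each chromosome.
    genotypes:
        ``(8, M)`` array over ``{0, 1, MISSING}`` (haploid calls; founders
        are inbred, heterozygous calls are stored as ``MISSING``).
    chrom_lengths:
        bp length per chromosome (used by the simulator; for panels read
        from disk it defaults to the last SNP position).
    true_tree:
        Optional newick string recording the generating founder tree.
    """

    founder_names: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    true_tree: str | None = None

    def __post_init__(self) -> None:
        self.founder_names = list(self.founder_names)
        if len(self.founder_names) != 8:
            raise ValueError(f"expected 8 founders, got {len(self.founder_names)}")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (8, self.pos.size):
            raise ValueError("genotypes must be 8 x M")
        bad = ~np.isin(self.genotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("founder genotypes must be 0, 1 or MISSING")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")
        if not self.chrom_lengths:
            self.chrom_lengths = {
                c: int(self.pos[self.chrom == c].max()) for c in self.chromosomes
            }

    @property
    def n_snps(self) -> int:
        return int(self.pos.size)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def founder_index(self, name: str) -> int:
        return self.founder_names.index(name)

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of SNPs with ``start <= pos <= end`` on ``chrom``."""
        return (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)


@dataclass
class LineMosaic:
    """Founder mosaic of one inbred line: two haplotypes per chromosome.

    ``haplotypes[chrom]`` is a pair of segment lists; each segment is
    ``(start_bp, end_bp, founder_index)`` with 1-based inclusive bounds.
    Segments must tile the chromosome without gaps or overlaps.
    """

    line_id: str
    haplotypes: dict[str, tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]]
    inbreeding_generations: int = 0

    def __post_init__(self) -> None:
        if self.inbreeding_generations < 0:
            raise ValueError("inbreeding_generations must be >= 0")

    def validate_tiling(self, chrom_lengths: dict[str, int]) -> None:
        for chrom, haps in self.haplotypes.items():
            length = chrom_lengths[chrom]
            for hap in haps:
                if hap[0][0] != 1 or hap[-1][1] != length:
                    raise ValueError(f"{self.line_id}:{chrom} does not span chromosome")
                for (s, e, f) in hap:
                    if not (1 <= s <= e <= length):
                        raise ValueError("bad segment bounds")
                    if not (0 <= f < 8):
                        raise ValueError(f"unknown founder index {f}")
                for prev, nxt in zip(hap, hap[1:]):
                    if nxt[0] != prev[1] + 1:
                        raise ValueError("segments do not tile contiguously")

    def founders_at(self, chrom: str, pos: int) -> tuple[int, int]:
        """Founder index on each haplotype covering ``pos``."""
        out = []
        for hap in self.haplotypes[chrom]:
            for (s, e, f) in hap:
                if s <= pos <= e:
                    out.append(f)
                    break
            else:
                raise ValueError(f"position {chrom}:{pos} not covered")
        return out[0], out[1]

    def founder_tracks(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """``(2, len(positions))`` founder indices along both haplotypes."""
        tracks = np.empty((2, positions.size), dtype=np.int8)
        for h, hap in enumerate(self.haplotypes[chrom]):
            ends = np.array([e for (_, e, _) in hap])
            founders = np.array([f for (_, _, f) in hap], dtype=np.int8)
            idx = np.searchsorted(ends, positions)
            tracks[h] = founders[idx]
        return tracks


@dataclass
class QtlSpec:
    """A planted biallelic QTL.

    The functional ("high") allele is carried identically by descent by the
    founders in ``functional_group``; lines carrying 0/1/2 functional
    haplotypes get trait shifts of 0, ``dominance * effect_size`` and
    ``effect_size``.  ``dominance = 0.5`` gives the partially dominant,
    intermediate-heterozygote architecture; 0 makes heterozygotes
    indistinguishable from non-carriers.
    """

    chrom: str
    pos: int
    functional_group: frozenset[str]
    effect_size: float
    dominance: float = 0.5
    h2_target: float | None = None

    def __post_init__(self) -> None:
        self.functional_group = frozenset(self.functional_group)
        if not self.functional_group:
            raise ValueError("functional_group must be nonempty")
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must be in [0, 1]")
        if self.h2_target is not None and not 0.0 < self.h2_target <= 1.0:
            raise ValueError("h2_target must be in (0, 1]")

    def validate_against(self, panel: FounderPanel) -> None:
        unknown = self.functional_group - set(panel.founder_names)
        if unknown:
            raise ValueError(f"unknown founders in functional_group: {sorted(unknown)}")
        if len(self.functional_group) >= 8:
            raise ValueError("functional_group must be a proper subset of the 8 founders")
        if self.chrom not in panel.chrom_lengths:
            raise ValueError(f"QTL chromosome {self.chrom!r} not simulated")
        if not 1 <= self.pos <= panel.chrom_lengths[self.chrom]:
            raise ValueError("QTL position outside chromosome")


@dataclass
class PhenotypeTable:
    """Tidy line x trait phenotype values plus simulation metadata."""

    data: pd.DataFrame  # columns: line_id, trait, value
    units: dict[str, str] = field(default_factory=dict)
    realized_h2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"line_id", "trait", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        if self.data.duplicated(["line_id", "trait"]).any():
            raise ValueError("one value per line x trait required")

    def trait(self, name: str) -> pd.Series:
        sub = self.data[self.data["trait"] == name]
        return pd.Series(sub["value"].to_numpy(), index=sub["line_id"].to_numpy())


@dataclass
class DosageMatrix:
    """Per-line founder-of-origin dosages on a set of genomic intervals.

    Every row of ``dosages`` sums to 2 (one contribution per haplotype).
    """

    line_id: str
    intervals: pd.DataFrame  # columns: chrom, start, end
    dosages: np.ndarray  # (n_intervals, 8)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.intervals), 8):
            raise ValueError("dosages must be n_intervals x 8")
        rows = self.dosages.sum(axis=1)
        if not np.allclose(rows, 2.0, atol=1e-8):
            raise ValueError("dosage rows must sum to 2")
        if (self.dosages < -1e-12).any() or (self.dosages > 2 + 1e-12).any():
            raise ValueError("dosages must lie in [0, 2]")


@dataclass
class IntervalSet:
    """Ordered, non-overlapping intervals produced by collapsing SNPs."""

    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        df = self.intervals
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if not ((e >= s).all() and (s[1:] > e[:-1]).all()):
                raise ValueError(f"intervals on {chrom} overlap or are unordered")

    @property
    def count(self) -> int:
        return len(self.intervals)
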