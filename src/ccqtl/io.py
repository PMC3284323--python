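"""File formats: VCF and TSV genotypes, BED regions, newick trees,
phenotype CSV, QTL summary tables, and JSON parameter sidecars.

Internal coordinates are 1-based inclusive; BED output is 0-based
half-open.  Founder VCF heterozygous GT calls map to ``MISSING`` on read
(the omission policy for shared-ancestry analysis).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import MISSING, FounderPanel, IntervalSet, LineMosaic
from .narrow import SharedRegion
from .scan import QtlResult


# ---------------------------------------------------------------------------
# genotypes


def write_vcf(
    path: str | Path,
    sample_names: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    genotypes: np.ndarray,
    chrom_lengths: dict[str, int] | None = None,
    diploid_codes: bool = False,
) -> None:
    """Write a minimal GT-only VCF.

    ``genotypes`` is samples x SNPs.  With ``diploid_codes`` entries are
    0/1/2 alt-allele counts (lines); otherwise 0/1 haploid founder calls
    written as homozygous diplotypes.  ``MISSING`` becomes ``./.``.
    """
    path = Path(path)
    gt_map_hap = {0: "0/0", 1: "1/1", MISSING: "./."}
    gt_map_dip = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    gt_map = gt_map_dip if diploid_codes else gt_map_hap
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if chrom_lengths:
            for c, ln in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(chrom):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for j in range(len(pos)):
            calls = "\t".join(gt_map[int(g)] for g in genotypes[:, j])
            fh.write(f"{chrom[j]}\t{pos[j]}\tsnp{j + 1}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_genotypes_vcf(path: str | Path, as_panel: bool = True):
    """Read a GT-only VCF into a founder panel or a line genotype matrix.

    For a panel, het GT calls become ``MISSING``; for lines the 0/1/2 alt
    count is kept.  Unsorted or duplicated positions are rejected.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    chrom, pos, rows = [], [], []
    lengths = {
        c: vf.header.contigs[c].length
        for c in vf.header.contigs
        if vf.header.contigs[c].length
    }
    seen = set()
    for rec in vf:
        key = (rec.chrom, rec.pos)
        if key in seen:
            raise ValueError(f"duplicate site {rec.chrom}:{rec.pos}")
        seen.add(key)
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        row = []
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                row.append(MISSING)
            else:
                row.append(int(sum(gt)))
        rows.append(row)
    vf.close()
    chrom_arr = np.array(chrom, dtype=object)
    pos_arr = np.array(pos, dtype=np.int64)
    for c in dict.fromkeys(chrom):
        p = pos_arr[chrom_arr == c]
        if p.size > 1 and not (np.diff(p) > 0).all():
            raise ValueError(f"positions not sorted on {c}")
    geno = np.array(rows, dtype=np.int8).T  # samples x SNPs
    if not as_panel:
        return samples, chrom_arr, pos_arr, geno
    # founder panel: diplotype 0 -> allele 0, 2 -> allele 1, 1 (het) -> MISSING
    hap = np.full_like(geno, MISSING)
    hap[geno == 0] = 0
    hap[geno == 2] = 1
    return FounderPanel(
        founder_names=samples,
        chrom=chrom_arr,
        pos=pos_arr,
        genotypes=hap,
        chrom_lengths=lengths,
    )


def write_genotypes_tsv(
    path: str | Path,
    sample_names: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    genotypes: np.ndarray,
) -> None:
    """Genotype matrix as TSV: chrom, pos, then one column per sample
    (MISSING written as NA)."""
    df = pd.DataFrame({"chrom": chrom, "pos": pos})
    for i, s in enumerate(sample_names):
        col = genotypes[i].astype(object)
        df[s] = [int(v) if v != MISSING else pd.NA for v in col]
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path, as_panel: bool = True):
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    chrom = df["chrom"].astype(str).to_numpy(dtype=object)
    pos = df["pos"].to_numpy(dtype=np.int64)
    geno = np.full((len(samples), len(df)), MISSING, dtype=np.int8)
    for i, s in enumerate(samples):
        col = df[s]
        ok = col.notna()
        geno[i, ok.to_numpy()] = col[ok].astype(int).to_numpy()
    if not as_panel:
        return samples, chrom, pos, geno
    return FounderPanel(
        founder_names=samples, chrom=chrom, pos=pos, genotypes=geno
    )


def read_genotypes(path: str | Path, fmt: str | None = None, as_panel: bool = True):
    """Dispatch on extension: .vcf -> VCF reader, otherwise TSV matrix."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return read_genotypes_vcf(path, as_panel=as_panel)
    return read_genotypes_tsv(path, as_panel=as_panel)


# ---------------------------------------------------------------------------
# regions, mosaics, trees, tables


def write_regions_bed(path: str | Path, regions: list[SharedRegion]) -> None:
    """Shared regions as BED (0-based half-open), name = sorted group."""
    with open(path, "w") as fh:
        for r in regions:
            name = "|".join(sorted(r.group))
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{r.n_snps}\n")


def write_mosaic_bed(path: str | Path, mosaic: LineMosaic, founder_names: list[str]) -> None:
    with open(path, "w") as fh:
        for chrom, haps in mosaic.haplotypes.items():
            for h, hap in enumerate(haps):
                for (s, e, f) in hap:
                    fh.write(f"{chrom}\t{s - 1}\t{e}\t{founder_names[f]}\thap{h + 1}\n")


def write_intervals_bed(path: str | Path, intervals: IntervalSet) -> None:
    with open(path, "w") as fh:
        for row in intervals.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\n")


def read_annotation_bed(path: str | Path) -> list[tuple[int, int, str]]:
    """BED gene annotation -> (start, end, name) half-open bp intervals.
    Track/browser header lines are skipped; 1-based-looking input is not
    silently accepted (BED is 0-based by definition)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}"
            out.append((int(parts[1]), int(parts[2]), name))
    return out


def write_tree(path: str | Path, newick: str) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def write_phenotypes_csv(path: str | Path, table) -> None:
    table.data.to_csv(path, index=False)


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"line_id", "trait", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype CSV needs columns {sorted(required)}")
    return df


TABLE1_COLUMNS = [
    "trait", "name", "chrom", "peak_mb", "lod",
    "ci_start_mb", "ci_end_mb", "ci_size_mb",
]


def write_qtl_table(path: str | Path, results: list[QtlResult]) -> None:
    """Summary-table TSV: Mb to 3 decimals, LOD to 1 decimal."""
    rows = []
    for q in results:
        rows.append(
            {
                "trait": q.trait,
                "name": q.name,
                "chrom": q.chrom,
                "peak_mb": f"{q.peak_pos / 1e6:.3f}",
                "lod": f"{q.peak_lod:.1f}",
                "ci_start_mb": f"{q.ci_start / 1e6:.3f}",
                "ci_end_mb": f"{q.ci_end / 1e6:.3f}",
                "ci_size_mb": f"{q.ci_size_mb:.3f}",
            }
        )
    pd.DataFrame(rows, columns=TABLE1_COLUMNS).to_csv(path, sep="\t", index=False)


def read_qtl_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_params_json(path: str | Path, params: dict) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_params_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
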