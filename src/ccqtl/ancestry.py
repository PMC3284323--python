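"""Founder-of-origin inference for mosaic inbred genomes.

A hidden Markov model assigns each SNP of each line a pair of founder
haplotypes.  States are ordered founder pairs (8 x 8 = 64); the transition
kernel factorizes over the two haplotypes, each switching ancestry between
adjacent SNPs with probability ``1 - exp(-switch_rate * d)`` for a gap of
``d`` bp, and the emission model flips each transmitted allele with a
symmetric per-allele genotyping error.  Forward-backward posteriors are
converted to expected founder dosages (8 reals summing to 2 per SNP), the
additive-model representation used for mapping; heterozygous or missing
founder calls contribute uninformative emissions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, DosageMatrix, FounderPanel, IntervalSet


def _emission_probs(
    line_geno: np.ndarray, panel_geno: np.ndarray, error_rate: float
) -> np.ndarray:
    """(M, 8, 8) probability of the observed genotype under each ordered
    founder pair."""
    M = line_geno.size
    # per-founder probability that the transmitted allele is 1
    p1 = np.where(panel_geno == MISSING, 0.5,
                  panel_geno * (1 - error_rate) + (1 - panel_geno) * error_rate)
    pi = p1.T[:, :, None]  # (M, 8, 1): haplotype one
    pj = p1.T[:, None, :]  # (M, 1, 8): haplotype two
    probs = np.empty((M, 8, 8, 3))
    probs[..., 0] = (1 - pi) * (1 - pj)
    probs[..., 2] = pi * pj
    probs[..., 1] = 1.0 - probs[..., 0] - probs[..., 2]
    emit = np.ones((M, 8, 8))
    obs = line_geno != MISSING
    emit[obs] = probs[obs, :, :, line_geno[obs]]
    return emit


def _apply_transition(mat: np.ndarray, stay: float) -> np.ndarray:
    """Apply the factorized one-step kernel to an (8, 8) mass matrix.

    Per haplotype: stay with probability ``stay``, otherwise jump to a
    founder chosen uniformly from all eight (lazy kernel, keeps the uniform
    distribution stationary).
    """
    move = (1.0 - stay) / 8.0
    colsum = mat.sum(axis=0, keepdims=True)
    rowsum = mat.sum(axis=1, keepdims=True)
    total = mat.sum()
    return (
        stay * stay * mat
        + stay * move * (colsum + rowsum)
        + move * move * total
    )


def infer_ancestry(
    line_genotypes: np.ndarray,
    panel: FounderPanel,
    error_rate: float = 0.002,
    switch_rate: float = 1e-7,
    line_id: str = "line",
    return_map_states: bool = False,
):
    """Posterior founder dosages for one line by forward-backward.

    Parameters
    ----------
    line_genotypes:
        Length-M array of 0/1/2 alt-allele counts (``MISSING`` allowed),
        on the same SNP set as ``panel``.
    error_rate, switch_rate:
        Per-allele genotyping error and per-bp ancestry switch rate; both
        must lie in (0, 1).

    Returns a :class:`DosageMatrix` with one point interval per SNP (rows
    sum to 2); with ``return_map_states`` also the per-SNP maximum-posterior
    unordered founder pair, used for interval collapsing.
    """
    line_genotypes = np.asarray(line_genotypes, dtype=np.int8)
    if line_genotypes.size != panel.n_snps:
        raise ValueError("line and panel SNP sets differ")
    if not (0 < error_rate < 1 and 0 < switch_rate < 1):
        raise ValueError("error_rate and switch_rate must be in (0, 1)")
    if (line_genotypes == MISSING).all():
        raise ValueError("all genotypes missing for line")

    dosages = np.empty((panel.n_snps, 8))
    map_states = np.empty((panel.n_snps, 2), dtype=np.int8)
    for chrom in panel.chromosomes:
        idx = np.flatnonzero(panel.chrom == chrom)
        emit = _emission_probs(line_genotypes[idx], panel.genotypes[:, idx], error_rate)
        gaps = np.diff(panel.pos[idx])
        stay = np.exp(-switch_rate * gaps)
        M = idx.size

        alpha = np.empty((M, 8, 8))
        scale = np.empty(M)
        a = emit[0] / 64.0
        scale[0] = a.sum()
        alpha[0] = a / scale[0]
        for t in range(1, M):
            a = _apply_transition(alpha[t - 1], stay[t - 1]) * emit[t]
            scale[t] = a.sum()
            alpha[t] = a / scale[t]

        beta = np.ones((8, 8))
        gamma = np.empty((M, 8, 8))
        gamma[M - 1] = alpha[M - 1]
        for t in range(M - 2, -1, -1):
            beta = _apply_transition(beta * emit[t + 1], stay[t])
            beta /= beta.sum()  # rescale; posteriors are normalized below
            g = alpha[t] * beta
            gamma[t] = g / g.sum()

        dosages[idx] = gamma.sum(axis=2) + gamma.sum(axis=1)
        # unordered MAP diplotype: symmetrize then argmax upper triangle
        sym = gamma + gamma.transpose(0, 2, 1)
        iu = np.triu_indices(8)
        flat = sym[:, iu[0], iu[1]]
        best = flat.argmax(axis=1)
        map_states[idx, 0] = iu[0][best]
        map_states[idx, 1] = iu[1][best]

    intervals = pd.DataFrame(
        {"chrom": panel.chrom, "start": panel.pos, "end": panel.pos}
    )
    dm = DosageMatrix(line_id=line_id, intervals=intervals, dosages=dosages)
    if return_map_states:
        return dm, map_states
    return dm


def infer_ancestry_all(
    genotype_matrix: np.ndarray,
    panel: FounderPanel,
    line_ids: list[str] | None = None,
    **kwargs,
) -> tuple[list[DosageMatrix], np.ndarray]:
    """Run :func:`infer_ancestry` for every row of an (N, M) genotype matrix.

    Returns the per-line dosage matrices and an (N, M, 2) array of MAP
    founder pairs.
    """
    n = genotype_matrix.shape[0]
    if line_ids is None:
        line_ids = [f"line{i + 1}" for i in range(n)]
    dms, maps = [], []
    for i in range(n):
        dm, mp = infer_ancestry(
            genotype_matrix[i], panel, line_id=line_ids[i],
            return_map_states=True, **kwargs
        )
        dms.append(dm)
        maps.append(mp)
    return dms, np.stack(maps)


def impute_merge(
    genotypes_a: np.ndarray,
    positions_a: pd.DataFrame,
    genotypes_b: np.ndarray,
    positions_b: pd.DataFrame,
    dosages: np.ndarray,
    panel: FounderPanel,
    margin: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge two disjoint-position genotype arrays by haplotype imputation.

    ``positions_*`` carry chrom/pos for the columns of each array; rows are
    the same lines in both.  ``dosages`` is (N, M_union, 8) on the merged,
    position-sorted SNP set (``panel`` must match it).  Unobserved entries
    are filled with twice the allele of the maximum-dosage founder; where
    the maximum is not unique by at least ``margin`` dosage, or the chosen
    founder is uncalled, the entry stays ``MISSING``.

    Returns the merged (N, M_union) matrix and a boolean imputed-flag mask.
    """
    key_a = list(zip(positions_a["chrom"], positions_a["pos"]))
    key_b = list(zip(positions_b["chrom"], positions_b["pos"]))
    if set(key_a) & set(key_b):
        raise ValueError("SNP positions present in both inputs")
    merged_key = list(zip(panel.chrom, panel.pos))
    col = {k: i for i, k in enumerate(merged_key)}
    n = genotypes_a.shape[0]
    out = np.full((n, len(merged_key)), MISSING, dtype=np.int8)
    for j, k in enumerate(key_a):
        out[:, col[k]] = genotypes_a[:, j]
    for j, k in enumerate(key_b):
        out[:, col[k]] = genotypes_b[:, j]

    imputed = np.zeros_like(out, dtype=bool)
    order = np.argsort(dosages, axis=2)
    best = order[:, :, -1]
    gap = (
        np.take_along_axis(dosages, order[:, :, -1:], axis=2)
        - np.take_along_axis(dosages, order[:, :, -2:-1], axis=2)
    )[:, :, 0]
    founder_allele = panel.genotypes[best, np.arange(len(merged_key))[None, :]]
    fill = (out == MISSING) & (gap >= margin) & (founder_allele != MISSING)
    out[fill] = (2 * founder_allele[fill]).astype(np.int8)
    imputed[fill] = True
    return out, imputed


def collapse_intervals(
    dosage_matrices: list[DosageMatrix],
    map_states: np.ndarray,
    panel: FounderPanel,
) -> tuple[IntervalSet, list[DosageMatrix]]:
    """Collapse SNPs between which no line's MAP ancestry changes.

    Adjacent SNPs on a chromosome are merged into one interval when every
    line keeps the same maximum-posterior unordered founder pair across the
    gap; per-line dosages are averaged within each merged run.  This loses
    nothing for the additive regression wherever no recombination actually
    falls inside an interval.
    """
    interval_rows = []
    interval_ids = np.empty(panel.n_snps, dtype=np.int64)
    next_id = 0
    for chrom in panel.chromosomes:
        idx = np.flatnonzero(panel.chrom == chrom)
        same = (map_states[:, idx[1:], :] == map_states[:, idx[:-1], :]).all(
            axis=(0, 2)
        )
        breaks = np.flatnonzero(~same) + 1  # run starts within chrom
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [idx.size]))
        for s, e in zip(starts, ends):
            interval_rows.append(
                (chrom, int(panel.pos[idx[s]]), int(panel.pos[idx[e - 1]]))
            )
            interval_ids[idx[s:e]] = next_id
            next_id += 1
    intervals = pd.DataFrame(interval_rows, columns=["chrom", "start", "end"])
    iset = IntervalSet(intervals)

    collapsed = []
    n_int = len(intervals)
    counts = np.bincount(interval_ids, minlength=n_int).astype(float)
    for dm in dosage_matrices:
        avg = np.zeros((n_int, 8))
        for k in range(8):
            avg[:, k] = np.bincount(
                interval_ids, weights=dm.dosages[:, k], minlength=n_int
            )
        avg /= counts[:, None]
        collapsed.append(
            DosageMatrix(line_id=dm.line_id, intervals=intervals, dosages=avg)
        )
    return iset, collapsed


def dosage_stack(dosage_matrices: list[DosageMatrix]) -> np.ndarray:
    """Stack per-line dosage matrices into the (N, I, 8) array mapping uses."""
    return np.stack([dm.dosages for dm in dosage_matrices])


def ancestry_accuracy(
    dosage_matrices: list[DosageMatrix], truth: np.ndarray
) -> float:
    """Fraction of line x SNP calls whose maximum-dosage founder carries
    positive true dosage (diagnostic used on simulated data)."""
    est = dosage_stack(dosage_matrices)
    best = est.argmax(axis=2)
    hit = np.take_along_axis(truth, best[:, :, None], axis=2)[:, :, 0] > 0
    return float(hit.mean())
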