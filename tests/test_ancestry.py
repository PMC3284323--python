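"""Ancestry HMM, imputation and interval collapsing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ccqtl import ancestry, scan, simulate
from ccqtl.core import DEFAULT_FOUNDERS, MISSING, DosageMatrix, LineMosaic

from conftest import make_panel


def exhaustive_posterior_dosages(line_geno, panel_geno, pos, error_rate, switch_rate):
    """Exact posterior founder dosages by enumerating every ordered
    state path (independent oracle; exponential in M, so tiny instances
    with few founders only)."""
    n_f = panel_geno.shape[0]
    M = line_geno.size
    p1 = np.where(panel_geno == MISSING, 0.5,
                  panel_geno * (1 - error_rate) + (1 - panel_geno) * error_rate)

    def emit(t, i, j):
        g = line_geno[t]
        if g == MISSING:
            return 1.0
        pi, pj = p1[i, t], p1[j, t]
        probs = [(1 - pi) * (1 - pj), pi * (1 - pj) + (1 - pi) * pj, pi * pj]
        return probs[g]

    gaps = np.diff(pos)
    stay = np.exp(-switch_rate * gaps)
    states = list(itertools.product(range(n_f), repeat=2))
    dosages = np.zeros((M, n_f))
    total = 0.0
    for path in itertools.product(states, repeat=M):
        p = (1.0 / n_f**2) * emit(0, *path[0])
        for t in range(1, M):
            s = stay[t - 1]
            move = (1 - s) / n_f
            ti = s + move if path[t][0] == path[t - 1][0] else move
            tj = s + move if path[t][1] == path[t - 1][1] else move
            p *= ti * tj * emit(t, *path[t])
        total += p
        for t, (i, j) in enumerate(path):
            dosages[t, i] += p
            dosages[t, j] += p
    return dosages / total


class TestInferAncestry:
    def test_pure_line_gets_dosage_two(self, small_panel):
        geno = 2 * small_panel.genotypes[4]
        geno = np.where(small_panel.genotypes[4] == MISSING, MISSING, geno)
        dm = ancestry.infer_ancestry(geno, small_panel)
        assert (dm.dosages[:, 4] > 1.9).mean() > 0.98

    def test_matches_exhaustive_path_enumeration(self):
        """Forward-backward dosages equal brute-force path summation on a
        tiny two-founder instance."""
        rng = np.random.default_rng(8)
        n_snps = 6
        panel_geno = np.zeros((8, n_snps), dtype=np.int8)
        panel_geno[0] = rng.integers(0, 2, n_snps)
        panel_geno[1] = 1 - panel_geno[0]
        # other founders far from the data to keep the oracle at 2 founders:
        # restrict comparison to a 2-founder panel instead
        two = panel_geno[:2]
        line = np.concatenate([2 * two[0, :3], 2 * two[1, 3:]]).astype(np.int8)
        pos = (np.arange(n_snps) + 1) * 100_000

        oracle = exhaustive_posterior_dosages(line, two, pos, 0.01, 1e-6)

        # run the production HMM with the same two founders duplicated
        # 4x (any 8-founder panel); instead build an equivalent 8-founder
        # panel where founders 2..7 are copies of founder 0 and compare
        # summed dosages is not equivalent -- so test the 2-state math by
        # monkey-building an 8-founder panel whose extra founders always
        # mismatch the line, making their posterior negligible.
        full = np.zeros((8, n_snps), dtype=np.int8)
        full[0], full[1] = two
        for k in range(2, 8):
            full[k] = 1 - (line // 2)  # always opposite allele
        panel = make_panel(full, spacing=100_000)
        dm = ancestry.infer_ancestry(line, panel, error_rate=0.01,
                                     switch_rate=1e-6)
        est = dm.dosages[:, :2]
        est = est / est.sum(axis=1, keepdims=True) * 2
        orc = oracle[:, :2]
        orc = orc / orc.sum(axis=1, keepdims=True) * 2
        # the 6 mismatching decoys absorb a little mass; compare the
        # renormalized two-founder split, which must match closely
        assert np.allclose(est, orc, atol=0.02)
        # and the MAP founder sequence matches exactly
        assert (est.argmax(axis=1) == orc.argmax(axis=1)).all()

    def test_breakpoint_localized_within_one_snp(self):
        rng = np.random.default_rng(9)
        n_snps = 50
        geno = rng.integers(0, 2, size=(8, n_snps), dtype=np.int8)
        geno[1] = 1 - geno[0]  # maximally informative pair
        panel = make_panel(geno, spacing=200_000)
        true_break = 24  # last SNP carried by founder 0
        line = np.concatenate([
            2 * geno[0, : true_break + 1], 2 * geno[1, true_break + 1 :]
        ]).astype(np.int8)
        dm = ancestry.infer_ancestry(line, panel)
        best = dm.dosages.argmax(axis=1)
        switches = np.flatnonzero(np.diff(best))
        assert len(switches) == 1
        assert abs(switches[0] - true_break) <= 1

    def test_missing_snp_returns_uniform_dosage(self, small_panel):
        geno = 2 * np.abs(small_panel.genotypes[0])
        geno[10] = MISSING
        dm = ancestry.infer_ancestry(geno, small_panel, switch_rate=0.5)
        # with a near-memoryless chain the all-missing SNP reverts to the
        # stationary prior: dosage 2/8 per founder
        assert np.allclose(dm.dosages[10], 0.25, atol=0.01)

    def test_row_sums_are_two(self, small_panel):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, small_panel.n_snps).astype(np.int8)
        dm = ancestry.infer_ancestry(geno, small_panel)
        assert np.allclose(dm.dosages.sum(axis=1), 2.0, atol=1e-8)

    def test_all_missing_line_rejected(self, small_panel):
        geno = np.full(small_panel.n_snps, MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="missing"):
            ancestry.infer_ancestry(geno, small_panel)

    def test_snp_set_mismatch_rejected(self, small_panel):
        with pytest.raises(ValueError, match="differ"):
            ancestry.infer_ancestry(np.zeros(10, dtype=np.int8), small_panel)

    def test_noiseless_accuracy_above_99pct(self):
        from ccqtl.benchmarks import hmm_accuracy

        result = hmm_accuracy(5, n_lines=8, n_snps=1000)
        assert result["accuracy_pct"] >= 99.0


class TestCollapseIntervals:
    def _dm(self, panel, dosages, line_id="L1"):
        intervals = pd.DataFrame(
            {"chrom": panel.chrom, "start": panel.pos, "end": panel.pos}
        )
        return DosageMatrix(line_id=line_id, intervals=intervals, dosages=dosages)

    def test_no_recombination_one_interval_per_chromosome(self, small_panel):
        M = small_panel.n_snps
        dosages = np.zeros((M, 8))
        dosages[:, 0] = 2.0
        maps = np.zeros((1, M, 2), dtype=np.int8)
        iset, collapsed = ancestry.collapse_intervals(
            [self._dm(small_panel, dosages)], maps, small_panel
        )
        assert iset.count == len(small_panel.chromosomes)

    def test_everywhere_recombinant_no_merging(self, small_panel):
        M = small_panel.n_snps
        dosages = np.zeros((M, 8))
        alt = np.arange(M) % 2
        dosages[np.arange(M), alt] = 2.0
        maps = np.zeros((1, M, 2), dtype=np.int8)
        maps[0, :, 0] = alt
        maps[0, :, 1] = alt
        iset, _ = ancestry.collapse_intervals(
            [self._dm(small_panel, dosages)], maps, small_panel
        )
        assert iset.count == M

    def test_boundaries_near_true_breakpoints(self, small_panel):
        """Collapsed-interval boundaries from noiseless HMM calls land
        within one SNP of the true mosaic breakpoints."""
        gmap = simulate.GeneticMap(chrom_lengths=dict(small_panel.chrom_lengths))
        mosaics = simulate.simulate_panel_lines(small_panel, 4, gmap, seed=55)
        geno = simulate.genotype_lines(small_panel, mosaics, seed=56)
        dms, maps = ancestry.infer_ancestry_all(
            geno, small_panel, line_ids=[m.line_id for m in mosaics]
        )
        iset, _ = ancestry.collapse_intervals(dms, maps, small_panel)
        boundaries = set(iset.intervals["start"]) | set(iset.intervals["end"])
        pos = small_panel.pos
        hits = 0
        total = 0
        for m in mosaics:
            for haps in m.haplotypes.values():
                for hap in haps:
                    for (s, e, f) in hap[:-1]:
                        # breakpoint after bp e: nearest flanking SNPs
                        total += 1
                        i = np.searchsorted(pos, e)
                        near = set(pos[max(i - 3, 0) : i + 3])
                        if near & boundaries:
                            hits += 1
        # breakpoints between locally identical founders are inherently
        # undetectable, so most but not all are localized
        assert total > 0
        assert hits / total >= 0.75

    def test_collapsing_lossless_for_regression(self, population):
        """Scan LODs on per-SNP dosages agree with LODs on collapsed
        intervals at interval representatives when dosages are constant
        within intervals (true dosages are piecewise constant)."""
        panel = population["panel"]
        X = population["dosages"]
        y = population["phenos"].trait("MCV")
        ids = population["line_ids"]
        # build MAP states from truth: diplotype = pair of argmax dosages
        n, M, _ = X.shape
        maps = np.zeros((n, M, 2), dtype=np.int8)
        for li in range(n):
            order = np.argsort(X[li], axis=1)
            top = np.sort(order[:, -2:], axis=1)
            hom = X[li].max(axis=1) > 1.5
            maps[li, :, 0] = np.where(hom, order[:, -1], top[:, 0])
            maps[li, :, 1] = np.where(hom, order[:, -1], top[:, 1])
        dms = [
            DosageMatrix(
                line_id=ids[li],
                intervals=pd.DataFrame({
                    "chrom": panel.chrom, "start": panel.pos, "end": panel.pos
                }),
                dosages=X[li],
            )
            for li in range(n)
        ]
        iset, collapsed = ancestry.collapse_intervals(dms, maps, panel)
        Xc = ancestry.dosage_stack(collapsed)
        lod_snp = scan.scan_trait(
            X, pd.DataFrame({"chrom": panel.chrom, "start": panel.pos,
                             "end": panel.pos}), y, ids
        ).lod
        lod_col = scan.scan_trait(Xc, iset, y, ids).lod
        # representative: first SNP of each collapsed interval
        reps = np.searchsorted(panel.pos, iset.intervals["start"].to_numpy())
        assert np.allclose(lod_col, lod_snp[reps], atol=1e-6)


class TestImputeMerge:
    def test_pure_line_imputes_founder_alleles(self, small_panel):
        M = small_panel.n_snps
        k = 2
        dosages = np.zeros((1, M, 8))
        dosages[:, :, k] = 2.0
        half = M // 2
        pos_a = pd.DataFrame({"chrom": small_panel.chrom[:half],
                              "pos": small_panel.pos[:half]})
        pos_b = pd.DataFrame({"chrom": small_panel.chrom[half:],
                              "pos": small_panel.pos[half:]})
        geno_a = (2 * small_panel.genotypes[k, :half])[None, :]
        merged, imputed = ancestry.impute_merge(
            geno_a, pos_a, np.empty((1, 0), dtype=np.int8),
            pos_b.iloc[:0], dosages, small_panel,
        )
        expect = 2 * small_panel.genotypes[k]
        called = small_panel.genotypes[k] != MISSING
        assert (merged[0, called] == expect[called]).all()
        assert imputed[0, half:][called[half:]].all()
        assert not imputed[0, :half].any()

    def test_dosage_tie_left_missing(self, small_panel):
        M = small_panel.n_snps
        dosages = np.full((1, M, 8), 0.25)
        pos_a = pd.DataFrame({"chrom": small_panel.chrom[:1],
                              "pos": small_panel.pos[:1]})
        geno_a = np.array([[0]], dtype=np.int8)
        merged, imputed = ancestry.impute_merge(
            geno_a, pos_a, np.empty((1, 0), dtype=np.int8),
            pos_a.iloc[:0], dosages, small_panel,
        )
        assert (merged[0, 1:] == MISSING).all()
        assert not imputed.any()

    def test_overlapping_positions_rejected(self, small_panel):
        pos = pd.DataFrame({"chrom": small_panel.chrom[:2],
                            "pos": small_panel.pos[:2]})
        with pytest.raises(ValueError, match="both"):
            ancestry.impute_merge(
                np.zeros((1, 2), dtype=np.int8), pos,
                np.zeros((1, 2), dtype=np.int8), pos,
                np.zeros((1, small_panel.n_snps, 8)), small_panel,
            )

    def test_noiseless_imputation_accuracy(self, population):
        """Random mosaics, noiseless genotypes: imputing one array's SNPs
        from ancestry recovers the simulator's truth."""
        panel = population["panel"]
        mosaics = population["mosaics"]
        X = population["dosages"]
        truth = simulate.genotype_lines(panel, mosaics, seed=77)
        M = panel.n_snps
        a_idx = np.arange(M) % 2 == 0
        pos_a = pd.DataFrame({"chrom": panel.chrom[a_idx], "pos": panel.pos[a_idx]})
        pos_b = pd.DataFrame({"chrom": panel.chrom[~a_idx], "pos": panel.pos[~a_idx]})
        merged, imputed = ancestry.impute_merge(
            truth[:, a_idx], pos_a,
            np.empty((truth.shape[0], 0), dtype=np.int8), pos_b.iloc[:0],
            X, panel,
        )
        both = imputed & (truth != MISSING) & (merged != MISSING)
        # homozygous truth imputes exactly; residual het sites may differ
        hom = truth != 1
        agree = (merged[both & hom] == truth[both & hom]).mean()
        assert agree > 0.97
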