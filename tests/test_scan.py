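"""Genome-scan regression: LOD scores, permutation thresholds, support
intervals, allele effects, conditional scans."""

import numpy as np
import pandas as pd
import pytest

from ccqtl import scan
from ccqtl.scan import LOD_CAP, interval_size_mb


def brute_force_lod(X, y, cov=None):
    """Independent per-interval OLS oracle: explicit design with intercept,
    RSS from lstsq residuals."""
    n = y.size
    lods = []
    base_cols = [np.ones(n)]
    if cov is not None:
        base_cols.append(cov)
    base = np.column_stack(base_cols)
    beta0, *_ = np.linalg.lstsq(base, y, rcond=None)
    rss0 = ((y - base @ beta0) ** 2).sum()
    for i in range(X.shape[1]):
        design = np.column_stack([base, X[:, i, :]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss1 = ((y - design @ beta) ** 2).sum()
        lods.append((n / 2) * np.log10(rss0 / rss1))
    return np.clip(np.array(lods), 0, LOD_CAP)


class TestScanTrait:
    def test_constant_phenotype_gives_zero_lod(self, population):
        ids = population["line_ids"]
        y = pd.Series(np.full(len(ids), 3.14), index=ids)
        curve = scan.scan_trait(
            population["dosages"], population["intervals"], y, ids
        )
        assert (curve.lod == 0).all()

    def test_matches_brute_force_regression(self, population):
        """Planted QTL scan equals an independent per-interval OLS oracle
        to 1e-8 and localizes the peak at the true position."""
        X = population["dosages"]
        y = population["phenos"].trait("MCV")
        ids = population["line_ids"]
        curve = scan.scan_trait(X, population["intervals"], y, ids)
        oracle = brute_force_lod(X, y.reindex(ids).to_numpy())
        assert np.allclose(curve.lod, oracle, atol=1e-8)
        peak = curve.peak_index
        df = population["intervals"].intervals
        assert df["start"].iloc[peak] <= population["qtl"].pos + 2_000_000
        assert df["end"].iloc[peak] >= population["qtl"].pos - 2_000_000

    def test_perfect_fit_capped(self, population):
        X = population["dosages"]
        ids = population["line_ids"]
        i = int(X[:, :, 0].var(axis=0).argmax())
        y = pd.Series(X[:, i, 0], index=ids)  # phenotype = one dosage column
        curve = scan.scan_trait(X, population["intervals"], y, ids)
        assert curve.lod[i] == LOD_CAP

    def test_affine_invariance(self, population):
        X = population["dosages"]
        ids = population["line_ids"]
        y = population["phenos"].trait("MCV")
        a = scan.scan_trait(X, population["intervals"], y, ids).lod
        b = scan.scan_trait(X, population["intervals"], -2.5 * y + 7.0, ids).lod
        assert np.allclose(a, b, atol=1e-8)

    def test_too_few_lines_rejected(self, population):
        X = population["dosages"][:5]
        ids = population["line_ids"][:5]
        y = population["phenos"].trait("MCV")
        with pytest.raises(ValueError, match="lines"):
            scan.scan_trait(X, population["intervals"], y, ids)


class TestPermutationThreshold:
    def test_alpha_monotonicity(self, population):
        X = population["dosages"]
        ids = population["line_ids"]
        y = population["phenos"].trait("MCV")
        t05 = scan.permutation_threshold(
            X, population["intervals"], y, ids, n_perm=200, alpha=0.05, seed=1
        )
        t10 = scan.permutation_threshold(
            X, population["intervals"], y, ids, n_perm=200, alpha=0.10, seed=1
        )
        assert t05 >= t10

    def test_alpha_one_gives_minimum(self, population):
        X = population["dosages"]
        ids = population["line_ids"]
        y = population["phenos"].trait("MCV")
        t, max_lods = scan.permutation_threshold(
            X, population["intervals"], y, ids, n_perm=100, alpha=1.0,
            seed=2, return_max_lods=True,
        )
        assert t == pytest.approx(max_lods.min())

    def test_insufficient_permutations_rejected(self, population):
        with pytest.raises(ValueError, match="n_perm"):
            scan.permutation_threshold(
                population["dosages"], population["intervals"],
                population["phenos"].trait("MCV"), population["line_ids"],
                n_perm=10, alpha=0.05,
            )

    def test_seed_stability_within_monte_carlo_error(self, population):
        X = population["dosages"]
        ids = population["line_ids"]
        y = population["phenos"].trait("MCV")
        t1 = scan.permutation_threshold(
            X, population["intervals"], y, ids, n_perm=500, alpha=0.05, seed=3
        )
        t2 = scan.permutation_threshold(
            X, population["intervals"], y, ids, n_perm=500, alpha=0.05, seed=4
        )
        assert abs(t1 - t2) / t1 < 0.2


class TestLodDropInterval:
    def _curve(self, lods, chrom="1", spacing=1_000_000):
        m = len(lods)
        pos = (np.arange(m) + 1) * spacing
        df = pd.DataFrame({"chrom": chrom, "start": pos, "end": pos + spacing - 1})
        return scan.LodCurve(intervals=df, lod=np.array(lods, dtype=float))

    def test_flat_curve_returns_whole_chromosome(self):
        curve = self._curve([5.0] * 10)
        lo, hi = scan.lod_drop_interval(curve, 4)
        assert lo == curve.intervals["start"].iloc[0]
        assert hi == curve.intervals["end"].iloc[9]

    def test_unimodal_curve_matches_contiguous_run_oracle(self):
        """For a strictly unimodal curve the support interval equals the
        brute-force widest qualifying contiguous run."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = 30
            peak_at = rng.integers(3, m - 3)
            lods = 10 - 0.7 * np.abs(np.arange(m) - peak_at) \
                + rng.uniform(0, 0.01, m)
            lods = np.maximum(lods, 0)
            curve = self._curve(list(lods))
            peak = int(np.argmax(lods))
            cut = lods[peak] - 1.5
            runs = []
            for i in range(m):
                for j in range(i, m):
                    if i <= peak <= j and (lods[i : j + 1] >= cut).all():
                        runs.append((i, j))
            best = max(runs, key=lambda r: r[1] - r[0])
            lo, hi = scan.lod_drop_interval(curve, peak)
            assert lo == curve.intervals["start"].iloc[best[0]]
            assert hi == curve.intervals["end"].iloc[best[1]]

    def test_restricted_to_peak_chromosome(self):
        lods = [8, 8, 8, 0, 8, 8, 8]
        pos = (np.arange(7) + 1) * 1_000_000
        df = pd.DataFrame({
            "chrom": ["1"] * 3 + ["2"] * 4,
            "start": pos, "end": pos + 999_999,
        })
        curve = scan.LodCurve(intervals=df, lod=np.array(lods, dtype=float))
        lo, hi = scan.lod_drop_interval(curve, 1)
        assert (lo, hi) == (1_000_000, 3_999_999)

    def test_mb_size_bookkeeping(self):
        # summary-table convention: end minus start in Mb, 3 decimals
        assert interval_size_mb(110_336_000, 116_242_000) == 5.906


class TestAlleleEffects:
    def test_biallelic_noiseless_two_values(self, small_panel):
        rng = np.random.default_rng(6)
        n = 100
        X = np.zeros((n, 8))
        picks = rng.integers(0, 8, size=(n, 2))
        for i, (a, b) in enumerate(picks):
            X[i, a] += 1
            X[i, b] += 1
        high = {0, 3, 4}
        y_vals = np.array([
            sum(4.0 if f in high else -1.0 for f in pair) for pair in picks
        ])
        ids = [f"L{i}" for i in range(n)]
        eff = scan.allele_effects(X[:, None, :][:, 0, :],
                                  pd.Series(y_vals, index=ids), ids)
        rounded = np.round(eff, 6)
        assert len(set(rounded)) == 2
        assert all(rounded[k] == rounded[0] for k in high)

    def test_weighted_mean_is_zero(self, population):
        X = population["dosages"]
        ids = population["line_ids"]
        y = population["phenos"].trait("MCV")
        peak = scan.scan_trait(X, population["intervals"], y, ids).peak_index
        eff = scan.allele_effects(X[:, peak, :], y, ids)
        w = X[:, peak, :].sum(axis=0) / X[:, peak, :].sum()
        assert abs(w @ eff) < 1e-8

    def test_agrees_with_dummy_coding_oracle(self, population):
        """Full 8-column no-intercept fit equals the intercept + 7-dummy
        parameterization after re-centering (same column space)."""
        X = population["dosages"]
        ids = population["line_ids"]
        y = population["phenos"].trait("MCV")
        peak = scan.scan_trait(X, population["intervals"], y, ids).peak_index
        Xp = X[:, peak, :]
        eff = scan.allele_effects(Xp, y, ids)
        yv = y.reindex(ids).to_numpy()
        design = np.column_stack([np.ones(len(ids)), Xp[:, :7]])
        coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
        beta = np.concatenate([coef[1:], [0.0]]) + coef[0] / 2.0
        w = Xp.sum(axis=0) / Xp.sum()
        oracle = beta - w @ beta
        assert np.allclose(eff, oracle, atol=1e-8)

    def test_collinear_dosages_flagged(self):
        n = 40
        X = np.zeros((n, 8))
        X[:, 0] = 2.0  # only one founder present: columns collinear
        ids = [f"L{i}" for i in range(n)]
        y = pd.Series(np.random.default_rng(1).normal(size=n), index=ids)
        with pytest.warns(UserWarning, match="collinear"):
            scan.allele_effects(X, y, ids)


@pytest.fixture(scope="module")
def two_qtl_population():
    """150 lines, two planted QTL on different chromosomes."""
    from ccqtl import simulate
    from ccqtl.core import QtlSpec

    panel = simulate.simulate_founders(
        800, chrom_lengths={"1": 50_000_000, "2": 50_000_000}, seed=71
    )
    gmap = simulate.GeneticMap(chrom_lengths=dict(panel.chrom_lengths))
    mosaics = simulate.simulate_panel_lines(panel, 150, gmap, seed=72)
    q1 = QtlSpec(chrom="1", pos=25_000_000,
                 functional_group=frozenset({"C57BL6J", "NODShiLtJ"}),
                 effect_size=8.0)
    q2 = QtlSpec(chrom="2", pos=25_000_000,
                 functional_group=frozenset({"CASTEiJ", "PWKPhJ", "WSBEiJ"}),
                 effect_size=8.0)
    phenos = simulate.assign_phenotypes(
        panel, mosaics, [q1, q2], noise_sd=4.0, seed=73
    )
    iset, X = simulate.true_dosages(panel, mosaics)
    ids = [m.line_id for m in mosaics]
    g1_idx = {panel.founder_index(n) for n in q1.functional_group}
    classes = []
    for m in mosaics:
        fa, fb = m.founders_at("1", q1.pos)
        classes.append(str((fa in g1_idx) + (fb in g1_idx)))
    return {
        "panel": panel, "intervals": iset, "dosages": X, "line_ids": ids,
        "y": phenos.trait("trait"),
        "condition_q1": pd.Series(classes, index=ids),
    }


class TestConditionalScan:
    def test_conditioning_on_own_genotype_collapses_lod(self, two_qtl_population):
        p = two_qtl_population
        plain = scan.scan_trait(p["dosages"], p["intervals"], p["y"],
                                p["line_ids"])
        cond = scan.conditional_scan(p["dosages"], p["intervals"], p["y"],
                                     p["line_ids"], p["condition_q1"])
        chrom1 = (p["intervals"].intervals["chrom"] == "1").to_numpy()
        peak1 = np.flatnonzero(chrom1)[np.argmax(plain.lod[chrom1])]
        # the conditioned locus collapses toward the overfit baseline of
        # an 8-parameter model, far below its unconditioned LOD
        assert plain.lod[peak1] > 7.0
        assert cond.lod[peak1] < 0.5 * plain.lod[peak1]
        assert cond.lod[peak1] < 4.5

    def test_conditioning_on_independent_factor_preserves_curve(self, population):
        X = population["dosages"]
        ids = population["line_ids"]
        y = population["phenos"].trait("MCV")
        rng = np.random.default_rng(8)
        random_factor = pd.Series(rng.integers(0, 2, len(ids)).astype(str),
                                  index=ids)
        plain = scan.scan_trait(X, population["intervals"], y, ids)
        cond = scan.conditional_scan(
            X, population["intervals"], y, ids, random_factor
        )
        assert np.corrcoef(plain.lod, cond.lod)[0, 1] > 0.95

    def test_independent_qtl_not_weakened(self, two_qtl_population):
        """Conditioning on the first QTL leaves the second's peak in place
        and does not cost it support (its LOD can only gain precision as
        the conditioned variance leaves the null)."""
        p = two_qtl_population
        plain = scan.scan_trait(p["dosages"], p["intervals"], p["y"],
                                p["line_ids"])
        cond = scan.conditional_scan(p["dosages"], p["intervals"], p["y"],
                                     p["line_ids"], p["condition_q1"])
        chrom2 = (p["intervals"].intervals["chrom"] == "2").to_numpy()
        idx2 = np.flatnonzero(chrom2)
        peak2 = idx2[np.argmax(plain.lod[chrom2])]
        peak2_cond = idx2[np.argmax(cond.lod[chrom2])]
        pos = p["intervals"].intervals["start"].to_numpy()
        # both peaks sit within the support-interval scale of each other
        lo, hi = scan.lod_drop_interval(plain, int(peak2))
        assert lo <= pos[peak2_cond] <= hi
        assert cond.lod[peak2] > plain.lod[peak2] - 1.0
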