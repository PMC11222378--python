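"""Methylation-region calling, interval annotation, specificity, trends,
enrichment and clustering statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from allelescope import regions
from allelescope.regions import (
    AnnotationHierarchy, aggregate_peaks_to_genes, call_methylation_regions,
    pairwise_clustering_ratio, permutation_enrichment, promoter_region,
    trend_pattern_id, trend_patterns,
)


def brute_force_regions(pos, sig, window=1500, min_run=3):
    """Oracle: examine every start CpG and extend while the rules hold."""
    out = []
    i = 0
    n = len(pos)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and sig[j + 1]
               and pos[j + 1] - pos[j] <= window):
            j += 1
        if j - i + 1 >= min_run:
            out.append((pos[i], pos[j] + 1, j - i + 1))
        i = j + 1
    return out


def results_frame(pos, sig, chrom="c"):
    return pd.DataFrame({"chrom": chrom, "pos": pos,
                         "fdr": [0.001 if s else 0.5 for s in sig]})


class TestMRCaller:
    def test_three_cpgs_within_window(self):
        df = results_frame([100, 600, 1400], [True, True, True])
        out = call_methylation_regions(df, "poeMR")
        assert len(out) == 1
        r = out[0]
        assert (r.start, r.end, r.n_cpgs) == (100, 1401, 3)

    def test_two_cpgs_no_region(self):
        df = results_frame([100, 200], [True, True])
        assert call_methylation_regions(df, "poeMR") == []

    def test_large_gap_breaks_run(self):
        df = results_frame([100, 200, 2000], [True, True, True])
        assert call_methylation_regions(df, "poeMR") == []

    def test_nonsignificant_tested_cpg_breaks_run(self):
        df = results_frame([100, 200, 300, 400, 500],
                           [True, True, False, True, True])
        assert call_methylation_regions(df, "poeMR") == []

    def test_unsorted_raises(self):
        df = results_frame([500, 100, 300], [True, True, True])
        with pytest.raises(ValueError):
            call_methylation_regions(df, "poeMR")

    def test_nan_fdr_not_significant(self):
        df = results_frame([100, 200, 300], [True, True, True])
        df.loc[1, "fdr"] = np.nan
        assert call_methylation_regions(df, "poeMR") == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        pos = np.sort(rng.choice(20000, size=n, replace=False))
        sig = rng.random(n) < 0.55
        df = results_frame(pos, sig)
        out = call_methylation_regions(df, "ageMR")
        got = [(r.start, r.end, r.n_cpgs) for r in out]
        assert got == brute_force_regions(list(pos), list(sig))

    def test_members_reverify(self):
        rng = np.random.default_rng(99)
        pos = np.sort(rng.choice(30000, size=40, replace=False))
        sig = rng.random(40) < 0.7
        df = results_frame(pos, sig)
        sigset = set(pos[sig])
        for r in call_methylation_regions(df, "poeMR"):
            assert r.n_cpgs >= 3
            assert all(p in sigset for p in r.cpg_positions)
            gaps = np.diff(r.cpg_positions)
            assert (gaps <= 1500).all()


@pytest.fixture
def annotated(toy_gtf):
    return AnnotationHierarchy(toy_gtf)


class TestAnnotation:
    def test_promoter_wins_over_exon(self, annotated):
        # gene_a is + strand with TSS 100: promoter [0,100); exon [100,200)
        cat, gene = annotated.annotate("chr1", 90, 120)
        assert cat == "promoter" and gene == "gene_a"

    def test_intron_only(self, annotated):
        cat, gene = annotated.annotate("chr1", 220, 280)
        assert cat == "intron" and gene == "gene_a"

    def test_intergenic(self, annotated):
        cat, gene = annotated.annotate("chr1", 5000, 5100)
        assert cat == "intergenic" and gene is None

    def test_order_sensitivity(self, toy_gtf):
        """Permuting the hierarchy changes assignments of multi-overlap
        intervals — the order genuinely matters."""
        default = AnnotationHierarchy(toy_gtf)
        flipped = AnnotationHierarchy(
            toy_gtf, order=["exon", "intron", "five_prime_utr",
                            "three_prime_utr", "promoter", "intergenic"])
        iv = ("chr1", 90, 120)   # overlaps promoter and exon of gene_a
        assert default.annotate(*iv)[0] == "promoter"
        assert flipped.annotate(*iv)[0] == "exon"

    def test_minus_strand_promoter(self, annotated):
        # gene_b is - strand with span [1000,1600): promoter [1600, 4600)
        cat, gene = annotated.annotate("chr1", 1700, 1800)
        assert cat == "promoter" and gene == "gene_b"


class TestPromoterRegion:
    def test_plus_strand(self):
        assert promoter_region(10_000, 20_000, "+") == (7_000, 10_000)

    def test_minus_strand(self):
        assert promoter_region(7_000, 10_000, "-") == (10_000, 13_000)

    def test_clipped_at_chromosome_start(self):
        assert promoter_region(1_000, 5_000, "+") == (0, 1_000)


class TestPeakAggregation:
    def test_intergenic_excluded_and_summed(self):
        counts = pd.DataFrame({"s1": [10, 5, 100]},
                              index=["p1", "p2", "p3"])
        counts.index.name = "feature_id"
        ann = pd.DataFrame({
            "feature_id": ["p1", "p2", "p3"],
            "category": ["promoter", "intron", "intergenic"],
            "gene_id": ["g", "g", None]})
        out = aggregate_peaks_to_genes(counts, ann)
        assert out.loc["g", "s1"] == 15

    def test_gene_with_only_intergenic_absent(self):
        counts = pd.DataFrame({"s1": [7]}, index=["p1"])
        counts.index.name = "feature_id"
        ann = pd.DataFrame({"feature_id": ["p1"], "category": ["intergenic"],
                            "gene_id": ["g"]})
        out = aggregate_peaks_to_genes(counts, ann)
        assert "g" not in out.index

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_summation(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        cats = rng.choice(["promoter", "exon", "intron", "intergenic"], n)
        genes = rng.choice(["g1", "g2", "g3"], n)
        counts = pd.DataFrame({"s": rng.integers(0, 100, n)},
                              index=[f"p{i}" for i in range(n)])
        counts.index.name = "feature_id"
        ann = pd.DataFrame({"feature_id": counts.index, "category": cats,
                            "gene_id": genes})
        out = aggregate_peaks_to_genes(counts, ann)
        for g in ["g1", "g2", "g3"]:
            exp = counts["s"][(cats != "intergenic") & (genes == g)].sum()
            if exp or ((cats != "intergenic") & (genes == g)).any():
                assert out.loc[g, "s"] == exp


class TestTrends:
    def _counts(self, rng, pattern, n_rep=6, base=200.0, fold=8.0):
        """Counts for 4 stages realizing a given up/down/flat pattern."""
        level = [base]
        for s in pattern:
            mult = {"up": fold, "down": 1 / fold, "flat": 1.0}[s]
            level.append(level[-1] * mult)
        cols, data = [], []
        meta = []
        for si, stage in enumerate(regions.TREND_STAGES):
            for r in range(n_rep):
                cols.append(f"{stage}_r{r}")
                meta.append({"sample_id": f"{stage}_r{r}", "stage": stage,
                             "sex": "F" if r % 2 else "M"})
            data.extend([level[si]] * n_rep)
        return cols, np.array(data), pd.DataFrame(meta)

    def test_exhaustive_27_patterns(self):
        """All 27 transition triples are realized and classified correctly."""
        rng = np.random.default_rng(0)
        patterns = list(itertools.product(["down", "flat", "up"], repeat=3))
        cols = meta = None
        rows = []
        for pat in patterns:
            c, mu, meta = self._counts(rng, pat)
            cols = c
            rows.append(rng.poisson(np.maximum(mu, 0.01)))
        counts = pd.DataFrame(rows, columns=cols,
                              index=[f"g{i}" for i in range(27)])
        # equalize library sizes so "flat" means flat after normalization
        counts.loc["filler"] = counts.sum().max() * 2 - counts.sum()
        out = trend_patterns(counts, meta, min_log2fc=1.0, alpha=0.05)
        out = out[out["feature_id"] != "filler"]
        assert sorted(out["pattern_id"]) == list(range(1, 28))
        got = {fid: tuple(t.split(",")) for fid, t in
               zip(out["feature_id"], out["transitions"])}
        for i, pat in enumerate(patterns):
            assert got[f"g{i}"] == pat

    def test_pattern_id_bijective(self):
        ids = {trend_pattern_id(p) for p in
               itertools.product(["down", "flat", "up"], repeat=3)}
        assert ids == set(range(1, 28))

    def test_missing_stage_raises(self):
        meta = pd.DataFrame({"sample_id": ["a"], "stage": ["F40"],
                             "sex": ["F"]})
        counts = pd.DataFrame({"a": [5]}, index=["g"])
        with pytest.raises(ValueError):
            trend_patterns(counts, meta)


class TestSpecificity:
    def _setup(self, rng, fold_vec, base=400.0, n_rep=4):
        """One gene per row; fold_vec gives per-tissue expression multipliers."""
        tissues = ["brain", "liver", "muscle"]
        cols, meta = [], []
        for t in tissues:
            for r in range(n_rep):
                cols.append(f"{t}_r{r}")
                meta.append({"sample_id": f"{t}_r{r}", "tissue": t,
                             "stage": "F70", "sex": "F" if r % 2 else "M"})
        rows = []
        for fv in fold_vec:
            mu = np.repeat([base * f for f in fv], n_rep)
            rows.append(rng.poisson(mu))
        counts = pd.DataFrame(rows, columns=cols,
                              index=[f"g{i}" for i in range(len(fold_vec))])
        counts.loc["filler"] = counts.sum().max() * 2 - counts.sum()
        return counts, pd.DataFrame(meta)

    def test_16fold_above_all_is_specific(self):
        rng = np.random.default_rng(0)
        counts, meta = self._setup(rng, [(20, 1, 1), (1, 1, 1)])
        out = regions.tissue_specific_genes(counts, meta)
        assert "g0" in out["brain"]
        assert "g1" not in out["brain"]

    def test_16fold_above_some_not_all(self):
        rng = np.random.default_rng(1)
        # 16-fold above liver but only 2-fold above muscle: not specific
        counts, meta = self._setup(rng, [(16, 1, 8)])
        out = regions.tissue_specific_genes(counts, meta)
        assert "g0" not in out["brain"]

    def test_flat_profile_not_specific(self):
        rng = np.random.default_rng(2)
        counts, meta = self._setup(rng, [(1, 1, 1)])
        out = regions.tissue_specific_genes(counts, meta)
        assert all("g0" not in s for s in out.values())

    def test_stage_specific_analogous(self):
        rng = np.random.default_rng(3)
        stages = ["F40", "F70", "D1", "D168"]
        cols, meta, = [], []
        for s in stages:
            for r in range(4):
                cols.append(f"{s}_r{r}")
                meta.append({"sample_id": f"{s}_r{r}", "stage": s,
                             "tissue": "muscle", "sex": "F" if r % 2 else "M"})
        mu = np.concatenate([np.full(4, 2000.0), np.full(12, 10.0)])
        counts = pd.DataFrame([rng.poisson(mu)], columns=cols, index=["g0"])
        counts.loc["filler"] = counts.sum().max() * 2 - counts.sum()
        out = regions.stage_specific_genes(counts, pd.DataFrame(meta))
        assert "g0" in out["F40"]
        assert all("g0" not in out[s] for s in ["F70", "D1", "D168"])


class TestEnrichment:
    def test_score_arithmetic(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        set_a = set(universe[:50])
        set_b = set(universe[:50])
        score, p = permutation_enrichment(set_a, set_b, universe,
                                          n_perm=200, rng=rng)
        # observed overlap 50, expected ~ 50*50/200 = 12.5
        assert score == pytest.approx(4.0, rel=0.15)
        assert p == pytest.approx(1 / 201)

    def test_p_counting_rule(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(100)]
        score, p = permutation_enrichment(set(universe[:20]),
                                          set(universe[:20]), universe,
                                          n_perm=100, rng=rng)
        assert p == pytest.approx(1 / 101)

    def test_null_pvalues_superuniform(self):
        """With set A drawn at random, P(p <= 0.05) stays near or below 0.05."""
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(300)]
        set_b = set(rng.choice(universe, 60, replace=False))
        hits = 0
        n_trials = 60
        for _ in range(n_trials):
            set_a = set(rng.choice(universe, 40, replace=False))
            _, p = permutation_enrichment(set_a, set_b, universe,
                                          n_perm=120, rng=rng)
            hits += p <= 0.05
        assert hits / n_trials <= 0.12

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            permutation_enrichment(set(), {"a"}, ["a"], n_perm=100)


class TestClusteringRatio:
    def _coords(self, positions, chrom="c1"):
        return pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(len(positions))],
            "chrom": chrom, "start": positions,
            "end": [p + 1000 for p in positions]})

    def test_tight_cluster_high_ratio(self):
        rng = np.random.default_rng(0)
        spread = list(np.linspace(0, 100e6, 100).astype(int))
        coords = self._coords(spread)
        # the first five genes, moved into one 0.5-Mb window
        coords.loc[:4, "start"] = [0, 100_000, 200_000, 300_000, 400_000]
        coords.loc[:4, "end"] = coords.loc[:4, "start"] + 1000
        ratio = pairwise_clustering_ratio(
            [f"g{i}" for i in range(5)], coords, n_draws=100, rng=rng)
        assert ratio > 2

    def test_random_set_ratio_near_one(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 50e6, 80)
        coords = self._coords(list(pos))
        ratios = [pairwise_clustering_ratio(
            list(rng.choice(coords["feature_id"], 20, replace=False)),
            coords, n_draws=60, rng=rng) for _ in range(10)]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.35)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 10e6, 30)
        chroms = rng.choice(["c1", "c2"], 30)
        coords = pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(30)],
            "chrom": chroms, "start": pos, "end": pos + 1000})
        sub = coords.iloc[:12]
        got = regions._close_pair_proportion(sub, 1e6)
        close = total = 0
        for i in range(12):
            for j in range(i + 1, 12):
                if sub.iloc[i]["chrom"] != sub.iloc[j]["chrom"]:
                    continue
                mi = sub.iloc[i]["start"] + 500
                mj = sub.iloc[j]["start"] + 500
                total += 1
                close += abs(mi - mj) < 1e6
        assert got == pytest.approx(close / total if total else np.nan)

    def test_small_set_raises(self):
        coords = self._coords([0, 10])
        with pytest.raises(ValueError):
            pairwise_clustering_ratio(["g0"], coords)
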