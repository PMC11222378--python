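"""Region-level analyses: allelic methylation regions, interval annotation,
tissue/stage specificity, developmental trends, enrichment statistics.

A poeMR (ageMR) is a genomic interval of at least three consecutive tested
CpGs, every one individually significant for the parent-of-origin (allele
genotype) effect, with no more than 1.5 kb between consecutive members.
"Consecutive" refers to the ordering of tested, filter-passing CpGs — a
tested but non-significant CpG breaks a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from allelescope import glm
from allelescope.asetest import design_matrix

MR_WINDOW = 1500
MR_MIN_RUN = 3
ANNOTATION_ORDER = ["promoter", "five_prime_utr", "three_prime_utr",
                    "exon", "intron", "intergenic"]
SPECIFICITY_FOLD = 16.0
TREND_STAGES = ["F40", "F70", "D1", "D168"]


@dataclass
class MethylationRegion:
    chrom: str
    start: int
    end: int
    kind: str                 # 'poeMR' or 'ageMR'
    cpg_positions: list[int] = field(default_factory=list)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def call_methylation_regions(cpg_results: pd.DataFrame, kind: str,
                             window: int = MR_WINDOW,
                             min_run: int = MR_MIN_RUN,
                             alpha: float = 0.05) -> list[MethylationRegion]:
    """Maximal runs of consecutive significant tested CpGs.

    ``cpg_results`` must be sorted by (chrom, pos) and carry an ``fdr``
    column (adjusted p-values for the requested effect).  A run extends
    while every CpG is significant and each gap between consecutive members
    is at most ``window``; runs shorter than ``min_run`` are dropped.
    """
    regions: list[MethylationRegion] = []
    for chrom, sub in cpg_results.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"CpG results not sorted by position on {chrom}")
        sig = (sub["fdr"] < alpha).to_numpy()
        run: list[int] = []
        for p, s in zip(pos, sig):
            if s and (not run or p - run[-1] <= window):
                run.append(int(p))
            else:
                if len(run) >= min_run:
                    regions.append(MethylationRegion(chrom, run[0], run[-1] + 1,
                                                     kind, run))
                run = [int(p)] if s else []
        if len(run) >= min_run:
            regions.append(MethylationRegion(chrom, run[0], run[-1] + 1, kind, run))
    return regions


def regions_to_bed(regions: list[MethylationRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "name": r.kind, "score": r.n_cpgs, "strand": ".",
    } for r in regions])


class AnnotationHierarchy:
    """Priority annotation of intervals against gene structure.

    Categories are tried in a fixed order (promoter, 5'UTR, 3'UTR, exon,
    intron); the first with at least 1 bp of overlap wins and its gene is
    attached; intervals overlapping nothing are intergenic.  The promoter
    is the strand-aware 3 kb window upstream of the TSS.
    """

    def __init__(self, gtf: pd.DataFrame, promoter_flank: int = 3000,
                 order: list[str] | None = None):
        self.order = list(order or ANNOTATION_ORDER)
        self.trees: dict[str, dict[str, IntervalTree]] = {
            cat: {} for cat in self.order if cat != "intergenic"}
        genes = gtf[gtf["feature"] == "gene"]
        for _, g in genes.iterrows():
            ps, pe = promoter_region(int(g["start"]), int(g["end"]),
                                     g["strand"], flank=promoter_flank)
            self._add("promoter", g["chrom"], ps, pe, g["gene_id"])
        for feat, cat in (("five_prime_utr", "five_prime_utr"),
                          ("three_prime_utr", "three_prime_utr"),
                          ("exon", "exon")):
            for _, f in gtf[gtf["feature"] == feat].iterrows():
                self._add(cat, f["chrom"], int(f["start"]), int(f["end"]),
                          f["gene_id"])
        # introns: gene span minus exon union
        exons = gtf[gtf["feature"] == "exon"]
        for gid, g in genes.set_index("gene_id").iterrows():
            ex = exons[exons["gene_id"] == gid]
            merged = []
            for s, e in sorted(zip(ex["start"], ex["end"])):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((int(s), int(e)))
            prev = int(g["start"])
            for s, e in merged:
                if s > prev:
                    self._add("intron", g["chrom"], prev, s, gid)
                prev = max(prev, e)
            if prev < int(g["end"]):
                self._add("intron", g["chrom"], prev, int(g["end"]), gid)

    def _add(self, cat: str, chrom: str, start: int, end: int, gene: str):
        if end > start and cat in self.trees:
            self.trees[cat].setdefault(chrom, IntervalTree())[start:end] = gene

    def annotate(self, chrom: str, start: int, end: int) -> tuple[str, str | None]:
        """(category, gene_id) of the first overlapping category in order."""
        for cat in self.order:
            if cat == "intergenic":
                break
            tree = self.trees.get(cat, {}).get(chrom)
            if tree is None:
                continue
            hits = tree[start:end]
            if hits:
                return cat, sorted(iv.data for iv in hits)[0]
        return "intergenic", None


def annotate_interval(interval: tuple[str, int, int],
                      hierarchy: AnnotationHierarchy) -> tuple[str, str | None]:
    return hierarchy.annotate(*interval)


def promoter_region(start: int, end: int, strand: str,
                    flank: int = 3000, chrom_length: int | None = None
                    ) -> tuple[int, int]:
    """Strand-aware promoter window upstream of the TSS, clipped to bounds."""
    if strand == "-":
        tss = end  # last base is the TSS for minus-strand genes
        lo, hi = tss, tss + flank
    else:
        tss = start
        lo, hi = tss - flank, tss
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def aggregate_peaks_to_genes(peak_counts: pd.DataFrame,
                             peak_annotations: pd.DataFrame) -> pd.DataFrame:
    """Sum peak counts to genes, dropping intergenic peaks.

    ``peak_annotations`` has feature_id, category, gene_id (from
    :class:`AnnotationHierarchy`); genes whose only peaks are intergenic are
    absent from the result.
    """
    ann = peak_annotations.set_index("feature_id")
    keep = ann[(ann["category"] != "intergenic") & ann["gene_id"].notna()]
    joined = peak_counts.join(keep[["gene_id"]], how="inner")
    return joined.groupby("gene_id").sum(numeric_only=True)


def _pairwise_level_tests(counts: pd.DataFrame, meta: pd.DataFrame,
                          level_col: str, alpha: float, fold: float,
                          dispersion_prior_weight: float = 0.9):
    """For each level: per-gene log2FC and significance against every other
    level (NB GLM with level indicator + sex)."""
    levels = sorted(meta[level_col].unique())
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            sub = meta[meta[level_col].isin([a, b])]
            Y = counts[sub["sample_id"]].to_numpy(dtype=float)
            lib = np.log(np.maximum(Y.sum(axis=0), 1.0))
            ind = (sub[level_col] == a).to_numpy(dtype=float)
            sex = sub["sex"].astype(str).str.upper().str.startswith("M")
            X = np.column_stack([np.ones(len(sub)), ind, sex.to_numpy(float)])
            keep = [0, 1] + ([2] if X[:, 2].std() > 0 else [])
            X = X[:, keep]
            disp = glm.estimate_dispersion(Y, X, lib,
                                           prior_weight=dispersion_prior_weight)
            full = glm.fit_nb_glm(Y, X, lib, disp)
            red = glm.fit_nb_glm(Y, X[:, [i for i in range(X.shape[1]) if i != 1]],
                                 lib, disp)
            p = glm.lrt_pvalues(full["loglik"], red["loglik"])
            res = pd.DataFrame({
                "log2fc": full["beta"][:, 1] / np.log(2.0),  # a over b
                "fdr": glm.bh_fdr(p),
            }, index=counts.index)
            results[(a, b)] = res
    return levels, results


def _specific_sets(counts, meta, level_col, fold, alpha,
                   dispersion_prior_weight=0.9) -> dict[str, set[str]]:
    levels, tests = _pairwise_level_tests(counts, meta, level_col, alpha, fold,
                                          dispersion_prior_weight)
    log2_gate = np.log2(fold)
    out: dict[str, set[str]] = {}
    for ref in levels:
        ok = pd.Series(True, index=counts.index)
        for other in levels:
            if other == ref:
                continue
            key = (ref, other) if (ref, other) in tests else (other, ref)
            res = tests[key]
            lfc = res["log2fc"] if key[0] == ref else -res["log2fc"]
            ok &= (lfc >= log2_gate) & (res["fdr"] < alpha)
        out[ref] = set(counts.index[ok])
    return out


def tissue_specific_genes(counts: pd.DataFrame, meta: pd.DataFrame,
                          fold: float = SPECIFICITY_FOLD, alpha: float = 0.05
                          ) -> dict[str, set[str]]:
    """Genes at least ``fold`` higher in one tissue than in *every* other
    tissue (FDR < alpha for each contrast), within one stage's samples."""
    return _specific_sets(counts, meta, "tissue", fold, alpha)


def stage_specific_genes(counts: pd.DataFrame, meta: pd.DataFrame,
                         fold: float = SPECIFICITY_FOLD, alpha: float = 0.05
                         ) -> dict[str, set[str]]:
    """Genes at least ``fold`` higher in one stage than in every other stage,
    within one tissue's samples."""
    return _specific_sets(counts, meta, "stage", fold, alpha)


def classify_transition(log2fc: float, fdr: float,
                        min_log2fc: float = 1.0, alpha: float = 0.05) -> str:
    """One stage-to-stage transition: up, down, or flat."""
    if fdr < alpha and log2fc >= min_log2fc:
        return "up"
    if fdr < alpha and log2fc <= -min_log2fc:
        return "down"
    return "flat"


_TREND_CODE = {"down": 0, "flat": 1, "up": 2}


def trend_pattern_id(signs: tuple[str, str, str]) -> int:
    """Base-3 encoding of the three transitions; ids are 1..27."""
    return 1 + sum(_TREND_CODE[s] * 3 ** i for i, s in enumerate(signs))


def trend_patterns(counts: pd.DataFrame, meta: pd.DataFrame,
                   stages: list[str] | None = None,
                   min_log2fc: float = 1.0, alpha: float = 0.05,
                   dispersion_prior_weight: float = 0.9) -> pd.DataFrame:
    """Developmental trend classification over ordered stages in one tissue.

    Each of the three consecutive stage transitions is tested with the NB
    GLM and classified up/down/flat; the triple is encoded into one of the
    27 (3^3) possible pattern classes.
    """
    stages = stages or TREND_STAGES
    present = [s for s in stages if (meta["stage"] == s).any()]
    if len(present) < len(stages):
        raise ValueError(f"missing stages: {set(stages) - set(present)}")
    per_transition = []
    for s0, s1 in zip(stages, stages[1:]):
        sub = meta[meta["stage"].isin([s0, s1])]
        Y = counts[sub["sample_id"]].to_numpy(dtype=float)
        lib = np.log(np.maximum(Y.sum(axis=0), 1.0))
        ind = (sub["stage"] == s1).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), ind])
        disp = glm.estimate_dispersion(Y, X, lib,
                                       prior_weight=dispersion_prior_weight)
        full = glm.fit_nb_glm(Y, X, lib, disp)
        red = glm.fit_nb_glm(Y, X[:, :1], lib, disp)
        p = glm.lrt_pvalues(full["loglik"], red["loglik"])
        per_transition.append(pd.DataFrame({
            "log2fc": full["beta"][:, 1] / np.log(2.0),
            "fdr": glm.bh_fdr(p),
        }, index=counts.index))
    rows = []
    for gene in counts.index:
        signs = tuple(
            classify_transition(t.loc[gene, "log2fc"], t.loc[gene, "fdr"],
                                min_log2fc, alpha)
            for t in per_transition)
        rows.append({"feature_id": gene,
                     "transitions": ",".join(signs),
                     "pattern_id": trend_pattern_id(signs)})
    return pd.DataFrame(rows)


def permutation_enrichment(set_a: set, set_b: set, universe: list,
                           n_perm: int = 1000,
                           rng: np.random.Generator | None = None
                           ) -> tuple[float, float]:
    """Overlap enrichment of two gene sets against random draws.

    Score = observed overlap / mean overlap of ``n_perm`` random sets of
    |set_a| drawn from the universe; p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if not set_a or not set_b:
        raise ValueError("empty gene set")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = rng or np.random.default_rng()
    universe = list(universe)
    b = set_b
    observed = len(set_a & b)
    perm = np.empty(n_perm)
    size = len(set_a)
    for i in range(n_perm):
        draw = rng.choice(len(universe), size=size, replace=False)
        perm[i] = sum(1 for j in draw if universe[j] in b)
    mean_perm = perm.mean()
    score = observed / mean_perm if mean_perm > 0 else np.inf
    p = (1 + int((perm >= observed).sum())) / (n_perm + 1)
    return float(score), float(p)


def _close_pair_proportion(coords: pd.DataFrame, max_dist: float) -> float:
    """Proportion of same-chromosome midpoint pairs closer than max_dist."""
    close = total = 0
    for _, sub in coords.groupby("chrom"):
        mid = ((sub["start"] + sub["end"]) / 2).to_numpy()
        n = len(mid)
        if n < 2:
            continue
        d = np.abs(mid[:, None] - mid[None, :])
        iu = np.triu_indices(n, k=1)
        close += int((d[iu] < max_dist).sum())
        total += len(iu[0])
    return close / total if total else float("nan")


def pairwise_clustering_ratio(gene_set: list, gene_coords: pd.DataFrame,
                              max_dist: float = 1e6, n_draws: int = 200,
                              rng: np.random.Generator | None = None) -> float:
    """Chromosomal clustering of a gene set relative to random sets.

    The proportion of same-chromosome pairwise midpoint distances under
    ``max_dist`` within the set, divided by the mean proportion over
    ``n_draws`` equally sized random gene sets.  Cross-chromosome pairs are
    excluded.
    """
    if len(gene_set) < 2:
        raise ValueError("gene set must contain at least 2 genes")
    rng = rng or np.random.default_rng()
    coords = gene_coords.set_index("feature_id")
    obs = _close_pair_proportion(coords.loc[list(gene_set)].reset_index(), max_dist)
    all_ids = list(coords.index)
    draws = []
    for _ in range(n_draws):
        pick = rng.choice(len(all_ids), size=len(gene_set), replace=False)
        sub = coords.iloc[pick].reset_index()
        draws.append(_close_pair_proportion(sub, max_dist))
    expected = float(np.nanmean(draws))
    return obs / expected if expected > 0 else float("inf")
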