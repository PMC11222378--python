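"""End-to-end validation checks on synthetic data with planted truth.

Each function builds its own inputs from a seed, runs the relevant part of
the package, and returns measured quantities (accuracy rates, calibration
statistics, recovery metrics).  They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from allelescope import asetest, glm, regions, sim
from allelescope.assignment import (
    CONFLICT, MATERNAL, PATERNAL, UNASSIGNED, assign_fragment,
)
from allelescope.genomes import DELETED, INSERTED, build_individualized_genome


def _reciprocal_sheet(n_per_sex=3):
    rows = []
    for d in ("DxL", "LxD"):
        for sex in ("F", "M"):
            for i in range(n_per_sex):
                rows.append({"sample_id": f"{d}_{sex}{i}",
                             "individual": f"{d}_{sex}{i}",
                             "tissue": "muscle", "stage": "F70",
                             "sex": sex, "cross_direction": d})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def design_enumeration() -> dict:
    """Tissue-sample counts of the full reciprocal-cross study design."""
    sheet = sim.make_sample_sheet(template="full")
    fetal = int((sheet["stage"].isin(["F40", "F70"])).sum())
    return {"fetal_samples": fetal, "total_samples": int(len(sheet))}


def trend_class_enumeration(seed: int) -> dict:
    """Distinct developmental-trend classes over an exhaustive profile set."""
    import itertools

    rng = np.random.default_rng(seed)
    patterns = list(itertools.product(["down", "flat", "up"], repeat=3))
    cols, meta = [], []
    for stage in regions.TREND_STAGES:
        for r in range(6):
            cols.append(f"{stage}_r{r}")
            meta.append({"sample_id": f"{stage}_r{r}", "stage": stage,
                         "sex": "F" if r % 2 else "M"})
    rows = []
    for pat in patterns:
        level = [200.0]
        for s in pat:
            level.append(level[-1] * {"up": 8, "down": 1 / 8, "flat": 1}[s])
        mu = np.repeat(level[:4], 6)
        rows.append(rng.poisson(mu))
    counts = pd.DataFrame(rows, columns=cols,
                          index=[f"g{i}" for i in range(27)])
    counts.loc["filler"] = counts.sum().max() * 2 - counts.sum()
    out = regions.trend_patterns(counts, pd.DataFrame(meta))
    out = out[out["feature_id"] != "filler"]
    correct = sum(
        tuple(t.split(",")) == pat
        for t, pat in zip(out.sort_values("feature_id", key=lambda s: s.str[1:]
                                          .astype(int))["transitions"], patterns))
    return {"n_pattern_classes": int(out["pattern_id"].nunique()),
            "n_profiles_correct": int(correct)}


def roundtrip_check(seed: int, n_genomes: int = 200) -> dict:
    """lift -> lift_back identity on every non-deleted base, plus exact
    length conservation, over random toy genomes with mixed SNPs/indels."""
    rng = np.random.default_rng(seed)
    n_positions = 0
    n_identity = 0
    n_length_ok = 0
    for _ in range(n_genomes):
        length = int(rng.integers(2000, 10001))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        variants = _random_variants(rng, seq,
                                    n_snp=int(rng.integers(5, 30)),
                                    n_indel=int(rng.integers(3, 15)))
        g = build_individualized_genome({"chr": seq}, variants)
        delta = sum(v.length_delta for v in variants)
        n_length_ok += len(g.sequences["chr"]) == length + delta
        cm = g.map.chroms["chr"]
        pos = rng.choice(length, size=min(length, 300), replace=False)
        for p in pos:
            f = cm.forward(int(p))
            if f is DELETED:
                continue
            n_positions += 1
            n_identity += cm.back(f) == p
    return {"n_genomes": n_genomes,
            "roundtrip_identity_pct": 100.0 * n_identity / n_positions,
            "length_conservation_pct": 100.0 * n_length_ok / n_genomes}


def _random_variants(rng, seq, n_snp, n_indel, max_indel=5):
    from allelescope.genomes import VariantRecord

    guard = max_indel + 2
    pos = np.sort(rng.choice(len(seq) - 2 * guard,
                             size=min(n_snp + n_indel, len(seq) // 20),
                             replace=False) + guard)
    keep = np.concatenate([[True], np.diff(pos) > guard])
    pos = pos[keep]
    out = []
    for i, p in enumerate(pos):
        p = int(p)
        refb = seq[p]
        if i % 3 == 0 and n_indel > 0:      # every third variant an indel
            k = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:
                ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, k)])
                out.append(VariantRecord("chr", p, refb, refb + ins))
            else:
                out.append(VariantRecord("chr", p, seq[p:p + k + 1], refb))
        else:
            alt = "ACGT"[(("ACGT".index(refb)) + 1 + int(rng.integers(3))) % 4]
            out.append(VariantRecord("chr", p, refb, alt))
    return out


def assignment_oracle(seed: int, target_fragments: int = 50_000) -> dict:
    """Error-free fragment assignment accuracy against generator truth.

    Counts only fragments whose reads cover at least one informative
    substitution site; also verifies that artificially conflicting mate
    pairs are always discarded.
    """
    import tempfile
    from pathlib import Path

    from allelescope.assignment import assign_sample
    from allelescope.pipeline import (
        _constitutive_union_by_chrom, build_parental_genomes,
        informative_by_direction,
    )
    from allelescope import io
    from allelescope.assignment import compute_constitutive_exons

    cfg = sim.SimulationConfig(
        seed=seed, chrom_lengths={"chr1": 400_000}, n_genes=100,
        mean_count=float(target_fragments) / 100 / 6, base_error=0.0,
        replicates_per_sex=3)
    rng = np.random.default_rng(seed)
    samples = sim.make_sample_sheet(cfg).iloc[:6]
    annotation = sim.simulate_annotation(cfg, rng)
    ref = sim.make_reference(cfg, rng)
    _, plan = sim.simulate_parental_genomes(cfg, rng, annotation, ref=ref)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        sim.write_vcf(plan, ref, tmp / "p.vcf")
        parental = build_parental_genomes(ref, tmp / "p.vcf")
        oriented = informative_by_direction(tmp / "p.vcf", annotation)
        truth = sim.plant_gene_effects(
            cfg, sorted(annotation[annotation["feature"] == "gene"]
                        ["gene_id"].unique()), rng)
        frag_truth = sim.simulate_rna(cfg, annotation, parental, samples,
                                      truth, rng, tmp / "sam")
        const = compute_constitutive_exons(annotation)
        union = _constitutive_union_by_chrom(annotation, const)
        n_checked = n_correct = n_conflict = 0
        site_pos = {c: np.sort(s["pos"].to_numpy())
                    for c, s in oriented["DxL"].groupby("chrom")}
        for _, s in samples.iterrows():
            par = sim.PARENTS[s["cross_direction"]]
            frags, _ = assign_sample(
                tmp / f"sam/{s['sample_id']}.rna.maternal.sam",
                tmp / f"sam/{s['sample_id']}.rna.paternal.sam",
                oriented[s["cross_direction"]],
                parental[par["dam"]].map, parental[par["sire"]].map,
                mode="rna", constitutive_union=union)
            lookup = frag_truth[frag_truth["sample_id"] == s["sample_id"]]
            lookup = dict(zip(lookup["fragment_id"], lookup["origin"]))
            for fr in frags:
                n_conflict += fr.decision == CONFLICT
                covered = False
                pos = site_pos.get(fr.chrom)
                if pos is not None:
                    for ivs in fr.mate_intervals:
                        for a, b in ivs:
                            i0, i1 = np.searchsorted(pos, [a, b])
                            if i1 > i0:
                                covered = True
                if not covered:
                    continue
                n_checked += 1
                want = MATERNAL if lookup[fr.fragment_id] == "maternal" else PATERNAL
                n_correct += fr.decision == want
    # constructed conflicting mate pairs must always be discarded
    n_conflict_tests = 500
    n_discarded = 0
    rng2 = np.random.default_rng(seed + 1)
    for i in range(n_conflict_tests):
        d1, d2 = (MATERNAL, PATERNAL) if rng2.random() < 0.5 else (PATERNAL, MATERNAL)
        n_discarded += assign_fragment(f"c{i}", [d1, d2]).decision == CONFLICT
    return {"n_fragments_checked": int(n_checked),
            "assignment_accuracy_pct": 100.0 * n_correct / n_checked,
            "n_conflicts_in_clean_data": int(n_conflict),
            "conflict_discard_pct": 100.0 * n_discarded / n_conflict_tests}


def null_calibration(seed: int, n_features: int = 2000,
                     mean_count: float = 100.0,
                     dispersion: float = 0.1) -> dict:
    """Raw p-value uniformity and realized false positive rate on null
    allelic counts (no PO or AG effect, NB noise)."""
    rng = np.random.default_rng(seed)
    design = asetest.build_design(_reciprocal_sheet())
    r = 1.0 / dispersion
    Y = rng.negative_binomial(r, r / (r + mean_count / 2),
                              size=(n_features, len(design)))
    mat, pat = {}, {}
    for j, (_, rr) in enumerate(design.iterrows()):
        (mat if rr["origin"] == "maternal" else pat)[rr["sample_id"]] = Y[:, j]
    res = asetest.fit_count_glm(pd.DataFrame(mat), pd.DataFrame(pat), design)
    out = {}
    for eff in ("POE", "AGE"):
        p = res[res["effect"] == eff]["pvalue"].dropna().to_numpy()
        out[f"{eff.lower()}_ks_pvalue"] = float(stats.kstest(p, "uniform").pvalue)
        out[f"{eff.lower()}_fpr_at_0.05"] = float((p < 0.05).mean())
    out["n_features"] = n_features
    return out


def effect_recovery(seed: int, n_features: int = 200,
                    mean_count: float = 100.0,
                    dispersion: float = 0.1) -> dict:
    """Planted-effect estimation accuracy and imprinting-rule coverage.

    POE/AGE log2FC planted from {1, 2, 3} (both signs); estimates compared
    to truth.  Imprinted features planted at paternal fraction 0.95 must
    all be flagged by the 95%/5% rule.
    """
    rng = np.random.default_rng(seed)
    sheet = _reciprocal_sheet()
    design = asetest.build_design(sheet)
    X = design[asetest.EFFECT_COLUMNS].to_numpy()
    lfcs = []
    Y = np.empty((n_features, len(design)))
    r = 1.0 / dispersion
    for f in range(n_features):
        lfc = [1.0, 2.0, 3.0][f % 3] * (1 if f % 2 else -1)
        col = 1 if f % 4 < 2 else 2            # alternate POE / AGE
        beta = np.zeros(5)
        beta[col] = lfc * np.log(2)
        eta = X @ beta
        mu = mean_count / 2 * np.exp(eta - eta.mean())
        Y[f] = rng.negative_binomial(r, r / (r + mu))
        lfcs.append((lfc, "POE" if col == 1 else "AGE"))
    mat, pat = {}, {}
    for j, (_, rr) in enumerate(design.iterrows()):
        (mat if rr["origin"] == "maternal" else pat)[rr["sample_id"]] = Y[:, j]
    res = asetest.fit_count_glm(pd.DataFrame(mat), pd.DataFrame(pat), design)
    n_ok = 0
    for f, (lfc, eff) in enumerate(lfcs):
        est = res[(res["effect"] == eff)].iloc[f]["log2fc"]
        n_ok += abs(est - lfc) <= 0.5
    # imprinted features at paternal fraction 0.95, coverage >= 100 per
    # sample: expected allelic counts exercise the inclusive 95%/5% boundary
    # (a stochastic draw at exactly 0.95 would straddle it by construction)
    n_imp = 50
    totals = rng.integers(100, 300, size=(n_imp, 12))
    m_counts = np.floor(0.05 * totals)
    p_counts = totals - m_counts
    fr = pd.DataFrame({
        "feature_id": np.repeat([f"imp{i}" for i in range(n_imp)], 12),
        "tissue": "muscle", "stage": "F70",
        "paternal_fraction": (p_counts / totals).ravel()})
    mean_fr = fr.groupby(["feature_id", "tissue", "stage"], as_index=False)[
        "paternal_fraction"].mean()
    flags = asetest.call_imprinted(mean_fr)
    return {"n_features": n_features,
            "recovery_within_0.5_pct": 100.0 * n_ok / n_features,
            "imprinted_flagged_pct": 100.0 * flags["imprint_flag"].mean()}


def mr_caller_equivalence(seed: int, n_instances: int = 500) -> dict:
    """Region caller vs brute-force enumeration on randomized instances."""
    rng = np.random.default_rng(seed)
    n_match = 0
    for _ in range(n_instances):
        n = int(rng.integers(3, 51))
        pos = np.sort(rng.choice(25_000, size=n, replace=False))
        sig = rng.random(n) < rng.uniform(0.3, 0.8)
        df = pd.DataFrame({"chrom": "c", "pos": pos,
                           "fdr": np.where(sig, 0.001, 0.5)})
        got = [(r.start, r.end, r.n_cpgs)
               for r in regions.call_methylation_regions(df, "poeMR")]
        # oracle: start at every significant CpG, extend while rules hold
        expect = []
        i = 0
        while i < n:
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and sig[j + 1] and pos[j + 1] - pos[j] <= 1500:
                j += 1
            if j - i + 1 >= 3:
                expect.append((int(pos[i]), int(pos[j]) + 1, j - i + 1))
            i = j + 1
        n_match += got == expect
    return {"n_instances": n_instances,
            "mr_caller_agreement_pct": 100.0 * n_match / n_instances}


def glm_oracle(seed: int, n_features: int = 40) -> dict:
    """Coefficient agreement with statsmodels GLM and the BH formula."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    design = asetest.build_design(_reciprocal_sheet())
    X, _ = asetest.design_matrix(design)
    n = len(X)
    offset = rng.normal(9, 0.1, n)
    alpha = np.full(n_features, 0.1)
    beta = rng.normal(0, 0.4, (n_features, X.shape[1]))
    beta[:, 0] = -5
    mu = np.exp(beta @ X.T + offset)
    r = 1 / alpha[:, None]
    Y = rng.negative_binomial(r, r / (r + mu))
    fit = glm.fit_nb_glm(Y, X, offset, alpha)
    nb_diff = 0.0
    for f in range(n_features):
        ref = sm.GLM(Y[f], X, family=sm.families.NegativeBinomial(
            alpha=alpha[f]), offset=offset).fit(tol=1e-12)
        nb_diff = max(nb_diff, float(np.abs(ref.params - fit["beta"][f]).max()))
    bb = rng.normal(0, 0.7, (n_features, X.shape[1]))
    p = 1 / (1 + np.exp(-(bb @ X.T)))
    N = np.full((n_features, n), 30)
    M = rng.binomial(N, p)
    fitb = glm.fit_binomial_glm(M, N - M, X)
    bin_diff = 0.0
    for f in range(n_features):
        ref = sm.GLM(np.column_stack([M[f], N[f] - M[f]]), X,
                     family=sm.families.Binomial()).fit(tol=1e-12)
        bin_diff = max(bin_diff, float(np.abs(ref.params - fitb["beta"][f]).max()))
    # BH against the textbook step-up formula
    pv = rng.random(137)
    q = glm.bh_fdr(pv)
    order = np.argsort(pv)
    ranked = pv[order] * len(pv) / np.arange(1, len(pv) + 1)
    expect = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1)
    back = np.empty_like(pv)
    back[order] = expect
    bh_diff = float(np.abs(q - back).max())
    return {"nb_coef_max_abs_diff": nb_diff,
            "binomial_coef_max_abs_diff": bin_diff,
            "bh_max_abs_diff": bh_diff}


def end_to_end(seed: int, outdir, modalities=("rna", "atac", "meth")) -> dict:
    """Demo-scale pipeline run; RNA gene-class recovery is the headline."""
    from allelescope.pipeline import run_pipeline

    cfg = sim.SimulationConfig(seed=seed)
    return run_pipeline(cfg, outdir, modalities=modalities, force=True)
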