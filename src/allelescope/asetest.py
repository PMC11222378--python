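"""Reciprocal-cross allelic testing: design, models, classification.

Each sample contributes two observations per feature — its maternal and its
paternal allelic count.  The reciprocal design (Duroc dam x Lulai sire and
the reverse) makes the parent-of-origin effect (POE) and the allele
genotype effect (AGE) separable: within one cross direction the two are
perfectly confounded, across both they are linearly independent.  The
allelic model is

    count ~ POE + AGE + MG + Sex        (log link, NB for RNA/ATAC)
    (m, u) ~ POE + AGE + MG + Sex       (logit link, binomial for CpGs)

where PO = 1 for paternal observations, AG = 1 for Duroc alleles, MG = 1
when the Duroc breed was the dam (absorbs maternal-environment differences
between the reciprocal directions) and Sex = 1 for males.  The offset is
each sample's log total assigned allelic reads, shared by both alleles of
the sample, so library-size normalization cannot alter within-sample
allelic ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from allelescope import glm

LN2 = np.log(2.0)

EFFECT_COLUMNS = ["intercept", "po", "ag", "mg", "sex"]

ASE_FOLD_RNA = 4.0      # origin fold-change gate for RNA allelic calls
ASE_FOLD_ATAC = 2.0     # and for ATAC peak/gene accessibility calls
IMPRINT_FRACTION = 0.95
STRONG_POE_FRACTION = 0.75


def maternal_breed(cross_direction: str) -> str:
    """'DxL' means Duroc dam x Lulai sire; the first letter is the dam."""
    d = cross_direction.replace("×", "x").upper()
    if d.startswith("D"):
        return "Duroc"
    if d.startswith("L"):
        return "Lulai"
    raise ValueError(f"unrecognized cross direction {cross_direction!r}")


def build_design(samples: pd.DataFrame, require_both_directions: bool = True
                 ) -> pd.DataFrame:
    """Two allele-level rows per sample with the PO/AG/MG/Sex encoding.

    Raises when only one cross direction is present (PO and AG are then
    structurally collinear) unless ``require_both_directions`` is False,
    in which case only the POE contrast remains testable.
    """
    if len(samples) == 0:
        raise ValueError("no samples")
    rows = []
    for _, s in samples.iterrows():
        mb = maternal_breed(s["cross_direction"])
        for origin in ("maternal", "paternal"):
            breed = mb if origin == "maternal" else ("Lulai" if mb == "Duroc" else "Duroc")
            rows.append({
                "sample_id": s["sample_id"],
                "origin": origin,
                "breed": breed,
                "intercept": 1.0,
                "po": 1.0 if origin == "paternal" else 0.0,
                "ag": 1.0 if breed == "Duroc" else 0.0,
                "mg": 1.0 if mb == "Duroc" else 0.0,
                "sex": 1.0 if str(s["sex"]).upper().startswith("M") else 0.0,
            })
    design = pd.DataFrame(rows)
    X = design[EFFECT_COLUMNS].to_numpy()
    # estimability: drop-column rank test for po and ag
    rank_full = np.linalg.matrix_rank(X[:, [0, 1, 2]])
    if rank_full < 3 and require_both_directions:
        raise ValueError(
            "PO and AG are collinear: the sample sheet contains a single "
            "cross direction; both reciprocal directions are required to "
            "separate parent-of-origin from allele-genotype effects")
    return design


def design_matrix(design: pd.DataFrame, drop: str | None = None
                  ) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in EFFECT_COLUMNS if c != drop]
    X = design[cols].to_numpy(dtype=float)
    # drop constant non-intercept columns (e.g. sex in a single-sex subset)
    keep = [i for i, c in enumerate(cols)
            if c == "intercept" or X[:, i].std() > 0]
    return X[:, keep], [cols[i] for i in keep]


def filter_expression(counts: pd.DataFrame, cpm_min: float = 1.0,
                      n_min: int = 6) -> pd.Index:
    """Features with CPM above ``cpm_min`` in at least ``n_min`` samples."""
    libsize = counts.sum(axis=0)
    cpm = counts.div(libsize.replace(0, np.nan), axis=1) * 1e6
    ok = (cpm > cpm_min).sum(axis=1) >= n_min
    return counts.index[ok]


def _observation_matrix(maternal: pd.DataFrame, paternal: pd.DataFrame,
                        design: pd.DataFrame) -> np.ndarray:
    """Stack allelic counts (features x observations) in design row order."""
    cols = []
    for _, r in design.iterrows():
        src = maternal if r["origin"] == "maternal" else paternal
        cols.append(src[r["sample_id"]].to_numpy(dtype=float))
    return np.column_stack(cols)


def allelic_offsets(maternal: pd.DataFrame, paternal: pd.DataFrame,
                    design: pd.DataFrame) -> np.ndarray:
    """log total assigned allelic reads per sample, shared by both alleles."""
    lib = maternal.sum(axis=0) + paternal.sum(axis=0)
    return np.array([np.log(max(float(lib[r["sample_id"]]), 1.0))
                     for _, r in design.iterrows()])


def fit_count_glm(maternal: pd.DataFrame, paternal: pd.DataFrame,
                  design: pd.DataFrame,
                  dispersion: np.ndarray | float | None = None,
                  dispersion_prior_weight: float = 0.9) -> pd.DataFrame:
    """Per-feature NB tests of the PO and AG coefficients.

    ``maternal`` / ``paternal`` are features x samples count tables aligned
    on index.  Returns a long DataFrame with one POE and one AGE row per
    feature: log2fc (paternal/maternal for POE, Duroc/Lulai for AGE),
    p-value (LRT), BH fdr, converged flag.
    """
    features = maternal.index
    Y = _observation_matrix(maternal, paternal, design)
    offset = allelic_offsets(maternal, paternal, design)
    X_full, cols = design_matrix(design)
    if dispersion is None:
        alpha = glm.estimate_dispersion(Y, X_full, offset,
                                        prior_weight=dispersion_prior_weight)
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (len(Y),))
    full = glm.fit_nb_glm(Y, X_full, offset, alpha)
    out = []
    for effect, col in (("POE", "po"), ("AGE", "ag")):
        if col not in cols:
            raise ValueError(f"column {col} not estimable in this design")
        X_red, _ = design_matrix(design, drop=col)
        red = glm.fit_nb_glm(Y, X_red, offset, alpha)
        pvals = glm.lrt_pvalues(full["loglik"], red["loglik"])
        ok = full["converged"] & red["converged"]
        pvals = np.where(ok, pvals, np.nan)
        out.append(pd.DataFrame({
            "feature_id": features,
            "effect": effect,
            "log2fc": full["beta"][:, cols.index(col)] / LN2,
            "pvalue": pvals,
            "fdr": glm.bh_fdr(pvals),
            "converged": ok,
        }))
    return pd.concat(out, ignore_index=True)


def fit_binomial_glm(m_counts: pd.DataFrame, u_counts: pd.DataFrame,
                     design: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG binomial tests of PO and AG on (methylated, unmethylated) pairs.

    Complete separation is flagged and the p-value set missing (never 0).
    Columns of ``m_counts``/``u_counts`` are design observations named
    '<sample>.maternal' / '<sample>.paternal'.
    """
    obs_names = [f"{r['sample_id']}.{r['origin']}" for _, r in design.iterrows()]
    M = m_counts[obs_names].to_numpy(dtype=float)
    U = u_counts[obs_names].to_numpy(dtype=float)
    X_full, cols = design_matrix(design)
    full = glm.fit_binomial_glm(M, U, X_full)
    out = []
    for effect, col in (("POE", "po"), ("AGE", "ag")):
        X_red, _ = design_matrix(design, drop=col)
        red = glm.fit_binomial_glm(M, U, X_red)
        pvals = glm.lrt_pvalues(full["loglik"], red["loglik"])
        ok = full["converged"] & red["converged"]
        pvals = np.where(ok, pvals, np.nan)
        out.append(pd.DataFrame({
            "feature_id": m_counts.index,
            "effect": effect,
            "log2fc": full["beta"][:, cols.index(col)] / LN2,  # log2 odds ratio
            "pvalue": pvals,
            "fdr": glm.bh_fdr(pvals),
            "converged": ok,
            "separated": full["separated"] | red["separated"],
        }))
    return pd.concat(out, ignore_index=True)


def allelic_fold_changes(maternal: pd.DataFrame, paternal: pd.DataFrame,
                         design: pd.DataFrame) -> pd.DataFrame:
    """Origin and breed fold changes from library-size-normalized allelic means.

    Returns per feature: paternal_fraction, fold_origin
    (max(pat, mat)/min(pat, mat)) and fold_breed (same for Duroc/Lulai),
    computed on counts normalized by each sample's total allelic library.
    """
    lib = (maternal.sum(axis=0) + paternal.sum(axis=0)).replace(0, np.nan)
    mat_n = maternal.div(lib, axis=1)
    pat_n = paternal.div(lib, axis=1)
    duroc_cols = {r["sample_id"]: r["origin"] for _, r in design.iterrows()
                  if r["breed"] == "Duroc"}
    duroc = pd.DataFrame({
        s: (mat_n[s] if o == "maternal" else pat_n[s])
        for s, o in duroc_cols.items()})
    lulai = pd.DataFrame({
        s: (pat_n[s] if o == "maternal" else mat_n[s])
        for s, o in duroc_cols.items()})
    eps = 1e-9
    mat_mean = mat_n.mean(axis=1) + eps
    pat_mean = pat_n.mean(axis=1) + eps
    d_mean = duroc.mean(axis=1) + eps
    l_mean = lulai.mean(axis=1) + eps
    return pd.DataFrame({
        "paternal_fraction": pat_mean / (mat_mean + pat_mean),
        "fold_origin": np.maximum(pat_mean / mat_mean, mat_mean / pat_mean),
        "fold_breed": np.maximum(d_mean / l_mean, l_mean / d_mean),
    }, index=maternal.index)


def classify_ase(results: pd.DataFrame, folds: pd.DataFrame,
                 mode: str = "rna", alpha: float = 0.05,
                 rescue_log2fc: float = 1.0) -> pd.DataFrame:
    """Per-feature POE/AGE class calls from per-context test results.

    ``results`` is long with columns feature_id, context, effect, log2fc,
    fdr; ``folds`` indexed by feature_id carries fold_origin / fold_breed.
    A feature is called in a context when fdr < alpha and the origin (POE)
    or breed (AGE) fold change clears the modality gate (>4x for RNA,
    >=2x for ATAC).  A cross-context rescue additionally calls features
    significant in one context with |log2fc| >= ``rescue_log2fc`` in at
    least two contexts.  When a feature carries both effects the class with
    the smaller minimum fdr is reported.
    """
    fold_gate = ASE_FOLD_RNA if mode == "rna" else ASE_FOLD_ATAC
    recs = []
    for (fid, effect), sub in results.groupby(["feature_id", "effect"]):
        fold = (folds.loc[fid, "fold_origin"] if effect == "POE"
                else folds.loc[fid, "fold_breed"])
        sig = sub["fdr"] < alpha
        if mode == "rna":
            primary = sig & (fold > fold_gate)
        else:
            primary = sig & (fold >= fold_gate)
        rescued = sig.any() and (sub["log2fc"].abs() >= rescue_log2fc).sum() >= 2
        if not (primary.any() or rescued):
            continue
        called = sub[sig] if sig.any() else sub
        direction = np.sign(called["log2fc"].mean())
        if effect == "POE":
            label = "POE_paternal_biased" if direction > 0 else "POE_maternal_biased"
        else:
            label = "AGE_duroc_biased" if direction > 0 else "AGE_lulai_biased"
        recs.append({"feature_id": fid, "effect": effect, "class": label,
                     "min_fdr": float(sub["fdr"].min())})
    if not recs:
        return pd.DataFrame(columns=["feature_id", "class", "effect", "min_fdr"])
    df = pd.DataFrame(recs)
    best = df.sort_values("min_fdr").drop_duplicates("feature_id")
    return best.reset_index(drop=True)


def call_imprinted(fractions: pd.DataFrame,
                   imprint_cut: float = IMPRINT_FRACTION,
                   strong_cut: float = STRONG_POE_FRACTION) -> pd.DataFrame:
    """Imprinting and strong-POE flags from mean paternal expression fractions.

    ``fractions``: long DataFrame with feature_id, tissue, stage,
    paternal_fraction (mean over the samples of that context).  A feature is
    imprinted when its bias reaches >= 95% / <= 5% in some tissue at >= 1
    stage; strong POE when > 75% / < 25%.
    """
    out = []
    for fid, sub in fractions.groupby("feature_id"):
        f = sub["paternal_fraction"]
        imprinted = bool(((f >= imprint_cut) | (f <= 1 - imprint_cut)).any())
        strong = bool(((f > strong_cut) | (f < 1 - strong_cut)).any())
        silenced = ""
        if imprinted:
            silenced = "maternal" if (f >= imprint_cut).any() else "paternal"
        out.append({"feature_id": fid, "imprint_flag": imprinted,
                    "strong_poe_flag": strong, "silenced_allele": silenced})
    return pd.DataFrame(out)


def detect_direction_switch(results: pd.DataFrame, alpha: float = 0.05
                            ) -> pd.DataFrame:
    """Flag features whose significant allelic bias flips sign across stages
    within a tissue.  ``results`` is long with feature_id, tissue, stage,
    log2fc, fdr."""
    out = []
    for fid, sub in results.groupby("feature_id"):
        flag = False
        for _, tsub in sub.groupby("tissue"):
            sig = tsub[tsub["fdr"] < alpha]
            if len(sig) >= 2 and sig["log2fc"].min() < 0 < sig["log2fc"].max():
                flag = True
                break
        out.append({"feature_id": fid, "direction_switch_flag": flag})
    return pd.DataFrame(out)


def bias_correlation(expr_fraction: pd.Series, acc_fraction: pd.Series
                     ) -> float:
    """Pearson correlation of allelic bias between expression and
    accessibility over the features measured in both; NaN below n=3."""
    joint = pd.concat([expr_fraction, acc_fraction], axis=1, join="inner").dropna()
    if len(joint) < 3:
        return float("nan")
    a, b = joint.iloc[:, 0], joint.iloc[:, 1]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
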