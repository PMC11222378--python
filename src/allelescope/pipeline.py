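"""End-to-end orchestration: simulate -> genomes -> assign -> test -> regions.

``run_pipeline`` drives the whole analysis on a synthetic reciprocal-cross
dataset with planted truth and reports recovery metrics per modality.  The
same building blocks are what a user would call on real data (the
simulation stages are then replaced by their actual FASTA/VCF/GTF/SAM
inputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from allelescope import asetest, genomes as gn, io, methylation as meth, regions, sim
from allelescope.assignment import (
    IntervalUnion, compute_allele_balance, compute_constitutive_exons,
    count_features, assign_sample, qc_filter_samples,
)

log = logging.getLogger(__name__)


def _config_hash(config: sim.SimulationConfig) -> str:
    return hashlib.sha1(config.to_json().encode()).hexdigest()[:12]


def build_parental_genomes(ref: dict[str, str], vcf_path,
                           parents=("DUROC_F", "DUROC_M", "LULAI_F", "LULAI_M")
                           ) -> dict[str, gn.IndividualizedGenome]:
    out = {}
    for p in parents:
        variants = gn.select_applicable_variants(str(vcf_path), p)
        out[p] = gn.build_individualized_genome(ref, variants, sample_id=p)
    return out


def informative_by_direction(vcf_path, annotation: pd.DataFrame):
    """Per cross direction, reference-frame sites oriented maternal/paternal."""
    exons = annotation[annotation["feature"] == "exon"][["chrom", "start", "end"]]
    oriented = {}
    for direction, par in sim.PARENTS.items():
        info = gn.select_informative_variants(str(vcf_path), sire=par["sire"],
                                              dam=par["dam"], exons=exons)
        oriented[direction] = info.oriented("dam")
    return oriented


def _constitutive_union_by_chrom(annotation, const):
    genes = annotation[annotation["feature"] == "gene"].set_index("gene_id")
    per_chrom: dict[str, list] = {}
    for gid, ivs in const.items():
        chrom = genes.loc[gid, "chrom"]
        per_chrom.setdefault(chrom, []).extend(ivs)
    return {c: IntervalUnion(ivs) for c, ivs in per_chrom.items()}


def assign_modality(samples: pd.DataFrame, sam_dir: Path, tag: str,
                    oriented, parental, mode: str,
                    features: pd.DataFrame,
                    constitutive=None, exon_union=None):
    """Run fragment assignment + feature counting for every sample.

    Returns (maternal, paternal, unassigned, total) count DataFrames and a
    per-sample balance table.
    """
    mats, pats, unas, tots, balances = {}, {}, {}, {}, []
    for _, s in samples.iterrows():
        par = sim.PARENTS[s["cross_direction"]]
        frags, _ = assign_sample(
            sam_dir / f"{s['sample_id']}.{tag}.maternal.sam",
            sam_dir / f"{s['sample_id']}.{tag}.paternal.sam",
            oriented[s["cross_direction"]],
            parental[par["dam"]].map, parental[par["sire"]].map,
            mode=mode, constitutive_union=exon_union)
        counts = count_features(frags, features, mode=mode,
                                constitutive=constitutive)
        sid = s["sample_id"]
        mats[sid] = counts["maternal"]
        pats[sid] = counts["paternal"]
        unas[sid] = counts["unassigned"]
        tots[sid] = counts["total"]
        balances.append(compute_allele_balance(
            sid, int(counts["maternal"].sum()), int(counts["paternal"].sum())))
    return (pd.DataFrame(mats), pd.DataFrame(pats), pd.DataFrame(unas),
            pd.DataFrame(tots), balances)


def ase_analysis(maternal, paternal, samples, mode: str,
                 context: str) -> dict:
    """Filter, fit the allelic model, classify, and flag imprinting."""
    design = asetest.build_design(samples)
    keep = asetest.filter_expression(maternal + paternal)
    m, p = maternal.loc[keep], paternal.loc[keep]
    results = asetest.fit_count_glm(m, p, design)
    results["context"] = context
    folds = asetest.allelic_fold_changes(m, p, design)
    classes = asetest.classify_ase(results, folds, mode=mode)
    fr = folds.reset_index().rename(columns={"index": "feature_id"})
    fr["tissue"] = samples["tissue"].iloc[0]
    fr["stage"] = samples["stage"].iloc[0]
    imprint = asetest.call_imprinted(fr)
    return {"design": design, "results": results, "folds": folds,
            "classes": classes, "imprint": imprint, "n_tested": len(keep)}


def run_pipeline(config: sim.SimulationConfig, outdir: str | Path,
                 modalities: tuple = ("rna", "atac", "meth"),
                 force: bool = False) -> dict:
    """Simulate a reciprocal-cross study and run the full analysis on it.

    Writes inputs, intermediate tables and result tables under ``outdir``
    and returns a metrics dict (also stored in ``manifest.json``).  Reruns
    with an unchanged config reuse the simulated inputs on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    manifest_path = outdir / "manifest.json"
    if not force and manifest_path.exists():
        stored = json.loads(manifest_path.read_text())
        if stored.get("config_hash") == chash:
            log.info("manifest matches config hash %s; reusing cached run", chash)
            stored["cached"] = True
            return stored
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    metrics: dict = {"config_hash": chash, "seed": config.seed}

    # ---- stage: simulate inputs -------------------------------------------
    samples = sim.make_sample_sheet(config)
    annotation = sim.simulate_annotation(config, rng)
    ref = sim.make_reference(config, rng)
    meth_truth = sim.plan_cpg_clusters(config, ref, rng) if "meth" in modalities else None
    reserved = ([(r.chrom, int(r.start), int(r.end))
                 for r in meth_truth.clusters.itertuples()]
                if meth_truth is not None else None)
    _, plan = sim.simulate_parental_genomes(config, rng, annotation,
                                            reserved=reserved, ref=ref)
    if meth_truth is not None:
        sim.plant_cluster_snps(config, ref, meth_truth, plan, rng)

    vcf_path = outdir / "parents.vcf"
    io.write_fasta(ref, outdir / "reference.fa")
    sim.write_vcf(plan, ref, vcf_path)
    io.write_gtf(annotation, outdir / "genes.gtf")
    io.write_tsv(samples, outdir / "sample_sheet.tsv")

    parental = build_parental_genomes(ref, vcf_path)
    for pid, g in parental.items():
        g.map.write(outdir / f"{pid}.coordmap.tsv")
    oriented = informative_by_direction(vcf_path, annotation)
    metrics["n_informative_sites"] = int(len(oriented["DxL"]))

    gene_rows = annotation[annotation["feature"] == "gene"]
    gene_features = pd.DataFrame({
        "feature_id": gene_rows["gene_id"].to_numpy(),
        "chrom": gene_rows["chrom"].to_numpy(),
        "start": gene_rows["start"].to_numpy(),
        "end": gene_rows["end"].to_numpy()})
    const = compute_constitutive_exons(annotation)
    exon_union = _constitutive_union_by_chrom(annotation, const)

    # ---- RNA ---------------------------------------------------------------
    if "rna" in modalities:
        gene_truth = sim.plant_gene_effects(config,
                                            list(gene_features["feature_id"]), rng)
        sam_dir = outdir / "rna_sam"
        frag_truth = sim.simulate_rna(config, annotation, parental, samples,
                                      gene_truth, rng, sam_dir)
        io.write_tsv(gene_truth.table, outdir / "truth_genes.tsv")
        mat, pat, una, tot, balances = assign_modality(
            samples, sam_dir, "rna", oriented, parental, "rna",
            gene_features, constitutive=const, exon_union=exon_union)
        for name, df in (("maternal", mat), ("paternal", pat),
                         ("unassigned", una), ("total", tot)):
            io.write_tsv(df.reset_index(), outdir / f"rna_counts_{name}.tsv")
        bal = pd.DataFrame([{"sample_id": b.sample_id,
                             "maternal_fraction": b.maternal_fraction,
                             "pass": b.pass_flag, "reason": b.reason}
                            for b in balances])
        io.write_tsv(bal, outdir / "rna_balance_qc.tsv")
        retained = qc_filter_samples(balances)
        smeta = samples[samples["sample_id"].isin(retained)]
        res = ase_analysis(mat[retained], pat[retained], smeta, "rna",
                           context=f"{smeta['tissue'].iloc[0]}:{smeta['stage'].iloc[0]}")
        io.write_tsv(res["results"], outdir / "rna_ase_results.tsv")
        io.write_tsv(res["classes"], outdir / "rna_ase_classes.tsv")
        io.write_tsv(res["imprint"], outdir / "rna_imprinting.tsv")
        rec = sim.evaluate_recovery(res["classes"], gene_truth)
        # fragment-level assignment accuracy against truth labels
        metrics["rna"] = rec
        metrics["rna"]["n_samples_retained"] = len(retained)
        metrics["rna"]["n_tested"] = res["n_tested"]

    # ---- ATAC --------------------------------------------------------------
    if "atac" in modalities:
        peaks = sim.simulate_peaks(config, rng, annotation)
        io.write_bed(peaks.assign(name=peaks["feature_id"]),
                     outdir / "peaks.bed")
        peak_truth = sim.plant_gene_effects(
            config, list(peaks["feature_id"]), rng,
            poe_fraction=config.atac_poe_fraction,
            age_fraction=config.atac_age_fraction, imprint_fraction=0.0)
        # ATAC means around the configured peak height
        peak_truth.table["base_mean"] = np.exp(
            rng.normal(np.log(config.atac_mean_count), 0.4, len(peaks)))
        sam_dir = outdir / "atac_sam"
        sim.simulate_atac(config, peaks, parental, samples, peak_truth,
                          rng, sam_dir)
        io.write_tsv(peak_truth.table, outdir / "truth_peaks.tsv")
        mat, pat, una, tot, balances = assign_modality(
            samples, sam_dir, "atac", oriented, parental, "atac", peaks)
        # insert-size QC: the nucleosomal periodicity of the first sample
        import pysam

        from allelescope.assignment import fragment_size_histogram
        s0 = samples["sample_id"].iloc[0]
        with pysam.AlignmentFile(
                str(sam_dir / f"{s0}.atac.maternal.sam"), check_sq=False) as sf:
            tlens = [r.template_length for r in sf
                     if r.is_read1 and r.is_proper_pair]
        hist = fragment_size_histogram(tlens)
        hist.rename("count").rename_axis("insert_size").reset_index().to_csv(
            outdir / "atac_insert_size_hist.tsv", sep="\t", index=False)
        io.write_tsv(mat.reset_index(), outdir / "atac_counts_maternal.tsv")
        io.write_tsv(pat.reset_index(), outdir / "atac_counts_paternal.tsv")
        res = ase_analysis(mat, pat, samples, "atac",
                           context=f"{samples['tissue'].iloc[0]}:{samples['stage'].iloc[0]}")
        io.write_tsv(res["results"], outdir / "atac_ase_results.tsv")
        io.write_tsv(res["classes"], outdir / "atac_ase_classes.tsv")
        # peak -> gene aggregation through the priority annotation
        hierarchy = regions.AnnotationHierarchy(annotation)
        ann = pd.DataFrame([
            {"feature_id": r["feature_id"],
             **dict(zip(("category", "gene_id"),
                        hierarchy.annotate(r["chrom"], r["start"], r["end"])))}
            for _, r in peaks.iterrows()])
        io.write_tsv(ann, outdir / "peak_annotation.tsv")
        gene_acc = regions.aggregate_peaks_to_genes(tot, ann)
        io.write_tsv(gene_acc.reset_index(), outdir / "atac_gene_counts.tsv")
        sites = oriented["DxL"]
        assessable = set()
        for _, pk in peaks.iterrows():
            sub = sites[(sites["chrom"] == pk["chrom"])
                        & (sites["pos"] >= pk["start"])
                        & (sites["pos"] < pk["end"])]
            if len(sub):
                assessable.add(pk["feature_id"])
        metrics["atac"] = sim.evaluate_recovery(
            res["classes"], peak_truth, min_mean=config.atac_mean_count / 2,
            assessable=assessable)
        metrics["atac"]["n_peaks"] = int(len(peaks))
        metrics["atac"]["n_assessable"] = len(assessable)

    # ---- methylation -------------------------------------------------------
    if "meth" in modalities:
        sam_dir = outdir / "bs_sam"
        sim.simulate_bisulfite(config, meth_truth, parental, samples, rng,
                               sam_dir)
        io.write_tsv(meth_truth.clusters, outdir / "truth_meth_clusters.tsv")
        per_sample = {}
        nonconv = {}
        for _, s in samples.iterrows():
            par = sim.PARENTS[s["cross_direction"]]
            gmat, gpat = parental[par["dam"]], parental[par["sire"]]
            tab = meth.extract_allelic_methylation(
                sam_dir / f"{s['sample_id']}.bs.maternal.sam",
                sam_dir / f"{s['sample_id']}.bs.paternal.sam",
                oriented[s["cross_direction"]], gmat.map, gpat.map,
                gmat.sequences, gpat.sequences)
            per_sample[s["sample_id"]] = meth.convert_cpg_coordinates(
                tab, gmat.map, gpat.map)
            nonconv[s["sample_id"]] = meth.estimate_nonconversion(
                sam_dir / f"{s['sample_id']}.bs.maternal.sam",
                {sim.SPIKE_CONTIG: ref[sim.SPIKE_CONTIG]})
        table = meth.CpGAlleleTable.from_samples(per_sample)
        snp_positions = {(c, int(p)) for c, p in
                         zip(plan.table["chrom"], plan.table["pos"])}
        table = meth.filter_cpgs_bulk(
            table, list(samples["sample_id"]), min_cov=10,
            min_samples=max(1, int(len(samples) * 10 / 12)),
            snp_positions=snp_positions)
        table = meth.filter_cpgs_allelic(table, samples)
        table.write(outdir / "cpg_allele_table.tsv")
        metrics["meth"] = {"n_cpgs_tested": int(len(table.m)),
                           "mean_nonconversion": float(np.mean(list(nonconv.values())))}
        if len(table.m) >= 10:
            design = asetest.build_design(samples)
            res = asetest.fit_binomial_glm(table.m, table.u, design)
            io.write_tsv(res, outdir / "cpg_ase_results.tsv")
            idx = table.m.index.to_frame(index=False)
            mrs = {}
            for effect, kind in (("POE", "poeMR"), ("AGE", "ageMR")):
                sub = res[res["effect"] == effect].copy()
                sub[["chrom", "pos", "strand"]] = idx[["chrom", "pos", "strand"]].to_numpy()
                sub = sub.sort_values(["chrom", "pos"])
                mrs[kind] = regions.call_methylation_regions(sub, kind)
                io.write_bed(regions.regions_to_bed(mrs[kind]),
                             outdir / f"{kind}.bed")
            metrics["meth"].update(_meth_recovery(mrs, meth_truth))

    metrics["runtime_seconds"] = round(time.time() - t0, 1)
    manifest_path.write_text(json.dumps(metrics, indent=2, default=float))
    return metrics


def _meth_recovery(mrs: dict, truth: sim.MethylationTruth) -> dict:
    """Cluster-level recovery of planted poe/age methylation regions."""
    out = {}
    for kind, cls in (("poeMR", "poe"), ("ageMR", "age")):
        called = mrs.get(kind, [])
        planted = truth.clusters[truth.clusters["class"] == cls]
        hit = 0
        for r in planted.itertuples():
            if any(m.chrom == r.chrom and m.start < r.end and r.start < m.end
                   for m in called):
                hit += 1
        false = 0
        for m in called:
            ok = any(m.chrom == r.chrom and m.start < r.end and r.start < m.end
                     for r in planted.itertuples())
            if not ok:
                false += 1
        out[f"{kind}_sensitivity"] = hit / len(planted) if len(planted) else float("nan")
        out[f"{kind}_fdp"] = false / max(len(called), 1)
        out[f"n_{kind}"] = len(called)
    return out
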