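"""Synthetic reciprocal-cross multi-omic data with planted truth.

The generator emulates the study design this package analyzes: two
divergent breeds (Duroc and Lulai) crossed reciprocally, with RNA-Seq,
ATAC-Seq and whole-genome bisulfite reads from F1 hybrids.  It writes
standard files (FASTA reference, parental VCF, GTF annotation, per-sample
SAM alignments against both individualized parental genomes, peak BED,
sample sheet) plus truth tables recording every fragment's parental origin
and every feature's planted effect, so pipeline output can be scored
against ground truth.

Reads are emitted pre-aligned: the generator knows each read's source
position in its parental genome, so SAM records are exact and no external
aligner is involved.  All randomness flows from a single seed;
regeneration under the same seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from allelescope.genomes import IndividualizedGenome

BASES = np.array(list("ACGT"))

PARENTS = {
    "DxL": {"dam": "DUROC_F", "sire": "LULAI_M"},
    "LxD": {"dam": "LULAI_F", "sire": "DUROC_M"},
}
BREED_OF = {"DUROC_F": "Duroc", "DUROC_M": "Duroc",
            "LULAI_F": "Lulai", "LULAI_M": "Lulai"}
SPIKE_CONTIG = "lambda_spike"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; the defaults are the demo scale
    (two 500 kb chromosomes, 300 genes, 1000 peaks) that runs end to end
    in minutes on one CPU."""

    seed: int = 1
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 600_000, "chr2": 600_000})
    # breed-divergent variation
    snp_rate: float = 0.002
    indel_rate: float = 0.0002
    max_indel: int = 6
    exonic_snp_spacing: int = 120
    shared_alt_fraction: float = 0.05   # non-informative: both breeds alt
    duroc_alt_fraction: float = 0.3     # informative sites where Duroc carries alt
    # annotation
    n_genes: int = 300
    exons_per_gene: tuple = (2, 4)
    exon_length: tuple = (150, 350)
    intron_length: tuple = (100, 500)
    intergenic_gap: tuple = (400, 1000)
    large_gap: tuple = (7600, 9000)     # hosts intergenic ATAC peaks
    large_gap_fraction: float = 0.1
    multi_isoform_fraction: float = 0.3
    # expression
    mean_count: float = 100.0           # mean total fragments per gene per sample
    dispersion: float = 0.1
    poe_fraction: float = 0.06
    age_fraction: float = 0.06
    imprint_fraction: float = 0.03
    effect_log2fc: tuple = (1.0, 2.5, 3.5)
    imprint_paternal_fraction: float = 0.95
    # reads
    read_length: int = 100
    fragment_mean: int = 220
    fragment_sd: int = 30
    base_error: float = 0.001
    # ATAC
    n_peaks: int = 1000
    peak_length: tuple = (300, 800)
    atac_mean_count: float = 30.0
    atac_dispersion: float = 0.1
    atac_poe_fraction: float = 0.05
    atac_age_fraction: float = 0.05
    # methylation
    n_cpg_clusters: int = 250
    cpgs_per_cluster: tuple = (6, 14)
    meth_coverage: float = 20.0         # per allele per CpG cluster
    meth_poe_fraction: float = 0.15     # of clusters
    meth_age_fraction: float = 0.15
    meth_high: float = 0.85
    meth_low: float = 0.10
    non_conversion: float = 0.005
    spike_length: int = 5000
    spike_reads_per_sample: int = 300
    # design
    tissues: tuple = ("muscle",)
    stages: tuple = ("F70",)
    replicates_per_sex: int = 3

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=list)


# ---------------------------------------------------------------------------
# sample sheets

FULL_DESIGN_STAGES = {
    "F40": ["brain", "liver", "muscle", "placenta"],
    "F70": ["brain", "liver", "muscle", "placenta"],
    "D1": ["brain", "liver", "muscle"],
    "D168": ["brain", "liver", "muscle"],
}


def make_sample_sheet(config: SimulationConfig | None = None,
                      template: str = "config") -> pd.DataFrame:
    """Enumerate tissue samples.

    ``template='full'`` reproduces the full study design: four tissues from
    six fetuses per cross at the two fetal stages and three tissues from
    six animals per cross at the two postnatal stages (96 fetal + 72
    postnatal = 168 records).  ``template='config'`` enumerates the
    configured demo design instead.
    """
    rows = []
    if template == "full":
        design = FULL_DESIGN_STAGES.items()
        reps = 3
    else:
        if config is None:
            raise ValueError("config required for template='config'")
        design = [(s, list(config.tissues)) for s in config.stages]
        reps = config.replicates_per_sex
    for stage, tissues in design:
        for direction in ("DxL", "LxD"):
            for sex in ("F", "M"):
                for rep in range(1, reps + 1):
                    individual = f"{direction}_{stage}_{sex}{rep}"
                    for tissue in tissues:
                        rows.append({
                            "sample_id": f"{individual}_{tissue}",
                            "individual": individual,
                            "tissue": tissue,
                            "stage": stage,
                            "sex": sex,
                            "cross_direction": direction,
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genomes, variants, annotation


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def simulate_annotation(config: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping genes with 1-3 transcripts; a fraction of genes are
    multi-isoform (one transcript skips an internal exon), exercising the
    constitutive-exon logic."""
    chroms = list(config.chrom_lengths)
    rows = []
    gene_serial = 0
    # budget genome space evenly between chromosomes
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    for chrom in chroms:
        length = config.chrom_lengths[chrom]
        cursor = 2000
        for _ in range(per_chrom):
            if gene_serial >= config.n_genes:
                break
            n_ex = int(rng.integers(*config.exons_per_gene))
            exons = []
            pos = cursor
            for k in range(n_ex):
                elen = int(rng.integers(*config.exon_length))
                exons.append((pos, pos + elen))
                pos += elen + int(rng.integers(*config.intron_length))
            gene_end = exons[-1][1]
            if gene_end > length - 4000:
                break
            gid = f"gene_{gene_serial:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            attr = f'gene_id "{gid}";'
            rows.append((chrom, "sim", "gene", exons[0][0], gene_end, ".",
                         strand, ".", attr, gid, ""))
            tx_exons = {f"{gid}.t1": exons}
            if n_ex >= 3 and rng.random() < config.multi_isoform_fraction:
                skip = int(rng.integers(1, n_ex - 1))
                tx_exons[f"{gid}.t2"] = [e for i, e in enumerate(exons)
                                         if i != skip]
            for tid, exs in tx_exons.items():
                tattr = f'gene_id "{gid}"; transcript_id "{tid}";'
                rows.append((chrom, "sim", "transcript", exs[0][0], exs[-1][1],
                             ".", strand, ".", tattr, gid, tid))
                for s, e in exs:
                    rows.append((chrom, "sim", "exon", s, e, ".", strand,
                                 ".", tattr, gid, tid))
            if rng.random() < config.large_gap_fraction:
                gap = int(rng.integers(*config.large_gap))
            else:
                gap = int(rng.integers(*config.intergenic_gap))
            cursor = gene_end + gap
            gene_serial += 1
    if gene_serial < config.n_genes:
        raise ValueError(
            f"genome too short for {config.n_genes} genes (placed {gene_serial})")
    return pd.DataFrame(rows, columns=[
        "chrom", "source", "feature", "start", "end", "score", "strand",
        "frame", "attributes", "gene_id", "transcript_id"])


def _constitutive_intervals(annotation: pd.DataFrame) -> dict[str, list]:
    from allelescope.assignment import compute_constitutive_exons
    return compute_constitutive_exons(annotation)


@dataclass
class VariantPlan:
    """Planted variant sites with per-breed alleles."""

    table: pd.DataFrame  # chrom, pos, ref, alt, duroc_alt, lulai_alt, kind


def make_reference(config: SimulationConfig,
                   rng: np.random.Generator) -> dict[str, str]:
    """Random reference sequences plus the unmethylated spike-in contig."""
    ref = {c: _random_sequence(rng, ln) for c, ln in config.chrom_lengths.items()}
    ref[SPIKE_CONTIG] = _random_sequence(rng, config.spike_length)
    return ref


def simulate_parental_genomes(config: SimulationConfig,
                              rng: np.random.Generator,
                              annotation: pd.DataFrame | None = None,
                              reserved: list[tuple[str, int, int]] | None = None,
                              ref: dict[str, str] | None = None,
                              ) -> tuple[dict[str, str], VariantPlan]:
    """Reference sequences plus breed-divergent homozygous variant sites.

    Background SNPs/indels are placed at the configured rates; when an
    annotation is given, additional informative SNPs are planted inside
    constitutive exons at ``exonic_snp_spacing`` so that most RNA fragments
    cover at least one informative allele.  ``reserved`` intervals (e.g.
    CpG clusters) are kept free of indels and of variants that would
    disturb planted cytosines.
    """
    if ref is None:
        ref = make_reference(config, rng)
    guard = 2 + config.max_indel
    reserved = reserved or []
    res_by_chrom: dict[str, list] = {}
    for c, s, e in reserved:
        res_by_chrom.setdefault(c, []).append((s, e))

    rows = []
    for chrom, ln in config.chrom_lengths.items():
        n_snp = rng.poisson(config.snp_rate * ln)
        n_indel = rng.poisson(config.indel_rate * ln)
        pos = np.sort(rng.choice(ln - 2 * guard, size=n_snp + n_indel,
                                 replace=False) + guard)
        if len(pos) == 0:
            continue
        # enforce spacing so variants never overlap
        keep = np.concatenate([[True], np.diff(pos) > guard])
        pos = pos[keep]
        is_indel = np.zeros(len(pos), dtype=bool)
        if len(pos):
            is_indel[rng.choice(len(pos), size=min(n_indel, len(pos)),
                                replace=False)] = True
        for p, ind in zip(pos, is_indel):
            p = int(p)
            in_reserved = any(s - guard <= p < e + guard
                              for s, e in res_by_chrom.get(chrom, []))
            if in_reserved:
                continue
            refb = ref[chrom][p]
            if ind:
                k = int(rng.integers(1, config.max_indel + 1))
                if rng.random() < 0.5:  # insertion
                    alt = refb + _random_sequence(rng, k)
                    rows.append((chrom, p, refb, alt, "indel"))
                else:                   # deletion
                    rows.append((chrom, p, ref[chrom][p:p + k + 1], refb, "indel"))
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != refb]))
                rows.append((chrom, p, refb, alt, "snp"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "kind"])

    # guaranteed informative SNPs inside constitutive exons
    if annotation is not None:
        taken = {(c, int(p)) for c, p in zip(df["chrom"], df["pos"])}
        extra = []
        gene_chrom = annotation[annotation["feature"] == "gene"] \
            .set_index("gene_id")["chrom"]
        for gid, ivs in _constitutive_intervals(annotation).items():
            chrom = gene_chrom[gid]
            for s, e in ivs:
                for p in range(int(s) + 10, int(e) - 10, config.exonic_snp_spacing):
                    near = any(abs(p - q) <= guard for c, q in taken
                               if c == chrom and abs(p - q) <= guard)
                    if near:
                        continue
                    in_reserved = any(rs - guard <= p < re + guard
                                      for rs, re in res_by_chrom.get(chrom, []))
                    if in_reserved:
                        continue
                    refb = ref[chrom][p]
                    alt = str(rng.choice([b for b in "ACGT" if b != refb]))
                    extra.append((chrom, p, refb, alt, "snp"))
                    taken.add((chrom, p))
        df = pd.concat([df, pd.DataFrame(
            extra, columns=["chrom", "pos", "ref", "alt", "kind"])],
            ignore_index=True)

    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    # drop any residual overlaps (first wins)
    keep_rows = []
    last_end: dict[str, int] = {}
    for r in df.itertuples():
        if r.pos < last_end.get(r.chrom, -1):
            continue
        keep_rows.append(r.Index)
        last_end[r.chrom] = r.pos + len(r.ref) + guard // 2
    df = df.loc[keep_rows].reset_index(drop=True)

    u = rng.random(len(df))
    shared = u < config.shared_alt_fraction
    duroc_alt = (~shared) & (u < config.shared_alt_fraction
                             + (1 - config.shared_alt_fraction) * config.duroc_alt_fraction)
    df["duroc_alt"] = shared | duroc_alt
    df["lulai_alt"] = shared | ~duroc_alt
    return ref, VariantPlan(df)


def plant_site(plan: VariantPlan, chrom: str, pos: int, ref_base: str,
               alt: str, duroc_alt: bool) -> None:
    """Add one extra informative SNP to a variant plan (used for CpG clusters)."""
    plan.table.loc[len(plan.table)] = {
        "chrom": chrom, "pos": pos, "ref": ref_base, "alt": alt,
        "kind": "snp", "duroc_alt": duroc_alt, "lulai_alt": not duroc_alt}


def write_vcf(plan: VariantPlan, ref: dict[str, str], path: str | Path) -> None:
    """Four parental samples (two per breed, monomorphic within breed)."""
    header = pysam.VariantHeader()
    for chrom, seq in ref.items():
        header.contigs.add(chrom, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    samples = ["DUROC_F", "DUROC_M", "LULAI_F", "LULAI_M"]
    for s in samples:
        header.add_sample(s)
    tbl = plan.table.sort_values(["chrom", "pos"])
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in tbl.itertuples():
            rec = vf.new_record(contig=r.chrom, start=int(r.pos),
                                alleles=(r.ref, r.alt))
            for s in samples:
                is_alt = r.duroc_alt if BREED_OF[s] == "Duroc" else r.lulai_alt
                rec.samples[s]["GT"] = (1, 1) if is_alt else (0, 0)
            vf.write(rec)


# ---------------------------------------------------------------------------
# read emission


class SamWriter:
    """Plain-text SAM emission for generator-aligned reads."""

    def __init__(self, path: str | Path, chrom_lengths: dict[str, int]):
        self.fh = open(path, "w")
        self.fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, ln in chrom_lengths.items():
            self.fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")

    def write_pair(self, qname, chrom, pos1, seq1, pos2, seq2, tags=""):
        q1 = "I" * len(seq1)
        q2 = "I" * len(seq2)
        tlen = (pos2 + len(seq2)) - pos1
        t = ("\t" + tags) if tags else ""
        self.fh.write(
            f"{qname}\t99\t{chrom}\t{pos1 + 1}\t60\t{len(seq1)}M\t=\t{pos2 + 1}"
            f"\t{tlen}\t{seq1}\t{q1}{t}\n")
        self.fh.write(
            f"{qname}\t147\t{chrom}\t{pos2 + 1}\t60\t{len(seq2)}M\t=\t{pos1 + 1}"
            f"\t{-tlen}\t{seq2}\t{q2}{t}\n")

    def write_single(self, qname, chrom, pos, seq, tags=""):
        t = ("\t" + tags) if tags else ""
        self.fh.write(
            f"{qname}\t0\t{chrom}\t{pos + 1}\t60\t{len(seq)}M\t*\t0\t0"
            f"\t{seq}\t{'I' * len(seq)}{t}\n")

    def close(self):
        self.fh.close()


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    s = list(seq)
    for i in rng.choice(len(seq), size=n, replace=False):
        s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
    return "".join(s)


def _nb_counts(rng, mean, dispersion, size=None):
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) * dispersion, size=size)
    return rng.poisson(lam)


@dataclass
class GeneTruth:
    table: pd.DataFrame  # feature_id, class, log2fc, imprint_paternal_fraction


def plant_gene_effects(config: SimulationConfig, gene_ids: list[str],
                       rng: np.random.Generator,
                       poe_fraction=None, age_fraction=None,
                       imprint_fraction=None) -> GeneTruth:
    """Assign each feature a planted class: poe / age / imprinted / none."""
    poe_fraction = config.poe_fraction if poe_fraction is None else poe_fraction
    age_fraction = config.age_fraction if age_fraction is None else age_fraction
    imprint_fraction = (config.imprint_fraction if imprint_fraction is None
                        else imprint_fraction)
    n = len(gene_ids)
    classes = np.array(["none"] * n, dtype=object)
    perm = rng.permutation(n)
    n_poe = int(round(poe_fraction * n))
    n_age = int(round(age_fraction * n))
    n_imp = int(round(imprint_fraction * n))
    classes[perm[:n_poe]] = "poe"
    classes[perm[n_poe:n_poe + n_age]] = "age"
    classes[perm[n_poe + n_age:n_poe + n_age + n_imp]] = "imprinted"
    lfc = np.zeros(n)
    imp = np.full(n, np.nan)
    for i in range(n):
        if classes[i] in ("poe", "age"):
            lfc[i] = rng.choice(config.effect_log2fc) * rng.choice([-1, 1])
        elif classes[i] == "imprinted":
            imp[i] = (config.imprint_paternal_fraction if rng.random() < 0.5
                      else 1 - config.imprint_paternal_fraction)
    base = np.exp(rng.normal(np.log(config.mean_count), 0.6, n))
    return GeneTruth(pd.DataFrame({
        "feature_id": gene_ids, "class": classes, "log2fc": lfc,
        "imprint_paternal_fraction": imp, "base_mean": base}))


def allelic_means(truth_row, direction: str) -> tuple[float, float]:
    """Expected (maternal, paternal) fragment counts for one sample."""
    mu = truth_row.base_mean
    cls = truth_row.cls if hasattr(truth_row, "cls") else truth_row["class"]
    if cls == "imprinted":
        f = truth_row.imprint_paternal_fraction
        return mu * (1 - f), mu * f
    m = p = mu / 2.0
    if cls == "poe":       # log2fc is paternal/maternal
        m = mu / 2 * 2 ** (-truth_row.log2fc / 2)
        p = mu / 2 * 2 ** (truth_row.log2fc / 2)
    elif cls == "age":     # log2fc is Duroc/Lulai
        duroc_is_maternal = direction == "DxL"
        d = mu / 2 * 2 ** (truth_row.log2fc / 2)
        l = mu / 2 * 2 ** (-truth_row.log2fc / 2)
        m, p = (d, l) if duroc_is_maternal else (l, d)
    return m, p


def _lift_interval(cm, start: int, end: int) -> tuple[int, int]:
    s = cm.forward_clamped(start, "left")
    e = cm.forward_clamped(end - 1, "right") + 1
    return s, e


def simulate_rna(config: SimulationConfig, annotation: pd.DataFrame,
                 genomes: dict[str, IndividualizedGenome],
                 samples: pd.DataFrame, truth: GeneTruth,
                 rng: np.random.Generator, outdir: str | Path
                 ) -> pd.DataFrame:
    """Paired-end RNA fragments per sample, written as SAM against the
    parental genome each fragment originates from; the mate SAM for the
    other genome lists nothing for that fragment (it is scored against the
    genome where it is mapped).  Returns the fragment truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    const = _constitutive_intervals(annotation)
    gene_meta = annotation[annotation["feature"] == "gene"].set_index("gene_id")
    rl = config.read_length
    truth_rows = []
    t = truth.table.set_index("feature_id")
    for _, s in samples.iterrows():
        par = PARENTS[s["cross_direction"]]
        gmat, gpat = genomes[par["dam"]], genomes[par["sire"]]
        writers = {}
        for origin, g in (("maternal", gmat), ("paternal", gpat)):
            lens = {c: len(seq) for c, seq in g.sequences.items()}
            writers[origin] = SamWriter(
                outdir / f"{s['sample_id']}.rna.{origin}.sam", lens)
        serial = 0
        for gid, row in t.iterrows():
            chrom = gene_meta.loc[gid, "chrom"]
            exons = [iv for iv in const.get(gid, []) if iv[1] - iv[0] >= rl + 4]
            if not exons:
                continue
            m_mu, p_mu = allelic_means(row, s["cross_direction"])
            for origin, mu, g in (("maternal", m_mu, gmat), ("paternal", p_mu, gpat)):
                n_frag = int(_nb_counts(rng, mu, config.dispersion))
                if n_frag == 0:
                    continue
                cm = g.map.chroms[chrom]
                seq = g.sequences[chrom]
                lifted = [_lift_interval(cm, a, b) for a, b in exons]
                lifted = [iv for iv in lifted if iv[1] - iv[0] >= rl + 4]
                if not lifted:
                    continue
                w = writers[origin]
                for _ in range(n_frag):
                    es, ee = lifted[int(rng.integers(len(lifted)))]
                    flen = int(np.clip(rng.normal(config.fragment_mean,
                                                  config.fragment_sd),
                                       rl, ee - es))
                    start = int(rng.integers(es, ee - flen + 1))
                    p1, p2 = start, start + flen - rl
                    s1 = _apply_errors(seq[p1:p1 + rl], config.base_error, rng)
                    s2 = _apply_errors(seq[p2:p2 + rl], config.base_error, rng)
                    qname = f"{s['sample_id']}:r{serial:07d}"
                    serial += 1
                    w.write_pair(qname, chrom, p1, s1, p2, s2)
                    truth_rows.append((s["sample_id"], qname, gid, origin))
        for w in writers.values():
            w.close()
    return pd.DataFrame(truth_rows, columns=["sample_id", "fragment_id",
                                             "feature_id", "origin"])


def simulate_peaks(config: SimulationConfig, rng: np.random.Generator,
                   annotation: pd.DataFrame) -> pd.DataFrame:
    """ATAC peak catalog: promoter-proximal, genic, and intergenic peaks.

    Intergenic peaks are confined to the annotation's large inter-gene gaps
    so the priority annotation genuinely classifies them as intergenic."""
    genes = annotation[annotation["feature"] == "gene"]
    rows = []
    n_promoter = min(len(genes), int(config.n_peaks * 0.35))
    pick = rng.choice(len(genes), size=n_promoter, replace=False)
    for i in pick:
        g = genes.iloc[i]
        plen = int(rng.integers(*config.peak_length))
        if g["strand"] == "-":
            s0 = int(g["end"]) + int(rng.integers(0, 300))
        else:
            s0 = max(0, int(g["start"]) - plen - int(rng.integers(0, 300)))
        rows.append((g["chrom"], s0, s0 + plen))
    # genic peaks anywhere within a gene body
    n_genic = int(config.n_peaks * 0.5)
    pick = rng.choice(len(genes), size=min(n_genic, 2 * len(genes)),
                      replace=True)
    for i in pick:
        g = genes.iloc[i]
        plen = int(rng.integers(*config.peak_length))
        span = int(g["end"]) - int(g["start"])
        if span <= plen + 2:
            continue
        s0 = int(g["start"]) + int(rng.integers(0, span - plen))
        rows.append((g["chrom"], s0, s0 + plen))
    # intergenic peaks in the centers of large gaps, clear of promoters
    margin = 3100
    for chrom, sub in genes.groupby("chrom"):
        ivs = sorted(zip(sub["start"], sub["end"]))
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            lo, hi = int(e0) + margin, int(s1) - margin
            plen = int(rng.integers(*config.peak_length))
            if hi - lo > plen + 10:
                p = lo + int(rng.integers(0, hi - lo - plen))
                rows.append((chrom, p, p + plen))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    # drop overlapping peaks so the catalog is a clean consensus set
    keep, last = [], {}
    for i, r in df.iterrows():
        if r["start"] >= last.get(r["chrom"], -1):
            keep.append(i)
            last[r["chrom"]] = r["end"]
    df = df.loc[keep].reset_index(drop=True)
    df["feature_id"] = [f"peak_{i:05d}" for i in range(len(df))]
    return df


def simulate_atac(config: SimulationConfig, peaks: pd.DataFrame,
                  genomes: dict[str, IndividualizedGenome],
                  samples: pd.DataFrame, truth: GeneTruth,
                  rng: np.random.Generator, outdir: str | Path) -> pd.DataFrame:
    """Paired-end ATAC fragments with nucleosomal insert-size periodicity."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rl = config.read_length
    t = truth.table.set_index("feature_id")
    truth_rows = []
    mix_means = np.array([80.0, 200.0, 400.0])
    mix_sds = np.array([15.0, 25.0, 40.0])
    mix_w = np.array([0.5, 0.35, 0.15])
    for _, s in samples.iterrows():
        par = PARENTS[s["cross_direction"]]
        gmat, gpat = genomes[par["dam"]], genomes[par["sire"]]
        writers = {}
        for origin, g in (("maternal", gmat), ("paternal", gpat)):
            lens = {c: len(seq) for c, seq in g.sequences.items()}
            writers[origin] = SamWriter(
                outdir / f"{s['sample_id']}.atac.{origin}.sam", lens)
        serial = 0
        for pid, row in t.iterrows():
            peak = peaks.set_index("feature_id").loc[pid]
            chrom = peak["chrom"]
            m_mu, p_mu = allelic_means(row, s["cross_direction"])
            for origin, mu, g in (("maternal", m_mu, gmat), ("paternal", p_mu, gpat)):
                n_frag = int(_nb_counts(rng, mu, config.atac_dispersion))
                if n_frag == 0:
                    continue
                cm = g.map.chroms[chrom]
                seq = g.sequences[chrom]
                ps, pe = _lift_interval(cm, int(peak["start"]), int(peak["end"]))
                if pe - ps < rl + 4:
                    continue
                w = writers[origin]
                comp = rng.choice(3, size=n_frag, p=mix_w)
                flens = rng.normal(mix_means[comp], mix_sds[comp])
                for flen in flens:
                    flen = int(np.clip(flen, rl, pe - ps))
                    start = int(rng.integers(ps, pe - flen + 1))
                    p1, p2 = start, start + flen - rl
                    s1 = _apply_errors(seq[p1:p1 + rl], config.base_error, rng)
                    s2 = _apply_errors(seq[p2:p2 + rl], config.base_error, rng)
                    qname = f"{s['sample_id']}:a{serial:07d}"
                    serial += 1
                    w.write_pair(qname, chrom, p1, s1, p2, s2)
                    truth_rows.append((s["sample_id"], qname, pid, origin))
        for w in writers.values():
            w.close()
    return pd.DataFrame(truth_rows, columns=["sample_id", "fragment_id",
                                             "feature_id", "origin"])


# ---------------------------------------------------------------------------
# bisulfite


@dataclass
class MethylationTruth:
    clusters: pd.DataFrame   # cluster_id, chrom, start, end, class
    cpgs: pd.DataFrame       # chrom, pos, cluster, p_maternal, p_paternal basis


def plan_cpg_clusters(config: SimulationConfig, ref: dict[str, str],
                      rng: np.random.Generator) -> MethylationTruth:
    """Choose CpG clusters on the reference and plant methylation truth.

    Clusters are runs of existing CpG dinucleotides.  A 'poe' cluster is
    methylated on one parental allele and unmethylated on the other
    (independent of breed); an 'age' cluster differs by breed instead.
    """
    cluster_rows, cpg_rows = [], []
    cid = 0
    chroms = [c for c in config.chrom_lengths]
    per_chrom = int(np.ceil(config.n_cpg_clusters / len(chroms)))
    for chrom in chroms:
        seq = ref[chrom]
        cpg_pos = []
        i = seq.find("CG")
        while i != -1:
            cpg_pos.append(i)
            i = seq.find("CG", i + 1)
        cpg_pos = np.asarray(cpg_pos)
        anchors = np.sort(rng.choice(len(cpg_pos) - 40, size=per_chrom,
                                     replace=False))
        last_end = -10_000
        for a in anchors:
            if cid >= config.n_cpg_clusters:
                break
            k = int(rng.integers(*config.cpgs_per_cluster))
            members = cpg_pos[a:a + k]
            members = members[members - members[0] < 1200]
            if len(members) < 4 or members[0] < last_end + 500:
                continue
            u = rng.random()
            if u < config.meth_poe_fraction:
                cls = "poe"
            elif u < config.meth_poe_fraction + config.meth_age_fraction:
                cls = "age"
            else:
                cls = "none"
            cluster_rows.append((f"mr_{cid:04d}", chrom, int(members[0]),
                                 int(members[-1]) + 2, cls))
            hi, lo = config.meth_high, config.meth_low
            for p in members:
                if cls == "none":
                    base = hi if rng.random() < 0.6 else lo
                    pa = pb = base
                elif cls == "poe":
                    pa, pb = (hi, lo) if cid % 2 == 0 else (lo, hi)  # maternal, paternal
                else:
                    pa, pb = (hi, lo) if cid % 2 == 0 else (lo, hi)  # duroc, lulai
                cpg_rows.append((chrom, int(p), f"mr_{cid:04d}", cls, pa, pb))
            last_end = int(members[-1])
            cid += 1
    clusters = pd.DataFrame(cluster_rows, columns=["cluster_id", "chrom",
                                                   "start", "end", "class"])
    cpgs = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "cluster", "class",
                                           "p_a", "p_b"])
    return MethylationTruth(clusters, cpgs)


def plant_cluster_snps(config: SimulationConfig, ref: dict[str, str],
                       truth: MethylationTruth, plan: VariantPlan,
                       rng: np.random.Generator) -> None:
    """Guarantee assignable bisulfite reads: inside every cluster's span plant
    conversion-safe informative SNPs of both orientations (an A/G pair,
    usable on top-strand reads, and a C/T pair, usable on bottom-strand
    reads) roughly every 120 bp, avoiding the cytosines themselves."""
    cpg_by_chrom = {c: set(sub["pos"]) for c, sub in truth.cpgs.groupby("chrom")}
    taken_by_chrom: dict[str, set] = {}
    for c, sub in plan.table.groupby("chrom"):
        taken: set[int] = set()
        for p, r_allele in zip(sub["pos"], sub["ref"]):
            taken.update(range(int(p) - 8, int(p) + len(r_allele) + 8))
        taken_by_chrom[c] = taken

    def _creates_cpg(seq, p, alt):
        return ((alt == "G" and seq[p - 1] == "C")
                or (alt == "C" and p + 1 < len(seq) and seq[p + 1] == "G"))

    for r in truth.clusters.itertuples():
        seq = ref[r.chrom]
        forbidden = cpg_by_chrom.get(r.chrom, set())
        taken = taken_by_chrom.setdefault(r.chrom, set())
        lo, hi = max(2, int(r.start) - 70), min(len(seq) - 2, int(r.end) + 70)
        candidates: dict[str, list] = {"AG": [], "CT": []}
        for p in range(lo, hi):
            if p in taken or "CG" in seq[p - 1:p + 2]:
                continue
            if any(abs(p - q) <= 2 for q in forbidden
                   if r.start - 80 <= q <= r.end + 80):
                continue
            refb = seq[p]
            if refb in "AG":
                alt = "G" if refb == "A" else "A"
                kind = "AG"
            elif refb in "CT":
                alt = "T" if refb == "C" else "C"
                kind = "CT"
            else:
                continue
            if _creates_cpg(seq, p, alt):
                continue
            candidates[kind].append((p, refb, alt))
        for kind in ("AG", "CT"):
            cand = candidates[kind]
            if not cand:
                continue
            picks = sorted({cand[0], cand[len(cand) // 2], cand[-1]})
            for p, refb, alt in picks:
                if p in taken:
                    continue
                duroc_alt = bool(rng.random() < 0.5)
                plant_site(plan, r.chrom, p, refb, alt, duroc_alt)
                taken.update(range(p - 8, p + 9))


_BG_METH = 0.75   # background methylation of CpGs outside planted clusters


def _keep_probability_arrays(g: IndividualizedGenome, chrom: str,
                             site_truth: dict[int, tuple], origin: str,
                             breed: str, non_conversion: float
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-position probability that a C (top strand) or G (bottom strand)
    survives bisulfite conversion in this genome, for reads of the given
    parental origin.  Methylated CpG cytosines always survive; everything
    else survives only at the non-conversion rate."""
    arr = np.frombuffer(g.sequences[chrom].encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    cpg_c = is_c.copy()
    cpg_c[:-1] &= is_g[1:]
    cpg_c[-1] = False
    p_meth = np.zeros(len(arr))
    p_meth[cpg_c] = _BG_METH
    for pos, (pa, pb, cls) in site_truth.items():
        if 0 <= pos < len(arr) and cpg_c[pos]:
            if cls == "age":
                p_meth[pos] = pa if breed == "Duroc" else pb
            else:
                p_meth[pos] = pa if origin == "maternal" else pb
    keep_c = np.where(is_c, p_meth + (1 - p_meth) * non_conversion, 1.0)
    # bottom strand: the G of a CpG mirrors the methylation of the C at pos-1
    p_meth_g = np.zeros(len(arr))
    p_meth_g[1:] = np.where(cpg_c[:-1], p_meth[:-1], 0.0)
    keep_g = np.where(is_g, p_meth_g + (1 - p_meth_g) * non_conversion, 1.0)
    return keep_c, keep_g


def _convert_read(arr: np.ndarray, start: int, strand: str,
                  keep_c: np.ndarray, keep_g: np.ndarray,
                  rng: np.random.Generator) -> str:
    rl = len(arr)
    r = rng.random(rl)
    out = arr.copy()
    if strand == "CT":
        conv = (out == ord("C")) & (r >= keep_c[start:start + rl])
        out[conv] = ord("T")
    else:
        conv = (out == ord("G")) & (r >= keep_g[start:start + rl])
        out[conv] = ord("A")
    return out.tobytes().decode()


def simulate_bisulfite(config: SimulationConfig, truth: MethylationTruth,
                       genomes: dict[str, IndividualizedGenome],
                       samples: pd.DataFrame, rng: np.random.Generator,
                       outdir: str | Path) -> None:
    """Single-end bisulfite reads over the CpG clusters plus the unmethylated
    spike-in contig.  Unmethylated cytosines convert to thymine (or, on
    bottom-strand reads, guanines to adenine) with probability
    1 - non_conversion; methylated CpG cytosines are retained."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rl = config.read_length
    # per-parental-genome CpG truth: lift reference CpG positions forward
    truth_by_parent: dict[str, dict[str, dict[int, tuple]]] = {}
    for parent, g in genomes.items():
        per_chrom: dict[str, dict[int, tuple]] = {}
        for chrom, sub in truth.cpgs.groupby("chrom"):
            cm = g.map.chroms[chrom]
            lifted, dropped = cm.forward_array(sub["pos"].to_numpy())
            d = {}
            for lp, bad, pa, pb, cls in zip(lifted, dropped, sub["p_a"],
                                            sub["p_b"], sub["class"]):
                if not bad:
                    d[int(lp)] = (float(pa), float(pb), cls)
            per_chrom[chrom] = d
        truth_by_parent[parent] = per_chrom

    keep_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    seq_cache: dict[tuple, np.ndarray] = {}

    def keep_arrays(parent, chrom, origin):
        key = (parent, chrom, origin)
        if key not in keep_cache:
            g = genomes[parent]
            st = truth_by_parent[parent].get(chrom, {}) if chrom != SPIKE_CONTIG else {}
            kc, kg = _keep_probability_arrays(g, chrom, st, origin,
                                              BREED_OF[parent],
                                              config.non_conversion)
            if chrom == SPIKE_CONTIG:
                # spike-in is fully unmethylated regardless of CpG context
                arr = seq_array(parent, chrom)
                kc = np.where(arr == ord("C"), config.non_conversion, 1.0)
                kg = np.where(arr == ord("G"), config.non_conversion, 1.0)
            keep_cache[key] = (kc, kg)
        return keep_cache[key]

    def seq_array(parent, chrom):
        key = (parent, chrom)
        if key not in seq_cache:
            seq_cache[key] = np.frombuffer(
                genomes[parent].sequences[chrom].encode(), dtype=np.uint8)
        return seq_cache[key]

    for _, s in samples.iterrows():
        par = PARENTS[s["cross_direction"]]
        writers = {}
        for origin, parent in (("maternal", par["dam"]), ("paternal", par["sire"])):
            g = genomes[parent]
            lens = {c: len(seq) for c, seq in g.sequences.items()}
            writers[origin] = SamWriter(
                outdir / f"{s['sample_id']}.bs.{origin}.sam", lens)
        serial = 0
        for origin, parent in (("maternal", par["dam"]), ("paternal", par["sire"])):
            w = writers[origin]
            for r in truth.clusters.itertuples():
                cm = genomes[parent].map.chroms[r.chrom]
                cs, ce = _lift_interval(cm, int(r.start), int(r.end))
                lo = max(0, cs - rl + 20)
                hi = max(lo + 1, ce - 20)
                span = (hi + rl) - lo
                n_reads = rng.poisson(config.meth_coverage * span / rl)
                arr = seq_array(parent, r.chrom)
                kc, kg = keep_arrays(parent, r.chrom, origin)
                starts = rng.integers(lo, hi, size=n_reads)
                strands = rng.random(n_reads) < 0.5
                for start, top in zip(starts, strands):
                    start = int(start)
                    strand = "CT" if top else "GA"
                    read = _convert_read(arr[start:start + rl], start, strand,
                                         kc, kg, rng)
                    read = _apply_errors(read, config.base_error, rng)
                    qname = f"{s['sample_id']}:b{serial:07d}"
                    serial += 1
                    w.write_single(qname, r.chrom, start, read,
                                   tags=f"XG:Z:{strand}")
            # spike-in: fully unmethylated control
            arr = seq_array(parent, SPIKE_CONTIG)
            kc, kg = keep_arrays(parent, SPIKE_CONTIG, origin)
            n_spike = config.spike_reads_per_sample // 2
            starts = rng.integers(0, len(arr) - rl, size=n_spike)
            strands = rng.random(n_spike) < 0.5
            for start, top in zip(starts, strands):
                start = int(start)
                strand = "CT" if top else "GA"
                read = _convert_read(arr[start:start + rl], start, strand,
                                     kc, kg, rng)
                qname = f"{s['sample_id']}:b{serial:07d}"
                serial += 1
                w.write_single(qname, SPIKE_CONTIG, start, read,
                               tags=f"XG:Z:{strand}")
        for w in writers.values():
            w.close()


# ---------------------------------------------------------------------------
# recovery metrics


def evaluate_recovery(calls: pd.DataFrame, truth: GeneTruth,
                      strong_log2fc: float = 2.0,
                      min_mean: float = 100.0,
                      assessable: set | None = None) -> dict:
    """Sensitivity and false discovery proportion against planted truth.

    'Strong' features are those with |planted log2FC| >= strong_log2fc (or
    imprinted) and base mean >= min_mean.  ``assessable`` optionally
    restricts scoring to features that carry informative variation (a
    feature without any informative site cannot be assessed, mirroring the
    study's restriction to genes with informative variants).
    """
    t = truth.table.set_index("feature_id")
    if assessable is not None:
        t = t.loc[t.index.isin(assessable)]
    called = set(calls["feature_id"]) if len(calls) else set()
    strong = t[((t["class"].isin(["poe", "age"]))
                & (t["log2fc"].abs() >= strong_log2fc)
                & (t["base_mean"] >= min_mean))
               | ((t["class"] == "imprinted") & (t["base_mean"] >= min_mean))]
    null = t[t["class"] == "none"]
    tp = len(set(strong.index) & called)
    fp = len(set(null.index) & called)
    sensitivity = tp / len(strong) if len(strong) else float("nan")
    fdp = fp / max(len(called), 1)
    return {"n_strong": int(len(strong)), "n_called": int(len(called)),
            "true_positives": tp, "false_positives_null": fp,
            "sensitivity": sensitivity, "fdp": fdp}
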