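"""Shared fixtures: tiny genomes, VCFs and annotations built on the fly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest


@pytest.fixture
def write_vcf(tmp_path):
    """Factory writing a small VCF: records are (chrom, pos0, ref, alt,
    {sample: gt-tuple-or-None}) with contig lengths inferred or given."""

    def _write(records, samples, contigs, name="test.vcf"):
        header = pysam.VariantHeader()
        for chrom, length in contigs.items():
            header.contigs.add(chrom, length=length)
        header.formats.add("GT", 1, "String", "Genotype")
        for s in samples:
            header.add_sample(s)
        path = tmp_path / name
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for chrom, pos, ref, alt, gts in records:
                alts = alt if isinstance(alt, tuple) else (alt,)
                rec = vf.new_record(contig=chrom, start=pos,
                                    alleles=(ref, *alts))
                for s in samples:
                    gt = gts.get(s)
                    rec.samples[s]["GT"] = gt if gt is not None else (None, None)
                vf.write(rec)
        return str(path)

    return _write


@pytest.fixture
def toy_gtf():
    """Two genes; gene_b has two transcripts sharing exon A (constitutive)
    while only one carries exon B."""
    rows = [
        # gene_a: single transcript, exons [100,200) and [300,400)
        ("chr1", "t", "gene", 100, 400, ".", "+", ".",
         'gene_id "gene_a";', "gene_a", ""),
        ("chr1", "t", "transcript", 100, 400, ".", "+", ".",
         'gene_id "gene_a"; transcript_id "a.1";', "gene_a", "a.1"),
        ("chr1", "t", "exon", 100, 200, ".", "+", ".",
         'gene_id "gene_a"; transcript_id "a.1";', "gene_a", "a.1"),
        ("chr1", "t", "exon", 300, 400, ".", "+", ".",
         'gene_id "gene_a"; transcript_id "a.1";', "gene_a", "a.1"),
        # gene_b: exon A shared, exon B in one transcript only
        ("chr1", "t", "gene", 1000, 1600, ".", "-", ".",
         'gene_id "gene_b";', "gene_b", ""),
        ("chr1", "t", "transcript", 1000, 1600, ".", "-", ".",
         'gene_id "gene_b"; transcript_id "b.1";', "gene_b", "b.1"),
        ("chr1", "t", "exon", 1000, 1200, ".", "-", ".",
         'gene_id "gene_b"; transcript_id "b.1";', "gene_b", "b.1"),
        ("chr1", "t", "transcript", 1000, 1600, ".", "-", ".",
         'gene_id "gene_b"; transcript_id "b.2";', "gene_b", "b.2"),
        ("chr1", "t", "exon", 1000, 1200, ".", "-", ".",
         'gene_id "gene_b"; transcript_id "b.2";', "gene_b", "b.2"),
        ("chr1", "t", "exon", 1400, 1600, ".", "-", ".",
         'gene_id "gene_b"; transcript_id "b.2";', "gene_b", "b.2"),
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "source", "feature", "start", "end", "score", "strand",
        "frame", "attributes", "gene_id", "transcript_id"])


@pytest.fixture
def reciprocal_samples():
    """Balanced 6+6 reciprocal sample sheet (one tissue, one stage)."""
    rows = []
    for direction in ("DxL", "LxD"):
        for sex in ("F", "M"):
            for rep in (1, 2, 3):
                rows.append({
                    "sample_id": f"{direction}_{sex}{rep}",
                    "individual": f"{direction}_{sex}{rep}",
                    "tissue": "muscle", "stage": "F70",
                    "sex": sex, "cross_direction": direction})
    return pd.DataFrame(rows)


def random_variants(rng, seq, n_snp, n_indel, max_indel=4):
    """Non-overlapping random homozygous variants for a toy chromosome."""
    from allelescope.genomes import VariantRecord

    guard = max_indel + 2
    n = n_snp + n_indel
    if n == 0:
        return []
    pos = np.sort(rng.choice(len(seq) - 2 * guard, size=min(n, 50),
                             replace=False) + guard)
    keep = np.concatenate([[True], np.diff(pos) > guard])
    pos = pos[keep]
    kinds = rng.permutation(
        ["snp"] * max(0, len(pos) - n_indel) + ["indel"] * min(n_indel, len(pos)))
    out = []
    for p, kind in zip(pos, kinds):
        p = int(p)
        refb = seq[p]
        if kind == "snp":
            alt = str(rng.choice([b for b in "ACGT" if b != refb]))
            out.append(VariantRecord("chr1", p, refb, alt))
        else:
            k = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:
                ins = "".join(rng.choice(list("ACGT"), k))
                out.append(VariantRecord("chr1", p, refb, refb + ins))
            else:
                out.append(VariantRecord("chr1", p, seq[p:p + k + 1], refb))
    return out
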