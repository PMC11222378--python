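"""Allele-specific CpG methylation from bisulfite alignments.

Bisulfite conversion turns unmethylated cytosines into thymines, so a
converted read can no longer be compared naively against allele sequences:
on top-strand (C->T converted) reads an informative site whose two alleles
are C and T is uninformative, as is a G/A site on bottom-strand reads.
Reads are therefore assigned to their parental genome of origin with those
conversion-ambiguous sites excluded from scoring.  Each assigned read then
contributes one methylated (unconverted C) or unmethylated (converted T)
call per covered CpG on its allele; CHG/CHH cytosines are discarded.
Cytosine records are per-cytosine (the two strands of a CpG are reported
separately).  Finally the per-parental-genome coordinates are converted
back to the reference frame so the two alleles can be compared; cytosines
inside inserted sequence, absent from the reference, are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from allelescope.assignment import (
    CONFLICT, MATERNAL, PATERNAL, UNASSIGNED,
    ReadAln, SiteIndex, assign_fragment, assign_read, load_alignments,
    score_read,
)
from allelescope.genomes import INSERTED, CoordinateMap

log = logging.getLogger(__name__)

TOP = "CT"      # top-strand conversion (reads report C/T at plus-strand Cs)
BOTTOM = "GA"   # bottom-strand conversion (reads report G/A at plus-strand Gs)


def find_cpg_sites(sequences: dict[str, str]) -> dict[str, np.ndarray]:
    """Plus-strand positions of the C in every CpG dinucleotide."""
    out = {}
    for chrom, seq in sequences.items():
        pos = []
        i = seq.find("CG")
        while i != -1:
            pos.append(i)
            i = seq.find("CG", i + 1)
        out[chrom] = np.asarray(pos, dtype=np.int64)
    return out


def bisulfite_site_indexes(oriented: pd.DataFrame, cmap: CoordinateMap | None
                           ) -> dict[str, SiteIndex]:
    """Per conversion strand, the informative sites safe to score.

    Top-strand reads cannot use sites whose allele pair is {C, T}; bottom-
    strand reads cannot use {G, A} pairs.
    """
    pair = oriented["maternal_allele"] + oriented["paternal_allele"]
    ct_ambiguous = pair.isin(["CT", "TC"])
    ga_ambiguous = pair.isin(["GA", "AG"])
    return {
        TOP: SiteIndex(oriented[~ct_ambiguous], cmap),
        BOTTOM: SiteIndex(oriented[~ga_ambiguous], cmap),
    }


def _read_conversion_strand(tags: dict | None) -> str:
    if tags and tags.get("XG") in (TOP, BOTTOM):
        return tags["XG"]
    return TOP


def _covered_positions(aln: ReadAln):
    """(genome_pos, query_pos) pairs covered by the alignment."""
    if aln.cigartuples is None:
        start = aln.pos
        return [(start + k, k) for k in range(len(aln.seq))]
    pairs = []
    qpos, gpos = 0, aln.pos
    for op, ln in aln.cigartuples:
        if op in (0, 7, 8):
            pairs.extend((gpos + k, qpos + k) for k in range(ln))
            qpos += ln
            gpos += ln
        elif op in (1, 4):
            qpos += ln
        elif op in (2, 3):
            gpos += ln
    return pairs


def _call_cpgs(aln: ReadAln, strand: str, cpg_pos: np.ndarray,
               counts: dict, allele: str) -> None:
    """Tally m/u calls for the CpG cytosines covered by one assigned read."""
    if aln.cigartuples is None:
        p0, p1 = aln.pos, aln.pos + len(aln.seq)
        lookup = None
    else:
        pairs = _covered_positions(aln)
        if not pairs:
            return
        lookup = dict(pairs)
        p0 = min(lookup)
        p1 = max(lookup) + 1
    if strand == TOP:
        # plus-strand C of the CpG, read base C (methylated) or T (converted)
        i0, i1 = np.searchsorted(cpg_pos, [p0, p1])
        for c in cpg_pos[i0:i1]:
            q = int(c - aln.pos) if lookup is None else lookup.get(int(c))
            if q is None or not (0 <= q < len(aln.seq)):
                continue
            b = aln.seq[q]
            if b in "CT":
                key = (aln.chrom, int(c), "+", allele)
                mu = counts.setdefault(key, [0, 0])
                mu[0 if b == "C" else 1] += 1
    else:
        # minus-strand C sits opposite the CpG's G at plus position c+1
        i0, i1 = np.searchsorted(cpg_pos + 1, [p0, p1])
        for c in cpg_pos[i0:i1]:
            g = int(c) + 1
            q = int(g - aln.pos) if lookup is None else lookup.get(g)
            if q is None or not (0 <= q < len(aln.seq)):
                continue
            b = aln.seq[q]
            if b in "GA":
                key = (aln.chrom, g, "-", allele)
                mu = counts.setdefault(key, [0, 0])
                mu[0 if b == "G" else 1] += 1


def load_alignments_with_tags(sam_path):
    """Like assignment.load_alignments but keeps the XG conversion-strand tag."""
    import pysam

    frags: dict[str, dict[int, tuple[ReadAln, str]]] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sf:
        for rec in sf:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            mate = 2 if rec.is_read2 else 1
            cig = rec.cigartuples
            if cig is not None and len(cig) == 1 and cig[0][0] == 0:
                cig = None
            qual = (np.asarray(rec.query_qualities, dtype=np.int16)
                    if rec.query_qualities is not None else None)
            strand = TOP
            try:
                strand = _read_conversion_strand(dict(rec.get_tags()))
            except Exception:
                pass
            frags.setdefault(rec.query_name, {})[mate] = (
                ReadAln(rec.reference_name, rec.reference_start,
                        rec.query_sequence, qual, cig, True), strand)
    return frags


def extract_allelic_methylation(maternal_sam, paternal_sam,
                                oriented_sites: pd.DataFrame,
                                maternal_map: CoordinateMap,
                                paternal_map: CoordinateMap,
                                maternal_sequences: dict[str, str],
                                paternal_sequences: dict[str, str],
                                min_base_quality: int = 20) -> pd.DataFrame:
    """Allelic CpG m/u counts for one sample, in parental-genome coordinates.

    Returns a long DataFrame (genome, chrom, pos, strand, allele, m, u)
    where ``genome`` names the parental frame the position lives in and
    ``allele`` is the read's assigned origin.  Fragments whose mates
    disagree are discarded; unassigned fragments contribute nothing.
    """
    idx = {
        "maternal": bisulfite_site_indexes(oriented_sites, maternal_map),
        "paternal": bisulfite_site_indexes(oriented_sites, paternal_map),
    }
    cpgs = {
        "maternal": find_cpg_sites(maternal_sequences),
        "paternal": find_cpg_sites(paternal_sequences),
    }
    frags_by_genome = {
        "maternal": load_alignments_with_tags(maternal_sam),
        "paternal": load_alignments_with_tags(paternal_sam),
    }
    counts: dict[tuple, list[int]] = {}
    per_genome_counts = {"maternal": {}, "paternal": {}}
    all_ids = set(frags_by_genome["maternal"]) | set(frags_by_genome["paternal"])
    for frag_id in all_ids:
        mates = {}
        for genome in ("maternal", "paternal"):
            for mate, rec in frags_by_genome[genome].get(frag_id, {}).items():
                mates.setdefault(mate, (genome, rec))
        decisions, alns = [], []
        for mate in sorted(mates):
            genome, (aln, strand) = mates[mate]
            sc = score_read(aln, idx[genome][strand], min_base_quality)
            decisions.append(assign_read(sc, None, "bs"))
            alns.append((genome, aln, strand, sc))
        frag = assign_fragment(frag_id, decisions,
                               [a[3] for a in alns])
        if frag.decision in (CONFLICT, UNASSIGNED):
            continue
        allele = "maternal" if frag.decision == MATERNAL else "paternal"
        for genome, aln, strand, _ in alns:
            _call_cpgs(aln, strand, cpgs[genome].get(aln.chrom, np.empty(0, dtype=np.int64)),
                       per_genome_counts[genome], allele)
    rows = []
    for genome, cdict in per_genome_counts.items():
        for (chrom, pos, strand, allele), (m, u) in cdict.items():
            rows.append((genome, chrom, pos, strand, allele, m, u))
    return pd.DataFrame(rows, columns=["genome", "chrom", "pos", "strand",
                                       "allele", "m", "u"])


def convert_cpg_coordinates(table: pd.DataFrame,
                            maternal_map: CoordinateMap,
                            paternal_map: CoordinateMap) -> pd.DataFrame:
    """Translate parental-frame cytosine records to the reference frame.

    Records inside inserted sequence (no reference counterpart) are dropped;
    maternal and paternal records for the same reference cytosine are merged
    (m/u summed per allele).
    """
    maps = {"maternal": maternal_map, "paternal": paternal_map}
    merged: dict[tuple, list[int]] = {}
    for genome, chrom, pos, strand, allele, m, u in table.itertuples(index=False):
        ref = maps[genome].back(chrom, int(pos))
        if ref is INSERTED:
            continue
        key = (chrom, int(ref), strand, allele)
        mu = merged.setdefault(key, [0, 0])
        mu[0] += int(m)
        mu[1] += int(u)
    rows = [(c, p, s, a, m, u) for (c, p, s, a), (m, u) in merged.items()]
    out = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "allele", "m", "u"])
    return out.sort_values(["chrom", "pos", "strand", "allele"]).reset_index(drop=True)


@dataclass
class CpGAlleleTable:
    """Reference-frame CpG x (sample, allele) methylated/unmethylated counts.

    ``m`` and ``u`` are DataFrames indexed by (chrom, pos, strand) whose
    columns are '<sample>.maternal' / '<sample>.paternal'.
    """

    m: pd.DataFrame
    u: pd.DataFrame

    @classmethod
    def from_samples(cls, per_sample: dict[str, pd.DataFrame]) -> "CpGAlleleTable":
        """Assemble from per-sample reference-frame long tables."""
        pieces_m, pieces_u = {}, {}
        for sample, df in per_sample.items():
            for allele, sub in df.groupby("allele"):
                key = f"{sample}.{allele}"
                s = sub.set_index(["chrom", "pos", "strand"])
                pieces_m[key] = s["m"]
                pieces_u[key] = s["u"]
        m = pd.DataFrame(pieces_m).fillna(0).astype(int).sort_index()
        u = pd.DataFrame(pieces_u).fillna(0).astype(int).sort_index()
        u = u.reindex(m.index).fillna(0).astype(int)
        return cls(m, u)

    def coverage_by_sample(self, samples: list[str]) -> pd.DataFrame:
        """Total coverage per sample (alleles summed)."""
        out = {}
        for s in samples:
            cols = [c for c in self.m.columns if c.startswith(s + ".")]
            out[s] = self.m[cols].sum(axis=1) + self.u[cols].sum(axis=1)
        return pd.DataFrame(out)

    def allele_coverage(self, sample: str, allele: str) -> pd.Series:
        col = f"{sample}.{allele}"
        if col not in self.m.columns:
            return pd.Series(0, index=self.m.index)
        return self.m[col] + self.u[col]

    def subset(self, keep: pd.Index) -> "CpGAlleleTable":
        return CpGAlleleTable(self.m.loc[keep], self.u.loc[keep])

    def write(self, path) -> None:
        wide = pd.concat(
            {"m": self.m, "u": self.u}, axis=1)
        wide.columns = [f"{col}.{kind}" for kind, col in wide.columns]
        wide.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "CpGAlleleTable":
        df = pd.read_csv(path, sep="\t").set_index(["chrom", "pos", "strand"])
        m_cols = [c for c in df.columns if c.endswith(".m")]
        u_cols = [c for c in df.columns if c.endswith(".u")]
        m = df[m_cols]
        m.columns = [c[:-2] for c in m_cols]
        u = df[u_cols]
        u.columns = [c[:-2] for c in u_cols]
        return cls(m, u)


def filter_cpgs_bulk(table: CpGAlleleTable, samples: list[str],
                     min_cov: int = 10, min_samples: int = 10,
                     snp_positions: set[tuple[str, int]] | None = None
                     ) -> CpGAlleleTable:
    """Bulk coverage filter: coverage strictly greater than ``min_cov`` in at
    least ``min_samples`` samples; cytosines at parental variant positions
    are removed."""
    cov = table.coverage_by_sample(samples)
    keep = (cov > min_cov).sum(axis=1) >= min_samples
    if snp_positions:
        at_snp = [(c, p) in snp_positions for c, p, _ in table.m.index]
        keep &= ~np.asarray(at_snp)
    return table.subset(table.m.index[keep])


def filter_cpgs_allelic(table: CpGAlleleTable, sample_meta: pd.DataFrame,
                        min_cov: int = 5, max_low: int = 2,
                        expected_group: int = 6) -> CpGAlleleTable:
    """Allelic coverage filter applied within each cross direction.

    A CpG is kept when, for each direction and each allele, at most
    ``max_low`` of the direction's samples have allele coverage below
    ``min_cov`` (with six samples per direction: at least 4/6 covered).
    Group sizes other than ``expected_group`` scale the allowance
    proportionally with a warning.
    """
    keep = pd.Series(True, index=table.m.index)
    for direction, group in sample_meta.groupby("cross_direction"):
        ids = list(group["sample_id"])
        allowance = max_low
        if len(ids) != expected_group:
            allowance = int(np.floor(max_low * len(ids) / expected_group))
            log.warning("direction %s has %d samples (expected %d); "
                        "low-coverage allowance scaled to %d",
                        direction, len(ids), expected_group, allowance)
        for allele in ("maternal", "paternal"):
            cov = pd.DataFrame({s: table.allele_coverage(s, allele) for s in ids})
            n_low = (cov < min_cov).sum(axis=1)
            keep &= n_low <= allowance
    return table.subset(table.m.index[keep])


def methylation_levels(df: pd.DataFrame) -> pd.Series:
    """m / (m + u); defined only where m + u > 0."""
    tot = df["m"] + df["u"]
    return (df["m"] / tot.replace(0, np.nan)).dropna()


def feature_methylation(cpgs: pd.DataFrame, features: pd.DataFrame) -> pd.Series:
    """Per-feature average methylation: sum(m) / sum(m + u) over covered CpGs.

    ``cpgs`` has columns chrom, pos, m, u; ``features`` has feature_id,
    chrom, start, end.  Features without covered CpGs are NaN.
    """
    out = {}
    by_chrom = {c: sub.sort_values("pos") for c, sub in cpgs.groupby("chrom")}
    for fid, chrom, s, e in zip(features["feature_id"], features["chrom"],
                                features["start"], features["end"]):
        sub = by_chrom.get(chrom)
        if sub is None:
            out[fid] = np.nan
            continue
        pos = sub["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [s, e])
        m = sub["m"].to_numpy()[i0:i1].sum()
        u = sub["u"].to_numpy()[i0:i1].sum()
        out[fid] = m / (m + u) if (m + u) > 0 else np.nan
    return pd.Series(out, name="methylation")


METHYLATION_BIN_LABELS = (
    ["<5%"] + [f"{5 + 10 * i}-{15 + 10 * i}%" for i in range(9)] + [">95%"])


def methylation_bins(levels) -> pd.Series:
    """Proportion of CpGs per methylation-level bin.

    Bins: low (<5%), nine 10% bins spanning 5%-95%, high (>95%).  The
    proportions partition the input and sum to 1.
    """
    x = np.asarray(levels, dtype=float)
    if x.size == 0:
        raise ValueError("no methylation levels supplied")
    low = (x < 0.05).sum()
    high = (x > 0.95).sum()
    mid = x[(x >= 0.05) & (x <= 0.95)]
    edges = np.linspace(0.05, 0.95, 10)
    counts, _ = np.histogram(mid, bins=edges)
    all_counts = np.concatenate([[low], counts, [high]])
    return pd.Series(all_counts / x.size, index=METHYLATION_BIN_LABELS)


def correlate_methylation(meth: pd.Series, other: pd.Series
                          ) -> tuple[float, float]:
    """Spearman correlation between feature methylation and another modality
    (expression or accessibility); (nan, nan) when undefined."""
    joint = pd.concat([meth, other], axis=1, join="inner").dropna()
    if len(joint) < 3:
        return float("nan"), float("nan")
    a, b = joint.iloc[:, 0], joint.iloc[:, 1]
    if a.nunique() == 1 or b.nunique() == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def estimate_nonconversion(sam_path, spike_sequences: dict[str, str]) -> float:
    """Bisulfite non-conversion rate from an unmethylated spike-in contig.

    The fraction of cytosine reference positions still sequenced as
    cytosine; the spike-in carries no methylation, so any retained C
    reflects incomplete conversion.
    """
    frags = load_alignments_with_tags(sam_path)
    kept = converted = 0
    for mates in frags.values():
        for aln, strand in mates.values():
            seq_ref = spike_sequences.get(aln.chrom)
            if seq_ref is None:
                continue
            for gpos, qpos in _covered_positions(aln):
                if gpos >= len(seq_ref):
                    continue
                refb = seq_ref[gpos]
                b = aln.seq[qpos]
                if strand == TOP and refb == "C":
                    if b == "C":
                        kept += 1
                    elif b == "T":
                        converted += 1
                elif strand == BOTTOM and refb == "G":
                    if b == "G":
                        kept += 1
                    elif b == "A":
                        converted += 1
    total = kept + converted
    return kept / total if total else float("nan")
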