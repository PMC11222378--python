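"""Fragment-level allelic read assignment and counting.

RNA-Seq / ATAC-Seq reads are aligned to both individualized parental
genomes.  Each read is scored at the informative sites it covers: a site
contributes to the maternal (paternal) score when the read base equals the
maternal (paternal) allele.  A read is assigned to the genome matching
strictly more of its covered informative alleles; ties and reads without
informative coverage stay unassigned.  The two mates of a fragment must not
disagree — disagreeing fragments are conflicts and are discarded from all
counts.  For RNA, an assignable read must additionally have at least 80% of
its aligned bases inside constitutive exons, which guards against intronic
or intergenic contamination of gene-level allelic counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from allelescope.genomes import CoordinateMap, DELETED

MATERNAL = "MATERNAL"
PATERNAL = "PATERNAL"
UNASSIGNED = "UNASSIGNED"
CONFLICT = "CONFLICT"

DEFAULT_MIN_BASE_QUALITY = 20
RNA_EXON_OVERLAP_MIN = 0.80


@dataclass
class ReadAln:
    """Minimal alignment record (one mate, one genome)."""

    chrom: str | None
    pos: int                      # 0-based leftmost aligned position
    seq: str
    qual: np.ndarray | None
    cigartuples: list | None      # None means a single full-length match
    mapped: bool
    tlen: int = 0


@dataclass
class AssignmentDecision:
    fragment_id: str
    decision: str
    n_sites_maternal_match: int
    n_sites_paternal_match: int


@dataclass
class AlleleBalance:
    sample_id: str
    maternal_count: int
    paternal_count: int
    pass_flag: bool
    reason: str = ""

    @property
    def maternal_fraction(self) -> float:
        tot = self.maternal_count + self.paternal_count
        return self.maternal_count / tot if tot else float("nan")


class SiteIndex:
    """Informative substitution sites in one parental genome's coordinates.

    Built from reference-frame oriented sites (maternal/paternal alleles)
    lifted forward through that genome's coordinate map.  Sites falling in a
    deleted interval of the genome are dropped for that genome.
    """

    def __init__(self, oriented: pd.DataFrame, cmap: CoordinateMap | None = None):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in oriented.groupby("chrom"):
            ref_pos = sub["pos"].to_numpy(dtype=np.int64)
            if cmap is None:
                ind_pos, dropped = ref_pos, np.zeros(len(ref_pos), dtype=bool)
            else:
                ind_pos, dropped = cmap._get(chrom).forward_array(ref_pos)
            keep = ~dropped
            order = np.argsort(ind_pos[keep])
            sel = np.flatnonzero(keep)[order]
            self.by_chrom[chrom] = (
                ind_pos[sel].astype(np.int64),
                ref_pos[sel],
                sub["maternal_allele"].to_numpy()[sel],
                sub["paternal_allele"].to_numpy()[sel],
            )

    def covering(self, chrom: str, start: int, end: int):
        """(ind_pos, ref_pos, maternal, paternal) arrays for sites in [start, end)."""
        if chrom not in self.by_chrom:
            return None
        pos, ref, mat, pat = self.by_chrom[chrom]
        i0 = int(np.searchsorted(pos, start))
        i1 = int(np.searchsorted(pos, end))
        if i0 == i1:
            return None
        return pos[i0:i1], ref[i0:i1], mat[i0:i1], pat[i0:i1]


class IntervalUnion:
    """Disjoint interval union with O(log n) overlap queries via prefix sums."""

    def __init__(self, intervals):
        merged = []
        for s, e in sorted(intervals):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.starts = np.array([s for s, _ in merged], dtype=np.int64)
        self.ends = np.array([e for _, e in merged], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(self.ends - self.starts)])

    def overlap(self, start: int, end: int) -> int:
        if len(self.starts) == 0 or end <= start:
            return 0
        i0 = int(np.searchsorted(self.ends, start, side="right"))
        i1 = int(np.searchsorted(self.starts, end, side="left"))
        if i0 >= i1:
            return 0
        total = int(self.cum[i1] - self.cum[i0])
        total -= max(0, start - int(self.starts[i0]))
        total -= max(0, int(self.ends[i1 - 1]) - end)
        return total


def score_read(aln: ReadAln, sites: SiteIndex,
               min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
               site_tally: dict | None = None) -> tuple[int, int]:
    """Count informative sites whose read base matches the maternal/paternal allele.

    Bases below ``min_base_quality`` and bases matching neither allele count
    for neither genome.  ``site_tally`` optionally accumulates per-site
    maternal/paternal base matches keyed by (chrom, reference position).
    """
    if not aln.mapped or aln.chrom is None:
        return 0, 0
    simple = aln.cigartuples is None or (
        len(aln.cigartuples) == 1 and aln.cigartuples[0][0] == 0)
    n_mat = n_pat = 0
    if simple:
        span = len(aln.seq)
        hit = sites.covering(aln.chrom, aln.pos, aln.pos + span)
        if hit is None:
            return 0, 0
        ind_pos, ref_pos, mat, pat = hit
        for p, rp, m, pa in zip(ind_pos, ref_pos, mat, pat):
            q = int(p - aln.pos)
            if aln.qual is not None and aln.qual[q] < min_base_quality:
                continue
            b = aln.seq[q]
            if b == m:
                n_mat += 1
            elif b == pa:
                n_pat += 1
            else:
                continue
            if site_tally is not None:
                t = site_tally.setdefault((aln.chrom, int(rp)), [0, 0])
                t[0 if b == m else 1] += 1
        return n_mat, n_pat
    # general (gapped) path: walk the CIGAR to map query onto genome positions
    qpos, gpos = 0, aln.pos
    pairs: dict[int, int] = {}
    for op, ln in aln.cigartuples:
        if op in (0, 7, 8):           # M/=/X
            for k in range(ln):
                pairs[gpos + k] = qpos + k
            qpos += ln
            gpos += ln
        elif op in (1, 4):            # I, S consume query
            qpos += ln
        elif op in (2, 3):            # D, N consume genome
            gpos += ln
    hit = sites.covering(aln.chrom, aln.pos, gpos)
    if hit is None:
        return 0, 0
    ind_pos, ref_pos, mat, pat = hit
    for p, rp, m, pa in zip(ind_pos, ref_pos, mat, pat):
        q = pairs.get(int(p))
        if q is None:
            continue
        if aln.qual is not None and aln.qual[q] < min_base_quality:
            continue
        b = aln.seq[q]
        if b == m:
            n_mat += 1
        elif b == pa:
            n_pat += 1
        else:
            continue
        if site_tally is not None:
            t = site_tally.setdefault((aln.chrom, int(rp)), [0, 0])
            t[0 if b == m else 1] += 1
    return n_mat, n_pat


def assign_read(scores: tuple[int, int], exon_overlap_fraction: float | None,
                mode: str) -> str:
    """Majority vote over informative alleles, with the RNA constitutive-exon rule.

    MATERNAL iff strictly more maternal than paternal matches (and, for RNA,
    overlap >= 0.80); symmetric for PATERNAL; otherwise UNASSIGNED.
    """
    n_mat, n_pat = scores
    if n_mat == n_pat:
        return UNASSIGNED
    if mode == "rna":
        if exon_overlap_fraction is None or exon_overlap_fraction < RNA_EXON_OVERLAP_MIN:
            return UNASSIGNED
    return MATERNAL if n_mat > n_pat else PATERNAL


def assign_fragment(fragment_id: str, mate_decisions: list[str],
                    scores: list[tuple[int, int]] | None = None) -> AssignmentDecision:
    """Combine per-mate decisions; disagreeing mates make the fragment a CONFLICT."""
    resolved = [d for d in mate_decisions if d != UNASSIGNED]
    n_mat = sum(s[0] for s in scores) if scores else 0
    n_pat = sum(s[1] for s in scores) if scores else 0
    if not resolved:
        dec = UNASSIGNED
    elif all(d == resolved[0] for d in resolved):
        dec = resolved[0]
    else:
        dec = CONFLICT
    return AssignmentDecision(fragment_id, dec, n_mat, n_pat)


def compute_constitutive_exons(gtf: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Per gene, the bases exonic in *every* annotated transcript.

    For single-transcript genes this is the exon set verbatim; transcripts
    with disjoint exon sets yield an empty constitutive set.
    """
    exons = gtf[gtf["feature"] == "exon"]
    result: dict[str, list[tuple[int, int]]] = {}
    for gene, gsub in exons.groupby("gene_id"):
        per_tx = []
        for _, tsub in gsub.groupby("transcript_id"):
            ivs = sorted(zip(tsub["start"], tsub["end"]))
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            per_tx.append(merged)
        acc = per_tx[0]
        for other in per_tx[1:]:
            out, i, j = [], 0, 0
            while i < len(acc) and j < len(other):
                s = max(acc[i][0], other[j][0])
                e = min(acc[i][1], other[j][1])
                if s < e:
                    out.append((s, e))
                if acc[i][1] < other[j][1]:
                    i += 1
                else:
                    j += 1
            acc = out
        result[gene] = acc
    return result


@dataclass
class FragmentRecord:
    """A fragment's decision plus its reference-frame footprint."""

    fragment_id: str
    chrom: str | None
    span: tuple[int, int] | None             # union span of both mates
    mate_intervals: list[list[tuple[int, int]]]  # per mapped mate: ref intervals
    decision: str
    n_mat: int = 0
    n_pat: int = 0


class FeatureIndex:
    """Interval lookup for genes or peaks."""

    def __init__(self, features: pd.DataFrame):
        if len(features) == 0:
            raise ValueError("empty feature set")
        self.features = features.reset_index(drop=True)
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for fid, chrom, s, e in zip(features["feature_id"], features["chrom"],
                                    features["start"], features["end"]):
            if e > s:
                self.trees[chrom][s:e] = fid

    @property
    def ids(self) -> list[str]:
        return list(self.features["feature_id"])

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        if chrom not in self.trees:
            return []
        return [iv.data for iv in self.trees[chrom][start:end]]


def count_features(fragments: list[FragmentRecord], features: pd.DataFrame,
                   mode: str = "rna",
                   constitutive: dict[str, list[tuple[int, int]]] | None = None,
                   min_exon_fraction: float = RNA_EXON_OVERLAP_MIN) -> pd.DataFrame:
    """Per-feature maternal/paternal/unassigned/total counts for one sample.

    Conflicting fragments contribute nothing.  A fragment overlapping several
    features counts for each; in RNA mode an assigned fragment contributes
    allelic counts to a gene only if every mapped mate has at least
    ``min_exon_fraction`` of its aligned bases inside that gene's
    constitutive exons.
    """
    index = FeatureIndex(features)
    unions = ({g: IntervalUnion(iv) for g, iv in constitutive.items()}
              if constitutive else {})
    counts = {fid: [0, 0, 0, 0] for fid in index.ids}  # mat, pat, unassigned, total
    for fr in fragments:
        if fr.decision == CONFLICT or fr.chrom is None or fr.span is None:
            continue
        for fid in index.overlapping(fr.chrom, *fr.span):
            c = counts[fid]
            c[3] += 1
            if fr.decision == UNASSIGNED:
                c[2] += 1
                continue
            if mode == "rna" and unions:
                u = unions.get(fid)
                ok = u is not None
                if ok:
                    for ivs in fr.mate_intervals:
                        alen = sum(e - s for s, e in ivs)
                        if alen == 0:
                            continue
                        ov = sum(u.overlap(s, e) for s, e in ivs)
                        if ov / alen < min_exon_fraction:
                            ok = False
                            break
                if not ok:
                    c[2] += 1
                    continue
            c[0 if fr.decision == MATERNAL else 1] += 1
    out = pd.DataFrame.from_dict(
        counts, orient="index",
        columns=["maternal", "paternal", "unassigned", "total"])
    out.index.name = "feature_id"
    return out


def compute_allele_balance(sample_id: str, maternal: int, paternal: int,
                           lo: float = 0.45, hi: float = 0.55) -> AlleleBalance:
    """Sample-level allelic balance QC.

    A sample passes when its paternal read fraction lies within [lo, hi]
    (bounds inclusive); samples with zero assigned reads are excluded with a
    distinct reason.
    """
    total = maternal + paternal
    if total == 0:
        return AlleleBalance(sample_id, 0, 0, False, reason="no_assigned_reads")
    pat_frac = paternal / total
    ok = lo <= pat_frac <= hi
    return AlleleBalance(sample_id, maternal, paternal, ok,
                         reason="" if ok else "allelic_imbalance")


def qc_filter_samples(balances: list[AlleleBalance]) -> list[str]:
    return [b.sample_id for b in balances if b.pass_flag]


def snp_level_fraction(site_tally: dict) -> pd.DataFrame:
    """Per informative site, the fraction of allele-matching read bases that
    matched the maternal allele.  Uncovered sites are absent."""
    rows = [(chrom, pos, m, p, m / (m + p))
            for (chrom, pos), (m, p) in sorted(site_tally.items()) if m + p > 0]
    return pd.DataFrame(rows, columns=["chrom", "pos", "maternal_matches",
                                       "paternal_matches", "maternal_fraction"])


def fragment_size_histogram(template_lengths) -> pd.Series:
    """Histogram of absolute template (insert) lengths, for ATAC QC."""
    sizes = pd.Series([abs(t) for t in template_lengths if t != 0], dtype=int)
    if sizes.empty:
        return pd.Series(dtype=int)
    return sizes.value_counts().sort_index()


def merge_peaks(peak_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of overlapping peak intervals across conditions.

    Each consensus peak records the conditions that contributed to it.
    """
    events = []
    for cond, df in peak_sets.items():
        for chrom, s, e in zip(df["chrom"], df["start"], df["end"]):
            events.append((chrom, int(s), int(e), cond))
    events.sort()
    rows = []
    cur = None
    for chrom, s, e, cond in events:
        if cur is not None and chrom == cur[0] and s <= cur[2]:
            cur = (chrom, cur[1], max(cur[2], e), cur[3] | {cond})
        else:
            if cur is not None:
                rows.append(cur)
            cur = (chrom, s, e, {cond})
    if cur is not None:
        rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "conditions"])
    out["conditions"] = out["conditions"].map(lambda c: ",".join(sorted(c)))
    out["feature_id"] = [f"peak_{i:06d}" for i in range(len(out))]
    return out


def compute_cpm_tpm(counts: pd.DataFrame, lengths: pd.Series | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """CPM and (when feature lengths are given) TPM normalization.

    ``counts`` is features x samples.  CPM divides by library size; TPM
    additionally divides by feature length in kb before rescaling each
    sample to one million.
    """
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        raise ValueError(f"zero library size for samples: {bad}")
    cpm = counts.div(libsize, axis=1) * 1e6
    tpm = None
    if lengths is not None:
        lengths = lengths.reindex(counts.index)
        if (lengths <= 0).any():
            raise ValueError("feature lengths must be positive")
        rate = counts.div(lengths / 1e3, axis=0)
        tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return cpm, tpm


# ---------------------------------------------------------------------------
# SAM-level driver


def load_alignments(sam_path: str | Path) -> dict[str, dict[int, ReadAln]]:
    """Group primary alignments by fragment id (qname) and mate number."""
    frags: dict[str, dict[int, ReadAln]] = defaultdict(dict)
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sf:
        for rec in sf:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = 2 if rec.is_read2 else 1
            if rec.is_unmapped:
                frags[rec.query_name].setdefault(
                    mate, ReadAln(None, -1, rec.query_sequence or "", None,
                                  None, False))
                continue
            cig = rec.cigartuples
            if cig is not None and len(cig) == 1 and cig[0][0] == 0:
                cig = None
            qual = (np.asarray(rec.query_qualities, dtype=np.int16)
                    if rec.query_qualities is not None else None)
            frags[rec.query_name][mate] = ReadAln(
                rec.reference_name, rec.reference_start, rec.query_sequence,
                qual, cig, True, rec.template_length)
    return frags


def _read_ref_intervals(aln: ReadAln, cmap: CoordinateMap | None) -> list[tuple[int, int]]:
    if not aln.mapped:
        return []
    if aln.cigartuples is None:
        blocks = [(aln.pos, aln.pos + len(aln.seq))]
    else:
        blocks = []
        gpos = aln.pos
        for op, ln in aln.cigartuples:
            if op in (0, 7, 8):
                blocks.append((gpos, gpos + ln))
                gpos += ln
            elif op in (2, 3):
                gpos += ln
    if cmap is None:
        return blocks
    cm = cmap._get(aln.chrom)
    out = []
    for s, e in blocks:
        out.extend(cm.back_intervals(s, e))
    return out


def assign_sample(maternal_sam: str | Path, paternal_sam: str | Path,
                  oriented_sites: pd.DataFrame,
                  maternal_map: CoordinateMap, paternal_map: CoordinateMap,
                  mode: str = "rna",
                  constitutive_union: dict[str, IntervalUnion] | None = None,
                  min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
                  collect_site_tally: bool = False):
    """Assign every fragment of one sample to its parental genome of origin.

    Reads aligned to the maternal genome are scored there; reads mapped only
    in the paternal genome are scored there instead.  ``constitutive_union``
    maps chromosome -> reference-frame constitutive-exon union (RNA mode).
    Returns (list[FragmentRecord], site_tally dict or None).
    """
    mat_idx = SiteIndex(oriented_sites, maternal_map)
    pat_idx = SiteIndex(oriented_sites, paternal_map)
    mat_frags = load_alignments(maternal_sam)
    pat_frags = load_alignments(paternal_sam)
    tally: dict | None = {} if collect_site_tally else None

    records: list[FragmentRecord] = []
    for frag_id in set(mat_frags) | set(pat_frags):
        mates_m = mat_frags.get(frag_id, {})
        mates_p = pat_frags.get(frag_id, {})
        decisions, scores, intervals = [], [], []
        chrom, span = None, None
        for mate in sorted(set(mates_m) | set(mates_p)):
            am, ap = mates_m.get(mate), mates_p.get(mate)
            if am is not None and am.mapped:
                aln, idx, cmap = am, mat_idx, maternal_map
            elif ap is not None and ap.mapped:
                aln, idx, cmap = ap, pat_idx, paternal_map
            else:
                continue
            sc = score_read(aln, idx, min_base_quality, site_tally=tally)
            ivs = _read_ref_intervals(aln, cmap)
            frac = None
            if mode == "rna" and ivs:
                chrom_u = (constitutive_union.get(aln.chrom)
                           if constitutive_union else None)
                if chrom_u is not None:
                    alen = sum(e - s for s, e in ivs)
                    ov = sum(chrom_u.overlap(s, e) for s, e in ivs)
                    frac = ov / alen if alen else 0.0
            decisions.append(assign_read(sc, frac, mode))
            scores.append(sc)
            intervals.append(ivs)
            if ivs:
                ref_chrom = aln.chrom  # same names in both frames
                lo = min(s for s, _ in ivs)
                hi = max(e for _, e in ivs)
                if chrom is None:
                    chrom, span = ref_chrom, (lo, hi)
                elif ref_chrom == chrom:
                    span = (min(span[0], lo), max(span[1], hi))
        dec = assign_fragment(frag_id, decisions, scores)
        records.append(FragmentRecord(frag_id, chrom, span, intervals,
                                      dec.decision, dec.n_sites_maternal_match,
                                      dec.n_sites_paternal_match))
    return records, tally
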