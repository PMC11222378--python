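"""Individualized parental genomes and coordinate translation.

A hybrid's reads are mapped against each parent's *individualized genome*:
the reference sequence with that parent's homozygous non-reference SNPs and
indels substituted in.  Because indels change sequence length, every
individualized genome carries a :class:`CoordinateMap` that translates
positions between the reference frame and the individualized frame in both
directions.  Downstream modules (read assignment, methylation extraction)
do all cross-sample comparison in the reference frame.

Coordinates are 0-based half-open throughout this module; the VCF/GTF
1-based conventions are handled in :mod:`allelescope.io`.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

#: Sentinel returned by lift_back for positions inside inserted sequence.
INSERTED = "INSERTED"
#: Sentinel returned by lift_forward for positions inside deleted sequence.
DELETED = "DELETED"


@dataclass
class VariantRecord:
    """A single applicable variant: the sample's homozygous non-reference allele.

    ``start`` is the 0-based reference position of the first base of
    ``ref_allele``.
    """

    chrom: str
    start: int
    ref_allele: str
    alt_allele: str

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.start, self.start + len(self.ref_allele)

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def length_delta(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


class ChromMap:
    """Per-chromosome piecewise-linear map between reference and individualized frames."""

    def __init__(self, blocks, inserted, deleted, ref_len, ind_len):
        blocks = [b for b in blocks if b[2] > 0]
        self.ref_starts = np.array([b[0] for b in blocks], dtype=np.int64)
        self.ind_starts = np.array([b[1] for b in blocks], dtype=np.int64)
        self.lengths = np.array([b[2] for b in blocks], dtype=np.int64)
        self.inserted = list(inserted)
        self.deleted = list(deleted)
        self.ref_len = ref_len
        self.ind_len = ind_len

    def _locate(self, starts, pos):
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < starts[i] + self.lengths[i]:
            return i
        return -1

    def forward(self, pos: int):
        """Reference position -> individualized position, or DELETED."""
        if not 0 <= pos < self.ref_len:
            raise ValueError(f"reference position {pos} out of range [0, {self.ref_len})")
        i = self._locate(self.ref_starts, pos)
        if i < 0:
            return DELETED
        return int(self.ind_starts[i] + (pos - self.ref_starts[i]))

    def back(self, pos: int):
        """Individualized position -> reference position, or INSERTED."""
        if not 0 <= pos < self.ind_len:
            raise ValueError(f"individualized position {pos} out of range [0, {self.ind_len})")
        i = self._locate(self.ind_starts, pos)
        if i < 0:
            return INSERTED
        return int(self.ref_starts[i] + (pos - self.ind_starts[i]))

    def forward_array(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized forward lift; second array flags positions inside deletions."""
        i = np.searchsorted(self.ref_starts, pos, side="right") - 1
        ok = i >= 0
        ii = np.where(ok, i, 0)
        inside = ok & (pos < self.ref_starts[ii] + self.lengths[ii])
        out = np.where(inside, self.ind_starts[ii] + (pos - self.ref_starts[ii]), -1)
        return out, ~inside

    def back_intervals(self, start: int, end: int) -> list[tuple[int, int]]:
        """Reference-frame intervals covered by individualized interval [start, end).

        Inserted stretches (no reference counterpart) are skipped.
        """
        out = []
        i = int(np.searchsorted(self.ind_starts, start, side="right")) - 1
        i = max(i, 0)
        while i < len(self.ind_starts) and self.ind_starts[i] < end:
            b_start = int(self.ind_starts[i])
            b_end = b_start + int(self.lengths[i])
            lo, hi = max(start, b_start), min(end, b_end)
            if lo < hi:
                r0 = int(self.ref_starts[i]) + (lo - b_start)
                out.append((r0, r0 + (hi - lo)))
            i += 1
        return out

    def forward_clamped(self, pos: int, side: str) -> int:
        """Forward lift with positions inside deletions clamped to the nearest
        surviving base: 'left' clamps downstream (next surviving base), 'right'
        clamps upstream (previous surviving base).  Used for annotation liftover."""
        r = self.forward(pos)
        if r is not DELETED:
            return r
        i = int(np.searchsorted(self.ref_starts, pos, side="right")) - 1
        if side == "left":
            j = i + 1
            if j >= len(self.ref_starts):
                return self.ind_len - 1
            return int(self.ind_starts[j])
        j = max(i, 0)
        return int(self.ind_starts[j] + self.lengths[j] - 1)


@dataclass
class CoordinateMap:
    """Bidirectional reference <-> individualized coordinate translation."""

    chroms: dict[str, ChromMap] = field(default_factory=dict)

    def forward(self, chrom: str, pos: int):
        return self._get(chrom).forward(pos)

    def back(self, chrom: str, pos: int):
        return self._get(chrom).back(pos)

    def _get(self, chrom: str) -> ChromMap:
        if chrom not in self.chroms:
            raise KeyError(f"chromosome {chrom!r} absent from coordinate map")
        return self.chroms[chrom]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, cm in self.chroms.items():
            for r, i, ln in zip(cm.ref_starts, cm.ind_starts, cm.lengths):
                rows.append((chrom, int(r), int(i), int(ln), cm.ref_len, cm.ind_len))
        return pd.DataFrame(rows, columns=["chrom", "ref_start", "ind_start",
                                           "length", "ref_len", "ind_len"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoordinateMap":
        chroms = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            blocks = list(zip(sub["ref_start"], sub["ind_start"], sub["length"]))
            blocks.sort()
            ref_len = int(sub["ref_len"].iloc[0])
            ind_len = int(sub["ind_len"].iloc[0])
            deleted, inserted = [], []
            for (r0, i0, l0), (r1, i1, _) in zip(blocks, blocks[1:]):
                if r0 + l0 < r1:
                    deleted.append((r0 + l0, r1))
                if i0 + l0 < i1:
                    inserted.append((i0 + l0, i1))
            if blocks:
                r_last, i_last, l_last = blocks[-1]
                if r_last + l_last < ref_len:
                    deleted.append((r_last + l_last, ref_len))
                if i_last + l_last < ind_len:
                    inserted.append((i_last + l_last, ind_len))
            chroms[chrom] = ChromMap(blocks, inserted, deleted, ref_len, ind_len)
        return cls(chroms)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CoordinateMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class IndividualizedGenome:
    sample_id: str
    sequences: dict[str, str]
    map: CoordinateMap
    n_variants_applied: int


def _is_hom_nonref(gt) -> bool:
    return (gt is not None and len(gt) == 2 and None not in gt
            and gt[0] == gt[1] and gt[0] is not None and gt[0] > 0)


def _is_hom(gt) -> bool:
    return (gt is not None and len(gt) == 2 and None not in gt and gt[0] == gt[1])


def _iter_vcf(vcf: str | Path | pysam.VariantFile):
    if isinstance(vcf, pysam.VariantFile):
        yield from vcf
    else:
        with pysam.VariantFile(str(vcf)) as vf:
            yield from vf


def _vcf_samples(vcf: str | Path | pysam.VariantFile) -> list[str]:
    if isinstance(vcf, pysam.VariantFile):
        return list(vcf.header.samples)
    with pysam.VariantFile(str(vcf)) as vf:
        return list(vf.header.samples)


def select_applicable_variants(vcf, sample: str) -> list[VariantRecord]:
    """Variants to substitute into ``sample``'s individualized genome.

    Keeps sites where the sample is homozygous for a non-reference allele
    (multi-allelic records use the sample's own allele).  Overlapping records
    are resolved first-by-position; in particular a SNP falling inside the
    reference span of a retained indel is removed.  Records at the same
    start are ordered indel-first so the indel wins such ties.
    """
    if sample not in _vcf_samples(vcf):
        raise ValueError(f"sample {sample!r} not present in VCF header")
    candidates: list[VariantRecord] = []
    last: dict[str, int] = {}
    for rec in _iter_vcf(vcf):
        if rec.start < last.get(rec.chrom, -1):
            raise ValueError(f"VCF not sorted at {rec.chrom}:{rec.pos}")
        last[rec.chrom] = rec.start
        gt = rec.samples[sample]["GT"]
        if not _is_hom_nonref(gt):
            continue
        alt = rec.alleles[gt[0]]
        candidates.append(VariantRecord(rec.chrom, rec.start, rec.ref, alt.upper()))
    # resolve overlaps: first by position wins; ties put indels first
    candidates.sort(key=lambda v: (v.chrom, v.start, not v.is_indel))
    kept: list[VariantRecord] = []
    end_by_chrom: dict[str, int] = {}
    for v in candidates:
        prev_end = end_by_chrom.get(v.chrom, -1)
        if v.start < prev_end:
            log.warning("dropping variant %s:%d overlapping a retained variant",
                        v.chrom, v.start + 1)
            continue
        kept.append(v)
        end_by_chrom[v.chrom] = v.ref_span[1]
    kept.sort(key=lambda v: (v.chrom, v.start))
    return kept


def build_individualized_genome(ref: dict[str, str],
                                variants: list[VariantRecord],
                                sample_id: str = "sample") -> IndividualizedGenome:
    """Apply sorted, non-overlapping variants to the reference sequences.

    Raises if a variant's REF allele does not match the reference sequence.
    The returned genome keeps every reference sequence name and carries a
    :class:`CoordinateMap` whose blocks are broken only at indels.
    """
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    sequences: dict[str, str] = {}
    chrom_maps: dict[str, ChromMap] = {}
    n_applied = 0
    for chrom, seq in ref.items():
        parts: list[str] = []
        blocks: list[tuple[int, int, int]] = []
        inserted: list[tuple[int, int]] = []
        deleted: list[tuple[int, int]] = []
        block_ref = block_ind = 0
        out_len = 0
        last_ref = 0
        for v in by_chrom.get(chrom, []):
            s, e = v.ref_span
            if seq[s:e] != v.ref_allele:
                raise ValueError(
                    f"REF mismatch at {chrom}:{s + 1}: VCF says {v.ref_allele!r}, "
                    f"reference has {seq[s:e]!r}")
            parts.append(seq[last_ref:s])
            out_len += s - last_ref
            r, a = len(v.ref_allele), len(v.alt_allele)
            k = min(r, a)          # co-linear (substituted) prefix
            parts.append(v.alt_allele[:k])
            out_len += k
            if a > r:              # insertion of a-r bases after the prefix
                blocks.append((block_ref, block_ind, (s + k) - block_ref))
                inserted.append((out_len, out_len + (a - r)))
                parts.append(v.alt_allele[k:])
                out_len += a - r
                block_ref, block_ind = s + k, out_len
            elif r > a:            # deletion of r-a reference bases
                blocks.append((block_ref, block_ind, (s + k) - block_ref))
                deleted.append((s + k, s + r))
                block_ref, block_ind = s + r, out_len
            last_ref = e
            n_applied += 1
        parts.append(seq[last_ref:])
        out_len += len(seq) - last_ref
        blocks.append((block_ref, block_ind, len(seq) - block_ref))
        sequences[chrom] = "".join(parts)
        chrom_maps[chrom] = ChromMap(blocks, inserted, deleted, len(seq), out_len)
        assert len(sequences[chrom]) == out_len
    return IndividualizedGenome(sample_id, sequences, CoordinateMap(chrom_maps), n_applied)


def lift_annotation(gtf: pd.DataFrame, cmap: CoordinateMap) -> pd.DataFrame:
    """Shift annotation coordinates into the individualized frame.

    Feature identifiers and the attribute column are preserved verbatim.  A
    boundary that falls inside a deleted interval is clamped to the nearest
    surviving base (with a log message), keeping the feature on record.
    """
    starts, ends = [], []
    n_clamped = 0
    for chrom, s, e in zip(gtf["chrom"], gtf["start"], gtf["end"]):
        cm = cmap._get(chrom)
        ls = cm.forward(s)
        if ls is DELETED:
            ls = cm.forward_clamped(s, "left")
            n_clamped += 1
        le = cm.forward(e - 1)
        if le is DELETED:
            le = cm.forward_clamped(e - 1, "right")
            n_clamped += 1
        starts.append(ls)
        ends.append(le + 1)
    if n_clamped:
        log.warning("clamped %d feature boundaries inside deleted intervals", n_clamped)
    out = gtf.copy()
    out["start"] = starts
    out["end"] = ends
    return out


def lift_back(chrom: str, ind_pos: int, cmap: CoordinateMap):
    """Individualized-frame position -> reference position, or INSERTED."""
    return cmap.back(chrom, ind_pos)


class InformativeVariantSet:
    """Sites where sire and dam are homozygous for different alleles.

    Every offspring read covering such a site reveals its parental genome of
    origin.  ``sites`` is a DataFrame with columns chrom, pos (0-based),
    sire_allele, dam_allele, exonic.
    """

    def __init__(self, sites: pd.DataFrame):
        self.sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def snp_sites(self) -> pd.DataFrame:
        """Substitution sites only (both alleles single bases); these are the
        sites usable for per-base read scoring."""
        s = self.sites
        m = (s["sire_allele"].str.len() == 1) & (s["dam_allele"].str.len() == 1)
        return s[m]

    def oriented(self, maternal_parent: str) -> pd.DataFrame:
        """Relabel sire/dam alleles as maternal/paternal for one cross.

        maternal_parent is 'sire' or 'dam'.
        """
        if maternal_parent not in ("sire", "dam"):
            raise ValueError("maternal_parent must be 'sire' or 'dam'")
        s = self.snp_sites
        if maternal_parent == "dam":
            mat, pat = s["dam_allele"], s["sire_allele"]
        else:
            mat, pat = s["sire_allele"], s["dam_allele"]
        return pd.DataFrame({
            "chrom": s["chrom"].to_numpy(),
            "pos": s["pos"].to_numpy(),
            "maternal_allele": mat.to_numpy(),
            "paternal_allele": pat.to_numpy(),
            "exonic": s["exonic"].to_numpy(),
        })

    def write(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "InformativeVariantSet":
        return cls(pd.read_csv(path, sep="\t"))


def _exon_lookup(exons: pd.DataFrame):
    by_chrom = {}
    for chrom, sub in exons.groupby("chrom"):
        ivs = sorted(zip(sub["start"], sub["end"]))
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        by_chrom[chrom] = (starts, ends)
    return by_chrom


def select_informative_variants(vcf, sire: str, dam: str,
                                exons: pd.DataFrame | None = None
                                ) -> InformativeVariantSet:
    """Sites where the two parents are homozygous for different alleles.

    ``exons`` is an optional DataFrame (chrom, start, end); when given, the
    exonic flag marks sites overlapping it.  Sites with a heterozygous or
    missing call in either parent are excluded.
    """
    samples = _vcf_samples(vcf)
    for s in (sire, dam):
        if s not in samples:
            raise ValueError(f"sample {s!r} not present in VCF header")
    lookup = _exon_lookup(exons) if exons is not None else {}
    rows = []
    for rec in _iter_vcf(vcf):
        gs = rec.samples[sire]["GT"]
        gd = rec.samples[dam]["GT"]
        if not (_is_hom(gs) and _is_hom(gd)) or gs[0] == gd[0]:
            continue
        sire_allele = rec.alleles[gs[0]].upper()
        dam_allele = rec.alleles[gd[0]].upper()
        exonic = False
        if rec.chrom in lookup:
            starts, ends = lookup[rec.chrom]
            i = int(np.searchsorted(starts, rec.start, side="right")) - 1
            exonic = i >= 0 and rec.start < ends[i]
        rows.append((rec.chrom, rec.start, sire_allele, dam_allele, exonic))
    return InformativeVariantSet(pd.DataFrame(
        rows, columns=["chrom", "pos", "sire_allele", "dam_allele", "exonic"]))


@dataclass
class ImputedGenotype:
    chrom: str
    start: int
    alleles: tuple[str, ...]
    allele_index: int


def impute_monomorphic_parent(vcf, breed_samples: list[str],
                              target: str) -> list[ImputedGenotype]:
    """Impute an unsequenced parent from breed-monomorphic sites.

    At sites where every genotyped breed member is homozygous for the same
    allele (unanimity, no missing calls), the target is assigned that
    genotype; all other sites are left missing (not emitted).
    """
    if not breed_samples:
        raise ValueError("at least one genotyped breed member is required")
    samples = _vcf_samples(vcf)
    for s in breed_samples:
        if s not in samples:
            raise ValueError(f"breed sample {s!r} not present in VCF header")
    out = []
    for rec in _iter_vcf(vcf):
        gts = [rec.samples[s]["GT"] for s in breed_samples]
        if not all(_is_hom(g) for g in gts):
            continue
        alleles = {g[0] for g in gts}
        if len(alleles) != 1:
            continue
        a = alleles.pop()
        out.append(ImputedGenotype(rec.chrom, rec.start, tuple(rec.alleles), a))
    return out
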