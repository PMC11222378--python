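"""Allelic bisulfite extraction, coordinate conversion, filters."""

import numpy as np
import pandas as pd
import pytest

from allelescope import methylation as meth
from allelescope.genomes import VariantRecord, build_individualized_genome
from allelescope.methylation import CpGAlleleTable


def write_sam(path, reads, chrom_lengths):
    """reads: (qname, flag, chrom, pos0, seq, tags-string)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for c, ln in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{c}\tLN:{ln}\n")
        for qname, flag, chrom, pos, seq, tags in reads:
            t = ("\t" + tags) if tags else ""
            fh.write(f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t60\t{len(seq)}M"
                     f"\t*\t0\t0\t{seq}\t{'I' * len(seq)}{t}\n")
    return path


@pytest.fixture
def flat_setup(tmp_path):
    """Identical parental genomes except an A/G informative site; one CpG."""
    #          0123456789012345
    ref_mat = "ATACGTTTAATTTTTT"   # CpG at 3; informative A at 8
    ref_pat = "ATACGTTTGATTTTTT"   # paternal allele G at 8
    gm = build_individualized_genome({"c": ref_mat}, [], "m")
    gp = build_individualized_genome({"c": ref_pat}, [], "p")
    sites = pd.DataFrame({"chrom": ["c"], "pos": [8],
                          "maternal_allele": ["A"], "paternal_allele": ["G"],
                          "exonic": [True]})
    return tmp_path, gm, gp, sites


class TestExtraction:
    def test_maternal_methylated_read(self, flat_setup):
        tmp, gm, gp, sites = flat_setup
        # top-strand read, maternal allele A, CpG C retained (methylated)
        sam_m = write_sam(tmp / "m.sam",
                          [("r1", 0, "c", 0, "ATACGTTTAATT", "XG:Z:CT")],
                          {"c": 16})
        sam_p = write_sam(tmp / "p.sam", [], {"c": 16})
        out = meth.extract_allelic_methylation(
            sam_m, sam_p, sites, gm.map, gp.map, gm.sequences, gp.sequences)
        row = out.iloc[0]
        assert (row["allele"], row["pos"], row["strand"]) == ("maternal", 3, "+")
        assert (row["m"], row["u"]) == (1, 0)

    def test_converted_read_counts_unmethylated(self, flat_setup):
        tmp, gm, gp, sites = flat_setup
        # CpG C converted to T; paternal allele G at site
        sam_m = write_sam(tmp / "m.sam", [], {"c": 16})
        sam_p = write_sam(tmp / "p.sam",
                          [("r1", 0, "c", 0, "ATATGTTTGATT", "XG:Z:CT")],
                          {"c": 16})
        out = meth.extract_allelic_methylation(
            sam_m, sam_p, sites, gm.map, gp.map, gm.sequences, gp.sequences)
        row = out.iloc[0]
        assert row["allele"] == "paternal"
        assert (row["m"], row["u"]) == (0, 1)

    def test_ct_site_unusable_on_top_strand(self, tmp_path):
        """A read whose only informative site is C/T on its conversion strand
        stays unassigned and contributes nothing."""
        ref = "ATACGTTTCATTTTTT"      # informative site at 8: C (mat) vs T (pat)
        gm = build_individualized_genome({"c": ref}, [], "m")
        gp = build_individualized_genome(
            {"c": ref[:8] + "T" + ref[9:]}, [], "p")
        sites = pd.DataFrame({"chrom": ["c"], "pos": [8],
                              "maternal_allele": ["C"], "paternal_allele": ["T"],
                              "exonic": [True]})
        sam_m = write_sam(tmp_path / "m.sam",
                          [("r1", 0, "c", 0, "ATACGTTTCATT", "XG:Z:CT")],
                          {"c": 16})
        sam_p = write_sam(tmp_path / "p.sam", [], {"c": 16})
        out = meth.extract_allelic_methylation(
            sam_m, sam_p, sites, gm.map, gp.map, gm.sequences, gp.sequences)
        assert len(out) == 0

    def test_bottom_strand_g_calls(self, tmp_path):
        """Bottom-strand reads report the CpG's G; a C/T informative site is
        conversion-safe for them (only G/A pairs are excluded)."""
        ref_mat = "ATACGTTTCATTTTTT"   # CpG at 3; maternal allele C at 8
        ref_pat = "ATACGTTTTATTTTTT"   # paternal allele T
        gm = build_individualized_genome({"c": ref_mat}, [], "m")
        gp = build_individualized_genome({"c": ref_pat}, [], "p")
        sites = pd.DataFrame({"chrom": ["c"], "pos": [8],
                              "maternal_allele": ["C"], "paternal_allele": ["T"],
                              "exonic": [True]})
        sam_m = write_sam(tmp_path / "m.sam",
                          [("r1", 0, "c", 0, "ATACGTTTCATT", "XG:Z:GA")],
                          {"c": 16})
        sam_p = write_sam(tmp_path / "p.sam", [], {"c": 16})
        out = meth.extract_allelic_methylation(
            sam_m, sam_p, sites, gm.map, gp.map, gm.sequences, gp.sequences)
        row = out.iloc[0]
        assert row["allele"] == "maternal"
        assert (row["pos"], row["strand"], row["m"], row["u"]) == (4, "-", 1, 0)

    def test_non_cpg_cytosine_absent(self, flat_setup):
        tmp, gm, gp, sites = flat_setup
        # the read contains C at pos 2 (CHH context): must not be reported
        sam_m = write_sam(tmp / "m.sam",
                          [("r1", 0, "c", 0, "ATACGTTTAATT", "XG:Z:CT")],
                          {"c": 16})
        sam_p = write_sam(tmp / "p.sam", [], {"c": 16})
        out = meth.extract_allelic_methylation(
            sam_m, sam_p, sites, gm.map, gp.map, gm.sequences, gp.sequences)
        assert set(out["pos"]) == {3}


class TestCoordinateConversion:
    def test_no_indels_positions_unchanged(self):
        gm = build_individualized_genome({"c": "ACGT" * 10}, [], "m")
        table = pd.DataFrame([("maternal", "c", 5, "+", "maternal", 3, 1)],
                             columns=["genome", "chrom", "pos", "strand",
                                      "allele", "m", "u"])
        out = meth.convert_cpg_coordinates(table, gm.map, gm.map)
        assert out.iloc[0]["pos"] == 5

    def test_insertion_site_dropped_and_merge_preserves_totals(self):
        ref = {"c": "AACGAACGAA"}
        gm = build_individualized_genome(
            ref, [VariantRecord("c", 4, "A", "ACG")], "m")
        gp = build_individualized_genome(ref, [], "p")
        # maternal frame: CpG inside the insertion at ind pos 5; CpG at 2 maps back
        table = pd.DataFrame([
            ("maternal", "c", 5, "+", "maternal", 4, 1),   # inserted -> dropped
            ("maternal", "c", 2, "+", "maternal", 3, 2),
            ("paternal", "c", 2, "+", "paternal", 1, 5),
        ], columns=["genome", "chrom", "pos", "strand", "allele", "m", "u"])
        out = meth.convert_cpg_coordinates(table, gm.map, gp.map)
        assert len(out) == 2
        assert out["m"].sum() + out["u"].sum() == 3 + 2 + 1 + 5

    def test_deletion_shifts_back(self):
        ref = {"c": "AAAATTTCGAA"}
        gm = build_individualized_genome(
            ref, [VariantRecord("c", 0, "AAAA", "A")], "m")
        # maternal CpG at ind pos 4 -> reference pos 7
        table = pd.DataFrame([("maternal", "c", 4, "+", "maternal", 1, 0)],
                             columns=["genome", "chrom", "pos", "strand",
                                      "allele", "m", "u"])
        out = meth.convert_cpg_coordinates(table, gm.map, gm.map)
        assert out.iloc[0]["pos"] == 7


def make_table(cov: dict):
    """cov: {(chrom,pos,strand): {obs_name: (m,u)}} -> CpGAlleleTable."""
    idx = pd.MultiIndex.from_tuples(cov.keys(), names=["chrom", "pos", "strand"])
    obs = sorted({o for d in cov.values() for o in d})
    m = pd.DataFrame(0, index=idx, columns=obs)
    u = pd.DataFrame(0, index=idx, columns=obs)
    for key, d in cov.items():
        for o, (mm, uu) in d.items():
            m.loc[key, o] = mm
            u.loc[key, o] = uu
    return CpGAlleleTable(m, u)


class TestFilters:
    def test_bulk_rule(self):
        samples = [f"s{i}" for i in range(12)]
        good = {f"{s}.maternal": (6, 0) for s in samples[:10]}
        good.update({f"{s}.paternal": (5, 0) for s in samples[:10]})
        bad = {f"{s}.maternal": (6, 5) for s in samples[:9]}
        table = make_table({("c", 10, "+"): good, ("c", 50, "+"): bad})
        out = meth.filter_cpgs_bulk(table, samples, min_cov=10, min_samples=10)
        assert list(out.m.index.get_level_values("pos")) == [10]

    def test_bulk_snp_removal(self):
        samples = ["s0"]
        cov = {f"s0.maternal": (20, 0)}
        table = make_table({("c", 10, "+"): cov, ("c", 50, "+"): cov})
        out = meth.filter_cpgs_bulk(table, samples, min_cov=1, min_samples=1,
                                    snp_positions={("c", 50)})
        assert list(out.m.index.get_level_values("pos")) == [10]

    def _allelic_table(self, low_maternal_dxl=0):
        meta = pd.DataFrame({
            "sample_id": [f"{d}{i}" for d in ("DxL", "LxD") for i in range(6)],
            "cross_direction": ["DxL"] * 6 + ["LxD"] * 6})
        cov = {}
        d = {}
        for i, s in enumerate(meta["sample_id"]):
            mcov = 2 if (s.startswith("DxL") and i < low_maternal_dxl) else 8
            d[f"{s}.maternal"] = (mcov, 0)
            d[f"{s}.paternal"] = (8, 0)
        cov[("c", 10, "+")] = d
        return make_table(cov), meta

    def test_allelic_rule_passes_at_4_of_6(self):
        table, meta = self._allelic_table(low_maternal_dxl=2)
        out = meth.filter_cpgs_allelic(table, meta, min_cov=5, max_low=2)
        assert len(out.m) == 1

    def test_allelic_rule_fails_at_3_of_6(self):
        table, meta = self._allelic_table(low_maternal_dxl=3)
        out = meth.filter_cpgs_allelic(table, meta, min_cov=5, max_low=2)
        assert len(out.m) == 0

    def test_all_zero_dropped(self):
        meta = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "cross_direction": ["DxL"] * 6})
        table = make_table({("c", 10, "+"):
                            {f"s{i}.maternal": (0, 0) for i in range(6)}})
        out = meth.filter_cpgs_allelic(table, meta)
        assert len(out.m) == 0

    def test_brute_force_recheck(self):
        """Filter equals an exhaustive per-site re-check on random tables."""
        rng = np.random.default_rng(0)
        meta = pd.DataFrame({
            "sample_id": [f"{d}{i}" for d in ("DxL", "LxD") for i in range(6)],
            "cross_direction": ["DxL"] * 6 + ["LxD"] * 6})
        cov = {}
        for p in range(40):
            d = {}
            for s in meta["sample_id"]:
                for a in ("maternal", "paternal"):
                    d[f"{s}.{a}"] = (int(rng.integers(0, 8)),
                                     int(rng.integers(0, 8)))
            cov[("c", p * 10, "+")] = d
        table = make_table(cov)
        out = meth.filter_cpgs_allelic(table, meta, min_cov=5, max_low=2)
        kept = set(out.m.index)
        for key in table.m.index:
            expect = True
            for direction in ("DxL", "LxD"):
                ids = [s for s in meta["sample_id"] if s.startswith(direction)]
                for a in ("maternal", "paternal"):
                    n_low = sum(
                        table.m.loc[key, f"{s}.{a}"]
                        + table.u.loc[key, f"{s}.{a}"] < 5 for s in ids)
                    if n_low > 2:
                        expect = False
            assert (key in kept) == expect


class TestLevelsAndBins:
    def test_feature_methylation(self):
        cpgs = pd.DataFrame({"chrom": ["c"] * 2, "pos": [10, 20],
                             "m": [8, 6], "u": [2, 4]})
        feats = pd.DataFrame({"feature_id": ["f1", "f2"], "chrom": ["c", "c"],
                              "start": [0, 100], "end": [50, 200]})
        out = meth.feature_methylation(cpgs, feats)
        assert out["f1"] == pytest.approx(0.7)
        assert np.isnan(out["f2"])

    def test_zero_methylation(self):
        cpgs = pd.DataFrame({"chrom": ["c"], "pos": [10], "m": [0], "u": [10]})
        feats = pd.DataFrame({"feature_id": ["f"], "chrom": ["c"],
                              "start": [0], "end": [50]})
        assert meth.feature_methylation(cpgs, feats)["f"] == 0.0

    def test_bins_partition_and_boundaries(self):
        out = meth.methylation_bins([1.0] * 5)
        assert out[">95%"] == 1.0
        out = meth.methylation_bins([0.04])
        assert out["<5%"] == 1.0
        rng = np.random.default_rng(1)
        x = rng.random(1000)
        out = meth.methylation_bins(x)
        assert out.sum() == pytest.approx(1.0)
        assert out["<5%"] == pytest.approx((x < 0.05).mean())

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            meth.methylation_bins([])

    def test_spearman(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        rho, _ = meth.correlate_methylation(x, -x)
        assert rho == pytest.approx(-1.0)
        rho, _ = meth.correlate_methylation(x, x)
        assert rho == pytest.approx(1.0)
        rho, _ = meth.correlate_methylation(x, pd.Series([1.0] * 4,
                                                         index=list("abcd")))
        assert np.isnan(rho)
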