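"""VCF ingestion, polarity, QC filters and per-population allele frequencies."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from parasweep.datatypes import PopulationMap
from parasweep.vcf_qc import (
    QcThresholds,
    apply_site_filters,
    genotype_dosage,
    pop_allele_freqs,
    read_phased_vcf,
)

from .conftest import make_block

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
    ##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##contig=<ID=chr1,length=100000>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1
    """
)


def write_vcf(tmp_path, records, popmap_lines=("S0\tA", "S1\tB")):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
    pm = tmp_path / "pm.tsv"
    pm.write_text("".join(l + "\n" for l in popmap_lines))
    return vcf, pm


class TestReadPhasedVcf:
    def test_triallelic_record_skipped(self, tmp_path):
        vcf, pm = write_vcf(
            tmp_path,
            [
                "chr1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|1",
                "chr1\t200\t.\tC\tG,T\t.\tPASS\t.\tGT\t0|1\t0|2",
                "chr1\t300\t.\tT\tC\t.\tPASS\tAA=T\tGT\t0|0\t0|1",
            ],
        )
        haps, sites, popmap = read_phased_vcf(vcf, pm)
        assert len(sites) == 2
        assert list(sites["pos"]) == [100, 300]

    def test_aa_alt_flips_derived_coding(self, tmp_path):
        vcf, pm = write_vcf(
            tmp_path, ["chr1\t100\t.\tA\tG\t.\tPASS\tAA=G\tGT\t0|1\t1|1"]
        )
        haps, sites, _ = read_phased_vcf(vcf, pm)
        # alt-allele frequency is 3/4; derived (=REF here) frequency 1/4
        np.testing.assert_array_equal(haps["chr1"].alleles[:, 0], [1, 0, 0, 0])
        assert sites["ancestral_allele"].iloc[0] == "G"
        assert bool(sites["aa_known"].iloc[0])

    def test_missing_aa_falls_back_to_alt_derived(self, tmp_path):
        vcf, pm = write_vcf(
            tmp_path, ["chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1"]
        )
        haps, sites, _ = read_phased_vcf(vcf, pm)
        np.testing.assert_array_equal(haps["chr1"].alleles[:, 0], [0, 1, 1, 1])
        assert not bool(sites["aa_known"].iloc[0])

    def test_unphased_genotype_is_hard_error(self, tmp_path):
        vcf, pm = write_vcf(
            tmp_path, ["chr1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0/1\t1|1"]
        )
        with pytest.raises(ValueError, match="chr1:100"):
            read_phased_vcf(vcf, pm)

    def test_sample_missing_from_popmap_is_hard_error(self, tmp_path):
        vcf, pm = write_vcf(
            tmp_path,
            ["chr1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|1"],
            popmap_lines=("S0\tA", "S9\tB"),
        )
        with pytest.raises(ValueError, match="S1"):
            read_phased_vcf(vcf, pm)

    def test_depth_and_mq_captured(self, tmp_path):
        vcf, pm = write_vcf(
            tmp_path,
            ["chr1\t100\t.\tA\tG\t.\tPASS\tAA=A;MQ=42.5\tGT:DP\t0|1:10\t1|1:20"],
        )
        _, sites, _ = read_phased_vcf(vcf, pm)
        assert sites["mean_depth"].iloc[0] == pytest.approx(15.0)
        assert sites["rms_mapping_quality"].iloc[0] == pytest.approx(42.5)

    def test_missing_genotypes_tracked(self, tmp_path):
        vcf, pm = write_vcf(
            tmp_path, ["chr1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t.|.\t1|1"]
        )
        haps, sites, _ = read_phased_vcf(vcf, pm)
        np.testing.assert_array_equal(haps["chr1"].alleles[:, 0], [-1, -1, 1, 1])
        assert sites["missing_ratio"].iloc[0] == pytest.approx(0.5)


def _sites(pos, depth=30.0, mq=50.0, missing=0.0, chrom="chr1"):
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "ancestral_allele": "A",
            "mean_depth": np.broadcast_to(depth, n).astype(float),
            "rms_mapping_quality": np.broadcast_to(mq, n).astype(float),
            "missing_ratio": np.broadcast_to(missing, n).astype(float),
            "aa_known": True,
            "functional_class": "",
            "gene_symbol": "",
        }
    )


def _haps_for(sites):
    n = len(sites)
    return {"chr1": make_block(np.zeros((4, n), dtype=np.int8), sites["pos"].to_numpy())}


class TestSiteFilters:
    def test_missing_ratio_boundary(self):
        # 8 of 78 missing = 0.1026 >= 0.10 -> removed; 7/78 kept
        sites = _sites([100, 200], missing=[8 / 78, 7 / 78])
        out, _, report = apply_site_filters(sites, _haps_for(sites))
        assert list(out["pos"]) == [200]
        assert report.removed["missing"] == 1

    def test_spacing_removes_both_members(self):
        sites = _sites([100, 103, 200])
        out, haps, report = apply_site_filters(sites, _haps_for(sites))
        assert list(out["pos"]) == [200]
        assert report.removed["spacing"] == 2
        assert haps["chr1"].n_sites == 1

    def test_spacing_enumeration_100_104_200(self):
        sites = _sites([100, 104, 200])
        out, _, _ = apply_site_filters(sites, _haps_for(sites))
        assert list(out["pos"]) == [200]

    def test_depth_and_mq_thresholds(self):
        sites = _sites([100, 200, 300], depth=[4.9, 5.0, 30.0], mq=[50.0, 19.9, 50.0])
        out, _, report = apply_site_filters(sites, _haps_for(sites))
        assert list(out["pos"]) == [300]
        assert report.removed == {"depth": 1, "mq": 1, "missing": 0, "spacing": 0}

    def test_null_column_disables_filter(self):
        sites = _sites([100, 200], depth=np.nan)
        out, _, report = apply_site_filters(sites, _haps_for(sites))
        assert len(out) == 2
        assert report.removed["depth"] == 0

    def test_idempotent(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 10_000), 200, replace=False))
        sites = _sites(pos, depth=rng.uniform(3, 40, 200), missing=rng.uniform(0, 0.2, 200))
        once_s, once_h, _ = apply_site_filters(sites, _haps_for(sites))
        twice_s, twice_h, rep2 = apply_site_filters(once_s, once_h)
        pd.testing.assert_frame_equal(once_s.reset_index(drop=True), twice_s)
        assert sum(rep2.removed.values()) == 0


class TestAlleleFreqs:
    def test_all_homozygous_derived(self):
        block = make_block(np.ones((12, 1), dtype=np.int8))
        pm = PopulationMap({f"S{i}": "A" if i < 5 else "B" for i in range(6)})
        sites = _sites([1000])
        out = pop_allele_freqs({"chr1": block}, pm, sites)
        assert out["af_A"].iloc[0] == 1.0

    def test_seven_of_ten(self):
        # pop A: 5 diploids carrying 7 derived of 10 haplotypes
        col = np.array([1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=np.int8).reshape(-1, 1)
        block = make_block(col)
        pm = PopulationMap({f"S{i}": "A" if i < 5 else "B" for i in range(6)})
        out = pop_allele_freqs({"chr1": block}, pm, _sites([1000]))
        assert out["af_A"].iloc[0] == pytest.approx(0.7)

    def test_matches_brute_force_recount(self, rng):
        alleles = rng.integers(0, 2, (20, 50)).astype(np.int8)
        alleles[rng.random(alleles.shape) < 0.1] = -1
        block = make_block(alleles, np.arange(1, 51) * 100)
        pops = {f"S{i}": ("A" if i < 4 else "B" if i < 7 else "C") for i in range(10)}
        pm = PopulationMap(pops)
        out = pop_allele_freqs({"chr1": block}, pm, _sites(np.arange(1, 51) * 100))
        for pop in ("A", "B", "C"):
            rows = block.haplotype_rows(pm.samples(pop))
            for j in range(50):
                col = [int(alleles[r, j]) for r in rows if alleles[r, j] >= 0]
                expect = sum(col) / len(col) if col else np.nan
                got = out[f"af_{pop}"].iloc[j]
                if np.isnan(expect):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect)

    def test_fully_missing_population_null(self):
        alleles = np.array([[1, 1], [1, 1], [-1, 0], [-1, 1]], dtype=np.int8)
        block = make_block(alleles)
        pm = PopulationMap({"S0": "A", "S1": "B"})
        out = pop_allele_freqs({"chr1": block}, pm, _sites([1000, 2000]))
        assert np.isnan(out["af_B"].iloc[0])
        assert out["af_B"].iloc[1] == pytest.approx(0.5)


def test_genotype_dosage_missing_propagates():
    alleles = np.array([[1, 0], [1, -1], [0, 1], [0, 1]], dtype=np.int8)
    block = make_block(alleles)
    dos = genotype_dosage(block, ["S0", "S1"])
    np.testing.assert_array_equal(dos, [[2, -1], [0, 2]])
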