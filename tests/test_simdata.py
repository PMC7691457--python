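"""Simulator: determinism, frequency spectrum, drift, LD, sweep planting,
and export round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parasweep.fst import wc_site_components
from parasweep.ihs import ehh_curve
from parasweep.simdata import (
    SimConfig,
    SweepSpec,
    make_qtl_table,
    plant_sweep,
    simulate_bundle,
    simulate_haplotypes,
    snap_core,
    truth_set,
)
from parasweep.vcf_qc import genotype_dosage, read_phased_vcf


def small_config(seed=0, length=1_000_000, **kw):
    return SimConfig(chrom_lengths={"chr1": length}, seed=seed, **kw)


class TestSimulateHaplotypes:
    def test_deterministic_given_seed(self):
        h1, s1, _ = simulate_haplotypes(small_config(seed=5))
        h2, s2, _ = simulate_haplotypes(small_config(seed=5))
        np.testing.assert_array_equal(h1["chr1"].alleles, h2["chr1"].alleles)
        pd.testing.assert_frame_equal(s1, s2)
        h3, _, _ = simulate_haplotypes(small_config(seed=6))
        assert not np.array_equal(h1["chr1"].alleles, h3["chr1"].alleles)

    def test_positions_sorted_unique_spaced(self):
        haps, _, _ = simulate_haplotypes(small_config())
        pos = haps["chr1"].positions
        assert np.all(np.diff(pos) >= 5)

    def test_infinite_drift_gives_no_differentiation(self):
        cfg = SimConfig(
            chrom_lengths={"chr1": 3_000_000},
            drift={"DLW": np.inf, "DU": np.inf, "EWB": np.inf},
            seed=3,
        )
        haps, _, popmap = simulate_haplotypes(cfg)
        block = haps["chr1"]
        assert block.n_sites >= 5000
        ga = genotype_dosage(block, popmap.samples("DLW"))
        gb = genotype_dosage(block, popmap.samples("EWB"))
        theta = wc_site_components(ga, gb).theta
        assert abs(np.nanmean(theta)) < 0.01

    def test_finite_drift_gives_differentiation(self):
        haps, _, popmap = simulate_haplotypes(small_config(seed=2))
        block = haps["chr1"]
        ga = genotype_dosage(block, popmap.samples("DLW"))
        gb = genotype_dosage(block, popmap.samples("EWB"))
        theta = wc_site_components(ga, gb).theta
        assert np.nanmean(theta) > 0.02

    def test_sfs_follows_one_over_k(self):
        cfg = SimConfig(chrom_lengths={"chr1": 1_000_000}, n_founders=20, seed=1)
        haps, _, _ = simulate_haplotypes(cfg)
        block = haps["chr1"]
        assert block.n_sites >= 1500
        # founder-level spectrum is 1/k; sample frequencies inherit its shape
        freqs = block.alleles.mean(axis=0)
        counts, _ = np.histogram(freqs, bins=np.linspace(0, 1, 11))
        k = np.arange(1, 11)
        rho = stats.spearmanr(counts, 1 / k).statistic
        assert rho > 0.9

    def test_ld_decays_with_distance(self):
        haps, _, popmap = simulate_haplotypes(small_config(seed=4, length=2_000_000))
        block = haps["chr1"]
        rows = block.haplotype_rows(popmap.samples("EWB"))
        sub = block.alleles[rows].astype(float)
        pos = block.positions
        rng = np.random.default_rng(0)
        bins = [(0, 10_000), (10_000, 50_000), (50_000, 200_000)]
        means = []
        for lo, hi in bins:
            r2s = []
            while len(r2s) < 300:
                i = int(rng.integers(0, block.n_sites))
                js = np.flatnonzero((pos > pos[i] + lo) & (pos <= pos[i] + hi))
                if len(js) == 0:
                    continue
                j = int(rng.choice(js))
                a, b = sub[:, i], sub[:, j]
                if a.std() == 0 or b.std() == 0:
                    continue
                r2s.append(np.corrcoef(a, b)[0, 1] ** 2)
            means.append(np.mean(r2s))
        assert means[0] >= means[1] >= means[2]

    def test_zero_sites_raises(self):
        cfg = SimConfig(chrom_lengths={"chr1": 100}, snp_density=1e-9)
        with pytest.raises(ValueError, match="snp_density"):
            simulate_haplotypes(cfg)


class TestPlantSweep:
    def _planted(self, seed=0, final_freq=0.95, pops=("DLW", "DU")):
        haps, sites, popmap = simulate_haplotypes(small_config(seed=seed))
        spec = snap_core(haps, SweepSpec("chr1", 500_000, pops, final_freq=final_freq))
        out_haps, out_sites = plant_sweep(haps, sites, spec, seed=99, popmap=popmap)
        return haps, out_haps, out_sites, spec, popmap

    def test_full_fixation_identical_haplotypes_and_ehh_one(self):
        _, haps, _, spec, popmap = self._planted(final_freq=1.0, pops=("DLW",))
        block = haps["chr1"]
        core = int(np.flatnonzero(block.positions == spec.core_pos)[0])
        rows = block.haplotype_rows(popmap.samples("DLW"))
        # all carriers; EHH of the derived class stays 1 until arms diverge
        c = ehh_curve(block.alleles[rows], block.positions, core, 1)
        assert c.left[0, 1] == 1.0
        assert np.all(block.alleles[rows, core] == 1)

    def test_core_frequencies(self):
        before, haps, sites, spec, popmap = self._planted(final_freq=0.95)
        row = sites[(sites["chrom"] == "chr1") & (sites["pos"] == spec.core_pos)].iloc[0]
        n_dlw = 2 * 28
        assert row["af_DLW"] == pytest.approx(0.95, abs=1 / n_dlw)
        assert row["af_DU"] == pytest.approx(0.95, abs=1 / (2 * 27))
        # EWB untouched: allele matrix identical
        ewb = before["chr1"].haplotype_rows(popmap.samples("EWB"))
        np.testing.assert_array_equal(
            before["chr1"].alleles[ewb], haps["chr1"].alleles[ewb]
        )

    def test_unknown_core_raises_with_nearest(self):
        haps, sites, popmap = simulate_haplotypes(small_config())
        with pytest.raises(ValueError, match="nearest"):
            plant_sweep(haps, sites, SweepSpec("chr1", 500_001, ("DLW",)), 0, popmap)

    def test_planting_raises_local_fst_sign_test(self):
        """Paired over 10 seeds: mean per-site Fst(DLW vs EWB) within 50 kb
        of the core is higher with the sweep planted than without."""
        wins = 0
        for seed in range(10):
            haps, sites, popmap = simulate_haplotypes(small_config(seed=seed))
            spec = snap_core(haps, SweepSpec("chr1", 500_000, ("DLW",)))
            planted, _ = plant_sweep(haps, sites, spec, seed=seed + 100, popmap=popmap)

            def local_mean_theta(h):
                block = h["chr1"]
                m = np.abs(block.positions - spec.core_pos) <= 50_000
                ga = genotype_dosage(block, popmap.samples("DLW"))[:, m]
                gb = genotype_dosage(block, popmap.samples("EWB"))[:, m]
                return np.nanmean(wc_site_components(ga, gb).theta)

            if local_mean_theta(planted) > local_mean_theta(haps):
                wins += 1
        assert wins >= 9  # sign test, p < 0.05 under the null


class TestExportBundle:
    def test_round_trip_allele_matrix(self, sim_bundle):
        paths = sim_bundle["paths"]
        haps, sites, popmap = read_phased_vcf(paths["vcf"], paths["popmap"])
        exported = pd.read_csv(paths["sites"], sep="\t")
        for chrom in ("chr1", "chr2"):
            got = haps[chrom].alleles
            assert got.shape[0] == 2 * 78
            assert np.all(got >= 0)
        # AFs recomputed from the VCF agree with the simulator's
        from parasweep.vcf_qc import pop_allele_freqs

        recomputed = pop_allele_freqs(haps, popmap, sites)
        for pop in ("DLW", "DU", "EWB"):
            np.testing.assert_allclose(
                recomputed[f"af_{pop}"], exported[f"af_{pop}"], atol=1e-9
            )

    def test_vcf_grammar(self, sim_bundle):
        lines = open(sim_bundle["paths"]["vcf"]).read().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        header = [l for l in lines if l.startswith("#CHROM")]
        assert len(header) == 1 and header[0].split("\t")[:9] == [
            "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
        ]
        body = [l.split("\t") for l in lines if not l.startswith("#")]
        by_chrom = {}
        for f in body:
            by_chrom.setdefault(f[0], []).append(int(f[1]))
            assert "AA=" in f[7]
        for poss in by_chrom.values():
            assert poss == sorted(poss)

    def test_truth_bed_categories(self, tmp_path):
        cfg = small_config(seed=1)
        sweeps = [SweepSpec("chr1", 300_000, ("DU",)),
                  SweepSpec("chr1", 700_000, ("DLW", "DU"))]
        ts = truth_set(sweeps, cfg.chrom_lengths)
        assert [t[3] for t in ts] == ["DU.sp", "PS"]
        paths = simulate_bundle(cfg, sweeps, tmp_path / "b")
        cats = [l.split("\t")[3].strip() for l in open(paths["truth"])]
        assert cats == ["DU.sp", "PS"]

    def test_export_deterministic(self, tmp_path):
        cfg = small_config(seed=7)
        sweeps = [SweepSpec("chr1", 500_000, ("DLW",))]
        p1 = simulate_bundle(cfg, sweeps, tmp_path / "a")
        p2 = simulate_bundle(cfg, sweeps, tmp_path / "b")
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_qtl_table_exercises_rules(self, rng):
        cfg = small_config(length=3_000_000)
        q = make_qtl_table(cfg, [SweepSpec("chr1", 500_000, ("DLW",))], rng)
        assert q["start"].isna().any()  # uncertain locations present
        lengths = (q["end"] - q["start"] + 1).dropna()
        assert (lengths > 1_000_000).any()  # over-length QTLs present
        assert set(q["qtl_class"].dropna()) <= {
            "Meat_and_Carcass", "Health", "Exterior", "Production", "Reproduction"
        }
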