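# parasweep

Detection of **parallel** and **population-specific selective sweeps**
from a phased multi-population VCF, with a built-in three-population
sweep simulator.

## The problem

When two commercial livestock breeds are bred independently toward the
same goal, the same genomic regions can come under selection in both — a
pattern called parallel selection. Distinguishing regions selected in
*both* domestic populations from regions selected in only *one* requires
combining allele-frequency differentiation against a wild reference with
haplotype-length evidence within each population, then intersecting and
subtracting the resulting candidate-region sets.

`parasweep` implements that scan for two domestic populations (default
names DLW, DU — e.g. two pig breeds) and a wild reference (EWB, e.g.
European wild boar):

1. **Site QC** — mean depth ≥ 5, RMS mapping quality ≥ 20, adjacent-SNP
   spacing ≥ 5 bp, sample missing ratio < 10%.
2. **Fst** — per-site Weir–Cockerham variance components (a, b, c) for
   the three population pairs; windowed ratio-of-sums Σa / Σ(a+b+c).
3. **iHS** — EHH curves per core allele, iHH by trapezoidal integration,
   raw iHS = ln(iHH_A/iHH_D), standardized within 100 derived-frequency
   bins; windows score mean |iHS|.
4. **Outlier windows** — 50-kb windows, 25-kb step, < 10 SNPs discarded;
   genome-wide empirical p-values; top 1% flagged; flagged windows
   extended 200 kb per side and merged.
5. **Classification** by interval algebra over the six tracks
   (F = windowed Fst regions, H = windowed |iHS| regions):
   * artificial (per breed): (F_breed,ref ∪ H_breed) − H_ref
   * parallel PS: ((F_D1,ref ∩ F_D2,ref) ∪ ((H_D1 ∩ H_D2) − H_ref)) − F_D1,D2
   * breed-specific: ((F_D1,ref ∩ F_D1,D2) ∪ ((H_D1 − H_D2) − H_ref)) − F_D2,ref
6. **Annotation** — gene overlap, QTL-consistency filtering (QTLs > 1 Mb
   dropped; ≥ 2 QTLs with the same trait retain a region), and a ΔAF
   scan over nonsynonymous variants (PS: (AF_D1+AF_D2)/2 − AF_ref;
   |ΔAF| ≥ 0.8 passes).

The simulator (`parasweep.simdata`) generates phased three-population
cohorts with realistic LD (founder-mosaic haplotypes), tunable drift, and
plantable hard sweeps — parallel or breed-specific — plus every companion
file (VCF, population map, gene table, QTL table, truth BED), so the
whole pipeline can be exercised and validated without external data.

See `docs/methods.md` for the model, defaults and their rationale.

## Worked example

```bash
cat > sim.yaml <<EOF
sim:
  chrom_lengths: {chr1: 10000000, chr2: 10000000}
  seed: 1
sweeps:
  - {chrom: chr1, core_pos: 3000000, selected_pops: [DLW, DU]}
  - {chrom: chr1, core_pos: 7000000, selected_pops: [DLW]}
  - {chrom: chr2, core_pos: 5000000, selected_pops: [DU]}
EOF
parasweep simulate --config sim.yaml --outdir data

cat > run.yaml <<EOF
vcf: data/cohort.vcf
popmap: data/popmap.tsv
genes: data/genes.tsv
qtls: data/qtls.tsv
chrom_lengths: {chr1: 10000000, chr2: 10000000}
outdir: out
EOF
parasweep run --config run.yaml --seed 1
```

prints

```
PS regions: 1 (325000 bp)
DLW.sp regions: 2 (675000 bp)
DU.sp regions: 2 (1000000 bp)
```

meaning: one parallel-selection region (it contains the planted shared
sweep at chr1:3 Mb), and the breed-specific sets each recover their
planted sweep (chr1:7 Mb for DLW, chr2:5 Mb for DU) plus small residual
intervals at region boundaries. `out/` holds per-track window TSVs with
empirical p-values and outlier flags, one BED per category
(`PS.bed`, `DLW.sp.bed`, `DU.sp.bed`, `artificial_*.bed`), gene / QTL /
ΔAF tables per category, a provenance TSV naming the operand tracks
behind every region, and `manifest.json` (config hash, seed, row counts).

Each stage is also runnable standalone (`parasweep qc|fst|ihs|windows|
classify|annotate --config run.yaml`), and the whole library is usable
directly (`parasweep.pipeline.run_pipeline`, `parasweep.fst`,
`parasweep.ihs`, `parasweep.regions`, ...).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates the default cohort (2 × 10 Mb; 28/27/23 diploids; one parallel
and two breed-specific sweeps), runs the complete pipeline at default
thresholds, prints the classified-region summary, and writes the JSON
report to `--out`.
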