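# Methods

`parasweep` detects selective sweeps shared by, or specific to, two
domestic populations relative to a wild reference, from a phased
multi-population VCF. This note documents the statistical procedure, the
simulator behind the test suite, and the numerical choices made where the
design was genuinely open.

## The scan

**Inputs.** One phased VCF (biallelic SNPs; `GT` like `0|1`), a
sample→population map with two "domestic" populations (default names DLW,
DU) and one "reference" (EWB), optionally a gene table, a QTL table, and
per-site functional annotation.

**Site QC.** Sites are kept when mean depth ≥ 5, RMS mapping quality
≥ 20, sample missing ratio < 10%, and the distance to any adjacent
surviving SNP is ≥ 5 bp. Filters apply in that order, spacing last; the
spacing rule removes *both* members of a close pair, which makes it
symmetric, order-independent and idempotent. A filter whose source field
is absent from the VCF (e.g. no `DP`) is disabled with a warning rather
than silently passing everything.

**Polarity.** iHS is undefined without an ancestral allele. The INFO `AA`
tag is used when present; otherwise the alternate allele is taken as
derived and the site is flagged (`aa_known = False`) so downstream
consumers know polarity is approximate.

**Fst.** Per-site Weir–Cockerham (1984) variance components — among
population *a*, among individual within population *b*, within individual
*c* — are computed for each of the three pairs (each domestic vs the
reference, and domestic vs domestic). Missing genotypes are excluded from
a site's counts; a site where either population is entirely missing is
skipped; sites monomorphic in the pooled pair contribute zeros. Windows
score the ratio of sums Σa / Σ(a+b+c) — the "weighted" convention of
VCFtools — and negative per-site components are retained unclamped, since
clamping would bias window values upward.

**iHS.** For every site with derived frequency in [0.05, 0.95], EHH is
computed for the ancestral and derived carrier classes in both
directions: haplotypes are partitioned by their exact core-to-site allele
string and EHH = Σ_h C(n_h,2) / C(n,2). The walk stops when EHH < 0.05,
when the gap to the next site exceeds 200 kb, or at the chromosome end
(the last two mark the site as truncated; truncated sites are dropped by
default — both behaviours are configurable). iHH is the trapezoidal
integral of EHH against physical distance summed over directions; the raw
score is ln(iHH_A / iHH_D), standardized within 100 equal-width
derived-frequency bins. Bins with fewer than 20 sites are merged with
their nearest (smaller-count, tie → left) neighbour so the operation
stays total at toy scale. Standardization uses the population (ddof = 0)
standard deviation, which makes the two-score {−1, +1} identity exact.
Missing alleles break homozygosity (treated as a distinct allele), a
conservative choice that can only shorten haplotype homozygosity.

**Windows and outliers.** Sliding 50-kb windows stepped every 25 kb,
anchored at position 1 per chromosome, terminal window truncated. Windows
with fewer than 10 contributing SNPs are invalid. Valid windows are
ranked genome-wide per track; empirical p = rank/N, and the top
ceil(0.01·N) windows are outliers, with ties broken by (score desc,
chrom, start) so the count is deterministic. Outlier windows are extended
by 200 kb per side (clipped to the chromosome), then merged — including
book-ended intervals, matching bedtools merge.

**Classification.** With domestic breeds D1, D2 and reference R, and the
six candidate-region tracks (three Fst pairs, three |iHS| populations):

* artificial selection in D1: (FST_D1R ∪ IHS_D1) − IHS_R
* parallel (PS): ((FST_D1R ∩ FST_D2R) ∪ ((IHS_D1 ∩ IHS_D2) − IHS_R)) − FST_D1D2
* D1-specific: ((FST_D1R ∩ FST_D1D2) ∪ ((IHS_D1 − IHS_D2) − IHS_R)) − FST_D2R

Chains evaluate left-to-right, the `− IHS_R` binds to the iHS branch
only, and the trailing Fst subtraction applies to the whole union.
Subtraction is coordinate-level (regions are split, not dropped). By
construction PS is disjoint from FST_D1D2 and each specific set is
disjoint from the other breed's reference contrast; both invariants are
asserted at run time.

**Annotation.** Genes overlap a region by ≥ 1 bp (1-based inclusive
touch counts). QTLs with missing coordinates or length > 1 Mb are
dropped; a region is retained when some trait term occurs ≥ 2 times
among its overlapping QTLs. The threshold is inclusive ("2 consistent
QTLs suffice") and configurable — field usage is ambiguous between "more
than two" and crediting regions with exactly two, and the inclusive
reading is the one consistent with reported examples. ΔAF is computed
per mode — PS: (AF_D1+AF_D2)/2 − AF_R; D1.sp: AF_D1 − (AF_D2+AF_R)/2;
D2.sp symmetric — over nonsynonymous variants with a gene symbol inside
the mode's regions; |ΔAF| ≥ 0.8 passes, and the signed value is reported
because the sign carries the direction of selection. A nullable
`sift_score` column is reserved for externally joined deleteriousness
predictions; no prediction is performed here.

## The simulator

The generator produces the statistical structure the scan consumes —
long-range haplotype identity, LD decay, baseline drift, near-fixed swept
haplotypes — without simulating genealogies:

* **Sites.** Poisson-like positions at `snp_density` (default 1/500 bp)
  with a 5-bp minimum spacing, so the QC spacing rule only fires when
  violations are injected deliberately.
* **Founders.** `n_founders` (default 30) haplotypes whose derived-allele
  counts k are drawn with P(k) ∝ 1/k, a neutral-SFS-like spectrum.
* **Samples.** Each haplotype is a Li–Stephens-style mosaic of founders
  with per-bp switch probability 1e-5 (mean segment 100 kb), so r² decays
  across the 0–10/10–50/50–200 kb bins. Founder weights per population
  are Dirichlet draws with concentration `drift` (default 0.15; lower =
  more drift). The default was calibrated by direct measurement to give
  genome-wide mean per-site Weir–Cockerham θ ≈ 0.10–0.15 between
  populations, in the range reported for commercial pig breeds vs
  European wild boar. `drift = ∞` recovers identical weights and θ ≈ 0.
* **Sweeps.** A hard sweep copies one fixed template haplotype (core
  allele forced derived) onto a `final_freq` fraction of haplotypes in
  each selected population; each carrier's replaced segment extends from
  the core by independent Exponential(300 kb) arms, mimicking
  recombination escape. Selecting both domestic populations plants a
  parallel sweep sharing one haplotype; selecting one plants a
  breed-specific sweep. Non-selected populations are untouched.
* **Companion files.** Phased VCF 4.2 (INFO `AA`, `MQ`; FORMAT `DP`),
  population map, gene table (a configurable fraction of genes lack
  symbols, exercising the no-symbol exclusion), QTL table (background
  QTLs, one guaranteed > 1 Mb QTL per chromosome, two with missing
  coordinates, and trait-consistent clusters over each planted sweep),
  and a truth BED (core ± mean arm length, categories PS / DLW.sp /
  DU.sp).

Default test genome: 2 chromosomes × 10 Mb, 28/27/23 diploids — large
enough for 50-kb windows and 200-kb flanks to be meaningful, small enough
for minutes-scale runs.

**What a green test does not establish.** The simulator has uniform
recombination and mutation, no demography beyond founder-weight drift, no
soft sweeps or background selection, and depth/quality fields drawn from
clean distributions. Recovery of planted hard sweeps therefore validates
the machinery (estimators, windowing, set algebra, thresholds wired
end-to-end), not the scan's power or false-discovery behaviour on real
resequencing data.

## Numerical and design choices

* Window "top 1%" is ceil(0.01·N) with deterministic tie-breaks; the
  empirical-p denominator is the valid-window count.
* EHH cutoff 0.05, 200-kb gap cap, MAF floor 0.05, physical distance, and
  trapezoidal integration are selscan's defaults; no genetic map is used.
* Edge-truncated iHS sites are dropped by default (configurable), since a
  truncated integral biases ln(iHH_A/iHH_D) toward 0.
* The interval engine stores 1-based inclusive coordinates internally and
  converts to 0-based half-open only on BED emission.
* Degenerate inputs: zero valid windows is an error; an empty
  post-QC site set is allowed with a warning; a site class with < 2
  carriers is skipped for that allele class.
* All randomness flows from explicit integer seeds; identical config +
  seed reproduces every BED/TSV byte-for-byte.

## Known limitations

* Fst is strictly two-population; the three pairs are computed
  independently rather than via a joint multi-population estimator.
* Depth/MQ filters act on per-site aggregates (mean `DP`, INFO `MQ`);
  read-level semantics are unrecoverable from a joint VCF.
* iHS uses physical distance; in regions where recombination rate varies
  strongly, selscan with a genetic map would rank sites differently.
* The QTL-consistency rule treats trait terms as exact strings; no
  ontology-aware matching is attempted.
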