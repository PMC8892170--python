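# Methods

## Model and procedure

`cosegscan` operationalizes a simple population-genetic idea: if a
regulatory SNP and a coding SNP sit on the same haplotype background, the
sets of individuals carrying their minor alleles largely coincide, so the
Hamming (XOR) distance between their binarized genotype columns is far
smaller than chance allows. The pipeline has four stages.

**Binarization.** Each biallelic SNV is oriented panel-wide: the most
frequent allele is coded 0, the minor allele 1 (frequency ties designate ALT
minor, for determinism). Two coding modes collapse diploid genotypes to one
bit per row:

- *carrier* (default): a row is an individual, coded 1 iff it carries at
  least one minor allele. This is the only collapse that yields one bit per
  individual without discarding heterozygotes.
- *haplotype*: a row is one phased haplotype (2N rows), coded by the allele
  it carries. Requires phased heterozygotes; unphased input is rejected with
  an instruction to use carrier mode.

Missing genotypes are imputed to the major allele (code 0) and counted; this
biases against calling co-segregation, never toward it. The minor-allele
count `mac` is the number of rows coded 1 under the active mode (column sums
equal `mac` exactly); `maf` is the allele frequency over 2N chromosomes and
is bounded by 0.5 after orientation. Note that in carrier mode `mac/N` is
the carrier fraction, which exceeds `maf` (≈ 2·maf for rare variants).

**Analysis universe.** Columns are restricted to the query rSNPs present in
the panel plus every SNP inside a transcribed region of the supplied
annotation (BED 0-based half-open intervals are converted to 1-based closed;
GFF3 is read as 1-based closed; VCF positions are 1-based). rSNPs are
retained regardless of annotation overlap; query ids absent from the panel
go to an absent-rSNP report rather than failing the run.

**Co-segregation scan.** For an rSNP with carrier set A and a marker with
carrier set B over N rows, with overlap k = |A ∩ B|:

    xor = |A| + |B| − 2k.

Under random assortment of carriers with both margins fixed, k is exactly
Hypergeometric(N, |A|, |B|); the test is one-sided toward small distances
(co-segregation, not anti-segregation, is the target):

    p = P(XOR ≤ xor_obs) = P(k ≥ (|A| + |B| − xor_obs)/2) .

The observed distance is validated against the feasible parity/range of the
margins before evaluation. A permutation null (uniformly permuting the row
order of one vector, add-one estimator (1 + hits)/(1 + B)) is provided as a
model-free cross-check; the two agree within Monte-Carlo error, which is the
content of one acceptance test. Markers with p < α are called
co-segregating; α defaults to 0.01, matching the raw-p calling convention of
the analysis the package reproduces, with Benjamini–Hochberg FDR control
available (`multiple_testing: benjamini_hochberg`).

Normalization of the distance divides by a minor-allele-occurrence
denominator. The default is the carrier-set union, giving the Jaccard
distance xor/|A ∪ B| — the only offered mode bounded in [0, 1] with 0 iff
the carrier sets coincide (and are non-empty); `min_mac`, `max_mac` and
`sum_mac` are selectable. Downstream calls use p-values only; the
normalized distance is reported for ranking and inspection.

**GWAS linking.** The association table (GWAS Catalog column dialect or a
minimal generic header) is filtered by a trait keyword signature with
case-insensitive word-boundary substring matching — "CAD" matches "CAD
risk" but not "decade". Multi-SNP rows are split on the catalog's ";" and
" x " separators; rows without parseable coordinates are dropped and
counted. An rSNP is linked to a retained GWAS SNP when they share a
chromosome ("chr" prefixes stripped) and lie within ±half_window bp (closed
bounds; default 5,000, i.e. a 10 Kbp window centered at the GWAS SNP — the
one-sided 10 Kbp reading is `--half-window 10000`). If the rSNP itself is
outside the window, the closest called marker of that rSNP inside the
window produces a `via_marker` link (ties broken by marker id); a direct
link always dominates a marker link for the same (rSNP, GWAS SNP) pair, and
at most one association per pair is emitted. Output order is
(chrom, GWAS position, rSNP id), fully deterministic.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.01 | calling threshold on (adjusted) p |
| `normalization` | `union` | Jaccard denominator for the reported distance |
| `null_model` | `hypergeometric_exact` | deterministic exact tail; `permutation` available |
| `n_permutations` | 1000 | permutation-null resolution (min 100) |
| `multiple_testing` | `none` | raw p < α calling; `benjamini_hochberg` optional |
| `half_window` | 5000 bp | closed window half-width around each GWAS SNP |
| `coding_mode` | `carrier` | diploid-to-binary collapse |
| `signature_terms` | 12-term cardio list | trait keyword filter |
| `seed` | 0 | single seed for all randomness |

## The synthetic generator

The generator emulates the *shape* of the study the pipeline targets — a
multi-population diploid reference panel queried with a few dozen rSNPs —
at a desk scale of 500 individuals, chosen as the smallest panel at which
planted pairs with carrier counts ≥ 25 are unambiguous and the null studies
are well resolved.

- **Population structure** is Balding–Nichols: each background SNP has a
  base frequency drawn from a Beta(0.8, 1.8) scaled into [0.01, 0.5], and
  each of the (default 4) populations draws its own frequency from
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F_ST = 0.05. Background SNPs are in
  linkage equilibrium: the scan's null needs clean independence plus planted
  signal, not realistic LD decay.
- **Planted pairs** are constructed at the carrier level: the rSNP column
  gets an exact carrier count round(f·N), and the marker column is a copy
  with independent per-row flips at probability ε. Diploid genotypes are
  then realized per column from the Hardy–Weinberg relation
  1 − (1 − q)² = f (carriers heterozygous or homozygous with the
  conditional probabilities, non-carriers 0|0); for unflipped rows the
  marker copies the rSNP's realized genotype, so ε = 0 pairs are identical
  in the written VCF under both coding modes.
- **Exact truth by geometry.** Every query rSNP owns a locus on chromosome
  1, loci separated by ≥ 20 window widths; planted markers sit at the
  center of their locus gene; background SNPs and the unlinked GWAS rows
  live on chromosome 2, hundreds of kilobases from any linked position. By
  default the query carrier sets are drawn *disjointly* across queries, so
  an ε = 0 planted marker has zero carrier overlap with every other query
  (p = 1 exactly) and no spurious cross-locus candidate can arise under any
  seed — the planted-candidate list in `truth.json` is therefore an exact
  prediction of the pipeline output, not a high-probability one. The
  `independent` carrier mode drops this guarantee and is used for the
  calibration and power studies, where disjointness is infeasible by
  counting. Loci whose marker offset exceeds the half-window can be linked
  only via the marker; their GWAS rows are placed inside the marker's
  window but outside the rSNP's, which is what exercises the `via_marker`
  path. Some direct rows are placed at distance exactly half_window to pin
  the closed boundary, and zero-distance rows reuse the rSNP's id,
  emulating GWAS index SNPs that are themselves regulatory.
- **What it does not emulate:** haplotype-block LD among background SNPs,
  coalescent genealogy, recombination, selection, genotyping error, or the
  allele-specific read-count evidence that nominates rSNPs upstream.
  Passing tests therefore demonstrate the correctness of the statistics and
  plumbing under a clean null with planted signal, not performance under
  realistic LD structure, where nearby non-causal markers would co-segregate
  legitimately.

Truth-file candidate expectations assume ε = 0 planted pairs (certain to be
called at any reasonable α); for ε > 0 the truth records the planted pairs
and flip rates but makes no calling guarantee.

## Numerical and edge-case choices

- Monomorphic columns (all-0 or all-1 codes) are retained in the matrix but
  excluded from the scan with reason "degenerate pair"; distances to a
  constant vector are uninformative and the union denominator can vanish.
- Observed distances are checked for parity/range feasibility against the
  margins; infeasible inputs are a hard consistency error, never silently
  clamped.
- Extreme planted pairs can drive the exact tail below double-precision
  (reported as 0.0); calling compares p < α, so underflow is harmless.
- Ranked outputs sort by (p, normalized distance, marker id); candidate
  associations by (chrom, GWAS position, rSNP id) — all ties deterministic.
- The scan streams markers in column chunks (default 8,192), bounding
  memory by a constant number of columns at panel widths of 10⁵–10⁶.
- The run manifest carries wall-clock timestamps and is the single
  non-byte-reproducible artifact; every data file is byte-identical under a
  fixed seed.

## Calibration of the exact test

The exact hypergeometric test is discrete and therefore conservative: the
attained size at nominal α is the largest achievable tail probability below
α, which for common-variant margins (carrier frequencies 0.05–0.5,
N = 500) averages noticeably below the nominal level. The calibration study
in `scripts/acceptance.py` measures the empirical type-I error on 10,000
independent null pairs at both α = 0.01 and α = 0.05; the corresponding
test asserts the property a conservative exact test actually guarantees —
empirical size positive and not exceeding the upper 99% binomial bound of
α. A two-sided check centered exactly at α fails for this estimator, and
that failure is a property of discreteness, not an implementation defect;
a mid-p variant would center the size at α at the cost of occasional
anti-conservativeness and is deliberately not the default.

## Problem sizes used by the test suite

Unit and property tests run on panels of 4–500 rows and tens of columns;
the statistical studies use 10,000 null pairs at N = 500 (calibration), 50
pairs at N = 200 with 10,000 permutations (oracle agreement), a 50-pair /
5,000-background panel at N = 500 (recovery) with a 20-replicate power grid
over ε ∈ {0, 0.05, 0.1, 0.2}, and the default 500 × 2,020 bundle for the
end-to-end checks. The full suite completes in well under a minute on one
CPU.

## Known limitations

- The binary XOR construction is not classical LD: no r²/D′ statistics, no
  dosage (0/1/2) information, and carrier coding loses the het/hom
  distinction by design.
- Raw p < 0.01 calling over many pairs admits the corresponding false
  discovery mass (visible in the worked example: 94 calls for 8 planted
  pairs over 14k tests); BH mode is the safer alternative when marker lists
  feed downstream analysis.
- Window linking is purely physical; it does not weigh LD with the GWAS
  index SNP, allele directionality, or effect sizes.
- Multi-allelic records and non-SNVs are skipped at ingestion, and no
  liftover or reference-based imputation is attempted.
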