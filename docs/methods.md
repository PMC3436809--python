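# Methods

This note documents the models, conventions and numerical choices behind
`eqtlnet`, in the order the pipeline applies them.

## Inputs and conventions

Six tab-separated tables drive an analysis: per-patient genotypes (one
column per SNP), per-patient expression (one row per gene by default;
an `orientation` parameter accepts the transpose or an `auto` mode keyed
on the first header token), a phenotype table (family id, individual id,
status; PLINK coding 2 = affected, 1 = unaffected), a per-SNP reference
nucleotide table, gene loci (1-based inclusive; BED input is converted
with an explicit flag), and PLINK-style single- and two-locus result
files.  All parsing is header-keyed, so column order never matters, and
column names live in named *dialects* (`plink`, `contest`) overridable
from a `key = value` config file.

Genotypes are unordered, unphased allele pairs stored in alphabetical
order (`CA` ≡ `AC`); the view encodings only ever distinguish homo- from
heterozygous, so phase carries no information here.  The missing tokens
`00`, `NN`, `--` and the empty string become MISSING; MISSING calls are
excluded from every count but tallied.  p = 0 in result files is stored
as written and only clamped at display time (below).

SNP coordinates come from `chrN:pos`-style SNP ids.  SNPs whose ids
carry no position (e.g. bare rs numbers without a map) cannot be
assigned to a gene and drop out of graph construction with a logged
count.

## Closest-gene assignment

A SNP inside a locus (start ≤ pos ≤ end) is assigned at distance 0;
otherwise its distance to each same-chromosome locus is the bp distance
to the nearer boundary, and the nearest gene wins.  Deterministic
tie-breaks, declared rather than inherited from any reference
implementation: equal distances go to the smaller start coordinate;
a SNP inside two overlapping loci goes to the smaller span (the more
specific annotation), then smaller start.  Cross-chromosome assignment
is never made, and there is no default distance cutoff (`--max-dist`
adds one).  Ties are logged.

## Association graph and filter cascade

Records with p < α (strict; α defaults to 0.05) become triples
⟨g_i, g_j, g_k⟩ and increment the ({g_i, g_j}, g_k) edge; each distinct
canonical SNP pair counts at most once per edge (duplicate rows collapse
at parse time).  Self-loops are legal (both partners near one gene), and
an edge whose trait gene equals an endpoint is flagged *cis*.  The node
set is the full locus table, so isolated genes render too.  A node is
*colored* iff ≥ 1 edge carries it as trait gene; this status is computed
on the unfiltered graph and deliberately survives τ-filtering — τ
narrows the display, not the semantics.  Node colors are assigned from a
~10-color categorical palette in alphabetical gene order (cycling with a
warning beyond that, as more categorical colors stop being
distinguishable).

The cascade thresholds are all strict inequalities as documented on
their operations: single-locus keep set = {SNPs with R² > 0.1 and
p < 0.05 for at least one trait}; pair restriction keeps pairs with at
least one partner in the keep set.  Node degree counts parallel
multi-edges separately and self-loops once; a merged-multi-edge variant
(`node_degree_merged`) is exposed because either reading is defensible.

## Genotype view

Simplification counts non-reference alleles: REF = 0, HET = 1, HOM = 2
(two *different* non-reference alleles still count as HOM — the
definition is "polymorphism in both alleles").  Consensus is the
majority state per group with the fixed tie-break order REF < HET < HOM
(ties logged); strength is the majority fraction of non-missing
patients.  A group with only missing calls has an undefined consensus,
strength 0, and is excluded from relevance detection (logged).

The relevance rule flags a SNP when consensus states differ or
|strength_affected − strength_unaffected| ≥ δ with δ = 0.10, inclusive
("at least 10 percentage points"), compared on exact fractions with a
1e-12 tolerance so decimal strengths such as 0.85 − 0.75 are not lost to
binary rounding.

The χ² test is hand-written Pearson (Σ(O−E)²/E, df = c−1, upper-tail
χ² p) on the 2 × c table of raw allele-pair genotypes per group — raw
categories are the default because the underlying comparison concerns
allele combinations; a `simplified` mode tests the three states instead.
No Yates correction and no pooling of sparse cells: it is the standard
test of independence, with expected counts < 5 merely flagged.  Fewer
than two nonzero categories (or an empty group) is degenerate and
returns p = 1 by convention.

Significance bars show −log₁₀ of the SNP's best single-locus p (minimum
over traits, with the argmin trait recorded, since each SNP is tested
against every quantitative trait), clamped at 1e-300 so p = 0 maps to
300 — the Manhattan-plot convention.  Columns order by (chrom, pos) by
default, with a majority-genotype ordering as the alternative.

## Expression statistics and mirror scans

The group comparison is a two-sample t-test per gene — Welch by default
(no variance-equality assumption), pooled switchable — with two-sided p.
BH-FDR is the step-up q_(i) = min_{j≥i} m·p_(j)/j clipped at 1, mapped
back to input order; genes rank by p ascending (1 = most significant).

The single- and two-locus scans exist so the pipeline is exercisable
without external tools: they *mirror the shape* of PLINK
quantitative-trait outputs (numerical equality with PLINK is neither
claimed nor tested).  Genotypes are coded additively (0/1/2
non-reference alleles, matching the simplification above); missing
calls are dropped per test.  Single-locus: simple linear regression,
reporting the slope-t p and model R².  Two-locus: expression ~ codeA +
codeB + codeA·codeB, reporting the interaction-term t-test p, as the
epistasis convention does.  Both are closed-form least squares
vectorized over SNPs/pairs via masked normal equations; a design with
condition number above 1e10 (e.g. duplicated SNPs) or fewer residual
degrees of freedom than parameters is flagged with p = 1, monomorphic
SNPs likewise.  An exact interaction fit (zero residual with a nonzero
interaction coefficient) reports p = 0 rather than a 0/0 statistic.
When written to files, two-locus rows can be restricted to p below a
reporting threshold `epi1`, mirroring how epistasis tools emit only
sub-threshold pairs; the readers accept exactly the dialects the writers
emit.

## Synthetic cohorts

The generator emulates a two-group eQTL cohort: independent biallelic
SNPs drawn from Hardy–Weinberg proportions with per-SNP non-reference
frequency ~ Uniform(maf_range) (default 0.1–0.5; no linkage
disequilibrium in this version, so tag-SNP weight pile-ups of real data
are *not* emulated), gene loci tiling a synthetic chromosome with SNPs
placed round-robin inside them, and expression = Σ spiked effects
(effect · codeA · codeB on the target gene) + N(0, noise_sd²).  The
reference allele is the empirical major allele of the combined cohort
(ties alphabetical).  Everything derives from one seed; equal seeds give
byte-identical files.

Two kinds of ground truth can be spiked:

* **Interaction pairs** (snp_a, snp_b → target gene, effect size).
  Causal SNPs get a fixed common frequency, `causal_maf = 0.4`, rather
  than a uniform draw: a pure interaction a·b also has a marginal
  (single-locus) component with R² ≈ μ_b²·var(a)/var(y), which at
  effect 1.0 / noise 1.0 is ≈ 0.17 at frequency 0.4 but falls below the
  cascade's R² > 0.1 gate at low frequencies (≈ 0.02 at 0.15).  A
  generator spiking rare causal variants would therefore test the
  cascade's power against variants the cascade is not designed to pass,
  rather than its ability to recover recoverable signal.
* **Relevant SNPs**: the affected group's non-reference frequency is
  shifted by +`shift` (default 0.2); a shift pushing the frequency
  outside [0, 1] is an error.  Base frequencies draw from
  `relevant_base_range = (0.1, 0.3)`, *not* the full MAF range: the
  consensus summary is mathematically blind to q → 1−q reflections
  (the heterozygote fraction 2q(1−q) is symmetric), so a 0.4 → 0.6
  shift yields identical HET consensus and strength in both groups.
  Spiking inside that blind spot would label SNPs "relevant" that the
  summary statistic cannot, even in principle, detect.  The blind spot
  itself is kept visible: a dedicated test shows such a shift is
  invisible to the consensus rule while the χ² test flags it — the same
  complementarity the view-plus-test analysis is designed around.

The reference study conditions used by the recovery study, the
acceptance script and the demos: 500 patients (250/250), 200 SNPs over
10 genes, 3 spiked trans interaction pairs (effect 1.0, noise 1.0), 10
spiked relevant SNPs (shift 0.2), two-locus files written with the
epistasis reporting threshold epi1 = 1e-4 (the PLINK default).  These
sizes keep a 50-replicate study comfortably on a laptop while leaving
the binomial error of the measured rates small.  Recovery is scored
conservatively: a replicate counts only if *every* spiked
(endpoints, color) edge survives the full cascade with weight ≥ the
heaviest non-spiked edge.

## Workflow and outputs

`eqtlnet run` executes parse → map → build (α) → single-locus filter →
restriction → τ display filter → genotype view (with relevance and χ²)
→ expression statistics → renders, writing every stage's SNP/pair sets
so all summary counts are recomputable from the artifacts.  The
genotype view analyses the post-restriction network SNP set by default;
τ affects display/export only (a flag switches the view to SNPs on
τ-surviving edges, since either reading of "the SNPs in the network" is
defensible).  A stage failure aborts with the stage name and removes
partial outputs.

Renderings are deterministic functions of (inputs, seed): a seeded
spring layout replaces interactive graph manipulation, SVGs embed no
timestamps and use a fixed hash salt, so identical calls give identical
bytes.  Gray-scale encodes consensus (REF = white, HET = 50% gray,
HOM = black); allele-pair boxes use chromatogram base colors, solid for
homozygous and hatched two-color for heterozygous; heatmaps center per
gene onto a symmetric diverging gradient with rows sorted by q.

## Known limitations

No LD / population structure / relatedness in the generator; two
phenotype groups only; no covariates, permutation p-values or logistic
trait models in the scans; plain tab-separated inputs only (no
VCF/PED); the mirror scans are a convenience, not a PLINK replacement.
Passing recovery tests on these synthetic cohorts demonstrates correct
mechanics and calibration, not performance on real data with LD
structure, batch effects or missingness patterns.
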