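# Methods

This note records the models, the choices behind them, and what the
package's tests do and do not establish.

## Study design the package assumes

A population sample of diploid individuals of one species (default 22,
"ingroup") plus a single conspecific-adjacent outgroup individual, all
genotyped against de novo transcriptome contigs, with gene models
(CDS/intron/UTR) on those contigs and per-gene Pfam accessions. An
optional interspecific hybrid individual can be present; it is excluded
from all statistics and serves only as a diagnostic target. One gene per
contig is the dominant case and the synthetic generator's invariant.

## Variant filtering

Sites survive when every inequality holds: 17.0 ≤ QUAL < 100000.0, total
AC ∉ {0, 2n}, −3.5 < BaseQRankSum < 7.0, DP ≥ 5, Dels < 0.1, FS < 90.0,
HaplotypeScore < 25.0, MQ ≥ 20.0, −25.0 < MQRankSum < 10.0,
−3.5 < ReadPosRankSum < 9.0, SB < 3.0. Genotypes failing DP ≤ 100 or
GQ ≥ 20 are set uncalled. Diallelic SNPs are loci where exactly two
single-nucleotide alleles are represented among surviving calls, one of
them the reference; a triallelic record whose third allele survives in no
called genotype qualifies. Choices:

- INFO metrics absent from a record pass: rank-sum annotations are
  undefined at sites without heterozygotes and an absent value cannot
  violate an inequality.
- The AC bound is parameterized as {0, 2n} so panels of any size work
  (48 = 2 × 24 in the original design).
- SB is treated as a plain numeric INFO key; no assumption about its
  scale beyond the < 3.0 bound.
- Coordinates are 1-based in VCF/GFF at file boundaries and 0-based
  half-open internally, converted exactly once at I/O.

## PBL dN/dS

Degeneracy classes per codon position (standard code, NCBI #1): 4-fold if
all three changes are synonymous, 0-fold if none, else 2-fold; changes
to or from a stop count as nonsynonymous for classification. Pairwise
counting excludes any codon column with an ambiguous base in either
sequence or where either codon is a stop (the ADJUSTSTOPS-style rule);
site counts are averaged over the two sequences, and a difference whose
class differs between the sequences contributes ½ to each class. K2P
components and the dN/dS combination are as in the README. Numerical
edges:

- (P, Q) outside the K2P domain (1−2P−Q ≤ 0 or 1−2Q ≤ 0), or an empty
  0-fold or 4-fold class, make the whole estimate invalid and the
  comparison non-qualifying rather than silently clamped.
- Sentinels: dN = 0 → ratio 0 (checked first); dS = 0 with dN > 0 →
  ratio 10. Rank-based downstream tests are insensitive to the exact
  sentinel magnitudes.
- The ≥ 6-substitution qualifying rule is applied per pairwise
  comparison; gene summaries use qualifying comparisons only.
- Delta-method variances of dN and dS are computed per class from the
  multinomial covariance of (P, Q) and reported as reference columns;
  nothing downstream consumes them.

Haplotype pairs: both coding sequences equal the contig CDS except at
filtered diallelic SNPs, where heterozygotes place one allele in each
sequence (phase-free; PBL counting is invariant to the assignment),
uncalled genotypes become ambiguity in both, and ends are padded with
ambiguity to codon boundaries (covering partial codons of incomplete
models via the GFF phase). The four-pairing concatenation h₁h₁h₂h₂ vs
g₁g₂g₁g₂ weights every haplotype pairing once.

Gene summaries are geometric means; sentinel zeros are floored at 2⁻¹⁰
inside the log-mean so the summary stays finite and rank-preserving
(the high sentinel 10 enters as-is). Tail calibration fits a normal to
log₂ summaries truncated to [−5, 1] by maximizing the truncated
likelihood (Nelder–Mead on (μ, log σ), initialized at the sample
moments); the α-threshold on the linear scale is 2^(μ + σ·z₁₋α). At
least 30 in-window values are required; all-equal values are a signalled
calibration failure.

## Fay & Wu's H

H = θ_π − θ_H with θ_π = Σ 2i(n−i)ξᵢ/(n(n−1)) and θ_H = Σ 2i²ξᵢ/(n(n−1)).
The ancestral allele is the outgroup's homozygous call; an uncalled *or
heterozygous* outgroup falls back to the ingroup-majority allele (a het
outgroup determines no single ancestral state), ties broken toward the
reference. The fallback biases H upward, i.e. against inferring sweeps.
Loci with more than 4 of 2n alleles missing are excluded; at every
surviving locus exactly n−4 = 40 alleles are resampled without
replacement (uniformly, including loci with no missing data, so all loci
share one sample size); sites monomorphic after resampling are dropped.
Ten replicate spectra are summarized by the median H. H is computed per
gene-containing contig over all of that contig's filtered diallelic SNPs
(not CDS-only). π_S divides θ_π over synonymous-labelled loci by the
effective synonymous site count, Σ(1 per 4-fold position + 1/3 per
2-fold position) over complete non-stop codons.

## Hardy–Weinberg density and heterozygosity

Qualifying loci (≥ 11 called ingroup genotypes and ≥ 1 of each genotype
category) each contribute their Dirichlet(1+n_r, 1+n_h, 1+n_v) posterior
under a uniform prior; the empirical density is the locus average, stored
as a natural log on a uniform barycentric lattice (default 201 points
per edge). Internally loci are aggregated by genotype-count triple, so
evaluation is a small weighted Dirichlet mixture and the density can be
evaluated exactly along arbitrary lines. The ridge diagnostic finds the
density argmax along each line from the h-vertex to the r–v edge (each
crosses the Hardy–Weinberg curve h = 2p(1−p), p = r + h/2, exactly once)
and reports its Euclidean distance to the curve in the equilateral
embedding; distances are reported without a pass/fail threshold.

Per-gene observed heterozygosity uses SNPs anywhere in the gene model's
span (paralog collapse affects all positions), qualifying when genotyped
in ≥ 10 of 22 ingroup individuals and in the outgroup, hybrid ignored;
the per-SNP value is het calls over called non-hybrid individuals, and
genes need ≥ 6 qualifying SNPs.

## Class scans

Each Pfam accession with ≥ 5 member genes (default) is tested against
all other genes with a two-sided Wilcoxon rank-sum test — two-sided with
a reported direction, since both unusually high and unusually low
classes are of interest. For combined n ≤ 20 the null is enumerated over
all rank assignments (exact even under ties; complete ties give p = 1);
larger samples use the tie-corrected normal approximation. Q-values are
Benjamini–Hochberg across the accessions of one scan (one statistic at a
time).

## Allele discovery

Alignments with MAPQ ≥ 20 and FLAG & 0x704 == 0 are decomposed into
maximal runs (insert / delete / mismatch; identical runs dropped;
soft-clipped bases excluded — they are not in 1:1 correspondence with
the reference). Quintuples (type, contig, position, ref seq, read seq)
seen ≥ 5 times with unambiguous read sequence become tentative alleles.
Indel loci are grown one nucleotide upstream so no VCF allele is empty.
Chains of tentative loci whose reference spans overlap **or abut** are
merged into one record spanning the chain, each alternate rewritten by
splicing its event into the grown span with all other positions at
reference; abutting loci are included because after upstream growth an
indel's anchor base makes adjacency and overlap operationally
indistinguishable for downstream genotyping. The per-position read
downsampling used before external genotyping is out of scope here.

## Ortholog calling

Hit tables are reduced per query (keep ≥ 99% of the query's top
bitscore, boundary inclusive) and then per subject, with subject-stage
tops computed on the query-stage survivors — the order the procedure
states; computing subject tops on the unreduced table is the documented
alternative. Splice-variant suffixes (configurable regex, default
`\.\d+$`) are collapsed before graph construction. Vertices with
out-degree ≠ 1 are removed and reciprocal arcs returned; the output is
always a partial matching.

## Synthetic data generator

What it emulates: panel composition (22 + 1 + optional hybrid), ~1.2–1.5%
within-ingroup SNP density (`theta_site` = 0.013), ts:tv imbalance
(`kappa` = 3.8 under P(transition) = κ/(κ+2), implying a ts:tv count
ratio of κ/2 = 1.9), per-gene-class ω via acceptance sampling of
proposed coding mutations (nonsynonymous accepted with min(1, ω),
synonymous with min(1, 1/ω)), neutral (ξᵢ ∝ 1/i) and sweep (0.5 mixture
mass uniform on counts ≥ n−4) derived-allele spectra, genotype DP/GQ and
site INFO metrics drawn from passing distributions with a 10%
contamination fraction given exactly one failing metric, and a hybrid
heterozygous at 80% of fixed interspecific differences. Coding sequence
is drawn codon-wise uniformly over non-stop codons (no internal stops
without rejection loops); ~20% of genes carry one GT..AG intron at a
codon boundary; about half the models are on the minus strand; one gene
per contig.

Deliberate choices and departures from realism:

- `outgroup_divergence` defaults to 0.05 per site — higher than a true
  white-oak pair — so that typical desk-scale CDS lengths yield tens of
  substitutions per comparison and the ≥ 6-substitution rule is
  routinely exercised. Sites are unlinked; there is no recombination,
  no coalescent genealogy and no read-level error model. Proposals
  creating or destroying stop codons are rejected, keeping CDSs clean
  rather than modelling nonsense polymorphism.
- Truth bookkeeping records, per emitted variant, the ancestral and
  derived alleles, the derived count among called emitted ingroup
  genotypes (so it is always recoverable from the VCF), the class
  membership and the planted failing metric if any.

Consequently, passing tests show the estimators recover parameters of
this generative process — they do not show robustness to linkage,
alignment error, allele-specific expression or assembly artifacts in
real transcriptome data (the heterozygosity and de Finetti diagnostics
exist precisely because real data contain such artifacts).

## Problem sizes used by the test suite

The distributional checks run at sizes chosen to make their tolerances
meaningful at interactive cost: ω-recovery uses 200 genes of 3000-nt CDS
per arm (median dN/dS in [0.8, 1.25] at ω=1, [0.15, 0.3] at ω=0.2);
sweep-vs-neutral H uses 100 genes per arm; the Hardy–Weinberg ridge uses
10⁴ random-mating loci on a 201-point grid (mean distance < 0.02);
calibration recovery uses 10⁴ simulated ratios (±0.05); oracle
equivalence uses 100 random 300-codon pairs at 10⁻¹⁰.

## Known limitations

- The geometric-mean floor for sentinel zeros (2⁻¹⁰) and the cap-free
  treatment of the high sentinel are completions of an under-specified
  summary; rank-based scans are insensitive to them, parametric reuse of
  the summaries would not be.
- The 22 comparisons against a single outgroup individual share that
  individual's haplotypes and are not statistically independent; the
  per-gene summary is reported as the procedure defines it, without an
  independence claim.
- Wilcoxon exactness is guaranteed only for combined n ≤ 20; beyond that
  the tie-corrected normal approximation is used.
- For a locus covered by two models on one contig the effect table
  reports one row per (locus, model) pair rather than electing a winner.
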