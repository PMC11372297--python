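# Methods

`hyperburst` analyzes somatic SNV catalogs from ultra-hypermutated,
mismatch-repair-deficient tumor exomes (the motivating setting is
high-grade glioma arising in constitutional MMR deficiency, CMMRD). The
pipeline takes pre-annotated per-patient mutation tables and answers
four questions: which mutational signatures are acting; how the VAF
distribution decomposes into mutation bursts; where the somatic
*POLE*/*POLD1* proofreading driver sits in that history and how much of
the burden precedes it; and which genes are recurrently hit, or
non-synonymously enriched, above the driver's VAF.

## SBS96 spectra

Substitutions are classified into the standard 96 trinucleotide
channels: the pyrimidine-strand substitution class (C>A, C>G, C>T, T>A,
T>C, T>G) crossed with the 5′ and 3′ flanking bases. Purine-reference
records are reverse-complemented before lookup, so each biological
event has exactly one canonical channel (192 encodings → 96 channels,
verified exhaustively). Channel order is the COSMIC convention,
class-major with contexts lexicographic, `A[C>A]A` at index 0; catalogs
read from disk are reordered to this canonical order whatever their row
order. Class fractions report the six classes plus the two aliases
conventional in MMR work: G:C→A:T transitions (the C>T class) and
C:G→A:T transversions (the C>A class).

## Supervised signature refitting

Given a fixed catalog (96 × S, columns simplex-normalized; column sums
may deviate from 1 by at most 1e-3 on read, anything worse is rejected
rather than silently rescaled), exposures are estimated by greedy
forward selection. Starting from the empty set, each step adds the
signature that most increases the cosine similarity between the
observed frequency vector and its non-negative least-squares (NNLS)
reconstruction; selection stops when the best gain falls below
`gain_threshold` (default 0.02, exposed in every entry point because
supervised-assignment tools differ here and no canonical value exists).
The final NNLS solution on the selected set is rescaled to mutation
counts summing to the observed total. NNLS uses an active-set solver;
problems are 96-dimensional, so exactness rather than speed is the
constraint. Ties in forward selection go to the lowest catalog column
index, making the fit fully deterministic; the selection path's cosine
is asserted non-decreasing.

The gain threshold trades sensitivity for sparsity: broad, nearly flat
signatures (SBS5-like) overlap everything and may add < 0.02 cosine
even at a true 15% exposure, so minor flat components are routinely
absorbed into the dominant peaked ones. This is visible in the
cohort-level mean exposure error (~0.1 on the default synthetic cohort)
and is the expected behavior of sparse supervised refitting, not a
fitting failure; lower the threshold for exploratory fits.

Per-burst refits run independently on each mutation subset; subsets
under 50 mutations are flagged "too small" instead of fitted, since a
96-channel spectrum from fewer counts is mostly zeros.

## Burst detection

Mutation bursts are modes of the VAF distribution. Rather than reading
peaks off a histogram, bursts are fitted as a K-component binomial
mixture on the raw read counts: a mutation with depth d in a burst of
cell fraction-scaled VAF p contributes alt reads ~ Binomial(d, p).
Modelling counts (not the VAF ratio) makes the depth-dependence of the
noise explicit — a 0.40-VAF mutation at 150× carries ±0.04 of binomial
standard deviation — and needs no bandwidth or binning choices. A
Gaussian-on-VAF fallback exists for depth-free tables.

For each K in 1..k_max (default 6, one above the largest clone count
typically reported in such tumors), EM runs from quantile-spaced
centers with 10 seeded jittered restarts; identical (alt, depth) pairs
are collapsed with weights, which makes the E-step cost proportional to
the number of distinct read-count pairs rather than mutations. The EM
log-likelihood is asserted non-decreasing at every iteration of every
restart (tolerance 1e-8 relative); convergence is declared at a 1e-9
relative change. K is selected by BIC with 2K−1 free parameters.
Components are ordered by decreasing VAF center, so component 0 is the
earliest ("first") burst; hard assignment is by maximum posterior with
ties to the lower index, giving the partition the per-burst refits
need. No copy-number or purity correction is applied: the intended
inputs are tumors where the relevant loci are copy-neutral, and VAF is
read directly as a clonal-timing proxy.

The qualifying-burst filter for per-burst signature analysis keeps
components with strictly more than 500 mutations and strictly more
than 5% of the patient's total.

Fewer than 20 records is refused with advice to treat the tumor as a
single burst: mixture selection below that size is noise.

## Driver calling and the above/below partition

The candidate driving polymerase mutation is selected from editable
curation rules: a protein-change whitelist (defaults P286R, V411L,
S459F, L424V for *POLE*) and exonuclease-domain residue intervals
(defaults *POLE* 268–471, *POLD1* 304–533). These defaults are
shipped curation, not measured data, and should be replaced by a
study's own validated list. Among matching records the highest VAF
wins; a selected VAF ≤ 0.31 triggers a warning, since proofreading
drivers in this setting are expected clonal (VAF typically near 0.40).

Given a driver, every other coding SNV is counted as before-driver
(VAF strictly above, with equality within 1e-9 counted as above — a
tie cannot be shown to be later) or after-driver; the driver itself is
on neither side. Reported quantities: TMB = coding SNVs per Mb of
captured exome; the after/before fold n_below/n_above (infinite when
nothing precedes the driver); and the ultra-hypermutation flags at the
conventional ≥ 100 coding SNV/Mb, both overall and restricted to the
above-driver set. `exome_mb` is a required configuration value with
default 54.0 — clinical research exome captures are in this range, and
a cohort reporting ~9,400 coding SNVs as ~174/Mb implies ≈ 54 Mb; the
default is documented as inferred and should be set to the actual
interval size when known.

Patients without a qualifying polymerase record get a burden-only
summary (TMB, ultra flag; partition fields null).

## Recurrence and the driver score

The recurrence matrix counts, per patient, non-synonymous coding SNVs
at or above the driver VAF (all non-synonymous SNVs for driverless
patients; synonymous always excluded; "non-synonymous" = missense,
nonsense, splice, other coding). Genes are kept when hit in at least
`ceil(2/3 · n_patients)` patients — 8 of 12 — expressed as a fraction
so other cohort sizes behave sensibly.

The driver score contrasts a gene's non-synonymous count against its
synonymous count. With ρ the cohort-wide non-synonymous:synonymous
ratio (estimated from all mutations, since the package never sees a
reference genome or codon tables), the null model gives the gene one
free rate λ with syn ~ Poisson(λ), nonsyn ~ Poisson(ρλ); the
alternative frees the non-synonymous rate. Both MLEs are closed form
(λ̂₀ = (n_s + n_n)/(1 + ρ); the alternative is saturated), the
statistic is 2(ℓ₁ − ℓ₀) referred to χ²(1), and genes with no mutations
score 0 with p = 1. Ranking is by statistic descending with
alphabetical tie-breaks; significance is Benjamini–Hochberg at
α = 0.05 by default. The χ² calibration is asymptotic: at the mutation
counts of hypermutated exomes (tens per gene) the null rejection rate
is within a couple of points of nominal, but the test is not exact for
genes with a handful of mutations. This score is a deliberate
simplification of full dN/dS-style driver inference — no per-gene
trinucleotide opportunity, no indels — capturing only the syn/non-syn
contrast.

## Cohort summaries

Clinical counts distinguish stain-based denominators (NA excluded) from
cohort-wide ones (all samples); both PDL1 denominators are reported
rather than choosing one. PDL1-positive means score ≥ 1 on the 0/1/2
grading; giant-cell histology keys on the exact phrase "giant
multi-nucleated cells" in the histology text (a deliberate literal
match: related phrasings like "giganto-cellular features" are not
counted). Medians of even-sized sets are the mean of the central pair.

TMB comparison between MMR-gene groups uses the two-sided
Wilcoxon–Mann–Whitney test: for combined n ≤ 20, full enumeration over
all rank assignments with midranks for ties, two-sided p defined as
the probability of a U statistic at least as far from its mean
n₁n₂/2 as observed (symmetric-deviation convention; for tie-free data
this equals the classical exact two-sided p). Larger samples use the
normal approximation with continuity and tie correction.

## The synthetic cohort generator

Because suitable per-patient catalogs are not freely downloadable, the
generator is first-class, tested code and defines the conditions every
downstream stage is validated under. Each patient is a list of bursts;
a burst has a VAF center, a mutation count, and a signature exposure
vector. Channels are drawn multinomially from the mixed catalog
columns and decoded to (ref, alt, context); genes are drawn
proportional to coding length from a 60-gene toy exome (20 named
cancer/recurrence genes plus filler, lengths 1–15 kb); effects are
synonymous with probability 0.25 (roughly the fraction of random
coding SNVs that are synonymous), else missense. Depth is
Poisson(150) — matching typical clinical tumor exome coverage —
truncated below at 20 to avoid degenerate VAFs; alt reads are
Binomial(depth, burst VAF). A strand-flip flag re-encodes half the
records on the purine strand to exercise spectrum normalization.
Fixed seeds give byte-identical output.

The default cohort plants the shape of a 12-patient CMMRD-glioma
series: TMB 1.3–635 coding SNV/Mb (median ≈ 175/Mb at the 54 Mb
default exome), nine ultra-hypermutated tumors, nine polymerase
drivers (eight *POLE*, one *POLD1* at true VAF 0.453), drivers always
in the highest-VAF burst at true VAF 0.31–0.45, one to four bursts per
tumor at fixed offsets (−0.14, −0.26, −0.37) below the clonal burst,
MMR-deficiency-dominated exposures (SBS15-style majority, SBS14/10a/10b
minority for *POLE* cases, SBS20-led for the *POLD1* case), and seven
recurrent driver genes (TP53, NF1, SETD2, PRKDC, EPHB2, DICER1, ATRX)
planted at above-driver VAF in 8–9 of 12 patients with double hits in
some. Per-burst exposures are illustrative — real per-burst exposure
values for such cohorts are not published — and are held identical
across a patient's bursts, mirroring the observation that burst
signatures change little within a tumor.

The bundled signature catalog is synthetic: columns carry COSMIC-style
names and qualitatively similar concentration patterns (e.g. the
SBS10a-like column peaks at T[C>A]T), built programmatically so that
no third-party matrix ships in the package; pairwise cosines are ≤
0.55, so refitting on it is an easier problem than on the real
67-signature COSMIC catalog, where near-collinear flat signatures make
exposures partially unidentifiable. Real COSMIC TSVs load through the
same reader and can be substituted everywhere.

What passing tests on this generator do not show: robustness to
copy-number and purity distortion of VAF (not simulated), indels and
doublet substitutions (absent), germline contamination, sequencing
artifacts, or signature catalogs with strongly collinear columns.

## Numerical and size choices

- EM: 10 restarts, quantile init with N(0, 0.02) jitter, probability
  floor 1e-6, convergence 1e-9 relative; BIC with 2K−1 parameters.
- NNLS convergence is the solver's machine-precision active-set
  criterion; exposures below solver tolerance count as unselected.
- Exact rank-sum enumeration is used up to combined n = 20
  (C(20,10) ≈ 1.8e5 assignments).
- The validation suite recovers burst structure on 20 seeded tumors
  with centers ≥ 0.12 apart and ≥ 800 mutations per burst at 150×;
  exposure recovery is checked at 20,000 mutations over three
  well-separated columns (±0.05); driver-score calibration uses 2,000
  null genes at ~80 expected mutations each and power uses 5×
  non-synonymous enrichment at ~160 expected mutations. The end-to-end
  run uses the full-size default cohort (~134,000 mutations).

## Known limitations

- VAF is treated as a clean clonal-timing proxy; any CNV/LOH at the
  polymerase locus or strong clonal selection breaks the above/below
  interpretation.
- The burst mixture is one-dimensional in VAF; it cannot separate
  clones with equal VAF, and binomial overdispersion (e.g. mapping
  bias) will inflate K.
- Forward selection is greedy; with strongly collinear catalogs the
  selected signature set, though deterministic, need not be the global
  cosine optimum.
- The driver score ignores per-gene mutational opportunity; long genes
  with unusual base composition can drift off calibration.
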