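# Methods

This note records the models, conventions, and design choices behind
`balscan`, in the order a user meets them in the pipeline: sequence
handling, spectra, neutrality tests, the coalescent null, haplogroup
dating, the splice/NMD model, assay statistics, and the synthetic-data
generators used by the test and acceptance suites.

## Sequence handling and QC

Coordinates are 1-based and inclusive throughout locus space; missing
bases (and outgroup gaps) are coded `N`.  FASTA input carries one record
per phased haplotype (`SAMPLE.1` / `SAMPLE.2`); VCF input must be fully
phased (`|`), and in strict mode only the first ALT allele is used.

Amplicon-edge filtering discards variants whose 1-based offset from either
end of a containing sequenced segment lies in 1..50 — base calls degrade
near amplicon ends.  The boundary is inclusive: offset 50 is removed,
offset 51 kept.  Quality filtering (threshold 99) applies only when the
caller supplies per-variant scores; the mapping from any particular
base-caller's score to this threshold is the caller's responsibility.
Singletons and triallelic sites are *flagged for review, never silently
dropped* — in the original protocol such sites were manually inspected —
with an opt-in strict mode that drops triallelic sites.  Filtering is
idempotent.

Polarization assigns the ancestral allele when the aligned outgroup base
matches one of the two segregating alleles; mismatches and gaps leave the
site unpolarized.  A site is a fixed difference (FD) only when the ingroup
is monomorphic and differs from a called outgroup base, so S and FD are
mutually exclusive by construction.  The SNPs-per-fixed-difference ratio
keeps its exact rational value internally (`ratio.exact * FD == S`
identically) and rounds to one decimal for display.

## Site-frequency spectra

Missing data gives every site its own called-chromosome count *m*; spectra
are made comparable by hypergeometric projection to a common *n* (default
15): a site with *d* derived copies contributes weight
C(d,j)·C(m−d,n−j)/C(m,n) to count *j*.  We use *expected* spectra — each
site contributes its full weight vector — rather than sampling one
projected outcome per site; this is deterministic and is also what the
per-site rank-test statistic needs (the expected folded minor count).
Mass projected to j = 0 or j = n is reported as `discarded_mass`, never
silently dropped.  Unpolarized sites cannot enter the unfolded spectrum
but still carry folded information through their minor-allele counts, so
they contribute to folded spectra and to the rank-test site list.  Sites
with m < n are skipped.

## Neutrality tests

**Tajima's D** uses the standard 1989 normalization.  Pairwise diversity
handles missing data pairwise, rescaling each pair's difference count by
its fraction of co-called sites.

**MWUhigh** is a one-sided Mann–Whitney U on per-site expected folded
frequencies, test region vs pooled controls, with midranks for ties.  The
one-sidedness means only an *excess* of intermediate-frequency variants
can be significant — a deficit (the positive-selection signature) cannot.
p is exact by complete enumeration when the combined site count is ≤ 12,
otherwise a normal approximation with tie and continuity corrections; the
two paths agree within |Δp| ≤ 0.02 on continuous inputs at the crossover
sizes.

**HKA** is the classic two-locus formulation with a single outgroup
sequence, time in units of 2N generations and an equal-sized ancestral
population: E[S] = θ·a₁(n), Var[S] = E[S] + θ²·b₂(n) (b₂ = Σ1/i²),
E[D] = θ·(T+1), Var[D] = E[D] + θ².  The three moment equations are
reduced to a single bracketed root solve in u = T+1.  The divergence
observation supplied by the pipeline is the fixed-difference count; this
undercounts true divergence by the shared-polymorphism fraction, a bias
absorbed by the fitted T̂ and by the simulation calibration.  X² has four
observation cells and three fitted parameters; the analytic p uses
χ²(1 df) and is secondary.  The primary p is a parametric bootstrap at the
fitted (θ̂₁, θ̂₂, T̂): S from Poisson mutations on simulated coalescent
tree lengths, D from Poisson(θ(T̂ + Exp(1))), refitting X² per replicate.
The scan treats the test locus vs the *pooled* controls as the two loci; a
multi-locus extension is out of scope.  The scan's HKA uses the pooled
(all-population) S and FD, so per-population differences enter only
through sample size.

**Empirical p-values** use the add-one estimator
p = (1 + #{draw ≥ obs}) / (1 + N), which cannot return 0; values at the
resolution floor display as "< 1/N".

## The coalescent null

The engine is a Hudson-style backward simulator: per-population lineage
lists, exponential/closed-form waiting times (exponential growth uses the
inverted time-change), migration as per-lineage hops, mass migrations as
population joins, and recombination via ancestral-segment tracking with
leaf-set bitmasks (segments whose leaf set reaches the full sample are
retired — the local MRCA is found).  Branch "pieces" (duration × genomic
span, with their leaf masks) are recorded at lineage destruction; mutation
placement draws pieces with probability proportional to weight, which
realizes both fixed-S conditioning (exactly S placements) and θ-mode
(Poisson(θ/2 × total weighted length)) under infinite sites.

Units: time in 2·N_ref generations (so E[pairwise TMRCA] = 1 and E[total
length] = 2Σ1/i at constant size — the closed forms the tests check),
sizes in diploids, θ = 4·N_ref·μ_locus.  The quoted recombination rate
10⁻⁶ per bp is interpreted as the population-scaled ρ = 4Nr per bp, the
parameterization native to simulation contexts; a config switch
(`rho_is_scaled=False`) selects the per-generation reading instead.

The default demographic null is the three-population out-of-Africa model
(African / European / East Asian) at its published point estimates:
ancestral 7,300 growing to 12,300 at 220 kya; bottleneck deme of 2,100
splitting at 140 kya; Europe (1,000, +0.4%/gen) and East Asia (510,
+0.55%/gen) splitting at 21.2 kya; symmetric migration 25·10⁻⁵ between
Africa and the bottleneck deme and 3/1.9/9.6·10⁻⁵ among the modern demes;
generation time 25 yr.  Study populations map onto demes as African → AF,
East Asian → AS, and European, Middle Eastern, and South Asian → EU
(config-overridable; the null has only three demes).  Any residual misfit
of the divergence model is absorbed by `calibrate_divergence`, which tunes
the outgroup stem length until simulated E[S]/E[FD] matches a target
(control regions: 0.82) within a relative tolerance (default 5%),
exploiting the linearity of E[FD] in the stem length and growing the
per-iteration batch so the stopping rule is bias- not noise-driven.

Fixed differences are generated as Poisson counts on the stem at the
replicate's own mutation rate (θ/2, or S/length under fixed-S).
"Conditioning on informative sites" defaults to S only; a joint S+FD mode
splits the fixed total binomially between tree and stem.

Simulation p-values in the scan condition each replicate on the observed
per-population segregating-site count, and re-simulate the control panel
per replicate (each control locus at its own observed site count) so the
rank test's null honors the shared-genealogy correlation of sites within
a locus.  The engine is cross-validated against an independent coalescent
implementation (msprime) at matched parameters in the test suite; ms-style
text output round-trips through the bundled parser.

## Haplogroup partition and rho dating

Haplotypes are clustered by complete linkage on pairwise Hamming distance
(missing entries skipped pairwise) and the dendrogram cut into two groups;
complete linkage resists chaining through recombinant intermediates.  When
the minimum between-group distance does not exceed the within-group
diameter the partition is flagged low-support (star-like data).
Diagnostic sites are those whose alleles perfectly separate the groups;
"nearly diagnostic" tolerates one crossover haplotype by default.

Dating replaces network-based root inference with a deterministic root:
the outgroup-polarized ancestral allele vector.  rho is the mean Hamming
distance of haplotypes to that root; its standard error is
σ = sqrt(Σ_sites (dᵢ/n)²), treating each segregating site as one inferred
mutation shared by its dᵢ derived-allele carriers.  Calibration uses the
full divergence branch — both lineages of the outgroup comparison — so
μ_locus/yr = FD/(2·T_div) with T_div = 6 Myr, and age = rho/μ.  Two
biases are documented rather than corrected: the calibration denominator
includes the within-sample TMRCA (μ is underestimated by roughly
TMRCA/(2·T_div), ~12% for a 1.4-Myr-old clade pair), and the sample TMRCA
slightly exceeds the clade-split time.  Parameter recovery on fixtures
with known split age stays well within the estimator's own 3σ (acceptance
suite); the estimator is a documented substitute for network-internal
dating, validated by recovery, not by matching any particular published
point value.

## Splice model and NMD

Donor strength is scored on the 9-mer spanning −3..+6 (3 exonic, 6
intronic bases).  Two scorer kinds: a PWM (log2-odds against a background
composition; the bundled toy PWM has a strong GT consensus and an
allele-sensitive +3 costing ~4.5 units for A→G) and the published 5′
maximum-entropy model, table-driven: score = log2(consensus-odds(+1,+2) ×
me2x5[remaining 7-mer]).  The 4⁷-entry table is an external asset of the
published scorer (loader provided); the PWM keeps everything runnable
offline.

Donor choice: the highest-scoring candidate at or above a threshold wins,
ties break upstream; if none clears the threshold, splicing falls through
to the next candidate downstream of the canonical donor (cryptic
activation).  This operationalizes an outcome that is otherwise only
reported per allele.  Strengthening the canonical donor can never switch
the choice away from it (monotonicity, tested).

Transcripts are assembled by concatenating exon intervals (the chosen
donor sets the variable exon's end), translated from the CDS start to the
first stop.  A stop is premature when its last base lies at or upstream of
the final exon–exon junction; NMD is called when the stop's 3′ end is at
least 50 nt upstream of that junction (the literature's rule spans 50–55
nt; 50 chosen, configurable; the boundary is inclusive at 50).  Gene-model
coordinates are 1-based inclusive; mRNA offsets 0-based internally.

## Assay statistics

*Standard curves.*  log₂(B:A mix ratio) is regressed on ΔCt = Ct_A − Ct_B
(standard allelic-discrimination practice; with ideal efficiency the slope
is 1).  At least three distinct mix fractions are required and fits with
R² < 0.9 are refused.  Unknowns are read off per replicate and summarized
as mean ± SEM; the heterozygous genomic-DNA control must read 1.0.  The
NMD contrast labels a cell line "NMD-consistent" when the untreated B:A
ratio is depressed (< 0.8) while the translation-blocked ratio returns to
~1 (0.8–1.25).

*Flow cytometry.*  Surface-marker MFI is standardized by dividing by the
constitutive marker's MFI per sample.  Outliers are removed within
experiment × genotype groups by the 1.5×IQR Tukey fence; quartiles use
linear interpolation (outlier sets depend on the quartile convention, so
it is pinned), and groups smaller than 4 pass through.  Inference is an
additive two-factor ANOVA (genotype + experiment, no interaction — the
two stated factors) on the two homozygote classes, plus per-experiment
Welch t-tests (the unequal-variance form, chosen as the conservative
default where the pooling convention is unstated).  The ANOVA matches a
hand-computed balanced two-way table exactly (acceptance suite).

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (spec, seed); fixed seeds give
byte-identical files, and every fixture carries a truth record sufficient
to score the downstream estimators.

The sequence fixture defaults mirror the study design: 30 diploids from
each of six populations, an 8,794-bp locus, 47 control regions, a
chimpanzee-like outgroup at 6 Myr.  Neutral mode simulates the
out-of-Africa null.  Balancing mode emulates selection *structurally*:
the two allelic classes are demes of size N·p and N·(1−p) exchanging no
migrants until their join at T_b (default mapped from 1.4 Myr at 25
yr/generation and N_ref = 10⁴), with a small ancestral deme closing the
genealogy so the sample TMRCA sits near T_b.  This reproduces exactly the
features the tests consume — deep clade divergence, diagnostic sites, an
intermediate-frequency excess — without forward simulation of selection
coefficients.  What it does not emulate: recombination between allelic
classes below the selected site's scale, sequencing error, recurrent
mutation, and any linkage to flanking loci; passing tests therefore
demonstrate estimator correctness under the model, not robustness to
those real-data complications.  Mutation rate defaults to 2·10⁻⁸ per bp
per generation, a conventional human point value giving realistic
polymorphism (~55 SNPs per locus) and divergence (~1% to the outgroup).

qPCR plates place standards at mix fractions spread over 0.1–0.9 with
Gaussian Ct noise (default sd 0.1 cycles); MFI tables are log-normal
(sd 0.15 on the log scale) with a 20% standardized-MFI reduction in BB
(half that in AB) and a 30% between-experiment shift — effect sizes of
the magnitude visible in the motivating data's boxplots.

## Problem sizes in the test and acceptance suites

Type-I calibration uses the constant-size null at 20 chromosomes with a
5,000-draw bank and 2,000 evaluation replicates per statistic (rejection
within 3 binomial SE of 5%).  Detection power uses 40 balancing fixtures
at the full default design against one 47-region control panel, scored on
the pooled sample (Tajima's D > 0 and rank-test p < 0.05; the pooled
sample is the fixture-level detection target — per-population power at 30
chromosomes is real but not saturating).  rho-dating recovery uses 200
default fixtures.  Engine closed forms use 3,000–5,000 replicates.  These
sizes give Monte-Carlo errors comfortably inside the asserted bands while
keeping the default suite to about a minute on one core.

## Known limitations

* The scan's HKA partner is the pooled control set; no multi-locus HKA.
* Fixed differences stand in for divergence in HKA; the resulting bias is
  absorbed by fitting and calibration but the fitted T̂ is not a clean
  divergence-time estimate.
* The rho dating inherits the calibration biases noted above; its σ is
  the within-genealogy mutational error, not the full coalescent-time
  variance.
* The maximum-entropy donor tables are an external asset; offline
  installs fall back to the PWM scorer.
* Per-variant quality filtering requires caller-supplied scores; no
  base-calling or chromatogram QC is performed.
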