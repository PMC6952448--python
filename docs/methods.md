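# Methods

This note records the models, conventions, and numerical choices behind
`cyp2b11kit`, and what the synthetic-data generators do and do not emulate.

## Marker panel and coordinates

The panel is nine biallelic markers on the canine *CYP2B11* gene: one
5′-enhancer SNP (c.-489 G/A), one synonymous exon-7 SNP (c.966 G/A), and
seven 3′-UTR markers from c.1913 to c.2536. Two are multi-nucleotide
(the c.1913 TCA/TCCA insertion and the c.2137 TG/CA dinucleotide
substitution); both are kept as single biallelic loci keyed by their
first-nucleotide position rather than normalised to a minimal VCF
representation, because every downstream analysis (phasing, LD, allelic
imbalance) treats each as one marker. cDNA coordinates place the adenine
of the start codon at +1 (no position 0; upstream positions are negative);
genomic positions are 1-based assembly positions of the first nucleotide.
Genomic↔cDNA mapping is a table lookup over the loaded panel — no general
liftover is attempted or needed. When variants are applied to a sequence,
an explicit offset map records the insertion shifts, and all reporting
stays in reference-transcript coordinates.

A documentation quirk carried through unchanged: the marker at c.2536 is
occasionally referred to elsewhere as c.2636; the panel follows the
position table (c.2536, genomic 112833204).

## Allele frequencies

Frequencies are `k/n` over observed chromosomes, with missing genotypes
excluded pairwise per site (the denominator is the number of observed
chromosomes at that site). Confidence intervals are Wilson score intervals
(via `statsmodels`), chosen because they reproduce the published 2-decimal
bounds at extreme proportions — `(0.87–1.0)` for 26/26 and `(0.09–0.38)`
for 5/26 — which Clopper–Pearson does not. One published row prints
`(0.30–0.70)` for 13/26 where the Wilson interval is `(0.32–0.68)`; the
original interval software is unknown, and this package reports Wilson.
Known limitation: Wilson coverage oscillates with p at fixed n; at n=26
the exact coverage is 0.951 pooled over p ∈ {0.1, …, 0.9} but dips to
0.9245 at p = 0.5.

Percent values meant for display round half-up (so 63/360 = 17.5% prints
as 18%), matching the published tables. Rounding happens only at the
presentation layer.

## EM haplotype phasing

Phasing uses the classical EM algorithm for haplotype frequencies from
unphased multilocus genotypes: the model is multinomial over unordered
haplotype pairs with Hardy-Weinberg pairing, `P(h_i, h_j) = (2−δ_ij) f_i f_j`.
Per genotype, all compatible phase configurations are enumerated (2^(h−1)
unordered pairs for h heterozygous sites); missing alleles are marginalised
over both states with a uniform site prior. Identical genotype vectors are
collapsed into classes so cost scales with distinct genotypes.

Numerical choices: deterministic uniform initialisation over the compatible
haplotype universe (no seed), convergence when the largest frequency change
falls below 1e-8, cap of 10⁴ iterations (hitting the cap sets a
non-convergence flag instead of raising), and post-hoc pruning of
haplotypes below frequency 1/(4N) with renormalisation. The log-likelihood
is recorded every iteration and is non-decreasing by construction; the
tests assert it. Per-dog diplotypes are the posterior argmax over surviving
pairs, ties broken by lexicographic label pair. On a two-site panel the EM
fixed point matches a brute-force grid maximisation of the multinomial
likelihood over the frequency simplex (coarse 0.02 grid plus 0.001 local
refinement) to within 2e-3.

## Linkage disequilibrium

From a counted haplotype pool, `D = p_AB − p_A p_B` and
`r² = D²/(p_A q_A p_B q_B)` using variant-allele frequencies; a
monomorphic site yields an undefined-LD sentinel rather than an exception
(e.g. marker #8, fixed in the Greyhound pool). Displayed values are
round-half-up percent. In the 45-breed pool, markers #4 and #5 never
co-occur on a haplotype, giving r² ≈ 0.75% (displayed 1%); published
matrices show 0% there, an unresolved display-rounding difference in the
original LD software that this package does not imitate.

## Allelic imbalance and the mapping-bias correction

For heterozygous samples, the per-site variant:reference RNA depth ratio is
`(var + pc)/(ref + pc)` with pseudocount 0 by default (depths in this
setting are high; a zero denominator flags the site rather than being
smoothed) and a minimum total depth of 20 reads for inclusion (default;
the original depth filter is unstated). Raw RNA ratios are averaged within
the breed × diplotype group *first*, then divided elementwise by the
averaged DNA ratio of a genomic-sequencing cohort of the same diplotype —
that order matches the original procedure; per-sample correction before
averaging is available as an option. The correction is valid exactly
because the variant:reference mapping-efficiency ratio b is a property of
the alignment around the site and is therefore shared between RNA and DNA
reads: RNA ratios estimate ρb, DNA ratios estimate b, and the quotient
estimates ρ. Simulation confirms the estimator is unbiased to within 3 SE
over 1000 cohorts at every cell of a {0.1, 0.7, 1.0} × {0.5, 1.0, 2.0}
(ρ, b) grid at depth 500 with 6 samples per cohort.

Imbalance is called when the corrected ratio falls strictly below 0.3
(configurable). The threshold separates the near-silenced regime observed
for truncated transcripts (corrected ratios around 0.05–0.15) from the
mildly reduced regime (~0.7) that carries no truncation information.

## Transcript 3′-end inference

Evidence combines per-site imbalance calls with RT-PCR amplicon presence
calls over fixed cDNA regions. Lower-bound candidates (the transcript
extends at least this far): the positions of expressed/balanced
heterozygous sites and the 3′ primer coordinates of regions with strong
bands. Upper-bound candidates (the transcript has ended by here): the
3′-most reference base of the most-5′ imbalanced site, and the 3′ primer
coordinates of regions called weak *or* absent — a weak band means
full-length amplicons are depleted, so the dominant transcript form ends
within the amplicon, while absent means essentially none span it. The
interval is (max of lower bounds, min of upper bounds); with no upper
bound it collapses to the annotated reference end, and an upper bound 5′
of a lower bound produces an inconsistency report instead of an interval.

Because the imbalanced marker at c.2137 is a dinucleotide (TG/CA), its
3′-most reference base is c.2138; the inferred H2 interval is therefore
(c.1913, c.2138), which also resolves an off-by-one between c.2137 and
c.2138 appearing in different descriptions of the same bound. Band
strength ("weak" vs "absent") is visual input, not computed here.

## Reaction phenotyping

Specific rates are `metabolite / (time × catalyst)`. Hepatic extrapolation
multiplies each recombinant isoform's per-pmol rate by its average liver
microsomal abundance; the default abundance table is the 11-isoform
mass-spectrometry panel (2.8, 82, 11, 7.7, 79, 52, 1.8, 143, 72, 125,
3.8 pmol/mg for CYPs 1A1, 1A2, 2A13, 2A25, 2B11, 2C21, 2C41, 2D15, 2E1,
3A12, 3A26). Contribution fractions normalise the extrapolated rates to
sum to 1 and are invariant to rescaling all specific rates; percent-of-pool
requires an explicitly supplied pooled-microsome measurement and is never
inferred from the panel. Immunoblot protein values are relative units
(each blot scaled to its dimmest sample) and are never compared across
panels in absolute terms.

Statistics: Spearman correlation uses average ranks for ties, with an
exact permutation p-value (full enumeration of rank pairings) for n ≤ 9
and the t-approximation above; Mann-Whitney U is exact when both groups
have ≤ 8 observations and no ties, otherwise normal with tie and
continuity correction; Holm-Sidak step-down adjustment follows the
closed form `1 − (1 − p_(i))^(m − i + 1)` with monotonicity enforcement;
quartiles use linear interpolation (the original convention is unstated).
The exact-vs-approximate thresholds are configurable.

## Synthetic-data generators

The generators produce inputs with exactly the statistical structure the
analyses assume, which is what makes parameter-recovery tests meaningful —
and bounds what they show about real data.

- **Breed panels**: each dog's two haplotypes are i.i.d. draws from the
  breed's haplotype frequency vector (Hardy-Weinberg). Real purebred
  populations are inbred; simulated panels therefore understate
  homozygosity, and EM accuracy on them is an upper bound on real-panel
  accuracy. Default Greyhound frequencies are the discovery-pool values
  8/26, 13/26, 5/26 for H1/H2/H3.
- **Allelic depths**: DNA variant depth ~ Binomial(d, b/(1+b)), RNA
  variant depth ~ Binomial(d, ρb/(1+ρb)), with the bias b shared between
  tissues — the exact assumption under which DNA normalisation is valid.
  Defaults (depth 500, 6 samples per cohort, ρ = 0.1, b = 0.8) mirror the
  near-silenced H1/H2 regime. Real read data adds overdispersion,
  alignment artefacts, and genotyping error that the binomial model does
  not carry, so passing recovery tests demonstrates correctness of the
  estimator, not robustness to those artefacts.
- **Activity panels**: liver activity is an abundance-weighted sum of
  isoform intrinsic rates, with lognormal multiplicative jitter on
  abundances (mean 1 at any CV; enzyme abundances are positive and
  right-skewed) and optional independent lognormal readout noise. Protein
  content shares the jitter, which creates the protein–activity
  correlation the attribution analysis looks for.
- **UTR sequences**: uniform-random background, rejection-sampled until
  neither the reference nor the variant-applied sequence contains an
  accidental AATAAA, with motifs planted at stated positions and marker
  reference alleles embedded. Overlaps between motif windows and marker
  spans are rejected at generation time.

Reproducibility: one global integer seed; each generator derives an
independent stream from `(seed, generator-name)` via a seed sequence with
a CRC32 spawn key, so any module regenerates bit-identically in isolation.

## Scope of the replication fixtures

The genuine published inputs bundled with the package are the marker
table, the six discovery haplotypes with pool counts, and the per-breed
diplotype count table; every quantity derived from them (Wilson bounds,
LD percents, haplotype percents) is exact desk-scale arithmetic. The
reference mRNA sequence is not redistributable here, so polyadenylation
analyses run on a synthetic transcript (labelled synthetic in its
filenames and headers) with the canonical hexamer planted at the two
annotated positions and the real variant set applied; the scan and
motif-diff machinery is identical to what runs on a downloaded accession.
Problem sizes used by the test suite — 500 simulated dogs for phasing,
1000 cohorts per grid cell for the imbalance estimator, 500 panels for
attribution, 10⁴ replicates per proportion for interval coverage — were
chosen so each property is measured well inside its sampling error.
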