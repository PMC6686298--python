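# Methods

This note documents the models, numerical choices and deliberate
simplifications behind each stage of the pipeline, and what the synthetic
data do and do not establish about behaviour on real data.

## qPCR quantification

Each well is reduced to a window-of-linearity fit. The baseline is the mean
of the first `baseline_cycles` readings (default 3; pass 0 for
pre-corrected data) and is subtracted before log-transforming. Candidate
windows are contiguous runs of 4–6 cycles whose baseline-subtracted
fluorescence lies between 5% and 80% of the observed maximum; among rising
candidates the window maximising r² of log₁₀F against cycle wins, with ties
going to the earlier start and then the longer window, so the choice is
deterministic. Efficiency is 10^slope (≈2 for perfect doubling) and the
window intercept at cycle 0 estimates the initial template amount on the
fluorescence scale.

Fractional Ct values come from inverting the fitted line at a plate-common
threshold, the geometric mean of the fitted window-midpoint fluorescences
across wells; a threshold outside a well's window span is still invertible
but flags the Ct as extrapolated. The construct dilution series is
regressed by ordinary least squares (Ct on log₁₀ concentration, at least 4
points; a sub-3-decade span warns but proceeds; a non-negative slope is an
error). Relative expression inverts that regression in **base 10** — the
base must match the calibration's logarithm or the relative weights change;
decade dilution series make base 10 the only consistent choice. Because
expression is a ratio of these inverted terms, it is exactly invariant to
adding any constant to all Cts, and — as long as all wells on a plate share
one curve shape and efficiency — it is also insensitive to the estimator's
common biases, which cancel between sample wells and the construct.

Efficiency percentages use the (E−1)·100 convention, so perfect doubling is
100% and the published 75–125% band brackets it symmetrically. Duplicate QC
requires both wells inside the band and a duplicate Ct standard deviation
(ddof = 1) of at most 0.5 cycles; singletons and non-amplifying pairs fail
with explicit reason codes, and passing pairs contribute their mean Ct.

The outlier screen is a Tukey fence, Q1 − 1.5·IQR to Q3 + 1.5·IQR with
type-7 (linear-interpolation) quartiles, applied separately per opsin and
island × phenotype population; groups below 4 values are left unfiltered
with a warning. Two guards deserve mention. First, values within 0.005 of
the population median are never flagged: with near-constant populations the
fence collapses to the width of the quantification residue (about 10⁻³ on
the fraction scale) and would otherwise exclude fish on numerical noise.
Second, when an opsin is excluded for a fish, the fish's profile is
recomputed over its surviving opsins — numerically identical to
renormalising the surviving fractions, since the per-opsin weights are
unchanged.

## LWS genotyping

The three alleles are identified purely by residues 216, 230 and 275
(H: Y/A/C; P: F/T/I; M3: Y/T/I). The caller anchors a sequence by exact
forward-primer match (trying the reverse complement automatically), checks
that the primer-delimited span has exactly the reference length for its
dialect (any indel is a frame error), extracts the three codons at fixed
offsets, expands IUPAC ambiguity codes to concrete codons and translates
them. The evidence kept per site is the intersection of the expanded amino
acids with that site's diagnostic residues ({Y,F}, {A,T}, {C,I}). The
intersection matters: the C and I codons differ at two positions, so the
positionwise IUPAC encoding of a C/I double peak also expands to serine and
phenylalanine codons that no allele carries; a codon supporting *no*
diagnostic residue leaves an empty set and an "inconsistent" call. A
genotype is called when the observed sets equal the residue union of
exactly one of the six unordered allele pairs — the six unions are pairwise
distinct (asserted by an exhaustive test), so a match is unique, and
heterozygous calls require ambiguity at exactly the sites where the two
alleles differ. Anything else is surfaced as a status, never guessed.

The bundled reference amplicon is **synthetic**: it obeys every published
structural constraint (the printed primer pair, 498 bp genomic span with a
91 bp GT…AG intron, 407 bp cDNA dialect, in-frame diagnostic codons with
216/230 on exon 4 and 275 on exon 5) but its filler bases and codon
nucleotides (216 Y=TAT/F=TTT, 230 A=GCA/T=ACA, 275 C=TGC/I=ATC) are
stand-ins, fixed by a deterministic seed. The 240/167 exon split is
arbitrary (the true split is not published). Users with real data can
anchor on their own reference.

## Light environment

Replicate spectra are averaged per measurement day and days averaged with
equal weight; aggregation is permutation-invariant and requires matching
wavelength grids. The orange ratio integrates irradiance by the trapezoid
rule over the native grid with both band edges inclusive — numerator
550–700 nm, denominator 400–549 nm, the 549→550 gap contributing to
neither. On a flat 1 nm spectrum this yields 150/149, which pins down the
convention; the choice affects the third decimal of OR. A zero denominator
returns +inf with a structured warning rather than dropping the spectrum.
The spectral midpoint is the smallest wavelength at which the cumulative
integral reaches half the 400–700 nm total, linearly interpolated inside
the straddling interval.

OR-by-depth profiles carry an OLS line of OR on depth fitted over **all**
measured depths, used only below the deepest measurement (the most turbid
island's spectra stop at 4 m while fish are caught deeper). Between
measured depths OR is interpolated linearly, consistent with the linear
extrapolation model; above the shallowest depth the shallowest value is
used with a warning. The unmeasured island (Anchor) receives, at each depth
shared by the two clear-water islands (Makobe, Python), the median of their
ORs — for two values, their mean — flagged "median-estimated"; depths
present at only one of the two are omitted.

## Visual model

Pigment absorbance uses the Govardovskii A1 template: the alpha band
Sα = 1/(exp(A(a−x)) + exp(B(b−x)) + exp(C(c−x)) + D) with x = λmax/λ,
A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922, c = 1.104 and
a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940), plus the beta band
0.26·exp(−((λ−(189+0.315·λmax))/(−40.5+0.195·λmax))²). The peak value is
within 1% of unity. Chromophore is pure A1 throughout; A1/A2 mixtures have
never been measured in this genus and are out of scope.

Quantum catch first normalises the irradiance spectrum to unit trapezoid
integral over 400–700 nm, making Q_c a pure spectral-overlap measure:
invariant to overall intensity, comparable across depths, and not trivially
smaller in darker habitats. The published description says only
"normalized"; unit integral is this package's choice. Q_ci is then
N_i·∫I_norm·R_i dλ on the native grid; totals equal the sum of parts to
1e-12 and agree with a 10×-finer grid to better than 1e-6 on smooth
spectra.

LWS λmax follows genotype: homozygotes take their allele's value (H 559, P
544 nm), heterozygotes the median of the two (551.5 nm) — a single
intermediate template, not a mixture of two templates, matching the
published treatment. M3 has no published λmax; for λmax arithmetic an M3
allele is treated as P-valued (configurable), but visual-performance
rosters exclude non-canonical genotypes by default (see below), so this
default never invents a sensitivity in the headline comparison.

The transplant comparison restricts rosters to blue PP and red HH fish —
the canonical genotype of each colour class — which simultaneously drops
mismatched-genotype fish, heterozygotes and M3 carriers, mirroring the
headline analysis; a flag widens rosters to all called genotypes. The
frequency-weighted mean depth treats each captured fish as one frequency
unit (the arithmetic mean of roster capture depths). Every resident and
every same-colour immigrant is evaluated with its own expression and
genotype at that depth in the resident island's light, the spectrum
interpolated linearly between bracketing measured depths (clamped to the
nearest depth outside the measured range). Islands without spectra are
excluded as residents, with a logged reason, but their fish still travel as
immigrants.

## Statistical inference

Expression fractions are analysed with Gaussian identity-link linear models
fitted by least squares; the reported log-likelihood uses the ML variance
(RSS/n, floored at 1e-12 for degenerate fits). The family is a documented
choice — the published analysis reports chi-square LRTs from GLMs without
stating a family. Factors use treatment coding with the alphabetically
first level as reference (recorded in coefficient names), factors with
fewer than two observed levels are dropped with a warning, and
rank-deficient designs raise an error naming the aliased columns. drop1
respects marginality: an interaction must leave before its main effects;
the statistic is 2·Δ log-likelihood against a chi-square with the
difference in coefficient count. At the sample sizes involved the
chi-square reference is asymptotic; a null simulation (n = 60, 1000
replicates) puts the realised size near 0.05–0.07 at nominal 0.05, within
the expected finite-sample liberality of ML-variance LRTs.

Pairwise post-hoc contrasts replace the studentized-range (Tukey)
adjustment with a seeded max-statistic permutation test: observed pairwise
mean-difference t statistics (pooled within-group variance) are referred to
the permutation distribution of the maximum absolute statistic under label
shuffling, which controls the family-wise error rate without special
tables. Rows are canonically sorted before permuting, so results are
deterministic under a fixed seed and invariant to input row order; adjusted
p-values live in [1/(n_perm+1), 1] with n_perm ≥ 999.

## Synthetic data

The generators define the study conditions. Light: a broad daylight-like
surface spectrum attenuated as I₀(λ)·exp(−K(λ)z) with K(λ) = k_base +
k_turb·exp(−(λ−400)/τ) + k_red·exp((λ−700)/57). The turbidity term decays
with wavelength (suspended/dissolved matter absorbs blue), ordered Luanso >
Kissenda ≈ Python > Anchor > Makobe along the real transect; the red term
is water's own long-wavelength absorption, identical everywhere. Turbidity
dominates (k_turb 0.55 down to 0.15 per metre against k_base 0.08), so the
orange ratio rises strictly with depth at every island, as observed in the
lake. Spectra are produced as field campaigns: 2–4 sampling days per
island, at least two replicate scans per depth on a 0.5 m grid, optional
lognormal scan noise. Anchor is generated without field spectra, matching
the study design.

Amplification curves are F(c) = plateau·u/(1+u^s)^(1/s) + baseline with
u = (N0/plateau)·E^c: exactly N0·E^c early, bending into the plateau over
about one cycle at the default knee sharpness s = 4. The sharpness matters:
real qPCR traces hold log-linearity over several decades, and a plain
logistic knee (s = 1) bends a full decade below the plateau, which would
bias window-fitted efficiencies low by 10–30% and defeat the 75–125% QC
band by construction. Plates carry duplicate sample wells, a duplicate
6-point decade construct series (10⁻⁵…10⁻¹⁰), 50 cycles, and optional
labelled QC failures (efficiency degraded to 0.75·E; second replicate
advanced 1.5 cycles for a Ct-SD failure). Identical seeds give
byte-identical plates.

Scenario bundles mirror the field collection: 112 males across five
islands (29/28/22/11/22), blue fish shallow (~1–2 m), red deeper
(truncated normals, floor 0.5 m), overlapping and undifferentiated at
Luanso (including a few intermediates), genotype frequencies following the
observed pattern (blue ~PP, red ~HH where differentiated, all PP at Luanso,
M3 replacing H in Anchor reds). In **adaptive** mode each population gets
the expression profile maximising its total quantum catch at its own
roster mean depth in its own light, searched on a 0.05-step simplex grid
floored at 0.05 per opsin; because quantum catch is linear in expression,
the unconstrained optimum is always a single-opsin corner — itself a neat
illustration of why raw quantum catch is a crude adaptive objective — and
the floor both keeps profiles biologically shaped and guarantees at least
two amplifying opsins per fish. Optimising at exactly the depth the
transplant evaluation uses makes "residents ≥ same-colour immigrants"
exact by construction. In **decoupled** mode every fish receives
logistic-normal jitter (σ = 0.08) around one shared profile (LWS 0.76,
RH2A 0.14, SWS2a 0.08, SWS2b 0.02 — the typical Lake Victoria pattern),
independent of island, so no systematic resident advantage exists and
roughly 95% of resident-immigrant mean differences fall within 2 SE. A
single master seed fans out via `SeedSequence.spawn` to independent child
streams, so each component is reproducible on its own.

What passing these tests shows — and does not. The synthetic world has
exponential attenuation, a single smooth surface spectrum, identical curve
shape and efficiency across wells of a plate, no inter-plate batch effects,
no chromatogram-level sequencing noise, and expression variation that is
either zero (adaptive) or exchangeable across islands (decoupled). Recovery
and calibration results therefore validate the estimators' correctness and
the pipeline's plumbing, not robustness to optics drift, inhibition,
inter-run chemistry differences or allele dropout in real material.

## Problem sizes and tolerances

Default verification sizes: 100 seeded noisy plates for expression
recovery (worst absolute error ≈ 0.002 against a 0.05 bound), 50 seeded
decoupled replicates (~1100 resident–immigrant comparisons) for the null
transplant contrast, 1000 replicates at n = 60 for LRT size, 999
permutations for contrasts. Numeric tolerances: profile sums to 1 ± 1e-9;
shift invariance and Q_c linearity to 1e-12; trapezoid-vs-fine-grid to
1e-6; table round-trips exact to the shortest float representation (the
reader parses with round-trip precision). End-to-end, recovered expression
fractions are accurate to about 10⁻³ (window discretisation on the integer
cycle grid), which is the resolution used when comparing tied transplant
groups through the full pipeline.

## Known limitations

No chromatogram parsing (inputs are base-called sequences), no A2
chromophore or ocular-media corrections, no receptor-noise discrimination
modelling, no mixed-effects or non-Gaussian models beyond an optional logit
transform, no multi-plate normalisation, and the exact published test
statistics are not reproducible without the field data — the package
reproduces the *procedures* and their construction-level guarantees.
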