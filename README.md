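# pundavision

Visual-ecology analysis for *Pundamilia* cichlids of Lake Victoria: from raw
qPCR amplification curves, Sanger-style LWS amplicon sequences and
depth-resolved underwater irradiance spectra to relative cone-opsin
expression profiles, LWS genotypes, orange-ratio light metrics and
quantum-catch comparisons of residents against hypothetical immigrants.

It is written for sensory/visual ecologists who want a tested, reusable and
fully synthetic-data-verifiable version of this analysis chain: every stage
can be exercised on generated inputs with known ground truth, without any
field data.

## What it computes

**Relative opsin expression.** Each well's amplification curve is fitted in
its window of linearity: the contiguous 4–6-cycle stretch of
baseline-subtracted, log-linear fluorescence, giving a per-well efficiency
*E* = 10^slope and a fractional threshold cycle *Ct*. A serially diluted
multi-opsin construct on the same plate calibrates *Ct* against log₁₀
concentration (slope *m*, intercept *b*), and expression of opsin *i*
relative to all measured opsins is

```
N_i / N_all = 10^((Ct_i − b)/m) / Σ_j 10^((Ct_j − b)/m)
```

Duplicates must agree (efficiency 75–125% on the (E−1)·100 scale, Ct SD
≤ 0.5) and profiles are screened per opsin × population with a 1.5 × IQR
fence.

**LWS genotype.** The three *Pundamilia* LWS alleles differ at residues
216/230/275 (H: Y/A/C, P: F/T/I, M3: Y/T/I). Diagnostic codons are read at
fixed offsets from the forward-primer anchor of the exon-4/5 amplicon
(gDNA and cDNA dialects, either strand); IUPAC ambiguity codes — Sanger
double peaks — are expanded and the per-site residue sets matched against
the residue unions of all six unordered allele pairs.

**Light environment.** The orange ratio OR = ∫₅₅₀–₇₀₀ I dλ / ∫₄₀₀–₅₄₉ I dλ
summarises how red-shifted a habitat is; profiles of OR against depth are
built per island, with a median rule for the unmeasured island (Anchor) and
linear-regression extrapolation below the deepest measurement.

**Visual performance.** Quantum catch per opsin,
Q_ci = N_i ∫₄₀₀–₇₀₀ I(λ) R(λ; λmax_i) dλ, uses Govardovskii A1 templates
with λmax 425/455/528 nm for SWS2b/SWS2a/RH2A and genotype-dependent LWS
(H 559, P 544, H/P heterozygote 551.5 nm). The transplant comparison
evaluates every resident and every same-colour immigrant at the resident
group's frequency-weighted mean depth in the resident island's light.

**Inference.** Gaussian linear models (`expression ~ species * island + OR
+ genotype`) with drop1 likelihood-ratio tests, and family-wise corrected
pairwise contrasts via a seeded max-statistic permutation test.

## Worked example

```python
import numpy as np
from pundavision import qpcr_quant as q, synthetic_data as sd
from pundavision import light_env as le, visual_model as vm

# a qPCR plate with known template amounts, 0.5% noise
plate, truth = sd.generate_plate(
    {"fish01": {"SWS2b": 2e-9, "SWS2a": 8e-9, "RH2A": 1.4e-8, "LWS": 7.6e-8}},
    efficiency=2.0, noise_sigma=0.005, seed=1,
)
expression, qc_report = q.quantify_plate(plate)
print(expression.round(4).to_string(index=False))

wl = np.arange(400.0, 701.0)
irr = sd.model_spectrum(sd.DEFAULT_LIGHT_PARAMS["Makobe"], 2.0, wl)
print(f"orange ratio at 2 m: {le.orange_ratio(wl, irr):.4f}")

profile = expression.iloc[0][["SWS2b", "SWS2a", "RH2A", "LWS"]].to_dict()
catch = vm.quantum_catch(profile, vm.lws_lambda_max("HP"), wl, irr)
print(f"total quantum catch (H/P heterozygote, 551.5 nm): {catch.total:.4f}")
```

prints

```
fish_id  SWS2b  SWS2a   RH2A    LWS  n_passing_opsins
 fish01   0.02 0.0799 0.1405 0.7595                 4
orange ratio at 2 m: 1.0312
total quantum catch (H/P heterozygote, 551.5 nm): 0.4396
```

The recovered fractions match the planted truth (0.02/0.08/0.14/0.76) to
about a part in a thousand; the orange ratio exceeds 1 because 2 m of
moderately clear water has already stripped more short- than long-wavelength
light; the quantum catch is the fraction of the (unit-normalised) spectrum
the fish's pigment complement captures.

A whole synthetic study — metadata, spectra, plates, sequences, truth
tables — and the full pipeline over it:

```bash
pundavision simulate --mode adaptive --seed 1 --out study/
pundavision run --out study_results/ study/
```

`study_results/` then holds `expression.tsv`, `qc_report.tsv`,
`genotypes.tsv`, `allele_freqs.tsv`, `or_profiles.tsv`, `fish_or.tsv`,
`quantum_catch.tsv`, `transplant.tsv`, `lrt_results.tsv` and
`contrasts.tsv`, each stamped with the pipeline version and config hash.

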