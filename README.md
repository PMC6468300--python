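# screensig

Tools for three linked analyses in the transcriptional regulation of
tissue-restricted genes:

1. **Arrayed perturbation screens read out by molecular counting.** A few
   dozen tissue-restricted genes (testis-, placenta-specific, …) are measured
   by nCounter-style probe counts across hundreds of wells, each perturbed by
   one activated kinase or one siRNA pool. The question is which single
   perturbations cause *illegitimate expression* — turning on a gene in cells
   where it is normally silent.
2. **Inhibitor-dependence gene signatures.** From a three-condition
   expression experiment (control / treated / treated + kinase inhibitor),
   partition treatment-responsive genes into inhibitor-independent,
   inhibitor-potentiated, and inhibitor-dependent classes; the dependent
   class is the kinase-activity signature.
3. **Signature activation scoring in tumor cohorts.** Score each tumor for
   signature activation relative to normal tissue, stratify tumors by a
   marker gene's expression deciles, cluster, and test score/marker
   correlations against a random-signature null with a Gumbel tail fit.

A synthetic-data module generates screens, three-condition experiments and
tumor/normal cohorts with known ground truth, so the whole pipeline is
testable without any external download.

## Methods in brief

**Screen hit calling.** Raw counts are rescaled per sample by the positive
spike ladder and then by housekeeping genes; both factors are
(mean of per-sample geometric means) / (this sample's geometric mean). For
each probe, log2(normalized + 1) values are standardized across *all* samples
of a screen arm (controls included): z = (x − x̄)/s with the n−1 sample SD. A
probe/perturbation pair is a hit when z exceeds 2.5 (and, more stringently,
3.5); one-tailed normal tails convert z to p (z = 3.12 → p = 9.0 × 10⁻⁴).
A per-probe Shapiro–Wilk flag records that not every probe's distribution is
normal; negative-control background (mean + 2 SD) is reported but never
subtracted.

**Signature derivation.** Per-gene fold change and two-sided Welch-t p-value
for treated vs control and treated+inhibitor vs control; responsive means
fc > 1.5 and p < 0.05. Responsive genes are *dependent* when the +inhibitor
contrast fails the same criterion, *repressed* when fc ratio ≥ 1.5,
*independent* otherwise — a disjoint, exhaustive partition.

**Cohort scoring.** Median-of-ratios size factors (the DESeq2 scheme)
normalize library depth. The activation score of tumor t is
Σ_g log2((x_gt + 1)/(x̄_g,normal + 1)) over signature genes g. Tumors are
stratified into first/last ⌈n/10⌉ deciles of a marker's expression; Ward
(squared-Euclidean) clustering on signature genes is compared to the strata
by adjusted Rand index. Significance of a score/marker Pearson correlation is
assessed against k-gene random signatures: a Gumbel(μ, β) is fitted to the
null correlations by method of moments (β̂ = s√6/π, μ̂ = m − γβ̂) and the
upper-tail p = 1 − exp(−exp(−(r − μ̂)/β̂)) is reported.

## Worked example

```python
import numpy as np
import screensig as ss
from screensig.cohort import MedianOfRatiosNormalizer, random_signature_null

# --- screen: 42 probes x (160 perturbations + 12 controls), 3 planted hits
raw, truth = ss.generate_screen(seed=1)
norm = ss.normalize_counts(raw)
hits = ss.call_hits(norm, raw.design, annotation=raw.annotation)
print(hits.sort_values("z", ascending=False)
          .head(3)[["probe_id", "perturbation_id", "z"]])

# --- cohort: 3000 genes, 112 normals, 500 tumors, planted 190-gene signature
counts, design, ct, sig = ss.generate_cohort(seed=1)
nm = MedianOfRatiosNormalizer().fit(counts).transform(counts)
tumors = design.index[design.group == "tumor"]
normals = design.index[design.group == "normal"]
scores = ss.activation_score(nm, sig, normals, tumors)
print("r(score, latent):", np.corrcoef(scores, ct.activation)[0, 1])
null = random_signature_null(nm, sig, ct.target_gene, normals, tumors,
                             seed=1, exclude=list(sig))
print("null p:", null.p_value)
```

prints

```
probe_id perturbation_id        z
   TRG07           si106 5.136848
   TRG25           si118 5.062555
   TRG01           si093 3.885648
r(score, latent): 0.999
null p: 6.70e-21
```

The three top-z pairs are exactly the three planted 8-fold inductions
(`truth.planted_hits`), each well above the 3.5σ threshold; the activation
score tracks the latent per-tumor activation almost perfectly, and no random
190-gene signature approaches the true signature's correlation with the
coupled marker (Gumbel tail p ≈ 7 × 10⁻²¹).

The same stages are available as a CLI:

```bash
screensig simulate-screen --seed 7 --out sim/
screensig screen-hits --counts sim/counts.tsv --annotation sim/annotation.tsv \
    --design sim/design.tsv --out out/
screensig simulate-expression --seed 7 --out expr/
screensig derive-signature --expression expr/expression.tsv --design expr/design.tsv --out sig/
screensig simulate-cohort --seed 7 --out cohort/
screensig score-cohort --counts cohort/counts.tsv --design cohort/design.tsv \
    --signature cohort/signature.gmt --target-gene $(python -c \
    "import json; print(json.load(open('cohort/truth.json'))['target_gene'])") \
    --out scored/
```

Every stage writes TSV tables plus a JSON audit record (version, config echo
and hash, seed); equal seed and config reruns are byte-identical.

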