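# Methods

## Scope and assumptions

The index models "PPI-modulator likeness" purely from the marginal
distributions of seven 2D physicochemical properties of a reference
compound collection. It assumes those marginals are unimodal and
right-skewed (which PPI-modulator collections empirically are), and it
deliberately ignores everything else: 3D conformation, structural alerts,
target identity, and cross-property correlations. Structural-alert and
PAINS screening are operational filters to be applied alongside the score,
never terms inside it — alert-poor reference collections would otherwise
bias the model.

## Descriptors

All eight descriptors (the seven modeled properties plus the total SSSR
ring count used only by the rule-of-four) are RDKit defaults: exact
(monoisotopic) molecular weight, Wildman–Crippen logP, default HBD/HBA
definitions (not Lipinski N+O counts), TPSA, the non-strict rotatable-bond
count, and aromatic/total ring counts. One convention is used consistently
for fitting and scoring; a model JSON records it in
`descriptor_convention`. Molecules are standardized first — largest
covalent fragment by heavy-atom count (ties: molecular weight, then
canonical SMILES), sanitized, re-canonicalized — so a given structure
always maps to one property vector.

## Curation

Deduplication is by standard InChI (default options), first occurrence
kept. Clustering uses Bemis–Murcko atomic frameworks; all acyclic molecules
(empty framework) share one cluster. Each cluster contributes its
highest-activity member, with activities read on a higher-is-better scale
(convert concentrations to negative logs before loading); missing
activities rank below any value and ties fall back to the lexicographically
smallest id, making the curated set reproducible byte for byte.

## ADS fitting

Histograms: integer properties get unit bins centered on 0..max;
continuous properties get fixed widths (MW 25 Da, ALogP 0.5, TPSA 10 Å² by
default, configurable) spanning the data range — chosen to give roughly
20–40 bins on typical modeling collections. Fitted peaks are mildly
binning-sensitive, which is why the widths are exposed.

Raw counts (not densities) are fitted; the subsequent normalization makes
the two equivalent up to scale. The fit is Levenberg–Marquardt least
squares with slopes parameterized as log e, log f (positivity by
construction), initialized at a = 0, b = max count, c = modal bin center,
d = interquartile range, e = f = range/10, with four additional
deterministically jittered starts; the best residual norm wins. Fewer than
30 values or fewer than 6 populated bins is a hard error rather than a
meaningless fit.

Normalization locates the maximum of Q numerically (no closed form): a
2001-point grid over the data range extended by 10% on each side, refined
by bounded scalar minimization between the neighboring grid points.
Desirabilities are clamped to [ε, 1] with ε = 1e−6 so the geometric mean's
logarithm stays finite; ε is configurable and recorded in the model.

## Weight search

The grid {0, 0.25, 0.5, 0.75, 1}⁷ minus the all-zero tuple (the score
divides by Σw) gives 78,124 combinations, enumerated lexicographically.
The Shannon entropy −Σₖ sₖ log₂ sₖ is computed literally over the raw
per-compound scores — they are not renormalized into a probability
distribution. Per-compound log-desirabilities are computed once and each
combination's scores are a single matrix product, chunked so the search
over ~1,000 compounds takes seconds on one CPU. Sorting is stable on
descending entropy, so entropy ties at the top-k boundary resolve in
lexicographic weight order; the final weights are the element-wise mean of
the top 1000 combinations.

## Scoring and classification conventions

The score is evaluated in the log domain,
exp(Σ wᵢ ln dᵢ / Σ wᵢ), making it invariant to rescaling all weights and
strictly increasing in every desirability with positive weight. Rule-of-four
thresholds are strict inequalities: MW exactly 400 (or ALogP/HBA/rings
exactly 4) counts as a violation. Classification treats score ≥ threshold
as predicted positive; the inclusive convention is stated in every
evaluation output. Undefined ratios (0/0) are reported as missing, never
as 0.

ROC curves sweep every distinct observed score plus a sentinel above the
maximum; with trapezoidal integration this makes the AUC equal the
Mann–Whitney statistic with ties counted half. Precision–recall curves use
the same sweep; their AUC is the trapezoid over recall with an implicit
anchor at recall 0 carrying the first point's precision (average-precision
interpolation would be a defensible alternative and gives slightly
different values). The F-maximizing threshold scan considers exactly the
distinct observed scores, returning the smallest maximizer on ties.

## Synthetic data

The generators emulate the statistical shape the method assumes, not real
chemistry:

* **Property populations** — each property is drawn independently from a
  lognormal parameterized by its target mode (defaults: the
  PPI-modulator-characteristic peaks 492.7 Da, 4.78, 1.61, 4.79, 76.9 Å²,
  6.37, 2.8) and a log-scale spread; integer properties are rounded, and
  the total ring count adds an independent Poisson(1) count of aliphatic
  rings to the aromatic count. The "negative" population scales every mode
  by (1 − shift). The default shift 0.4 mirrors the observed mode ratios
  between PPI-modulator and oral-drug collections (e.g. 305.8/492.7 ≈
  0.62 for MW).
* **ADS histograms** — Poisson counts (or exact expectations) around a
  known ADS curve scaled to a target total, the parameter-recovery harness
  for the fitter.
* **SMILES collections** — a hand-picked ~50-molecule set (salts,
  duplicate spellings, acyclic molecules) for curation tests, and a
  combinatorial generator (alkyl chains × linked phenyls × hydroxyl runs ×
  polar tails) whose property ranges are broad enough to fit a complete
  model, used by the end-to-end CLI tests.

Because properties are sampled independently, the synthetic mirror lacks
the cross-property correlations of real collections, and the unimodal
desirabilities penalize both flanks of each wide synthetic marginal. At
the realistic shift 0.4 the fitted index separates the two populations
with ROC AUC ≈ 0.65; the end-to-end separation experiment therefore uses
a large shift of 0.6, where the AUC is ≈ 0.96–0.97 across seeds — the
check demonstrates that the fitted index orders strongly shifted
populations correctly, not that it reproduces real-data enrichment, which
depends on correlated properties the generator does not model.

Problem sizes in the test suite and the acceptance script — 600 compounds
per population, 250-molecule modeling sets, histograms of 1,000–2,000
counts, 20 recovery seeds — keep every fit well-conditioned while the full
suite runs in well under a minute; the weight search always scans the full
78,124-combination grid.

## Known limitations

* Fitted peaks (and hence scores near the flanks) move slightly with the
  histogram binning; compare models only with identical bin widths.
* The ADS family is single-peaked: genuinely multimodal property
  distributions will be summarized by whichever mode dominates the fit.
* The entropy criterion selects weights for score spread, not for
  discriminating any particular negative class; weights therefore need no
  negative data but are also not optimized for classification.
* QED is consumed from RDKit's published parameterization as a comparison
  axis; this package does not refit it.
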