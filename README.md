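# qeppi

A quantitative estimate index for compounds targeting protein–protein
interactions (PPIs), for early-stage virtual screening.

Classical drug-likeness filters and scores are calibrated on oral drugs;
PPI modulators are systematically larger, more lipophilic and more
acceptor-rich, so those filters reject exactly the chemical matter a PPI
screening campaign is looking for. QEPPI transplants the desirability-based
QED construction onto a curated PPI-modulator compound collection: it turns
"looks like the compounds known to modulate PPIs" into a continuous score in
(0, 1], usable as a ranking function, an adjustable-threshold filter, or a
reward term in generative molecular design. The package is aimed at
cheminformaticians and computational chemists running early hit-finding
against PPI targets.

## The model

For each of seven physicochemical properties
*i* ∈ {MW, ALogP, HBD, HBA, TPSA, ROTB, AROM} — exact molecular weight,
Wildman–Crippen logP, H-bond donors and acceptors, topological polar surface
area, rotatable bonds, aromatic rings — a histogram of the modeling
collection is fitted with an asymmetric double sigmoid (ADS)

    Q(x) = a + b · σ((x − c + d/2)/e) · [1 − σ((x − c − d/2)/f)],

where σ is the logistic function and e, f > 0 are independent flank slopes.
Each fitted curve, normalized to a maximum of 1, is the desirability
function d̃ᵢ(x). A compound k with property values xᵢ scores

    QEPPIₖ = exp( Σᵢ wᵢ ln d̃ᵢ(xᵢ) / Σᵢ wᵢ ),

the weighted geometric mean of its desirabilities. The weights wᵢ are chosen
by exhaustive grid search over {0, 0.25, 0.5, 0.75, 1}⁷ (the all-zero tuple
excluded), maximizing the Shannon entropy H = −Σₖ QEPPIₖ log₂ QEPPIₖ of the
modeling-set score distribution; the final weight vector is the element-wise
mean of the 1000 highest-entropy combinations.

The package also implements:

* **curation** — salt stripping, InChI deduplication, Bemis–Murcko scaffold
  clustering and best-activity representative selection, to build a
  non-redundant modeling set from a raw export;
* **the rule-of-four (RO4)** — the rule-based PPI-inhibitor filter
  (MW > 400, ALogP > 4, HBA > 4, rings > 4, judged by violations), which the
  continuous index generalizes;
* **evaluation** — confusion matrices, precision/recall/F-score, ROC and
  precision–recall curves with trapezoidal AUC, and the F-score-maximizing
  threshold scan (score ≥ threshold predicts positive);
* **synthetic fixtures** — generators for ADS-shaped histograms and
  two-population property sets, so the whole pipeline is testable offline.

## Worked example

Fit a model on a compound table (CSV with a `smiles` column) and score
molecules:

```sh
qeppi fit modeling.csv -o model.json --seed 1
qeppi score probes.smi --model model.json -o scores.csv
```

On the packaged synthetic modeling collection
(`qeppi.fixtures.synthetic_modeling_smiles(250, seed=0)`) this prints

```
fit: 250 compounds
peaks: MW=581, ALogP=6.93, HBD=3.6, HBA=3.04, TPSA=19.5, ROTB=11.5, AROM=6.81
weights: MW=0.21, ALogP=0.59, HBD=0.43, HBA=0.90, TPSA=0.06, ROTB=0.51, AROM=0.04
```

— the fitted peak of each desirability function (the property value the
collection finds most typical, where d̃ᵢ = 1) and the entropy-selected
weights. Scoring three probe molecules gives

```
      id  QEPPI   QED  QED_inv  RO4_violations
 aspirin  0.664 0.550    0.450               4
diazepam  0.507 0.571    0.429               3
 ethanol  0.341 0.407    0.593               4
```

QEPPI is the index itself; QED is the oral-drug analogue (computed with
RDKit's published parameterization) and QED_inv = 1 − QED its inversion;
RO4_violations counts how many of the four rule criteria the molecule
fails. Against this deliberately large-and-aromatic modeling collection,
aspirin-sized molecules score mid-range and ethanol scores low — the score
tracks closeness to the modeled property peaks, not general drug-likeness.

Evaluating any score against labeled positives and negatives:

```sh
qeppi evaluate --pos pos_scores.csv --neg neg_scores.csv -o metrics.json
qeppi evaluate --confusion 163 239 158 1357 -o ro4_metrics.json   # metrics-only mode
```

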