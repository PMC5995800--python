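# Methods

`iopqsar` reimplements, as a tested pipeline, a QSAR workflow that links
the chemical structure of fused benzimidazole derivatives (imidazo- and
pyrimido-benzimidazoles) to their intraocular-pressure (IOP) lowering
activity via their systemic hypotensive activity. The workflow has five
stages: fragment-pair descriptor generation, hypergeometric pharmacophore
enrichment, 2-means activity classing, an ED20-based potency scale, and an
ensemble of two-layer perceptrons validated by Spearman rank correlation.
This note records the models, the conventions chosen where the published
description is silent, and what the synthetic benchmarks do and do not
demonstrate.

## Fragment-pair descriptors

Each molecule (SMILES or SDF V2000; multi-fragment records are rejected)
is reduced to *descriptor keys* with four slots:

* **SD1, SD2** — structure tokens for atom environments or rings,
* **LD** — topological length: shortest-path bond count between the two
  sites (0 is reserved for a site paired with itself or its own ring),
* **BD** — a bond-path code classifying the bonds along one canonical
  shortest path.

Any non-empty slot subset is itself a descriptor; projected keys inherit
the counts of the full quadruples they project from, and the degenerate
`{SD1}` family counts one bare token per site (heavy atom or ring).
Aromaticity and smallest-set-of-smallest-rings perception come from RDKit;
hydrogens are implicit and appear only inside tokens (`-CH3`, `-OH`,
`=NH`). Tokens are assigned by ordered rules on (element, charge,
aromaticity, H count, bond-order multiset); the vocabulary covers the
symbols that appear in the published pharmacophore tables for this series
(`-CH3`, `>C(<)`, `>C=`, `-C(Ar)<`, `-N<`, `-N=`, `>N+=`, `=NH`, `-OH`,
`>O`, `=O`, `>S`, `-Cl`, `>PH<`), and anything outside it falls back to a
generated `El(pattern)` token so tokenization is total. Rings are
`CycNN`/`CycArNN` (e.g. `Cyc06`, `CycAr06`); a ring participates in pair
descriptors through its atom set, its distance to another site being the
minimum over its atoms, with smallest-index atoms as tie-broken endpoints.

The original descriptor language is proprietary and not published, so the
bond-path codes here are a *declared dialect*, not a recovered one:

| code | meaning |
|------|---------|
| `...` | all single bonds, no aromatic atom on the path |
| `.A.` | every bond on the path aromatic (through an aromatic ring) |
| `.a.` | mixed aromatic/non-aromatic bonds, or single bonds touching an aromatic atom |
| `p..` | contains a non-aromatic double/triple bond, no aromatic atom |
| `pA.` | contains a non-aromatic double/triple bond and an aromatic atom |

The canonical path is the lexicographically smallest shortest atom-index
path, which makes the code deterministic and invariant to input atom
order; symmetric keys are stored with the lexicographically smaller token
first. On molecules with few heavy atoms the enumeration is verified
against an independent networkx-based all-pairs enumerator.

The packaged transcriptions of the published presence/absence tables keep
the 0/1 digit that follows each printed bond code (e.g. `...1`, `.A.1`)
as part of the BD token — the printed columns are run together in the
source and only the Pa/Pi/Pr columns enter any quantitative check.

## Enrichment statistics

For every key, `pa` and `pi` are its frequencies in the active and
inactive classes, and `pr` is a one-sided hypergeometric tail probability
for the observed imbalance, computed from log-gamma binomial coefficients
and `logsumexp` (exact to ~1e-14; verified against exhaustive draw
enumeration for pooled sizes up to 12). The decision rule is the published
one: presence if `pr <= 0.05` and `pa > pi`; absence if `pr <= 0.05` and
`pi > pa`; neutral otherwise, ties included. The test direction follows
the sign of `pa - pi`, and no multiplicity correction is applied by
default (matching the published analysis; Benjamini–Hochberg is available
as an option).

Two urns are implemented because the original software's choice is not
documented. **Occurrence mode** (default) pools descriptor *instances*:
`pa` is the key's share of the active class's instance total. This matches
the granularity of the published frequencies (values like 0.0094 are not
multiples of 1/9 or 1/18, the class sizes of the studied series).
**Compound mode** counts compounds containing the key. The two differ
statistically: only in compound mode is the hypergeometric model identical
to the compound-label permutation distribution. In occurrence mode a
compound's many instances are correlated, so under compound-label
permutation the instance-level test is anti-conservative (we measure a
per-key null hit rate of roughly 0.14 instead of 0.05 at the default
benchmark conditions). Calibration checks therefore use compound mode,
while screening defaults to occurrence mode for fidelity to the published
frequency scale; hits from occurrence-mode screens should be read as a
ranking, not as calibrated p-values.

## Potency scale and activity classing

ED20 — the dose lowering systemic arterial pressure by 20% — maps to an
ordinal Index with left-open/right-closed intervals: 3 points for
ED20 ≤ 4.0 mg/kg, 2 for (4.0, 10.0], 1 for (10.0, 25.0], 0 above
25.0 mg/kg. This boundary convention reproduces all 27 published
(ED20, Index) pairs and the bendazole reference (18.8 mg/kg → Index 1).
Dose conversion is `umol/kg = mg/kg / MW * 1000`.

The binary IOP class comes from 2-means clustering of a compounds × 6
matrix of IOP-lowering indicators. The six indicators' identities are not
published, so they are treated as opaque numeric columns and z-scored
before clustering (their scales are unknown and possibly heterogeneous).
Lloyd-style k-means (scikit-learn, `algorithm="lloyd"`, random
initialization) keeps the best of 50 restarts by within-cluster sum of
squares; the seed is mandatory. The cluster whose members have the larger
mean raw indicator value is labelled active (1). All-identical rows are an
error. On small inputs the partition is checked against an exhaustive
minimum-WCSS search.

## Perceptron ensemble

The QSAR model maps four hypotensive predictors — ED20 (mg/kg), Index,
ED20 (umol/kg), Level — to two output units (active / inactive class),
through one hidden layer. The training protocol reconstructs the stated
automatic search: 1000 networks with 3–10 hidden units; hidden activation
from {identity, logistic, tanh, exponential, sine}, output additionally
allowing softmax; each network gets its own seeded stratified 80/20 split
and initialization; the top 50 by test accuracy are retained and the top-1
selected. Ties break by train accuracy, then fewer hidden units, then
sampling order. The original tool's optimizer and loss are proprietary, so
this package uses full-batch L-BFGS with analytic gradients; the loss is
categorical cross-entropy for softmax outputs and mean sum-of-squares
against one-hot targets otherwise. `exponential` is `exp(x)` with inputs
clipped at ±30 (zero gradient in the clipped region); inputs are z-scored
with statistics from the training split only. Splits are stratified rather
than fully random because at n = 27 (9 active / 18 inactive) an
unstratified 20% test set is frequently single-class; this is a documented
deviation. Everything derives from one master seed, so an ensemble is
bit-reproducible; models serialize to JSON and reload to bit-identical
forward passes.

Selection bias matters at this sample size: the maximum of 1000 test
accuracies on a ~6–12 row test set is optimistic even under the null, so
"at chance under no link" is assessed on the ensemble's *median* test
accuracy (central band of Binomial(n_test, 0.5)), and honest generalization
claims require fresh data, not the selected model's own test score.

## Validation

Spearman's rho is the Pearson correlation of average-ranked values (ties:
average ranks), equal to `1 − 6Σd²/(n(n²−1))` in the tie-free case and
checked to 1e−12 against a rank-then-Pearson oracle and `scipy`'s
implementation. It is undefined (an error) when either vector has zero
rank variance, and no p-value is attached by default. Confusion
diagnostics report TP/FP/TN/FN, accuracy, sensitivity (w.r.t. the active
class) and specificity; rho is computed against predicted probabilities by
default, hard labels being the alternative.

## Synthetic benchmarks

No raw structures or indicator matrices are published for the studied
series, so the generators plant known signal:

* **Library**: cores drawn from a small grammar of benzimidazole-like
  scaffolds, decorated with 0–2 class-neutral substituents; each planted
  fragment (default: a methylthio group, `SC`, rates 0.8 active / 0.1
  inactive, 30 + 30 compounds) attaches independently at aromatic CH
  positions with its class-specific probability; invalid assemblies are
  resampled with bounded retries.
* **IOP matrix**: 6 columns, normal noise (sd 1.0), active mean shifted by
  `effect_size × sd` (default 3).
* **Hypotensive table**: log-ED20 normal (sd 0.6) around 12 mg/kg for
  inactives, shifted down `link_strength` sds (default 3) for actives;
  Index derived from ED20 by construction; MW drawn uniformly from
  200–550 g/mol (not computed from a structure, keeping this generator
  independent of the chemistry module); Level drawn from class-tilted
  categorical weights that flatten as the link strength goes to 0.

These defaults are the benchmark's study conditions and are chosen to
resemble the published series (balanced-ish classes of tens of compounds,
ED20 spanning roughly 1–50 mg/kg, MW around 200–550). What passing the
benchmarks shows: each stage recovers a signal of the planted kind at
realistic sizes and stays at chance when the signal is absent. What it
does not show: performance on real chemistry (real substituent
correlations, activity cliffs, measurement error in ED20, or the true
unknown identity of the six IOP indicators).

## Numerical and degenerate-input conventions

Hypergeometric tails are computed in log space and clamped to (0, 1];
boundary draws return exactly 1. k-means raises on fewer distinct rows
than clusters. `index_from_ed20` rejects non-positive or non-finite doses.
Training splits retry a bounded number of times if a class has fewer than
two training examples, then fail. Individual ensemble-network failures are
excluded; more than 10% failures aborts the run. Spearman on a constant
vector is an error, reported as NaN inside the confusion report. Default
problem sizes in the test suite and the reproduction script (20–100 seeds
for recovery rates, 1000-network ensembles, 30+30-compound libraries) are
the package's chosen benchmark sizes.

## Known limitations

* The descriptor dialect reproduces the published tables' *vocabulary*,
  not the proprietary generator byte-for-byte; the published descriptor
  sets themselves cannot be regenerated because the compound structures
  are not machine-readable in the source, so the printed tables are
  exercised as inputs to the decision rule only.
* Occurrence-mode Pr values are not calibrated p-values (see above).
* The perceptron protocol is a documented reconstruction of the stated
  settings; the original tool's loss, optimizer, and retention rule are
  unknown.
* No stereochemistry, 3D pharmacophores, or conformer handling; dose–
  response curves and raw tonometry time-courses are out of scope.
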