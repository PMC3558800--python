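# Methods

## Model and assumptions

The central assumption is that the functional impact of an amino-acid
substitution is captured by the change in position-specific emission
probability between the wild-type and mutant residues at a match state of a
profile HMM covering the site.  Match states model conserved alignment
columns; insert and delete states are parsed for format fidelity but never
interrogated, because a residue aligned to an insert state carries no
position-specific information.  Consequently a substitution is scorable only
where a significant domain hit (or a whole-protein model) aligns its
position to a match state — absence of coverage yields *no prediction*, a
first-class outcome tracked as a coverage statistic, not an error.

When several models cover a site (overlapping domains from different
libraries, or a domain plus a whole-protein model), the one whose match
state carries the most information — the largest Kullback–Leibler divergence
from background — is interrogated.  This prefers models with sharp,
well-determined emission distributions over flat ones.

## Score algebra

The text of record describes the score's behaviour (zero when probabilities
are unchanged, negative for unfavourable substitutions, monotone in the
magnitude of the probability change, weighted variant modulated by W_d and
W_n) without an unambiguous printed algebra.  The score is therefore a
pluggable strategy pinned by that behavioural contract, with two
implemented forms:

* **ratio** (default): S = ln(P_m/P_w); weighted S = ln((P_m·W_n)/(P_w·W_d)).
  The weighted form is the unweighted score plus the constant offset
  ln(W_n/W_d), which makes the weight effect transparent and testable.
* **odds**: S = ln[(P_m/(1−P_m))/(P_w/(1−P_w))]; weighted
  S = ln[((1−P_w)·W_n)/((1−P_m)·W_d)].  The odds forms satisfy the same
  sign and monotonicity contract; the weighted odds form does not reduce to
  the unweighted odds score at W_d = W_n and is provided as the documented
  alternative reading.

Both strategies are antisymmetric under exchange of P_w and P_m (with
neutral weights), strictly increasing in P_m and decreasing in P_w.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| e-value threshold | 0.01 (inclusive) | — | significance bound for domain hits |
| pseudo-count | 1.0 | counts | keeps W_d, W_n > 0; unmapped domains exactly weight-neutral |
| unweighted threshold | −3.0 | nats | joint sens/spec maximum on a large human benchmark |
| weighted threshold | −1.5 | nats | same calibration for the weighted scorer |
| probability floor ε | 1e-10 | probability | `*` cells (probability 0) occur in real models; ROC needs finite scores |
| KL window | 1 state | states | single-state comparison; a symmetric windowed mean is available via `window` |

All logarithms are natural, so scores and information content share one
unit (nats).

Weight form: the default W = c + 1.0 keeps a never-observed domain exactly
neutral (W_d = W_n = 1).  The relative-frequency reading
W = (c + 1)/(T + 1) is available via `WeightTable(normalized=True)`; since
only W_n/W_d enters the score, the two differ by one global score offset
ln(T_d′/T_n′), which shifts every weighted score equally and is absorbed by
threshold recalibration.

Background composition resolves as: user-supplied file, else the model's
own `COMPO` line, else uniform 1/20.  A user file applies globally, making
information content comparable across models; per-model `COMPO` is the
fallback when no global composition is given.  A database-average
composition file ships as package data (`data/example_composition.txt`) for
users who want a concrete global reference.

## Numerical choices

* Stored emission values are negative natural logs (HMMER3 convention);
  `*` decodes to probability exactly 0.  Our writer emits 10 decimal
  places so write→read round-trips preserve probabilities to 1e-9; genuine
  HMMER files carry 5 decimal places, so parsed rows are only guaranteed to
  sum to 1 within 1e-4, and that is the row-sum tolerance enforced
  package-wide.
* KL terms with p(a) = 0 contribute 0; a background zero under non-zero
  emission mass is rejected rather than silently producing infinity.
  Round-off can drive the 20-term sum a few ulp below zero at p ≈ q; the
  result is clipped at 0.
* Information ties break deterministically: library priority
  superfamily > Pfam-A > Pfam-B > ab initio, then lexicographic model id.
* Classification uses strict inequality (score < threshold ⇒ damaging); a
  score exactly at the threshold is tolerated.
* Threshold calibration scans midpoints between adjacent distinct scores
  plus sentinels beyond both extremes, maximising min(sensitivity,
  specificity); ties prefer larger sensitivity + specificity, then the
  larger threshold.
* Leave-one-out weight adjustment is exact bookkeeping, not re-counting:
  each counted record stores the set of models it incremented, so removal
  and re-addition are inverse operations by construction.
* Degenerate inputs are errors with named locations: single-class inputs to
  ROC/calibration, empty classes under normalization, zero metric
  denominators (the failing metric is named), residues outside the
  20-letter alphabet (including X/B/Z).

## Design choices where the design was open

* **Overlapping hits across libraries** all become candidates; information
  ranking decides.  No envelope merging or library precedence beyond the
  tie-break.
* **Weight counting under overlap**: a catalogued substitution increments
  *every* significant covering model, not only the most informative one;
  the same rule is applied symmetrically in leave-one-out.
* **Duplicate catalogue records** deduplicate on (protein, position,
  wild-type, mutant, label): public mutation databases list the same
  substitution many times.
* **Weighted mode excludes whole-protein (ab initio) models**, since
  weights exist only for curated domain models; unweighted mode ranks both
  kinds together purely by information.
* **Hit exchange format**: per-residue alignment maps are carried
  explicitly as run-length M/I/D strings rather than re-derived from
  alignments; `domtblout` input requires a companion map file for the same
  reason, with `hmm_from` seeding the state counter.

## Evaluation

Normalized metrics rescale each class to unit mass before computing the six
measures, making results comparable across datasets with different
disease/neutral ratios; normalized accuracy equals balanced accuracy
exactly.  ROC curves and AUC come from a standard sweep over all distinct
score thresholds (trapezoid area), oriented so that more-negative scores
rank as more disease-like, with a flag for scorers oriented the other way
and a truncated view for low-false-positive-rate comparisons.

## Synthetic data: what it does and does not show

`synth_benchmark` builds models whose match states are split between a
high-conservation stratum (default 0.99 point mass on a consensus residue,
uniform remainder) and a low-conservation stratum (default 0.1).  Disease
records substitute the consensus residue of a conserved state for an
off-consensus one (large probability drop); neutral records swap two
off-consensus residues at a weakly conserved state (score ≈ 0).  By default
5% of records are planted on the opposite stratum while keeping their
label, emulating annotation errors in curated catalogues; with the default
noise, calibrated sensitivity and specificity sit near 0.95 rather than
1.0.  The problem sizes used in the shipped tests and the acceptance script
(10 models of 40 states, 500+500 records, 200 randomized pipeline-oracle
fixtures, 10,000-draw property checks) keep the whole suite in the
seconds range.

Passing on this generator demonstrates that the plumbing — parsing,
state resolution, model selection, score algebra, weighting, calibration,
metrics — is correct and internally consistent.  It does *not* demonstrate
real-world predictive accuracy: synthetic emission profiles lack the
Dirichlet-mixture structure of curated libraries, hits have no realistic
insert/delete geometry, class sizes are balanced by construction, and the
planted separation is far cleaner than biological signal.  Reproducing the
published benchmark metric rows from their confusion counts validates the
metric definitions, not the upstream predictions.

The MSA-based profile builder (`profile_from_msa`) uses plain pseudo-counted
frequencies; profiles built from the same alignment by HMMER with
Dirichlet-mixture priors will differ, especially for shallow alignments.
It exists so whole-protein models can be constructed and exercised without
external tools.

## Known limitations

* HMMER3 ASCII only; binary pressed databases and DNA alphabets are out of
  scope, as is running homology searches internally.
* Weighted predictions are restricted to substitutions inside curated
  domains — inherited from the weighting scheme itself.
* Ontology annotation consumes precomputed domain→term tables; it does not
  re-derive domain-ontology associations, and domain-level terms can be
  diluted when one domain harbours mutations with distinct phenotypes.
* Method-overlap analysis supports two or three sets (the standard Venn
  comparison), not arbitrary collections.
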