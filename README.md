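# taxsim

Semantic similarity search over taxonomy-annotated patient safety event
(PSE) reports.

Voluntary reporting systems collect adverse and near-miss events as case
reports annotated against a multi-axis taxonomy (six "perspectives" such as
*safety target* or *error type*, ~219 terms in total).  Learning from such
a repository hinges on retrieving the cases most similar to a new report.
`taxsim` implements that similarity engine with the ontology-based measures
familiar from Gene Ontology analysis, plus the evaluation protocol
(expert-agreement assessment with a permutation baseline) and a
feedback-driven weight-tuning loop, all runnable on synthetic data at the
real study's scale.

## The measures

For terms annotated against a rooted DAG, with information content
IC(t) = −ln p(t) estimated from propagated annotation frequencies:

- **Lin / IC pairwise** — term similarity
  sim(t₁,t₂) = 2·IC(MICA) / (IC(t₁)+IC(t₂)), where MICA is the most
  informative common ancestor (the terms themselves included); two
  annotation sets are compared by the average over all term pairs.
- **NTO (normalized term overlap)** — |A⁺ ∩ B⁺| / min(|A⁺|, |B⁺|), where
  A⁺ extends A with all ancestors (axis root excluded).
- **VS (vector space)** — cosine of annotation-indicator vectors over the
  axis's term universe, binary or with IC values as inverse-frequency
  weights.

Per-axis scores are combined as a convex combination under axis weights
(initially equal).  Axes unannotated in both cases are excluded and the
remaining weights renormalized; an axis annotated on one side only scores
zero.

A ranking is evaluated against expert judgements on a 4-point Likert scale:
the algorithm's scores are mapped to labels with the experts' label
histogram (distribution matching, lowest scores → lowest labels), the
binarized agreement ratio ({1,2} vs {3,4}) is computed, and compared with
10,000 random permutations of the expert labels via a one-sample t-test.
User agree/disagree feedback updates the axis weights multiplicatively:
w_a ← w_a · exp(η·y·(sim_a − overall)), renormalized.

## Worked example

`examples/` holds one short script per capability.
`python examples/03_expert_agreement.py` builds the full-scale synthetic
study (6 axes, 219 terms, 366 cases with planted event clusters), ranks
the corpus against a query case with each measure, samples the 15-nonzero
+ 5-zero review list, simulates expert consensus labels from the cluster
truth, and prints:

```
review list: 20 cases; expert label counts 1..4 = (6, 5, 5, 4)
 vs: agreement 60%  baseline 50.5%  t = -84.2  p = 0**
nto: agreement 70%  baseline 50.5%  t = -173.0  p = 0**
 ic: agreement 80%  baseline 50.5%  t = -261.8  p = 0**
```

Each line is one measure's binarized agreement with the simulated experts,
the mean agreement of 10,000 random relabelings (the chance level for this
label mix), and the t-test of the observed ratio against that null — the
stars mark p < 0.01.  All three measures sit far above chance on this
corpus.  `examples/04_feedback_learning.py` shows 200 simulated feedback
events shrinking the L1 distance between learned and hidden ground-truth
axis weights from 0.633 to 0.440.

A thin CLI mirrors the workflow: `taxsim simulate` writes synthetic
fixtures, `taxsim query` ranks cases, `taxsim assess` scores a ranking
against a ratings table, `taxsim feedback` folds a verdict into a weights
file.  Run any subcommand with `--help` for options.

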