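# Methods

## The regulation model

A gene regulatory interaction (GRI) is stored as a multi-input transition
rather than a binary TF→TG edge. A transition's inputs are (i) context
signals — extra- or intracellular conditions such as "ethanol present" or
"glucose absent" — and (ii) transcription factors in a required discrete
activity state: direction up/down with magnitude weak/medium/strong, the
magnitude `na` when a source states only the sign, or the special states
knockout (⇒ down) and overexpression (⇒ up). Its outputs are discretized
expression effects on target genes, direction up/down with magnitude
weak/medium/strong. When a numeric fold change is reported it is binned
with the empirical thresholds: weak < 2-fold, medium 2–5-fold, strong >
5-fold. The boundary convention is inclusive at both ends of the middle
bin (exactly 2-fold and exactly 5-fold are medium), and sub-unity folds
are inverted (0.25 ⇒ 4-fold repression) rather than rejected, since
repression is reported both ways in the literature.

The regulation type of each output (activation/inhibition) is implied by
the stored states: equal TF and target directions mean activation,
opposite mean inhibition (so a knockout that up-regulates its target is an
inhibitor). For transitions with no TF input (pure signal→target rules,
used e.g. for signal-driven TF activation) the type follows the output
direction. The type is stored in the files for auditability; the
validator flags a stored type that disagrees with the derived one instead
of silently recomputing it.

Entities (genes, TFs, signals, conditions, complexes) live in a small is-a
ontology with multiple parents allowed, edges stored child→parent.
Generalization queries walk the upward closure, so a query for
"non-fermentable carbon source" with specializations enabled finds
transitions gated on ethanol. Ancestor order is the topological order of
the ancestor sub-DAG, ties broken by id, which makes query output stable
under re-serialization.

## Evidence and confidence

Each annotation records the article, an evidence class (binding,
expression, consensus, author_statement), the technique and an optional
quote anchor. Confidence is binary: high iff the transition has at least
one binding-class and at least one expression-class record, pooled over
all articles; consensus matches and author statements never lift
confidence because their experimental basis is not traceable. Pooling
across sources is deliberate — an interaction with binding support in one
resource and expression support in another is high confidence.
Contradictory annotations (the same pair active in one context, repressive
in another) are kept as separate transitions and do not penalize
confidence.

## Fuzzy execution semantics

Activity is a level in [0, 1]; the neutral baseline defaults to 0.5 so
both directions have symmetric headroom. Levels map to discrete states
through seven triangular membership functions with centers at baseline +
{−0.45, −0.30, −0.15, 0, +0.15, +0.30, +0.45}; adjacent triangles overlap
so the degrees form a partition of unity, with shoulder behaviour beyond
the extreme centers. A TF input required "up, magnitude na" uses the
summed membership of the three up terms; knockout/overexpression
requirements use the extreme terms.

A transition's firing degree is the minimum over its input satisfaction
degrees (conjunctive semantics: *if signal and TF, then target*); a signal
required present contributes its level, required absent contributes
1 − level, so a transition whose gate is fully absent contributes exactly
zero whatever its other inputs do. Across transitions targeting the same
gene, contributions add: the new level is baseline + Σ firing × signed
step, with steps weak ±0.15, medium ±0.30, strong ±0.45, clipped to
[0, 1]. Additive cross-transition aggregation is a declared
simplification — combinatorial control can be synergistic in reality, but
no cross-transition algebra is given by curated sources, and additivity
keeps the Boolean limit exact. Updates are synchronous with fixed-point
detection (tolerance 1e-6, at most 100 sweeps by default); contexts and
perturbations are clamped and never updated. All constants sit in
`EngineParams` and can be set from the CLI or a key=value config file.

Differential responses between two contexts discretize the fixed-point
level difference per target with thirds of the maximum step range:
|Δ| < 0.15 weak, [0.15, 0.30) medium, ≥ 0.30 strong; differences below the
convergence tolerance do not register.

The membership shapes, step sizes and aggregation rule are this package's
own concrete choices — the simplest scheme consistent with three named
strengths per direction; they are not claimed to be canonical.

## Curation-completeness estimation

The rarefaction curve of distinct interactions vs number of curated
articles is averaged over 100 seeded random article orderings (the true
curation order carries no information). The mean curve is fitted with the
first-order Hill form n(a) = nmax·a/(k + a) by nonlinear least squares
(scipy), seeded with a Lineweaver–Burk linearization (1/n vs 1/a) and
bounded to nmax ∈ [max(n), 100·max(n)], k > 0; the fit is deterministic.
`HillSaturationModel` exposes this as an sklearn-style estimator.

Reported network completeness is n_observed/nmax — the curated network
against the fitted asymptote. Model completeness at article count a is
a/(k + a); it satisfies the exact doubling identity c′ = 2c/(1 + c), and
inverting it gives the article cost of a target completeness,
a = k·c/(1 − c). Anchoring the model at completeness 0.71 after 410
articles gives k ≈ 167.5 and a doubled-corpus completeness of 83.0%, i.e.
a gain of 12.0 percentage points; because the identity is exact, any
smaller printed gain for the same rounded anchor reflects underlying fit
parameters that differ from the rounded 0.71.

## The synthetic generator

`generate_network` draws seeded random networks with a two-level signal
ontology, one TF input plus 0–3 signal gates per transition, and uniform
output directions/magnitudes; defaults mirror the aggregate shape of a
curated process-scale yeast network (100 target genes, 68 TFs, ~50
signals, 322 transitions). `simulate_curation` gives each of 410 articles
a Poisson number of annotations (mean ≈ 2.8, so coverage ≈ 3.5 annotations
per interaction) citing transitions at random; a configurable fraction
(default 0.66) of transitions is destined for high confidence by
alternating binding/expression records, the rest draw from classes that
never combine to high.

Per-interaction literature attention is heterogeneous by default: each
transition draws an Exponential(1) attention weight and annotations sample
transitions proportionally. This matters for the completeness analytics:
an exponential mixture of discovery rates makes the expected accumulation
curve exactly first-order Hill, which is the saturation behaviour real
curation corpora show — well-studied interactions are annotated again and
again while others surface late. Uniform attention
(`heterogeneous_attention=False`) yields the coupon-collector curve
N·(1 − (1 − 1/N)^m) instead, which a Hill fit systematically
over-extrapolates (nmax biased high by ~30%); it is retained for
comparison, not as the default study condition.

What the generator does not emulate: real promoter sequences or
position-weight-matrix predictions, biologically structured topology
(hubs, motifs), per-process overlap patterns, or correlated evidence
classes within articles. Passing tests therefore demonstrate the
correctness and calibration of the machinery on networks with realistic
aggregate shape, not biological fidelity of any particular synthetic
network.

Two deterministic fixtures complement the random generator. The PCK1
fixture encodes the context-gated activation of the gluconeogenic gene
PCK1 by CAT8, SIP4, RDS2, ERT1 and GSM1 (ethanol present / glucose absent),
with signal→TF activation transitions for CAT8 and SIP4 so the gating is
simulatable end-to-end; its effect strengths and quote anchors are
illustrative. The full-network summary fixture reproduces the totals of a
complete curated diauxic-shift network — 100 genes, 68 TFs, 322
interactions of which 212 (66%) high confidence, 1133 annotations over 410
articles, a mean coverage of 3.52 annotations per interaction — with
per-process structure distributed deterministically but arbitrarily; only
the totals are contractual. (Curated sources disagree internally on the TF
total, 68 in the tabulated summary vs 72 in the running text; the fixture
follows the table.)

## File formats

The flat dialect is three UTF-8 TSV files with strict headers, LF endings
and `#` comments: `entities.tsv` (id, name, etype, parents pipe-joined),
`transitions.tsv` (id, process, inputs, outputs; input tokens
`entity:role:direction:magnitude[:special]`, output tokens
`entity:direction:magnitude:rtype`, both `;`-joined) and `evidence.tsv`
(transition_id, article, eclass, technique, quote). Free-text fields
escape backslash/tab/CR/LF. Loading is strict — malformed rows abort with
file, line and column, unknown enumeration tokens list the legal ones, and
the assembled network must pass full validation. Writing sorts rows by
id, making write→read→write byte-identical.

SBML-qual export emits one qualitative species per entity with maxLevel 6
(the seven-state scale embedded as levels 0–6, neutral = 3) and one qual
transition per transition with signed inputs, outputs, a neutral default
term and a function term whose result level encodes the first output's
effect with a conjunctive MathML condition over the inputs. Because
resultLevel is per-transition in the qual standard, per-output effect
strengths of multi-output transitions are carried only by the topology;
fixtures and the generator emit single-output transitions. The document
is checked by an own structural validator (unique ids, resolvable species
references, level bounds, default terms present). GraphML export writes
the bipartite entity/transition digraph with role/direction/magnitude edge
attributes and pooled confidence on transition nodes; layout coordinates
are the consumer's job.

## Numerical and design notes

* Degenerate inputs: fold change ≤ 0 or exactly 1 is rejected ("no
  change"); confidence of an evidence-free transition raises an
  "unsupported interaction" error (the CLI prints `unsupported`); a
  constant accumulation curve or fewer than 3 distinct article counts
  cannot be fitted; an observed count exceeding the fitted asymptote
  clamps completeness to 1.0 with a warning.
* Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from explicit config/CLI seeds; repeated runs are byte-identical.
* Problem sizes in the test suite (networks of 10–500 transitions, 15–410
  articles, 8–30 rarefaction orderings) were chosen as the smallest sizes
  at which the statistical properties under test are stable.
* Known limitations: no asynchronous or stochastic update schedules, no
  token multiset semantics, no ODE conversion (kinetic parameters are
  rarely curated), no weighted confidence scores, no import of third-party
  database dumps.
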