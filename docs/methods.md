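# Methods

## Scope and model

The package treats prosthesis planning for one jaw as a deterministic
function from a 16-position findings chart to a 16-position plan chart,
and asks how well sequence neural networks approximate that function from
labelled examples.  Everything is in-silico: the cases are synthetic, the
labels come from the package's own rule engine, and the rule engine is
therefore both the data source and the evaluation oracle.  Nothing here
is a claim about real patients; the value of the setup is that the target
function is exactly known, so learning behaviour can be measured cleanly.

## The rule engine

`plan_case` applies, in order: per-position structural validation
(R1 pontic runs flanked by crowns, R2 uniform sufficiency within a
pontic-containing crown/bridge block, R3 all-or-none sufficiency of
denture teeth), gap analysis, the removable-pathway decision, and
per-tooth plan assembly (rules P1–P6, reported by
`plan_case_explained`).  The removable pathway fires when four or more
non-wisdom teeth need replacement, when a gap lacks a crownable abutment
on either side (cantilever bridges are not allowed), or when an existing
denture needs renewal; in that case all new replacements and all denture
teeth go onto one appliance.

Choices the rule set does not pin down, decided here once:

* **Crownable abutments** are `.`, `ww`, `k`, `kw` — natural teeth and
  crowns.  Crowns that are already abutments of an existing bridge are
  *not* eligible: existing bridges are left untouched, so a gap beside
  one is unbridgeable and routes to the removable pathway.
* A sufficient crown recruited as an abutment of a new bridge is
  replanned as `K` (the plan vocabulary has no "keep as is" symbol).
* Condemned teeth (`x`) are planned as if already extracted.
* `ww` maps to `K` even with no gap nearby: among the four plan symbols,
  a crown is the only restorative option for a retained tooth.
* Gap runs touching the jaw ends have their wisdom positions trimmed
  before boundedness and threshold logic; missing wisdom teeth are never
  replaced and never counted.
* A sufficient denture (`e`) with no trigger maps to `-`; when the
  removable pathway fires for any reason the denture is renewed/extended
  and every `e`/`ew` position goes to `E`.
* Argmax ties in `decode_plan` break toward the lowest symbol index, so
  predictions are deterministic.

## Synthetic case generation

Charts are built constructively so that every draw is valid: first the
removable prosthesis (present with probability 0.3; complete denture with
probability 0.15 given present, otherwise 1–6 scattered non-wisdom teeth;
all-sufficient or all-renewal with probability 0.5), then
missing/condemned teeth (count uniform on 0..10, each `f` or `x` with
probability 0.5), then bridges on eligible free spans (probability 0.4
per span, 1–3 pontics, sufficiency 0.5 per appliance), then isolated
crowns (0.1 per tooth, kept off bridge neighbours so blocks stay
uniform), then `ww` on the remainder (0.1 per tooth).  Denture teeth are
never placed on wisdom positions.  Every second case is redrawn (bounded
rejection) until its plan contains a bridge; duplicates are redrawn at
the same rank so that parity is preserved.  The train/test split is
drawn once at generation time and stored in the file; training draws
(`draw_ncal`) can only touch the training pool.

These distribution parameters are declared package defaults, chosen to
exercise all ten finding codes at non-negligible frequency; they are
*not* a reconstruction of any particular clinical population, and all of
them are exposed on `GeneratorConfig`.  Two consequences matter when
reading results.  First, the variability is not biological (no canine
persistence, no age structure).  Second, absolute accuracies depend
strongly on this distribution: harder mixes (more cases near the
four-tooth threshold, more unbounded-gap decisions) depress mid-curve
accuracy even though the learning dynamics are unchanged.  Under these
defaults the baseline reaches ≈99% exact-set accuracy (98.9-99.7
observed across runs) at N_cal = 7,000 but ≈84% at N_cal = 700 and ≈61% at N_cal = 300 — the
same qualitative curve as the reference study but several points lower
in the middle, which is the expected signature of a harder case mix
rather than of a different training procedure.  The non-recurrent M1
lands near 23% rather than near 8%: under these defaults more cases are
decidable tooth-by-tooth, which raises the ceiling of a position-wise
model.

## Networks and training

The NumPy engine implements embedding, bidirectional LSTM (gate order
i,f,g,o; glorot-uniform input kernels, orthogonal recurrent kernels,
forget-gate bias 1), position-wise dense layers, inverted dropout, and a
per-tooth softmax, with explicit backpropagation verified against
central-difference gradients (absolute error < 1e-7 in float64).
Arithmetic is float32; runs are single-threaded deterministic given the
seed.

The training protocol is fixed: categorical cross-entropy averaged over
batch and positions; Adam (1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7); learning
rate halved after 5 epochs without strict validation-loss improvement,
floored at 1e-7; early stopping after 10 such epochs with best weights
restored; at most 200 epochs; batch 32; inner 80/20 train/validation
split of each N_cal draw, redrawn per repetition under the run seed.
Plateau detection uses zero tolerance (any strict improvement resets
both patience counters); this is declared rather than tuned.

Architecture notes: M4/M5 scale the embedding dimension together with
the recurrent and dense widths ("all layers" read uniformly); all
recurrent layers are bidirectional with the stated width per direction;
M1's replacement dense layer is position-wise, which makes its
per-tooth outputs provably independent of other teeth (tested as a
structural probe) and explains its collapse: the four-missing-teeth
threshold and gap boundedness are whole-jaw properties; M2's extra
dropout uses rate 0.5 like the others.

## Experiments and statistics

Each run is identified by (architecture, N_cal, repetition); its draw,
initialization and shuffling seeds are derived by SHA-256 hashing of
(base seed, architecture, N_cal, repetition), so any single run is
reproducible in isolation.  The learning-curve grid is 21 geometric
points on [50, 7000]; the architecture comparison runs all six models at
N_cal = 300.  Exact-set accuracy samples are compared with the
tie-corrected Kruskal–Wallis test (scipy) and a hand-implemented
Dunn post-hoc (pooled mean ranks, tie-corrected variance, two-sided
normal p, Bonferroni factor k(k−1)/2 capped at 1) with effect size
r = |z|/√(n₁+n₂); both are tested against brute-force rank arithmetic.
Per-condition summaries report mean, sd, and a Student-t 95% CI.

## Problem sizes used in tests and the acceptance script

Training the bidirectional LSTM in NumPy on one core makes full
10-repetition experiments expensive, so the shipped experiment drivers
default to the full protocol while the test suite and
`scripts/acceptance.py` run desk-scale versions, a package choice made
once: 2–3 repetitions per condition (1 at N_cal = 7,000, where
run-to-run spread is small), and accuracy scored on the first 1,500–2,000
cases of the frozen 10,000-case test pool (binomial standard error
≤ 1.1 points at 2,000 cases).  Generation-level checks always use the
full 20,000 cases.

## Known limitations

* Single jaw, no implants, no periodontal/endodontic detail, no
  occlusion; the ten-symbol finding vocabulary compresses each tooth to
  one overall judgement.
* The generator's sampling law is a declared stand-in; absolute
  accuracies (unlike the structural guarantees and the qualitative
  size/architecture effects) should be read relative to it.
* The rule engine resolves ambiguities (abutment eligibility, `ww`
  handling, extension of sufficient dentures) by declared convention;
  other defensible conventions would relabel a fraction of cases.
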