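# prosthoplan

Rule-based dental prosthesis planning for a single 16-tooth jaw, a
constrained synthetic case generator, and neural networks that learn the
planner — with the experiments to measure how well, as a function of
training-set size and architecture.

## The problem

Under the German standard-care rules for publicly insured patients, the
choice of dental prosthesis follows a fixed rule set.  Planning is framed
here as a mapping between two 16-element categorical vectors over one jaw
(FDI numbering, teeth 18..11/21..28):

* **findings chart** — one of ten findings per tooth: `f` missing, `.`
  sufficient, `x` condemned, `k`/`b` sufficient crown/bridge unit, `e`
  sufficient removable-denture tooth, `ww` insufficient but preservation
  worthy, `kw`/`bw` insufficient crown/bridge unit, `ew` denture tooth
  needing renewal;
* **plan chart** — one of four choices per tooth: `-` nothing, `K` crown,
  `B` bridge unit, `E` replacement on a removable denture (RDP).

The structural rules: pontics must be flanked by crowned abutments on both
sides (no cantilever bridges); a bridge is renewed as a whole; denture
teeth are all-sufficient or all-renewed; missing wisdom teeth are never
replaced; four or more teeth to replace, an unbridgeable gap, or a denture
due for renewal force the removable pathway.

The package provides three layers:

1. `prosthoplan.rules` — a deterministic planner `plan_case` implementing
   those rules (also the labelling oracle and the reference every network
   is scored against), plus a structural validator;
2. `prosthoplan.generate` — a constructive generator of valid, unique,
   labelled case collections (20,000 cases by default, half frozen as a
   test pool, every second case forced to contain a bridge);
3. `prosthoplan.nn` / `prosthoplan.experiments` — six sequence-network
   architectures (M0: embedding → bidirectional LSTM(128/direction) →
   dropout → dense(64) → dropout → per-tooth softmax; M1–M5 published
   variants), the training protocol (Adam 10⁻³, plateau halving to 10⁻⁷,
   early stopping with best-weight restore, ≤200 epochs, batch 32, 80/20
   split of the N_cal cases drawn per run), and the learning-curve and
   architecture-comparison experiments with Kruskal–Wallis and
   Dunn–Bonferroni statistics (effect size r = |z|/√(n₁+n₂)).

The networks run on a self-contained NumPy engine (explicit
backpropagation through the bidirectional LSTM, seeded and
single-threaded deterministic); no deep-learning framework is required.

The headline metric everywhere is **exact-set accuracy**: the percentage
of unseen cases whose predicted plan matches the rule engine at *all* 16
positions.

## Worked example

```bash
$ prosthoplan plan --findings ". . . kw bw kw . . . . . . . . . ."
- - - K B K - - - - - - - - - -
```

The worn-out bridge (`kw bw kw`) is renewed as a whole: crowns on the
abutments, a bridge unit over the gap.  From Python, with the rule trace:

```python
>>> from prosthoplan import parse_chart, plan_case_explained
>>> chart = parse_chart(". . ew ew . . . . . f . . . . . .", "finding")
>>> plan, rules = plan_case_explained(chart)
>>> str(plan)
'- - E E - - - - - E - - - - - -'
```

The insufficient denture (`ew`) must be renewed, and that forces the new
gap at tooth 10 onto the same removable prosthesis (rule P2) rather than
onto a bridge.

Generating and training (`examples/02_generate_cases.py`,
`examples/03_train_and_predict.py` are runnable versions):

```
cases generated:        2000
unique findings charts: 2000
test-pool size:         1000
plans containing a bridge: 67.2% (>= 50% by the every-second-case rule)
```

Trained on N_cal = 7,000 cases, the baseline M0 reaches ≈99% exact-set
accuracy on unseen cases — the network has effectively learned the
rule set.  Trained on only 300 cases it reaches ≈60%, and the
non-recurrent M1, whose per-tooth outputs cannot see the rest of the
chart, collapses to ≈23%: counting missing teeth across the whole jaw is
exactly what it cannot do.

The `examples/` directory walks through each capability: planning,
generation, training/prediction, the learning curve, and the
architecture comparison with statistics.

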