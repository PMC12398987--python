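"""Train the baseline network on a small draw and inspect predictions.

Trains M0 (embedding > bidirectional LSTM > dense > softmax per tooth)
on N_cal = 300 cases under the study protocol (Adam 1e-3 with plateau
halving, early stopping with best-weight restore) and compares its
predictions with the rule engine on unseen cases.
"""

from prosthoplan import (
    GeneratorConfig, generate_collection, draw_ncal,
    build_model, train_model, TrainingConfig, evaluate_model,
    predict_plan, plan_case,
)

collection = generate_collection(GeneratorConfig(n_total=4000, n_test=2000, seed=3))
subset = draw_ncal(collection, 300, seed=0)

model = build_model("M0", seed=0)
model, history = train_model(model, subset, TrainingConfig(seed=0))
print(f"trained for {history.stopped_epoch} epochs "
      f"(best validation loss {min(history.val_loss):.4f} "
      f"at epoch {history.best_epoch})")

result = evaluate_model(model, collection.testpool)
print(f"exact-set accuracy on {result.n_cases} unseen cases: "
      f"{result.exact_set_accuracy:.2f}%  (all 16 teeth correct)")
print(f"per-tooth accuracy: {result.per_tooth_accuracy:.2f}%")

print("\npredictions vs. rule engine on three unseen charts:")
for case in collection.testpool.cases[:3]:
    predicted = predict_plan(model, case.findings)
    tag = "ok " if predicted == case.plan else "DIFF"
    print(f"  [{tag}] {case.findings}")
    print(f"         network: {predicted}")
    print(f"         rules:   {case.plan}")
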