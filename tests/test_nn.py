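"""Network structure, gradients, training protocol, and evaluation."""

import numpy as np
import pytest

from prosthoplan.chart import FindingsChart, PlanChart, encode_plan
from prosthoplan.generate import draw_ncal
from prosthoplan.rules import plan_case
from prosthoplan.nn import (
    ArchitectureSpec, ARCHITECTURES, build_model,
    TrainingConfig, train_model, evaluate_model, predict_plan,
)
from prosthoplan.nn.model import softmax, Sequential
from prosthoplan.nn.io import save_run, load_run


class TestArchitectures:
    def test_presets_match_published_layout(self):
        m0 = ARCHITECTURES["M0"]
        assert (m0.embedding_dim, m0.recurrent_units, m0.dense_widths) == \
            (64, 128, (64,))
        assert ARCHITECTURES["M1"].recurrent_units == 0
        assert ARCHITECTURES["M1"].dense_widths == (128, 64)
        assert ARCHITECTURES["M2"].dense_widths == (64, 32)
        assert ARCHITECTURES["M3"].dense_widths == ()
        assert ARCHITECTURES["M4"].recurrent_units == 256
        assert ARCHITECTURES["M5"].recurrent_units == 64

    def test_output_rows_are_probabilities(self):
        m = build_model("M0", seed=0)
        x = np.random.default_rng(0).integers(0, 10, size=(3, 16))
        probs = m.predict_proba(x)
        assert probs.shape == (3, 16, 4)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_parameter_count_ordering(self):
        n = {name: build_model(name, seed=0).n_params
             for name in ("M0", "M4", "M5")}
        assert n["M4"] > n["M0"] > n["M5"]

    def test_m1_positions_are_independent(self):
        """Without recurrence, changing tooth j cannot affect tooth i != j."""
        m = build_model("M1", seed=1)
        x = np.ones((1, 16), dtype=np.int64)
        base = m.predict_proba(x)[0]
        for j in (0, 7, 15):
            x2 = x.copy()
            x2[0, j] = 5
            out = m.predict_proba(x2)[0]
            others = [i for i in range(16) if i != j]
            assert np.allclose(out[others], base[others], atol=1e-12)

    def test_m0_positions_interact(self):
        m = build_model("M0", seed=1)
        x = np.ones((1, 16), dtype=np.int64)
        base = m.predict_proba(x)[0]
        x2 = x.copy()
        x2[0, 7] = 5
        out = m.predict_proba(x2)[0]
        assert not np.allclose(out[0], base[0], atol=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec("bad", 0, 128, (64,))
        with pytest.raises(ValueError):
            ArchitectureSpec("bad", 64, 0, ())
        with pytest.raises(ValueError):
            ArchitectureSpec("bad", 64, 128, (0,))

    def test_seeded_build_is_deterministic(self):
        a = build_model("M5", seed=9).get_weights()
        b = build_model("M5", seed=9).get_weights()
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestGradients:
    def test_numerical_gradient_check(self):
        spec = ArchitectureSpec("tiny", 5, 4, (6,), dropout_rate=0.0)
        m = build_model(spec, seed=3)
        for layer in m.layers:  # float64 for finite-difference precision
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(np.float64)
        bil = m.layers[1]
        for tag, d in (("fwd", bil.fwd), ("bwd", bil.bwd)):
            d.Wx = bil.params[f"{tag}_Wx"]
            d.Wh = bil.params[f"{tag}_Wh"]
            d.b = bil.params[f"{tag}_b"]
        rng = np.random.default_rng(0)
        X = rng.integers(0, 10, size=(3, 16))
        y = rng.integers(0, 4, size=(3, 16))

        def loss_of():
            probs = softmax(m.forward(X))
            rows = np.arange(3)[:, None]
            cols = np.arange(16)[None, :]
            return float(-np.log(probs[rows, cols, y]).mean())

        m.loss_and_grad(X, y, rng)
        for layer in m.layers:
            for k, p in layer.params.items():
                g = layer.grads[k]
                for _ in range(3):
                    idx = tuple(int(rng.integers(0, s)) for s in p.shape)
                    eps = 1e-5
                    old = p[idx]
                    p[idx] = old + eps
                    lp = loss_of()
                    p[idx] = old - eps
                    lm = loss_of()
                    p[idx] = old
                    num = (lp - lm) / (2 * eps)
                    assert abs(num - g[idx]) < 1e-7


@pytest.fixture(scope="class")
def trained(small_collection_cls, tiny_arch_cls):
    sub = draw_ncal(small_collection_cls, 60, seed=0)
    model = build_model(tiny_arch_cls, seed=0)
    cfg = TrainingConfig(max_epochs=40, seed=0)
    model, hist = train_model(model, sub, cfg)
    return model, hist, cfg


class TestTrainingProtocol:
    def test_stops_within_max_epochs(self, trained):
        _, hist, cfg = trained
        assert 1 <= hist.stopped_epoch <= cfg.max_epochs
        assert 1 <= hist.best_epoch <= hist.stopped_epoch

    def test_restored_weights_reproduce_best_val_loss(
            self, trained, small_collection_cls):
        model, hist, cfg = trained
        # recompute the validation loss of the restored model on the same split
        sub = draw_ncal(small_collection_cls, 60, seed=0)
        X, y = sub.encoded()
        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(60)
        n_val = max(1, int(round(cfg.val_fraction * 60)))
        val = perm[:n_val]
        assert model.loss(X[val], y[val]) == pytest.approx(
            min(hist.val_loss), abs=1e-9)

    def test_best_epoch_is_curve_minimum(self, trained):
        _, hist, _ = trained
        assert hist.val_loss[hist.best_epoch - 1] == min(hist.val_loss)
        assert hist.val_loss[hist.best_epoch - 1] <= hist.val_loss[0]

    def test_learning_rate_schedule(self, trained):
        _, hist, cfg = trained
        lr = np.asarray(hist.learning_rate)
        assert (np.diff(lr) <= 0).all()
        assert (lr >= cfg.lr_floor).all()
        assert lr[0] == cfg.initial_lr

    def test_history_complete(self, trained):
        _, hist, _ = trained
        assert len(hist.train_loss) == len(hist.val_loss) \
            == len(hist.learning_rate) == hist.stopped_epoch

    def test_too_few_cases_rejected(self, small_collection_cls, tiny_arch_cls):
        sub = draw_ncal(small_collection_cls, 9, seed=0)
        with pytest.raises(ValueError, match="at least 10"):
            train_model(build_model(tiny_arch_cls, seed=0), sub)

    def test_seed_determinism(self, small_collection_cls, tiny_arch_cls):
        sub = draw_ncal(small_collection_cls, 30, seed=1)
        runs = []
        for _ in range(2):
            m = build_model(tiny_arch_cls, seed=5)
            _, h = train_model(m, sub, TrainingConfig(max_epochs=8, seed=5))
            runs.append(h.val_loss)
        assert runs[0] == runs[1]


class _StubPerfect(Sequential):
    """Returns the one-hot encoding of the true plan for each findings row."""

    def __init__(self):
        super().__init__([])

    def forward(self, x, train=False, rng=None):
        from prosthoplan.chart import decode_findings
        out = np.zeros((x.shape[0], 16, 4))
        for i, row in enumerate(x):
            plan = plan_case(decode_findings(row))
            out[i] = encode_plan(plan)
        return 1000.0 * out  # logits; softmax ~ one-hot


class _StubAllNone(Sequential):
    def __init__(self):
        super().__init__([])

    def forward(self, x, train=False, rng=None):
        out = np.zeros((x.shape[0], 16, 4))
        out[:, :, 0] = 1000.0
        return out


class TestEvaluation:
    def test_perfect_stub_scores_100(self, small_collection_cls):
        res = evaluate_model(_StubPerfect(), small_collection_cls.testpool)
        assert res.exact_set_accuracy == 100.0
        assert res.per_tooth_accuracy == 100.0

    def test_all_none_stub_misses_treated_cases(self, small_collection_cls):
        pool = small_collection_cls.testpool
        treated = [i for i, c in enumerate(pool.cases)
                   if any(s != "-" for s in c.plan)]
        res = evaluate_model(_StubAllNone(), pool.subset(treated))
        assert res.exact_set_accuracy == 0.0

    def test_hand_built_three_case_arithmetic(self):
        """One wrong tooth in one of three cases: exact 2/3, tooth 47/48."""
        X = np.zeros((3, 16), dtype=np.int64)
        y = np.zeros((3, 16), dtype=np.int64)

        class OneError(Sequential):
            def __init__(self):
                super().__init__([])

            def forward(self, x, train=False, rng=None):
                out = np.zeros((x.shape[0], 16, 4))
                out[:, :, 0] = 1000.0
                out[2, 5] = [0, 1000.0, 0, 0]  # wrong tooth 6 of case 3
                return out

        res = evaluate_model(OneError(), (X, y))
        assert res.exact_set_accuracy == pytest.approx(200.0 / 3, abs=1e-9)
        assert res.per_tooth_accuracy == pytest.approx(100.0 * 47 / 48, abs=1e-9)
        assert res.confusion.sum() == 48

    def test_exact_never_exceeds_per_tooth(self, small_collection_cls):
        m = build_model(ArchitectureSpec("t", 4, 4, ()), seed=0)
        res = evaluate_model(m, small_collection_cls.testpool)
        assert res.exact_set_accuracy <= res.per_tooth_accuracy
        assert res.confusion.sum() == 16 * res.n_cases

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_model(_StubAllNone(), (np.zeros((0, 16), int),
                                            np.zeros((0, 16), int)))

    def test_predict_plan_type_contract(self):
        m = build_model("M5", seed=0)
        plan = predict_plan(m, FindingsChart(["."] * 16))
        assert isinstance(plan, PlanChart) and len(plan) == 16

    def test_perfect_stub_predicts_oracle_plan(self):
        chart = FindingsChart([".", ".", "f"] + ["."] * 13)
        assert predict_plan(_StubPerfect(), chart) == plan_case(chart)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, tiny_arch_cls):
        m = build_model(tiny_arch_cls, seed=2)
        save_run(tmp_path / "run", m, tiny_arch_cls)
        back, spec = load_run(tmp_path / "run")
        assert spec == tiny_arch_cls
        x = np.random.default_rng(0).integers(0, 10, size=(4, 16))
        assert np.allclose(m.predict_proba(x), back.predict_proba(x))


# class-scoped clones of the session fixtures (pytest cannot mix scopes here)
@pytest.fixture(scope="class")
def small_collection_cls(request):
    from prosthoplan.generate import GeneratorConfig, generate_collection
    return generate_collection(GeneratorConfig(n_total=400, n_test=200, seed=7))


@pytest.fixture(scope="class")
def tiny_arch_cls():
    return ArchitectureSpec("tiny", embedding_dim=8, recurrent_units=8,
                            dense_widths=(8,), dropout_rate=0.2)
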