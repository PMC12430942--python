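import numpy as np
import pytest

from dgtta.core import Volume
from dgtta.losses import DiceLossConfig
from dgtta.optim import AdamW
from dgtta.tta import TTAConfig, adapt, adapt_and_predict_ensemble, tta_step


def tiny_tta_cfg(**kw):
    base = dict(steps=2, patches_per_step=3, patch_size=(16, 16, 16), seed=4)
    base.update(kw)
    return TTAConfig(**base)


@pytest.fixture
def target_volume(rng):
    return Volume(rng.normal(size=(24, 24, 24)))


class TestSingleStep:
    def test_zero_learning_rate_keeps_parameters(self, untrained_model, target_volume):
        cfg = tiny_tta_cfg(learning_rate=0.0, weight_decay=0.0)
        before = {k: v.data.copy() for k, v in untrained_model.net.params.items()}
        adapted, trace = adapt(untrained_model, target_volume, cfg)
        assert np.isfinite(trace).all()
        for k in before:
            np.testing.assert_array_equal(adapted.net.params[k].data, before[k])

    def test_accumulated_equals_batched_update(self, untrained_model, target_volume):
        # same patches and transforms, two computation orders, one update
        from dgtta.pretrain import normalize_volume
        x_norm = normalize_volume(target_volume).data
        results = {}
        for batched in (False, True):
            model = untrained_model.copy()
            cfg = tiny_tta_cfg(patches_per_step=4)
            opt = AdamW(model.net.params, lr=cfg.learning_rate,
                        weight_decay=cfg.weight_decay)
            tta_step(model, x_norm, cfg, np.random.default_rng(3), opt,
                     batched=batched)
            results[batched] = {k: v.data.copy()
                                for k, v in model.net.params.items()}
        for k in results[True]:
            assert np.abs(results[True][k] - results[False][k]).max() <= 1e-6

    def test_gradient_flow_respects_branch_config(self, untrained_model, target_volume):
        # asymmetric branch roles give different updates than symmetric ones
        from dgtta.pretrain import normalize_volume
        x_norm = normalize_volume(target_volume).data
        updates = {}
        for branches in ("A", "B", "AB"):
            model = untrained_model.copy()
            cfg = tiny_tta_cfg(grad_branches=branches, learning_rate=1e-3)
            opt = AdamW(model.net.params, lr=cfg.learning_rate, weight_decay=0.0)
            tta_step(model, x_norm, cfg, np.random.default_rng(3), opt)
            updates[branches] = np.concatenate(
                [v.data.ravel() for v in model.net.params.values()])
        assert not np.allclose(updates["A"], updates["AB"])
        assert not np.allclose(updates["A"], updates["B"])


class TestAdapt:
    def test_exactly_n_steps_and_trace(self, untrained_model, target_volume):
        cfg = tiny_tta_cfg(steps=3)
        _, trace = adapt(untrained_model, target_volume, cfg)
        assert len(trace) == 3

    def test_base_model_never_mutated(self, untrained_model, target_volume):
        before = {k: v.data.copy() for k, v in untrained_model.net.params.items()}
        adapt(untrained_model, target_volume, tiny_tta_cfg(learning_rate=1e-3))
        for k in before:
            np.testing.assert_array_equal(untrained_model.net.params[k].data,
                                          before[k])

    def test_adaptation_is_deterministic(self, untrained_model, target_volume):
        cfg = tiny_tta_cfg()
        a1, t1 = adapt(untrained_model, target_volume, cfg)
        a2, t2 = adapt(untrained_model, target_volume, cfg)
        assert t1 == t2
        for k in a1.net.params:
            np.testing.assert_array_equal(a1.net.params[k].data,
                                          a2.net.params[k].data)

    def test_per_sample_isolation(self, untrained_model, rng):
        x1 = Volume(rng.normal(size=(24, 24, 24)))
        x2 = Volume(rng.normal(size=(24, 24, 24)))
        cfg = tiny_tta_cfg(learning_rate=1e-3)
        adapt(untrained_model, x1, cfg)  # must not leak into the next sample
        a_after, t_after = adapt(untrained_model, x2, cfg)
        a_fresh, t_fresh = adapt(untrained_model, x2, cfg)
        assert t_after == t_fresh
        for k in a_fresh.net.params:
            np.testing.assert_array_equal(a_after.net.params[k].data,
                                          a_fresh.net.params[k].data)

    def test_parameter_subset_restricts_updates(self, untrained_model, target_volume):
        cfg = tiny_tta_cfg(parameter_subset="normalization_only",
                           learning_rate=1e-3, weight_decay=0.0)
        adapted, _ = adapt(untrained_model, target_volume, cfg)
        for name, p in untrained_model.net.params.items():
            changed = not np.array_equal(adapted.net.params[name].data, p.data)
            assert changed == name.startswith("n_")


class TestEnsemble:
    def test_singleton_matches_single_adapt_predict(self, untrained_model, target_volume):
        from dgtta.pretrain import predict
        cfg = tiny_tta_cfg()
        seg = adapt_and_predict_ensemble([untrained_model], target_volume, cfg,
                                         predict_kwargs={"patch_size": (16, 16, 16)},
                                         member_seeds=[cfg.seed])
        adapted, _ = adapt(untrained_model, target_volume, cfg)
        direct = predict(adapted, target_volume,
                         patch_size=(16, 16, 16)).argmax_labels()
        np.testing.assert_array_equal(seg.data, direct.data)

    def test_identical_members_same_seed_match_single(self, untrained_model, target_volume):
        cfg = tiny_tta_cfg()
        kw = {"patch_size": (16, 16, 16)}
        one = adapt_and_predict_ensemble([untrained_model], target_volume, cfg,
                                         predict_kwargs=kw, member_seeds=[7])
        three = adapt_and_predict_ensemble([untrained_model] * 3, target_volume,
                                           cfg, predict_kwargs=kw,
                                           member_seeds=[7, 7, 7])
        np.testing.assert_array_equal(one.data, three.data)

    def test_empty_ensemble_rejected(self, target_volume):
        with pytest.raises(ValueError):
            adapt_and_predict_ensemble([], target_volume, tiny_tta_cfg())

    def test_class_subset_restricts_output(self, untrained_model, target_volume):
        cfg = tiny_tta_cfg(loss_cfg=DiceLossConfig(class_subset=[1]))
        seg = adapt_and_predict_ensemble([untrained_model], target_volume, cfg,
                                         predict_kwargs={"patch_size": (16, 16, 16)})
        assert set(np.unique(seg.data)) <= {0, 1}


class TestConfigValidation:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TTAConfig(steps=0)
        with pytest.raises(ValueError):
            TTAConfig(grad_branches="C")
        with pytest.raises(ValueError):
            TTAConfig(learning_rate=-1.0)
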