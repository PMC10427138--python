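import numpy as np
import pytest

from glottiseg import TrainConfig, UNetSpec
from glottiseg.dataset_io import BatchSchedule, frames_from_samples
from glottiseg.retrain import (
    RetrainPlan,
    _draw_frame_batches,
    _old_share,
    evaluate_per_group,
    finetune_kd,
    incremental_finetune,
    incremental_finetune_mixed,
    retrain_from_scratch,
    train_baseline,
)
from glottiseg.synthetic import generate_corpus


def _max_param_diff(a, b):
    return max(float(np.abs(a.state[k] - b.state[k]).max()) for k in a.state)


@pytest.fixture(scope="module")
def pools(small_domain, shifted_domain):
    old = frames_from_samples(generate_corpus([small_domain], 6, 6, seed=21))
    new = frames_from_samples(generate_corpus([shifted_domain], 6, 6, seed=22))
    return old, new


@pytest.fixture(scope="module")
def fast_setup(pools):
    old, new = pools
    cfg = TrainConfig(seed=2, max_epochs=2, patience=1)
    spec = UNetSpec(depth=2, base_channels=4)
    baseline, _ = train_baseline(old, spec, cfg)
    return old, new, cfg, spec, baseline


class TestPlanValidation:
    def test_unknown_strategy_rejected(self, pools):
        old, new = pools
        with pytest.raises(ValueError):
            RetrainPlan("nonsense", BatchSchedule.from_b(1.0), new, TrainConfig(seed=0))

    def test_fkd_requires_teacher_mode(self, pools):
        _, new = pools
        with pytest.raises(ValueError):
            RetrainPlan("fkd", BatchSchedule.from_b(1.0), new, TrainConfig(seed=0))

    def test_teacher_mode_only_for_fkd(self, pools):
        _, new = pools
        with pytest.raises(ValueError):
            RetrainPlan(
                "incremental", BatchSchedule.from_b(1.0), new, TrainConfig(seed=0),
                teacher_mode="static",
            )

    def test_unset_alpha_defaults_to_half_with_warning(self, pools):
        _, new = pools
        with pytest.warns(UserWarning, match="0.5"):
            plan = RetrainPlan(
                "fkd", BatchSchedule.from_b(1.0), new, TrainConfig(seed=0),
                teacher_mode="static",
            )
        assert plan.alpha == 0.5


class TestEquivalences:
    """The strategy lattice collapses at its degenerate corners: these are
    exact checkpoint-level identities at fixed seeds."""

    def test_scratch_without_new_data_equals_baseline(self, fast_setup):
        old, new, cfg, spec, baseline = fast_setup
        plan = RetrainPlan("scratch", BatchSchedule.from_b(1.0), [], cfg, spec, old_train=old)
        ckpt = retrain_from_scratch(plan)
        assert _max_param_diff(ckpt, baseline) == 0.0

    def test_fkd_alpha_one_equals_incremental(self, fast_setup):
        old, new, cfg, spec, baseline = fast_setup
        sched = BatchSchedule.from_b(0.5)
        inc = incremental_finetune(
            RetrainPlan("incremental", sched, new, cfg, spec), baseline
        )
        kd = finetune_kd(
            RetrainPlan("fkd", sched, new, cfg, spec, alpha=1.0, teacher_mode="static"),
            baseline,
        )
        assert _max_param_diff(inc, kd) <= 1e-6

    def test_static_equals_dynamic_for_single_batch(self, fast_setup):
        old, new, cfg, spec, baseline = fast_setup
        sched = BatchSchedule.from_b(1.0)
        stat = finetune_kd(
            RetrainPlan("fkd", sched, new, cfg, spec, alpha=0.5, teacher_mode="static"),
            baseline,
        )
        dyn = finetune_kd(
            RetrainPlan("fkd", sched, new, cfg, spec, alpha=0.5, teacher_mode="dynamic"),
            baseline,
        )
        assert _max_param_diff(stat, dyn) == 0.0

    def test_baseline_untouched_by_finetuning(self, fast_setup):
        old, new, cfg, spec, baseline = fast_setup
        before = {k: v.copy() for k, v in baseline.state.items()}
        incremental_finetune(
            RetrainPlan("incremental", BatchSchedule.from_b(1.0), new, cfg, spec), baseline
        )
        assert all((baseline.state[k] == before[k]).all() for k in before)


class TestBatchingAndShares:
    def test_four_batches_for_quarter_schedule(self, pools):
        _, new = pools
        batches = _draw_frame_batches(new, BatchSchedule.from_b(0.25), [0, 1])
        assert len(batches) == 4
        vids = [frozenset(f.video_id for f in b) for b in batches]
        assert not any(vids[i] & vids[j] for i in range(4) for j in range(i + 1, 4))

    def test_old_share_has_exactly_equal_frame_count(self, pools):
        old, _ = pools
        share = _old_share(old, 10, [0])
        assert len(share) == 10

    def test_old_share_with_replacement_warns(self, pools):
        old, _ = pools
        with pytest.warns(UserWarning, match="replacement"):
            share = _old_share(old, len(old) + 5, [0])
        assert len(share) == len(old) + 5

    def test_mixed_runs_and_differs_from_plain(self, fast_setup):
        old, new, cfg, spec, baseline = fast_setup
        sched = BatchSchedule.from_b(1.0)
        plain = incremental_finetune(
            RetrainPlan("incremental", sched, new, cfg, spec), baseline
        )
        mixed = incremental_finetune_mixed(
            RetrainPlan("incremental_mixed", sched, new, cfg, spec, old_train=old), baseline
        )
        assert _max_param_diff(plain, mixed) > 0.0


class TestEvaluatePerGroup:
    def test_group_and_pooled_reports(self, fast_setup):
        old, new, cfg, spec, baseline = fast_setup
        model = baseline.to_model()
        reports = evaluate_per_group(model, old + new, cfg)
        keys = [r.group_key for r in reports]
        assert keys == ["cam_a", "cam_b", "all"]

    def test_pooled_is_frame_weighted_mean_of_groups(self, fast_setup):
        old, new, cfg, spec, baseline = fast_setup
        model = baseline.to_model()
        reports = {r.group_key: r for r in evaluate_per_group(model, old + new, cfg)}
        weighted = (
            reports["cam_a"].miou * reports["cam_a"].n_frames
            + reports["cam_b"].miou * reports["cam_b"].n_frames
        ) / (reports["cam_a"].n_frames + reports["cam_b"].n_frames)
        assert reports["all"].miou == pytest.approx(weighted)

    def test_baseline_vs_itself_gives_zero_delta(self, fast_setup):
        old, new, cfg, spec, baseline = fast_setup
        model = baseline.to_model()
        reports = evaluate_per_group(model, old, cfg, baseline=baseline.to_model())
        assert all(r.delta_miou_pp == 0.0 for r in reports)

    def test_unknown_group_key_rejected(self, fast_setup):
        old, new, cfg, spec, baseline = fast_setup
        with pytest.raises(ValueError, match="unknown group"):
            evaluate_per_group(baseline.to_model(), old, cfg, groups=["cam_b"])
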