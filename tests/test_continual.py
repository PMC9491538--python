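"""Scheduling, pseudo-labeling, fine-tuning and the experiment loop."""

import datetime as dt
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glottikit.continual import (
    ContinualStrategy,
    FineTuneConfig,
    continual_step,
    make_schedule,
    pseudo_label_batch,
    run_experiment,
)
from glottikit.errors import ConfigurationError
from glottikit.phantom import PhantomSpec, generate_recording
from glottikit.segmentation import build_model, predict_masks, to_luminance
from glottikit.videoio import ROIBox


def _dated(days):
    """Minimal date-carrying items."""

    class Item:
        def __init__(self, i, d):
            self.i = i
            self.date = dt.date(2020, 1, 1) + dt.timedelta(days=int(d))

        def __repr__(self):
            return f"I{self.i}@{self.date}"

    return [Item(i, d) for i, d in enumerate(days)]


class TestStrategy:
    def test_parse(self):
        s = ContinualStrategy.parse("quantity:10")
        assert s.kind == "fixed_quantity" and s.batch_size == 10
        t = ContinualStrategy.parse("time:7")
        assert t.kind == "fixed_time" and t.period_days == 7

    @pytest.mark.parametrize("bad", ["weekly", "quantity:x", "time"])
    def test_parse_rejects(self, bad):
        with pytest.raises(ConfigurationError):
            ContinualStrategy.parse(bad)

    def test_exclusive_fields(self):
        with pytest.raises(ConfigurationError):
            ContinualStrategy(kind="fixed_time", period_days=7, batch_size=10)
        with pytest.raises(ConfigurationError):
            ContinualStrategy(kind="fixed_quantity")


class TestMakeSchedule:
    def test_fixed_quantity_chunks_and_pending(self):
        items = _dated(range(25))
        sched = make_schedule(
            items, ContinualStrategy(kind="fixed_quantity", batch_size=10)
        )
        assert [len(b) for b in sched.batches] == [10, 10]
        assert len(sched.pending) == 5

    def test_fixed_time_windows(self):
        items = _dated([0, 1, 8, 9, 20])
        sched = make_schedule(
            items, ContinualStrategy(kind="fixed_time", period_days=7)
        )
        got = [[it.i for it in b] for b in sched.batches]
        assert got == [[0, 1], [2, 3], [4]]  # days {0,1}, {8,9}, {20}

    def test_empty_input(self):
        for strat in (
            ContinualStrategy(kind="fixed_quantity", batch_size=10),
            ContinualStrategy(kind="fixed_time", period_days=7),
        ):
            sched = make_schedule([], strat)
            assert sched.batches == [] and sched.pending == []

    def test_date_order_respected(self):
        items = _dated([5, 1, 3, 0, 4, 2])
        sched = make_schedule(
            items, ContinualStrategy(kind="fixed_quantity", batch_size=3)
        )
        flat = [it.date for b in sched.batches for it in b]
        assert flat == sorted(flat)

    @settings(max_examples=100, deadline=None)
    @given(
        days=st.lists(st.integers(0, 120), min_size=0, max_size=40),
        qty=st.integers(1, 15),
        period=st.integers(1, 40),
    )
    def test_partition_property(self, days, qty, period):
        """Batches plus pending always partition the input exactly."""
        items = _dated(days)
        for strat in (
            ContinualStrategy(kind="fixed_quantity", batch_size=qty),
            ContinualStrategy(kind="fixed_time", period_days=period),
        ):
            sched = make_schedule(items, strat)
            seen = [it.i for b in sched.batches for it in b] + [
                it.i for it in sched.pending
            ]
            assert sorted(seen) == sorted(it.i for it in items)
            if strat.kind == "fixed_quantity":
                assert all(len(b) == qty for b in sched.batches)
                assert len(sched.pending) < qty
            else:
                # every batch fits inside one period-long window
                for b in sched.batches:
                    span = (b[-1].date - b[0].date).days
                    assert span < period


@pytest.fixture(scope="module")
def tiny_cohort():
    """Small 32x32 phantoms: cheap enough for loop bookkeeping tests."""
    base = dict(H=32, W=32, T=6, axis_a=6.0, A_peak=100.0, f0=400.0)
    out = []
    for i in range(6):
        pr = generate_recording(PhantomSpec(seed=300 + i, **base))
        pr.rec.date = dt.date(2020, 1, 1) + dt.timedelta(days=3 * i)
        pr.rec.name = f"c{i}"
        out.append(pr)
    return out


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(depth=2, base_channels=2, seed=0)


WIDE_PRIOR = ROIBox(x0=0, y0=0, width=32, height=32)
TINY_PRIOR = ROIBox(x0=0, y0=0, width=2, height=2)


class TestPseudoLabelBatch:
    def test_clean_batch_all_contribute(self, tiny_model, tiny_cohort):
        frames, masks, excluded = pseudo_label_batch(
            tiny_model, tiny_cohort[:3], prior=WIDE_PRIOR
        )
        assert frames.shape[0] == 18 and masks.shape == frames.shape
        assert excluded == []

    def test_filter_off_keeps_everything(self, tiny_model, tiny_cohort):
        frames, _, excluded = pseudo_label_batch(
            tiny_model, tiny_cohort[:3], artifact_filter=False
        )
        assert frames.shape[0] == 18 and excluded == []

    def test_flagged_recordings_excluded(self, tiny_model, tiny_cohort):
        # a tiny prior makes any sizable predicted component spurious
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frames, _, excluded = pseudo_label_batch(
                tiny_model,
                tiny_cohort[:3],
                prior=TINY_PRIOR,
                min_component_px=1,
                flag_fraction=0.0,
            )
        # everything the model segments lies outside a 2x2 prior corner
        assert len(excluded) == 3 and frames.size == 0

    def test_empty_batch_warns(self, tiny_model):
        with pytest.warns(UserWarning):
            frames, masks, _ = pseudo_label_batch(tiny_model, [], prior=WIDE_PRIOR)
        assert frames.size == 0

    def test_max_frames_subsampling(self, tiny_model, tiny_cohort):
        frames, _, _ = pseudo_label_batch(
            tiny_model, tiny_cohort[:2], prior=WIDE_PRIOR,
            max_frames_per_recording=2,
        )
        assert frames.shape[0] == 4


class TestContinualStep:
    def test_zero_lr_keeps_parameters(self, tiny_model, tiny_cohort):
        model = tiny_model.copy()
        frames, masks, _ = pseudo_label_batch(
            model, tiny_cohort[:2], prior=WIDE_PRIOR
        )
        cfg = FineTuneConfig(epochs=2, learning_rate=0.0, seed=0)
        out = continual_step(model, (frames, masks), cfg)
        for k in tiny_model.net.params:
            np.testing.assert_array_equal(
                out.net.params[k], tiny_model.net.params[k]
            )

    def test_defaults_match_fine_tuning_regime(self):
        cfg = FineTuneConfig()
        assert cfg.epochs == 10 and cfg.learning_rate == pytest.approx(1e-6)

    def test_empty_pairs_noop_with_warning(self, tiny_model):
        model = tiny_model.copy()
        with pytest.warns(UserWarning):
            out = continual_step(
                model,
                (np.empty((0, 0, 0), np.uint8), np.empty((0, 0, 0), bool)),
                FineTuneConfig(),
            )
        assert out is model

    def test_loss_drops_on_own_pseudo_labels(self, tiny_model, tiny_cohort):
        model = tiny_model.copy()
        frames, masks, _ = pseudo_label_batch(
            model, tiny_cohort[:2], prior=WIDE_PRIOR
        )
        cfg = FineTuneConfig(epochs=8, learning_rate=1e-3, seed=1)
        out = continual_step(model, (frames, masks), cfg)
        assert out.loss_history[-1] <= out.loss_history[0]


class TestRunExperiment:
    def _eval_set(self):
        base = dict(H=32, W=32, T=6, axis_a=6.0, A_peak=100.0, f0=400.0)
        out = []
        for i in range(2):
            pr = generate_recording(PhantomSpec(seed=900 + i, **base))
            pr.rec.date = dt.date(2020, 6, 1)
            pr.rec.name = f"e{i}"
            out.append(pr)
        return out

    def test_bookkeeping_two_steps(self, tiny_model, tiny_cohort):
        res = run_experiment(
            tiny_cohort,
            ContinualStrategy(kind="fixed_quantity", batch_size=3),
            FineTuneConfig(epochs=1, learning_rate=1e-5, seed=0),
            self._eval_set(),
            tiny_model,
            prior=WIDE_PRIOR,
        )
        assert res.n_steps == 2
        assert len(res.excluded_per_step) == 2

    def test_overlapping_eval_rejected(self, tiny_model, tiny_cohort):
        with pytest.raises(ConfigurationError):
            run_experiment(
                tiny_cohort,
                ContinualStrategy(kind="fixed_quantity", batch_size=3),
                FineTuneConfig(),
                tiny_cohort[:1],
                tiny_model,
                prior=WIDE_PRIOR,
            )

    def test_deterministic_given_seeds(self, tiny_model, tiny_cohort):
        def run():
            return run_experiment(
                tiny_cohort,
                ContinualStrategy(kind="fixed_quantity", batch_size=3),
                FineTuneConfig(epochs=1, learning_rate=1e-4, seed=5),
                self._eval_set(),
                tiny_model,
                prior=WIDE_PRIOR,
            )

        a, b = run(), run()
        for ra, rb in zip(a.step_reports, b.step_reports):
            np.testing.assert_array_equal(ra.iou_per_frame, rb.iou_per_frame)

    def test_baseline_model_not_mutated(self, tiny_model, tiny_cohort):
        before = {k: v.copy() for k, v in tiny_model.net.params.items()}
        run_experiment(
            tiny_cohort,
            ContinualStrategy(kind="fixed_quantity", batch_size=3),
            FineTuneConfig(epochs=1, learning_rate=1e-3, seed=0),
            self._eval_set(),
            tiny_model,
            prior=WIDE_PRIOR,
            max_steps=1,
        )
        for k, v in before.items():
            np.testing.assert_array_equal(v, tiny_model.net.params[k])
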