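"""The interaction loop: memory chaining, click bookkeeping, convergence,
reproducibility, and the ensemble protocol."""

import numpy as np
import pytest

from clickseg.clicks import Click, ClickSet, POSITIVE
from clickseg.session import (
    SingleModelSegmenter,
    TwoStageSegmenter,
    ensemble_session,
    refine_step,
    run_initial,
    run_session,
)
from clickseg.volumes import ProbabilityVolume


@pytest.fixture
def segmenter(tiny_nets):
    return TwoStageSegmenter(tiny_nets[2], tiny_nets[5])


class _StubModel:
    """Duck-typed 'network' returning one of its input channels."""

    def __init__(self, channel: int):
        self.channel = channel

    def predict(self, x):
        return np.asarray(x[self.channel], dtype=np.float32)


class _ConstSegmenter:
    """Interactive segmenter emitting a fixed probability volume."""

    uses_memory = False
    sigma_vox = 2.0

    def __init__(self, prob):
        self.prob = prob

    def predict_initial(self, pair):
        return ProbabilityVolume(self.prob, pair.spacing_mm)

    def predict_refine(self, pair, prev, channels):
        return ProbabilityVolume(self.prob, pair.spacing_mm)


class TestInitial:
    def test_session_t0_is_the_plain_initial_forward(self, tiny_phantom, segmenter):
        trace = run_session(
            tiny_phantom.pair, tiny_phantom.gt, segmenter, 0, np.random.default_rng(0)
        )
        assert len(trace) == 1 and len(trace.clicks[0]) == 0
        standalone = run_initial(tiny_phantom.pair, segmenter.initial)
        np.testing.assert_array_equal(trace.probs[0].data, standalone.data)

    def test_inference_is_deterministic(self, tiny_phantom, tiny_nets):
        a = run_initial(tiny_phantom.pair, tiny_nets[2])
        b = run_initial(tiny_phantom.pair, tiny_nets[2])
        np.testing.assert_array_equal(a.data, b.data)


class TestRefineStep:
    def test_empty_clickset_rejected(self, tiny_phantom):
        prev = ProbabilityVolume(np.full(tiny_phantom.pair.shape, 0.5, np.float32))
        with pytest.raises(ValueError, match="click"):
            refine_step(tiny_phantom.pair, prev, ClickSet(), _StubModel(2))

    def test_identity_stub_reaches_fixed_point(self, tiny_phantom, rng):
        """A refinement model that returns its memory channel leaves the
        probability volume unchanged."""
        prev = ProbabilityVolume(
            rng.random(tiny_phantom.pair.shape).astype(np.float32)
        )
        clicks = ClickSet([Click((4, 4, 4), POSITIVE, 1)])
        out = refine_step(tiny_phantom.pair, prev, clicks, _StubModel(2))
        np.testing.assert_array_equal(out.data, prev.data)


class TestSessionLoop:
    def test_click_count_equals_interaction_index(self, tiny_phantom, segmenter):
        trace = run_session(
            tiny_phantom.pair, tiny_phantom.gt, segmenter, 4, np.random.default_rng(1)
        )
        for t, cs in enumerate(trace.clicks):
            if trace.converged_at is None or t <= trace.converged_at:
                assert len(cs) == t

    def test_every_click_lies_in_preceding_disagreement(self, tiny_phantom, segmenter):
        trace = run_session(
            tiny_phantom.pair, tiny_phantom.gt, segmenter, 4, np.random.default_rng(2)
        )
        for t in range(1, len(trace.clicks)):
            if len(trace.clicks[t]) == len(trace.clicks[t - 1]):
                continue  # converged-frozen tail
            click = trace.clicks[t][-1]
            err = trace.masks[t - 1].data.astype(bool) ^ tiny_phantom.gt.data.astype(bool)
            assert err[click.coord]

    def test_identical_seeds_reproduce_the_trace(self, tiny_phantom, segmenter):
        a = run_session(tiny_phantom.pair, tiny_phantom.gt, segmenter, 3,
                        np.random.default_rng(5))
        b = run_session(tiny_phantom.pair, tiny_phantom.gt, segmenter, 3,
                        np.random.default_rng(5))
        assert len(a) == len(b)
        for pa, pb in zip(a.probs, b.probs):
            np.testing.assert_array_equal(pa.data, pb.data)
        assert list(a.clicks[-1]) == list(b.clicks[-1])

    def test_perfect_initial_freezes_the_trace(self, tiny_phantom):
        gt_prob = tiny_phantom.gt.data.astype(np.float32)
        seg = _ConstSegmenter(gt_prob)
        trace = run_session(tiny_phantom.pair, tiny_phantom.gt, seg, 3,
                            np.random.default_rng(0))
        assert trace.converged_at == 0
        assert len(trace) == 4 and len(trace.clicks[-1]) == 0
        for p in trace.probs[1:]:
            np.testing.assert_array_equal(p.data, trace.probs[0].data)

    def test_memory_channel_chains_previous_output(self, tiny_phantom, tiny_nets):
        """The refinement input's memory channel at step t must be the t-1
        probability volume bit-exactly."""
        seen = []

        class Spy:
            config = tiny_nets[5].config

            def predict(self, x):
                seen.append(x[2].copy())
                return tiny_nets[5].predict(x)

        seg = TwoStageSegmenter(tiny_nets[2], Spy())
        trace = run_session(tiny_phantom.pair, tiny_phantom.gt, seg, 3,
                            np.random.default_rng(3))
        for t, mem in enumerate(seen, start=1):
            np.testing.assert_array_equal(mem, trace.probs[t - 1].data)

    def test_trace_export_writes_tables(self, tiny_phantom, segmenter, tmp_path):
        trace = run_session(tiny_phantom.pair, tiny_phantom.gt, segmenter, 2,
                            np.random.default_rng(0))
        trace.export(tmp_path)
        assert (tmp_path / "metrics.tsv").exists()
        assert (tmp_path / "clicks.tsv").exists()
        lines = (tmp_path / "metrics.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["t", "dsc", "hd95_mm"]
        assert len(lines) == len(trace) + 1


class TestEnsemble:
    def test_five_identical_members_match_single_model(self, tiny_phantom, tiny_nets):
        single = TwoStageSegmenter(tiny_nets[2], tiny_nets[5])
        members = [TwoStageSegmenter(tiny_nets[2], tiny_nets[5]) for _ in range(5)]
        a = run_session(tiny_phantom.pair, tiny_phantom.gt, single, 3,
                        np.random.default_rng(9))
        b = ensemble_session(tiny_phantom.pair, tiny_phantom.gt, members, 3,
                             np.random.default_rng(9))
        for pa, pb in zip(a.probs, b.probs):
            np.testing.assert_allclose(pa.data, pb.data, atol=1e-6)

    def test_ensemble_probability_is_the_member_mean(self, tiny_phantom):
        lo = _ConstSegmenter(np.full(tiny_phantom.pair.shape, 0.2, np.float32))
        hi = _ConstSegmenter(np.full(tiny_phantom.pair.shape, 0.8, np.float32))
        trace = ensemble_session(tiny_phantom.pair, tiny_phantom.gt, [lo, hi], 0,
                                 np.random.default_rng(0))
        np.testing.assert_allclose(trace.probs[0].data, 0.5, atol=1e-7)

    def test_members_share_click_coordinates(self, tiny_phantom, tiny_nets):
        calls = []

        class Spy:
            config = tiny_nets[5].config

            def __init__(self, tag):
                self.tag = tag

            def predict(self, x):
                calls.append((self.tag, x[3].copy(), x[4].copy()))
                return tiny_nets[5].predict(x)

        members = [TwoStageSegmenter(tiny_nets[2], Spy(i)) for i in range(3)]
        ensemble_session(tiny_phantom.pair, tiny_phantom.gt, members, 2,
                         np.random.default_rng(4))
        # group calls per interaction: every member saw identical channels
        for t in range(len(calls) // 3):
            batch = calls[3 * t : 3 * t + 3]
            for _, pos, neg in batch[1:]:
                np.testing.assert_array_equal(pos, batch[0][1])
                np.testing.assert_array_equal(neg, batch[0][2])

    def test_zero_members_rejected(self, tiny_phantom):
        with pytest.raises(ValueError, match="member"):
            ensemble_session(tiny_phantom.pair, tiny_phantom.gt, [], 1,
                             np.random.default_rng(0))


class TestBaselineSegmenter:
    def test_four_channel_model_accepts_zero_clicks_at_t0(self, tiny_phantom, tiny_nets):
        seg = SingleModelSegmenter(tiny_nets[4])
        p = seg.predict_initial(tiny_phantom.pair)
        assert p.shape == tiny_phantom.pair.shape
        assert p.data.min() >= 0.0 and p.data.max() <= 1.0
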