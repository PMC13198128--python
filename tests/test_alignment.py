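"""InfoNCE correctness, batch sampling, training loop and retrieval."""

import math

import numpy as np
import pytest

from trialign.alignment import (
    AlignmentConfig,
    BatchPlan,
    TriModalBatch,
    combined_loss,
    encode_corpus,
    info_nce,
    pretrain,
    retrieve,
    sample_batch,
)
from trialign.corpus_io import build_manifest, CorpusManifest
from trialign.synthetic_data import SyntheticSpec, generate_corpus


def brute_force_info_nce(Q, K, tau):
    """Independent per-row softmax evaluation with explicit loops."""
    n = len(Q)
    total = 0.0
    for i in range(n):
        scores = [math.exp(float(np.dot(Q[i], K[j])) / tau) for j in range(n)]
        total += -math.log(scores[i] / sum(scores))
    return total / n


class TestInfoNCE:
    def test_matches_brute_force_on_100_random_8x8(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            Q = rng.normal(size=(8, 8))
            K = rng.normal(size=(8, 8))
            Q /= np.linalg.norm(Q, axis=1, keepdims=True)
            K /= np.linalg.norm(K, axis=1, keepdims=True)
            tau = float(rng.uniform(0.05, 2.0))
            assert info_nce(Q, K, tau) == pytest.approx(brute_force_info_nce(Q, K, tau), abs=1e-6)

    @pytest.mark.parametrize("N", [2, 16, 80])
    def test_identical_rows_give_ln_n(self, N):
        rng = np.random.default_rng(1)
        v = rng.normal(size=4)
        v /= np.linalg.norm(v)
        M = np.tile(v, (N, 1))
        assert info_nce(M, M, 0.07) == pytest.approx(math.log(N), abs=1e-9)

    def test_orthogonal_aligned_closed_form(self):
        Q = np.eye(2)
        K = np.eye(2)
        assert info_nce(Q, K, 1.0) == pytest.approx(math.log(1 + math.exp(-1)), abs=1e-9)

    def test_fewer_than_two_rows_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            info_nce(np.ones((1, 3)), np.ones((1, 3)), 0.07)

    def test_non_finite_errors(self):
        Q = np.ones((2, 3))
        K = np.ones((2, 3))
        K[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            info_nce(Q, K, 0.07)

    def test_temperature_drives_loss_toward_ln_n(self):
        rng = np.random.default_rng(5)
        Q = rng.normal(size=(8, 8))
        K = rng.normal(size=(8, 8))
        gaps = [abs(info_nce(Q, K, t) - math.log(8)) for t in (0.07, 0.7, 7.0, 700.0)]
        assert gaps == sorted(gaps, reverse=True)


class TestCombinedLoss:
    def _batch(self, rng, n1=4, n2=5, d=6):
        def unit(n):
            M = rng.normal(size=(n, d))
            return M / np.linalg.norm(M, axis=1, keepdims=True)

        return TriModalBatch(
            seq_for_struct=unit(n1), struct=unit(n1), seq_for_text=unit(n2), text=unit(n2)
        )

    def test_missing_structure_subset_gives_text_loss_exactly(self):
        rng = np.random.default_rng(0)
        b = self._batch(rng)
        b_no_struct = TriModalBatch(
            seq_for_struct=None, struct=None, seq_for_text=b.seq_for_text, text=b.text
        )
        total, breakdown = combined_loss(b_no_struct, AlignmentConfig())
        assert total == pytest.approx(info_nce(b.seq_for_text, b.text, 0.07), abs=1e-12)
        assert breakdown["missing"] == ["seq_struct"]

    def test_equal_weights_sum(self):
        rng = np.random.default_rng(1)
        b = self._batch(rng)
        total, bd = combined_loss(b, AlignmentConfig())
        assert total == pytest.approx(bd["seq_struct"] + bd["seq_text"], abs=1e-12)

    def test_within_subset_permutation_invariance(self):
        rng = np.random.default_rng(2)
        b = self._batch(rng)
        perm1, perm2 = rng.permutation(4), rng.permutation(5)
        b2 = TriModalBatch(
            seq_for_struct=b.seq_for_struct[perm1],
            struct=b.struct[perm1],
            seq_for_text=b.seq_for_text[perm2],
            text=b.text[perm2],
        )
        t1, _ = combined_loss(b, AlignmentConfig())
        t2, _ = combined_loss(b2, AlignmentConfig())
        assert t1 == pytest.approx(t2, abs=1e-6)

    def test_both_subsets_empty_errors(self):
        with pytest.raises(ValueError):
            combined_loss(TriModalBatch(None, None, None, None), AlignmentConfig())

    def test_average_reduction_halves_sum(self):
        rng = np.random.default_rng(3)
        b = self._batch(rng)
        t_sum, _ = combined_loss(b, AlignmentConfig(loss_reduction="sum"))
        t_avg, _ = combined_loss(b, AlignmentConfig(loss_reduction="average"))
        assert t_avg == pytest.approx(t_sum / 2, abs=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AlignmentConfig(temperature=0.0)
        with pytest.raises(ValueError):
            AlignmentConfig(batch_struct=1)
        with pytest.raises(ValueError):
            AlignmentConfig(w_seq_text=-0.5)


class TestSampleBatch:
    def _manifest(self, n_struct, n_text):
        return CorpusManifest(
            seq_text_ids=tuple(f"t{i}" for i in range(n_text)),
            seq_struct_ids=tuple(f"s{i}" for i in range(n_struct)),
        )

    def test_exhaustive_draw_covers_every_pair(self):
        m = self._manifest(6, 10)
        cfg = AlignmentConfig(batch_struct=6, batch_text=10)
        plan = sample_batch(m, cfg, np.random.default_rng(0))
        assert sorted(plan.struct_ids) == sorted(m.seq_struct_ids)
        assert sorted(plan.text_ids) == sorted(m.seq_text_ids)

    def test_seed_determinism(self):
        m = self._manifest(20, 30)
        cfg = AlignmentConfig(batch_struct=5, batch_text=7)
        p1 = sample_batch(m, cfg, np.random.default_rng(42))
        p2 = sample_batch(m, cfg, np.random.default_rng(42))
        assert p1 == p2

    def test_oversized_request_errors_without_replacement(self):
        m = self._manifest(3, 10)
        cfg = AlignmentConfig(batch_struct=5, batch_text=5)
        with pytest.raises(ValueError, match="with_replacement"):
            sample_batch(m, cfg, np.random.default_rng(0))
        cfg2 = AlignmentConfig(batch_struct=5, batch_text=5, with_replacement=True)
        plan = sample_batch(m, cfg2, np.random.default_rng(0))
        assert len(plan.struct_ids) == 5

    def test_selection_frequencies_within_3_sigma(self):
        m = self._manifest(10, 10)
        cfg = AlignmentConfig(batch_struct=2, batch_text=2)
        rng = np.random.default_rng(7)
        counts = {i: 0 for i in m.seq_struct_ids}
        draws = 10_000
        for _ in range(draws):
            for rid in sample_batch(m, cfg, rng).struct_ids:
                counts[rid] += 1
        p = 2 / 10
        sigma = math.sqrt(draws * p * (1 - p))
        for c in counts.values():
            assert abs(c - draws * p) < 3 * sigma


class TestPretrainLoop:
    def test_overfit_one_repeated_batch(self):
        # memorisation check: every record must be distinguishable in every
        # modality, so use large coordinate noise (default structures are
        # deliberately class-identical and bound the loss from below)
        records, _ = generate_corpus(SyntheticSpec(n=8, K=2, structure_coverage=1.0, noise_sigma=0.5, seed=3))
        cfg = AlignmentConfig(batch_struct=8, batch_text=8, total_steps=200, lr=1e-3, seed=0)
        result = pretrain(records, cfg)
        first = result.history[0]["total"]
        last = np.mean([h["total"] for h in result.history[-5:]])
        assert last < 0.1 * first

    def test_same_seed_identical_trajectories(self):
        records, _ = generate_corpus(SyntheticSpec(n=20, K=2, structure_coverage=0.5, seed=1))
        cfg = AlignmentConfig(batch_struct=4, batch_text=4, total_steps=8, lr=1e-3, seed=9)
        h1 = [h["total"] for h in pretrain(records, cfg).history]
        h2 = [h["total"] for h in pretrain(records, cfg).history]
        assert h1 == h2

    def test_resume_reproduces_trajectory(self):
        records, _ = generate_corpus(SyntheticSpec(n=20, K=2, structure_coverage=0.5, seed=1))
        cfg_full = AlignmentConfig(batch_struct=4, batch_text=4, total_steps=12, lr=1e-3, seed=2)
        full = pretrain(records, cfg_full)
        half = pretrain(records, cfg_full, keep_state=True, stop_after=6)
        assert len(half.history) == 6
        resumed = pretrain(records, cfg_full, resume_state=half.state)
        assert [h["total"] for h in resumed.history] == [h["total"] for h in full.history]

    def test_text_only_corpus_trains_without_structures(self):
        records, _ = generate_corpus(SyntheticSpec(n=12, K=2, structure_coverage=0.0, seed=5))
        cfg = AlignmentConfig(batch_struct=4, batch_text=4, total_steps=3, lr=1e-3, seed=0)
        result = pretrain(records, cfg)
        assert all(h["n_struct"] == 0 for h in result.history)
        assert all(h["loss_seq_struct"] == 0.0 for h in result.history)

    def test_every_texted_record_participates(self):
        records, _ = generate_corpus(SyntheticSpec(n=10, K=2, structure_coverage=0.5, seed=6))
        cfg = AlignmentConfig(batch_struct=4, batch_text=5, total_steps=30, lr=1e-3, seed=0)
        result = pretrain(records, cfg)
        assert set(result.text_participation) == {r.id for r in records if r.text is not None}
        assert all(v > 0 for v in result.text_participation.values())


class TestRetrieve:
    def test_gallery_equals_queries_recall_one(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(10, 4))
        out = retrieve(Q, Q, ks=(1,))
        assert out["recall@1"] == 1.0

    def test_identical_labels_class_top1_one(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(6, 4))
        G = rng.normal(size=(6, 4))
        out = retrieve(Q, G, ks=(1,), labels=[3] * 6)
        assert out["class_top1"] == 1.0

    def test_k_exceeding_gallery_errors(self):
        Q = np.eye(3)
        with pytest.raises(ValueError, match="exceeds"):
            retrieve(Q, Q, ks=(4,))

    def test_chance_level_recall_for_random_vectors(self):
        recalls = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            Q = rng.normal(size=(100, 16))
            G = rng.normal(size=(100, 16))
            recalls.append(retrieve(Q, G, ks=(1,))["recall@1"])
        mean = float(np.mean(recalls))
        p = 1 / 100
        sigma = math.sqrt(p * (1 - p) / (100 * 50))
        assert abs(mean - p) < 3 * sigma


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=40)
@given(st.integers(min_value=2, max_value=60), st.integers(min_value=0, max_value=10_000))
def test_uniform_similarity_loss_is_ln_n_property(N, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=5)
    v /= np.linalg.norm(v)
    M = np.tile(v, (N, 1))
    assert info_nce(M, M, 0.07) == pytest.approx(math.log(N), abs=1e-9)


@settings(derandomize=True, max_examples=30)
@given(st.integers(min_value=0, max_value=10_000))
def test_combined_loss_subset_swap_invariance_property(seed):
    # swapping which subset is structure and which is text swaps the
    # per-term breakdown but leaves the equal-weight total unchanged
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(4, 6)); A /= np.linalg.norm(A, axis=1, keepdims=True)
    B = rng.normal(size=(4, 6)); B /= np.linalg.norm(B, axis=1, keepdims=True)
    C = rng.normal(size=(5, 6)); C /= np.linalg.norm(C, axis=1, keepdims=True)
    D = rng.normal(size=(5, 6)); D /= np.linalg.norm(D, axis=1, keepdims=True)
    t1, _ = combined_loss(TriModalBatch(A, B, C, D), AlignmentConfig())
    t2, _ = combined_loss(TriModalBatch(C, D, A, B), AlignmentConfig())
    assert t1 == pytest.approx(t2, abs=1e-9)


def test_checkpoint_cadence_epoch_and_best(tmp_path):
    from trialign.encoders import load_checkpoint

    records, _ = generate_corpus(SyntheticSpec(n=12, K=2, structure_coverage=0.5, seed=4))
    # 12 texts / batch 4 -> 3 steps per epoch; 6 steps = 2 epoch boundaries
    cfg = AlignmentConfig(batch_struct=4, batch_text=4, total_steps=6, lr=1e-3, seed=0)
    result = pretrain(records, cfg, checkpoint_dir=tmp_path / "ckpt")
    params, cfgs, vocab, meta = load_checkpoint(tmp_path / "ckpt")
    assert meta["step"] == 6
    _, _, _, best_meta = load_checkpoint(tmp_path / "ckpt" / "best")
    assert best_meta["loss"] == min(h["total"] for h in result.history)
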