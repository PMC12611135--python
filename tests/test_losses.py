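"""Triplet hinge, schedule, combined loss and constrained mining."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from salr.losses import (
    LossConfig,
    Triplet,
    TripletMiner,
    combined_loss,
    gamma_schedule,
    mine_triplets,
    triplet_margin_loss,
    triplet_margin_loss_batch,
    triplets_to_frame,
)
from _oracles import brute_force_triplets, random_small_metadata
from conftest import make_manifest, metadata_frame


STATED = LossConfig(formula_variant="stated_aims")
LITERAL = LossConfig(formula_variant="literal_printed")

# hand-arithmetic oracle: (anchor, positive, negative, margin) -> expected
# loss under each variant, computed from d(a,p) and d(a,n) by hand
HAND_CASES = [
    # a==p: d_ap=0, d_an=1
    ((0.0, 0.0), (0.0, 0.0), (0.0, 1.0), 0.05, 0.0, 1.05),
    # d_ap=5 (3-4-5 triangle), d_an=1
    ((0.0, 0.0), (3.0, 4.0), (0.0, 1.0), 0.05, 4.05, 0.0),
    # symmetric distances: only the margin survives
    ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0), 0.05, 0.05, 0.05),
    ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0), 0.0, 0.0, 0.0),
    # d_ap=2, d_an=6
    ((1.0, 1.0), (3.0, 1.0), (1.0, 7.0), 0.5, 0.0, 4.5),
    # d_ap=6, d_an=2
    ((1.0, 1.0), (1.0, 7.0), (3.0, 1.0), 0.5, 4.5, 0.0),
    # a==p==n and zero margin
    ((2.0, 2.0), (2.0, 2.0), (2.0, 2.0), 0.0, 0.0, 0.0),
    # a==p==n with margin: hinge equals the margin in both variants
    ((2.0, 2.0), (2.0, 2.0), (2.0, 2.0), 0.3, 0.3, 0.3),
    # 1-D: d_ap=2, d_an=3
    ((0.0,), (2.0,), (-3.0,), 0.05, 0.0, 1.05),
    # 3-D: d_ap=3, d_an=sqrt(3)
    ((0.0, 0.0, 0.0), (1.0, 2.0, 2.0), (1.0, 1.0, 1.0), 0.1,
     3.0 - np.sqrt(3.0) + 0.1, 0.0),
    # exactly-at-margin boundary: hinge argument is 0 -> loss 0
    ((0.0, 0.0), (1.0, 0.0), (0.0, 1.05), 0.05, 0.0, 0.1),
]


class TestTripletMarginLoss:
    @pytest.mark.parametrize("a,p,n,m,stated,literal", HAND_CASES)
    def test_hand_arithmetic_both_variants(self, a, p, n, m, stated, literal):
        cs = LossConfig(margin=m, formula_variant="stated_aims")
        cl = LossConfig(margin=m, formula_variant="literal_printed")
        assert triplet_margin_loss(a, p, n, cs) == pytest.approx(stated, abs=1e-12)
        assert triplet_margin_loss(a, p, n, cl) == pytest.approx(literal, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            triplet_margin_loss((0.0, 0.0), (1.0,), (0.0, 1.0), STATED)

    @pytest.mark.parametrize("variant", ["stated_aims", "literal_printed"])
    def test_nonnegative_and_translation_invariant_on_random_triplets(self, variant):
        cfg = LossConfig(formula_variant=variant)
        rng = np.random.default_rng(17)
        A, P, N = (rng.standard_normal((1000, 5)) for _ in range(3))
        shift = rng.standard_normal(5)
        losses, _ = triplet_margin_loss_batch(A, P, N, cfg)
        shifted, _ = triplet_margin_loss_batch(A + shift, P + shift, N + shift, cfg)
        assert np.all(losses >= 0.0)
        np.testing.assert_allclose(losses, shifted, atol=1e-10)

    def test_batch_gradients_zero_when_hinge_inactive(self):
        a = np.array([[0.0, 0.0]])
        p = np.array([[0.0, 0.1]])
        n = np.array([[5.0, 0.0]])
        losses, (dA, dP, dN) = triplet_margin_loss_batch(a, p, n, STATED)
        assert losses[0] == 0.0
        assert not dA.any() and not dP.any() and not dN.any()


class TestSchedules:
    @pytest.mark.parametrize(
        "step,warmup,expected",
        [(0, 3000, 0.0), (2999, 3000, 0.0), (3000, 3000, 1.0),
         (10**6, 3000, 1.0), (0, 0, 1.0), (5, 0, 1.0)],
    )
    def test_gamma_schedule(self, step, warmup, expected):
        assert gamma_schedule(step, LossConfig(gamma_warmup_steps=warmup)) == expected

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            gamma_schedule(-1, STATED)

    def test_combined_loss_hand_arithmetic(self):
        cfg = LossConfig(epsilon=0.01, gamma_warmup_steps=3000)
        assert combined_loss(2.0, 5.0, 0, cfg) == pytest.approx(0.02)
        assert combined_loss(2.0, 5.0, 3000, cfg) == pytest.approx(5.02)
        assert combined_loss(0.0, 5.0, 3000, cfg) == pytest.approx(5.0)

    def test_combined_loss_ce_only_reduction(self):
        cfg = LossConfig(epsilon=0.0, gamma_warmup_steps=0)
        assert combined_loss(123.0, 0.7, 0, cfg) == 0.7

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            combined_loss(np.nan, 1.0, 0, STATED)


@given(
    a=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
    p=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
    n=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
    m=st.floats(0, 2),
    shift=st.floats(-20, 20),
    variant=st.sampled_from(["stated_aims", "literal_printed"]),
)
@settings(deadline=None, max_examples=200, derandomize=True)
def test_hinge_properties(a, p, n, m, shift, variant):
    """Nonnegativity, the zero-case, and translation invariance of the hinge."""
    cfg = LossConfig(margin=m, formula_variant=variant)
    a, p, n = np.array(a), np.array(p), np.array(n)
    loss = triplet_margin_loss(a, p, n, cfg)
    assert loss >= 0.0
    d_ap = np.linalg.norm(a - p)
    d_an = np.linalg.norm(a - n)
    arg = (d_ap - d_an if variant == "stated_aims" else d_an - d_ap) + m
    if arg <= 0:
        assert loss == 0.0
    shifted = triplet_margin_loss(a + shift, p + shift, n + shift, cfg)
    assert shifted == pytest.approx(loss, abs=1e-8)


class TestMining:
    def test_two_speaker_two_word_enumeration(self, two_speaker_manifest):
        """Exhaustive enumeration of the smallest nontrivial case: 4 triplets."""
        triplets = mine_triplets(two_speaker_manifest, n_triplets=100, rng_seed=0)
        got = {(t.anchor_id, t.positive_id, t.negative_id) for t in triplets}
        assert len(got) == 4
        assert got == brute_force_triplets(metadata_frame(two_speaker_manifest))

    def test_specific_triplet_roles(self, two_speaker_manifest):
        # anchor w1@S1, positive w2@S2 (same severity), negative w2@S1
        triplets = mine_triplets(two_speaker_manifest, n_triplets=100, rng_seed=0)
        assert Triplet("S1_B1_w1", "S2_B1_w2", "S1_B1_w2") in triplets

    def test_single_speaker_severity_class_yields_nothing(self):
        m = make_manifest(
            rows=[("S1", "w1", "uncommon", 1), ("S1", "w2", "uncommon", 1),
                  ("S2", "w1", "uncommon", 1), ("S2", "w2", "uncommon", 1)],
            speakers={"S1": ("low", 60.0), "S2": ("high", 10.0)},
        )
        with pytest.warns(UserWarning, match="no valid triplet"):
            assert mine_triplets(m, n_triplets=10, rng_seed=0) == []

    def test_sampled_triplets_always_satisfy_constraints(self, small_corpus):
        _, manifest, _ = small_corpus
        meta = metadata_frame(manifest).set_index("utterance_id")
        sev = {r.speaker_id: int(r.severity) for r in manifest.records}
        triplets = mine_triplets(manifest, n_triplets=500, rng_seed=3)
        assert len(triplets) == 500
        for t in triplets:
            a, p, n = meta.loc[t.anchor_id], meta.loc[t.positive_id], meta.loc[t.negative_id]
            assert a.speaker_id == n.speaker_id
            assert a.word_id != n.word_id
            assert p.word_id == n.word_id
            assert p.speaker_id != a.speaker_id
            assert sev[p.speaker_id] == sev[a.speaker_id]

    def test_mining_reproducible_from_seed(self, small_corpus):
        _, manifest, _ = small_corpus
        t1 = mine_triplets(manifest, n_triplets=50, rng_seed=5)
        t2 = mine_triplets(manifest, n_triplets=50, rng_seed=5)
        assert t1 == t2

    def test_matches_brute_force_on_random_small_tables(self):
        """Oracle equivalence on 40 random metadata tables (<=6 spk, <=4 words)."""
        rng = np.random.default_rng(99)
        nonempty = 0
        for _ in range(40):
            meta = random_small_metadata(rng)
            if meta.empty:
                continue
            expected = brute_force_triplets(meta)
            miner = TripletMiner(meta)
            assert miner.total_count == len(expected)
            got = {
                (t.anchor_id, t.positive_id, t.negative_id)
                for t in miner.enumerate_all()
            }
            assert got == expected
            nonempty += len(expected) > 0
        assert nonempty >= 5  # the family genuinely exercises mining

    def test_export_frame_columns(self, two_speaker_manifest):
        triplets = mine_triplets(two_speaker_manifest, n_triplets=100, rng_seed=0)
        df = triplets_to_frame(triplets)
        assert list(df.columns) == ["anchor_id", "positive_id", "negative_id"]
        assert len(df) == len(triplets)
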