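import numpy as np
import pytest

from rnamod.interpretation import (
    AttentionProfile,
    PositionFrequencyMatrix,
    export_meme_minimal,
    extract_token_attention,
    harvest_motif,
    parse_meme_minimal,
    substrate_scan,
    token_to_position_scores,
)
from rnamod.io import SequenceRecord
from rnamod.tokenization import build_vocab, encode_tokens


def _toks(seq="GAUUACAUGGCA", k=3, max_len=32):
    return encode_tokens(seq, build_vocab(k), max_len=max_len)


class TestTokenAttention:
    def test_scores_cover_kmers_only_and_form_softmax_subrow(self, tiny_encoder):
        toks = _toks()
        scores = extract_token_attention(tiny_encoder, toks)
        assert scores.shape == (toks.n_kmers,)
        assert np.all(scores >= 0) and scores.sum() <= 1.0 + 1e-9

    def test_default_policy_is_last_layer(self, tiny_encoder):
        toks = _toks()
        default = extract_token_attention(tiny_encoder, toks)
        explicit = extract_token_attention(tiny_encoder, toks, layer=1)
        first = extract_token_attention(tiny_encoder, toks, layer=0)
        assert np.array_equal(default, explicit)
        assert not np.array_equal(default, first)

    def test_head_mean_equals_hand_average(self, tiny_encoder):
        toks = _toks()
        mean = extract_token_attention(tiny_encoder, toks, head="mean")
        per_head = [
            extract_token_attention(tiny_encoder, toks, head=h) for h in range(4)
        ]
        assert np.allclose(mean, np.mean(per_head, axis=0), atol=1e-12)

    def test_out_of_range_layer_and_head(self, tiny_encoder):
        toks = _toks()
        with pytest.raises(IndexError):
            extract_token_attention(tiny_encoder, toks, layer=5)
        with pytest.raises(IndexError):
            extract_token_attention(tiny_encoder, toks, head=9)


class TestPositionScores:
    def test_uniform_token_scores_normalize_to_ones(self):
        out = token_to_position_scores(np.full(6, 0.2), k=3, L=8)
        assert np.array_equal(out, np.ones(8))

    def test_single_nonzero_token_supports_exactly_its_window(self):
        # brute-force coverage oracle for every token index
        L, k = 10, 3
        for t in range(L - k + 1):
            scores = np.zeros(L - k + 1)
            scores[t] = 1.0
            out = token_to_position_scores(scores, k, L)
            support = set(np.flatnonzero(out))
            assert support == {t, t + 1, t + 2}

    def test_degenerate_single_token_sequence(self):
        out = token_to_position_scores(np.array([0.7]), k=3, L=3)
        assert np.array_equal(out, np.ones(3))

    def test_all_zero_profile_stays_zero(self):
        out = token_to_position_scores(np.zeros(4), k=3, L=6)
        assert np.array_equal(out, np.zeros(6))

    def test_count_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            token_to_position_scores(np.ones(5), k=3, L=10)

    def test_support_conservation(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=8) * (rng.uniform(size=8) > 0.5)
        L, k = 10, 3
        out = token_to_position_scores(scores, k, L)
        raw_support = {
            i
            for i in range(L)
            if any(
                scores[t] > 0
                for t in range(max(0, i - k + 1), min(i, L - k) + 1)
            )
        }
        # normalization can zero the minimum, so compare raw coverage
        assert set(np.flatnonzero(out)) <= raw_support

    def test_minmax_normalization_is_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=9)
        once = token_to_position_scores(x, k=3, L=11)
        span = once.max() - once.min()
        again = (once - once.min()) / span
        assert np.allclose(once, again)


def _profile(seq_id, scores):
    return AttentionProfile(
        sequence_id=seq_id, k=3, token_scores=None, position_scores=np.asarray(scores)
    )


class TestHarvestMotif:
    def test_identical_peaked_sequences_give_single_base_columns(self):
        seq = "ACGUACGUACG"
        scores = np.zeros(11)
        scores[3:8] = [0.5, 0.8, 1.0, 0.8, 0.5]
        profiles = [_profile(f"s{i}", scores) for i in range(6)]
        pfm = harvest_motif([seq] * 6, profiles, width=5)
        assert pfm.n_windows == 6
        assert np.all(pfm.counts.max(axis=0) == 6)
        assert pfm.consensus() == seq[3:8]

    def test_column_sums_equal_window_count(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGU"), size=15)) for _ in range(10)]
        profiles = [_profile(f"s{i}", rng.uniform(size=15)) for i in range(10)]
        pfm = harvest_motif(seqs, profiles, width=5)
        assert np.all(pfm.counts.sum(axis=0) == pfm.n_windows)

    def test_flat_profiles_are_filtered_by_quantile(self):
        profiles = [_profile("s", np.ones(11))]
        pfm = harvest_motif(["ACGUACGUACG"], profiles, width=5, quantile=0.75)
        assert pfm.n_windows == 0

    def test_window_wider_than_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            harvest_motif(["ACGU"], [_profile("s", np.ones(4))], width=5)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            harvest_motif(["ACGUAC"], [_profile("s", np.ones(6))], width=4)


class TestMemeExport:
    def _pfm(self):
        counts = np.array(
            [[10, 0, 3], [0, 10, 3], [0, 0, 2], [0, 0, 2]], dtype=float
        )
        return PositionFrequencyMatrix(counts=counts, n_windows=10)

    def test_pure_column_normalizes_to_unit_row(self):
        lines = export_meme_minimal(self._pfm()).splitlines()
        header_idx = next(
            i for i, l in enumerate(lines) if l.startswith("letter-probability")
        )
        assert lines[header_idx + 1].split() == [
            "1.000000", "0.000000", "0.000000", "0.000000"
        ]

    def test_header_declares_meme_version(self):
        assert export_meme_minimal(self._pfm()).startswith("MEME version")

    def test_roundtrip_recovers_probabilities(self):
        pfm = self._pfm()
        back = parse_meme_minimal(export_meme_minimal(pfm))
        assert np.allclose(back, pfm.probabilities(), atol=1e-6)

    def test_zero_windows_is_an_error(self):
        empty = PositionFrequencyMatrix(counts=np.zeros((4, 3)), n_windows=0)
        with pytest.raises(ValueError):
            export_meme_minimal(empty)


def _records(seqs, label=1):
    return [SequenceRecord(f"r{label}_{i}", s, label) for i, s in enumerate(seqs)]


class TestSubstrateScan:
    @staticmethod
    def _planted(n, motif="U.AAU", L=21, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            seq = list("".join(rng.choice(list("ACGU"), size=L)))
            start = L // 2 - len(motif) // 2
            for j, ch in enumerate(motif):
                if ch != ".":
                    seq[start + j] = ch
            out.append("".join(seq))
        return out

    def test_wildcard_match_rate_in_uniform_background(self):
        # exactly 4 of the 4^5 equiprobable 5-mers match U.AAU -> (1/4)^4
        from itertools import product

        n_match = sum(
            all(p == "." or p == c for p, c in zip("U.AAU", word))
            for word in product("ACGU", repeat=5)
        )
        assert n_match / 4**5 == pytest.approx(0.25**4)

    def test_planted_pattern_ranks_first(self):
        rng = np.random.default_rng(1)
        pos = _records(self._planted(80, seed=1))
        bg = _records(
            ["".join(rng.choice(list("ACGU"), size=21)) for _ in range(80)], label=0
        )
        top = substrate_scan(pos, bg, width=5)[0]
        # the top pattern must not contradict the planted motif
        assert all(
            a == "." or b == "." or a == b for a, b in zip(top.pattern, "U.AAU")
        )
        assert sum(a == b for a, b in zip(top.pattern, "U.AAU") if b != ".") >= 3

    def test_no_enrichment_when_positives_equal_background(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            seqs = ["".join(rng.choice(list("ACGU"), size=21)) for _ in range(60)]
            found = substrate_scan(_records(seqs), _records(seqs, 0), width=5)
            assert found == []

    def test_width_exceeding_sequences_is_an_error(self):
        with pytest.raises(ValueError):
            substrate_scan(_records(["ACGU"]), _records(["ACGU"], 0), width=5)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            substrate_scan([], _records(["ACGUACGU"]), width=3)
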