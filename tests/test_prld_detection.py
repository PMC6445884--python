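import math
from collections import Counter

import numpy as np
import pytest

from prionscape._validation import ValidationError
from prionscape.prld_detection import (AMINO_ACIDS, AmyloidMatrix,
                                       CompositionModel, amyloid_core_score,
                                       call_prionlike,
                                       estimate_background_frequencies,
                                       find_prion_domain, llr_profile,
                                       read_fasta)
from prionscape.synthetic_data import generate_proteome, write_proteome_fasta


def brute_force_core(profile, core_length):
    """O(n*L) exhaustive window-sum oracle; returns (start, score) or None."""
    n = len(profile)
    if n < core_length:
        return None
    best_start, best_score = 0, -math.inf
    for s in range(n - core_length + 1):
        score = sum(profile[s:s + core_length])
        if score > best_score + 1e-12:
            best_start, best_score = s, score
    if best_score <= 0:
        return None
    return best_start, best_score


def brute_force_amyloid(seq, matrix):
    """Exhaustive 21-mer enumeration oracle."""
    best = None
    for s in range(len(seq) - 20):
        window = seq[s:s + 21]
        if any(ch not in AMINO_ACIDS for ch in window):
            continue
        raw = sum(matrix.weights[k, AMINO_ACIDS.index(ch)]
                  for k, ch in enumerate(window))
        if best is None or raw > best[1] + 1e-12:
            best = (s, raw)
    if best is None:
        return None
    return best[0], matrix.rescale(best[1])


class TestBackgroundFrequencies:
    def test_single_sequence_poly_a(self):
        freqs = estimate_background_frequencies(["AAAA"])
        assert freqs["A"] == pytest.approx(1.0, abs=1e-4)
        assert abs(sum(freqs.values()) - 1.0) < 1e-9

    def test_concatenation_invariance(self):
        s1, s2 = "ACDEFGHIK", "LMNPQRSTVWY"
        assert estimate_background_frequencies([s1, s2]) == \
            estimate_background_frequencies([s1 + s2])

    def test_matches_direct_tally(self):
        proteome = generate_proteome(30, 0.1, seed=1)
        seqs = [s for _, _, s in proteome.records]
        freqs = estimate_background_frequencies(seqs)
        counts = Counter("".join(seqs))
        total = sum(counts[aa] for aa in AMINO_ACIDS)
        for aa in AMINO_ACIDS:
            assert freqs[aa] == pytest.approx(counts[aa] / total, abs=1e-4)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValidationError):
            estimate_background_frequencies([])


class TestLLRProfile:
    def test_identity_model_all_zero(self, uniform_model):
        profile = llr_profile("ACDEFGHIKLMNPQRSTVWY" * 3, uniform_model)
        assert np.allclose(profile, 0.0)

    def test_monotone_in_prion_freq(self, default_model):
        base = dict(default_model.prion_freqs)
        boosted = dict(base)
        boosted["Q"] = base["Q"] * 1.5
        total = sum(boosted.values())
        boosted = {aa: v / total for aa, v in boosted.items()}
        m2 = CompositionModel(boosted, default_model.background_freqs)
        assert llr_profile("Q", m2)[0] > llr_profile("Q", default_model)[0]

    def test_elementwise_oracle(self, default_model, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=200))
        profile = llr_profile(seq, default_model)
        expected = [
            math.log(default_model.prion_freqs[ch]
                     / default_model.background_freqs[ch])
            for ch in seq
        ]
        assert np.allclose(profile, expected)

    def test_unknown_residues_score_zero(self, default_model):
        profile = llr_profile("QXQ", default_model)
        assert profile[1] == 0.0
        assert profile[0] != 0.0

    def test_length_matches(self, default_model):
        assert llr_profile("QNQNQ", default_model).size == 5


class TestFindPrionDomain:
    def test_all_negative_no_call(self, default_model):
        profile = -np.ones(200)
        assert find_prion_domain(profile, default_model) is None

    def test_short_sequence_no_call(self, default_model):
        assert find_prion_domain(np.ones(59), default_model) is None

    def test_constructed_block(self, uniform_model):
        profile = np.concatenate([-np.ones(30), np.ones(60), -np.ones(30)])
        (start, end), score = find_prion_domain(profile, uniform_model)
        assert (start, end) == (30, 90)
        assert score == pytest.approx(60.0)

    def test_leftmost_tie_break(self, uniform_model):
        profile = np.ones(120)  # every window ties
        (start, _), score = find_prion_domain(profile, uniform_model)
        assert start == 0 and score == pytest.approx(60.0)

    def test_brute_force_window_oracle(self, default_model, rng):
        for _ in range(100):
            profile = rng.normal(0.05, 1.0, size=300)
            result = find_prion_domain(profile, default_model)
            oracle = brute_force_core(profile, default_model.core_length)
            if oracle is None:
                assert result is None
            else:
                (start, end), score = result
                assert score == pytest.approx(oracle[1])
                # the best core window lies inside the reported domain
                assert start <= oracle[0] and oracle[0] + 60 <= end


class TestAmyloidCoreScore:
    def test_exact_21mer(self, default_matrix):
        seq = "FYIVML" * 4
        result = amyloid_core_score(seq[:21], default_matrix)
        assert result is not None
        (s, e), score = result
        assert (s, e) == (0, 21)
        assert 0 <= score <= 100

    def test_short_domain_sentinel(self, default_matrix):
        assert amyloid_core_score("FYIVML", default_matrix) is None

    def test_uniform_zero_matrix_constant(self):
        matrix = AmyloidMatrix(weights=np.zeros((21, 20)),
                               score_min=-10.0, score_max=10.0)
        expected = -(-10.0) / 20.0 * 100
        for seq in ("Q" * 30, "FYIVML" * 6):
            _, score = amyloid_core_score(seq, matrix)
            assert score == pytest.approx(expected)

    def test_nonstandard_windows_excluded(self, default_matrix):
        seq = "F" * 10 + "X" + "F" * 30
        (s, e), _ = amyloid_core_score(seq, default_matrix)
        assert s >= 11  # every window containing the X is excluded

    def test_all_windows_excluded(self, default_matrix):
        assert amyloid_core_score("FFFFFFFFFFXFFFFFFFFFF", default_matrix) is None

    def test_brute_force_enumeration_oracle(self, default_matrix, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=80))
            (s, e), score = amyloid_core_score(seq, default_matrix)
            os_, oscore = brute_force_amyloid(seq, default_matrix)
            assert s == os_
            assert score == pytest.approx(oscore)


class TestCallPrionlike:
    def test_zero_cutoff_equals_stage1(self, small_proteome):
        calls = call_prionlike(small_proteome.sequences(), cutoff=0.0)
        for c in calls:
            stage1_with_core = c.passes_composition and \
                c.amyloid_score is not None
            assert c.positive == stage1_with_core

    def test_cutoff_monotonicity(self, small_proteome):
        seqs = small_proteome.sequences()
        pos = {}
        for cutoff in (0.0, 40.0, 60.0, 80.0, 101.0):
            pos[cutoff] = {c.protein_id
                           for c in call_prionlike(seqs, cutoff=cutoff)
                           if c.positive}
        cuts = sorted(pos)
        for lo, hi in zip(cuts, cuts[1:]):
            assert pos[hi] <= pos[lo]

    def test_identity_model_no_candidates(self, small_proteome, uniform_model):
        calls = call_prionlike(small_proteome.sequences(), model=uniform_model)
        assert not any(c.passes_composition for c in calls)

    def test_sorted_by_protein_id(self, small_calls):
        ids = [c.protein_id for c in small_calls]
        assert ids == sorted(ids)

    def test_core_interval_inside_domain(self, small_calls):
        for c in small_calls:
            if c.amyloid_core_start is None:
                continue
            assert c.domain_start <= c.amyloid_core_start
            assert c.amyloid_core_end <= c.domain_end
            assert c.amyloid_core_end - c.amyloid_core_start + 1 == 21

    def test_passes_amyloid_implies_cutoff(self, small_calls, default_matrix):
        for c in small_calls:
            if c.passes_amyloid:
                assert c.amyloid_score >= default_matrix.cutoff

    def test_recovery_on_planted_proteome(self):
        proteome = generate_proteome(500, 0.1, seed=1)
        calls = call_prionlike(proteome.sequences())
        planted = set(proteome.planted_ids)
        positives = {c.protein_id for c in calls if c.positive}
        tp = len(positives & planted)
        fp = len(positives - planted)
        assert tp / len(planted) >= 0.9
        assert 1 - fp / (500 - len(planted)) >= 0.95


class TestFastaRoundTrip:
    def test_read_back(self, small_proteome, tmp_path):
        path = tmp_path / "p.fasta"
        write_proteome_fasta(small_proteome, path)
        records = read_fasta(path)
        assert records == small_proteome.records

    def test_wrapped_lines(self, small_proteome, tmp_path):
        path = tmp_path / "p.fasta"
        write_proteome_fasta(small_proteome, path)
        for line in path.read_text().splitlines():
            assert len(line) <= 63


class TestModelValidation:
    def test_frequencies_must_sum_to_one(self):
        bad = {aa: 0.1 for aa in AMINO_ACIDS}
        with pytest.raises(ValidationError):
            CompositionModel(prion_freqs=bad,
                             background_freqs={aa: 0.05 for aa in AMINO_ACIDS})

    def test_matrix_shape_enforced(self):
        with pytest.raises(ValidationError):
            AmyloidMatrix(weights=np.zeros((20, 20)), score_min=0.0,
                          score_max=1.0)

    def test_rescale_clamped(self, default_matrix):
        assert default_matrix.rescale(default_matrix.score_max + 100) == 100.0
        assert default_matrix.rescale(default_matrix.score_min - 100) == 0.0
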