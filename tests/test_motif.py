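"""PWM scanning, allele-specific affinity deltas, and motif enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from var2func.motif import (
    PWM,
    allele_delta,
    enrichment_test,
    integrate_evidence,
    read_jaspar,
    reverse_complement,
    scan_best,
)
from var2func.synth import gen_allelic_sequences

BASES = "ACGT"


def brute_force_best(pwm, seq):
    """Exhaustive window x strand enumeration with per-base log-odds sums."""
    lo = pwm.log_odds
    best = -np.inf
    for strand_seq in (seq, reverse_complement(seq)):
        for start in range(len(strand_seq) - pwm.length + 1):
            window = strand_seq[start:start + pwm.length]
            score = sum(lo[i, "ACGTN".index(b)] for i, b in enumerate(window))
            best = max(best, score)
    return best


class TestScanner:
    def test_consensus_reaches_maximum_score(self, gata_pwm):
        s_min, s_max = gata_pwm.score_range
        assert scan_best(gata_pwm, gata_pwm.consensus) == pytest.approx(s_max)

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("flat", np.full((4, 4), 0.25))
        assert scan_best(pwm, "ACGTACGTAA") == pytest.approx(0.0)

    def test_matches_brute_force_enumeration(self, toy_pwm):
        rng = np.random.default_rng(2)
        for _ in range(25):
            seq = "".join(rng.choice(list(BASES), size=10))
            assert scan_best(toy_pwm, seq) == pytest.approx(brute_force_best(toy_pwm, seq))

    def test_matches_biopython_pssm(self, toy_pwm):
        # independent scoring route through Bio.motifs (no pseudocount there,
        # so rebuild the PWM from the regularised probabilities)
        from Bio.Seq import Seq
        from Bio.motifs import Motif
        from Bio.motifs.matrix import FrequencyPositionMatrix

        reg = toy_pwm.probs + toy_pwm.pseudocount
        reg = reg / reg.sum(axis=1, keepdims=True)
        counts = {b: [reg[i, k] for i in range(toy_pwm.length)]
                  for k, b in enumerate(BASES)}
        pssm = Motif(alphabet="ACGT", counts=FrequencyPositionMatrix("ACGT", counts)) \
            .counts.normalize().log_odds()
        seq = "ACGTTACGGC"
        expected = max(float(np.nanmax(pssm.calculate(Seq(seq)))),
                       float(np.nanmax(pssm.calculate(Seq(reverse_complement(seq))))))
        assert scan_best(toy_pwm, seq) == pytest.approx(expected, abs=1e-6)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.text(alphabet=BASES, min_size=6, max_size=30))
    def test_strand_symmetry(self, seq):
        pwm = PWM("g", np.array([[0.7, 0.1, 0.1, 0.1]] * 3 + [[0.1, 0.1, 0.1, 0.7]] * 3))
        assert scan_best(pwm, seq) == pytest.approx(scan_best(pwm, reverse_complement(seq)))

    def test_n_scored_as_background(self, toy_pwm):
        assert scan_best(toy_pwm, "NNNN") == pytest.approx(0.0)

    def test_too_short_sequence_rejected(self, toy_pwm):
        with pytest.raises(ValueError, match="shorter"):
            scan_best(toy_pwm, "ACG")

    def test_jaspar_round_trip(self, tmp_path, gata_pwm):
        path = tmp_path / "m.jaspar"
        counts = (gata_pwm.probs * 100).round().astype(int)
        lines = [">MA0000.1 GATA_like"]
        for k, b in enumerate(BASES):
            lines.append(f"{b} [ " + " ".join(str(c) for c in counts[:, k]) + " ]")
        path.write_text("\n".join(lines) + "\n")
        pwms = read_jaspar(path)
        assert len(pwms) == 1
        assert pwms[0].consensus == gata_pwm.consensus


class TestAlleleDelta:
    def test_consensus_break_called_loss(self, gata_pwm):
        ref, alt, offset = gen_allelic_sequences(gata_pwm, 22, ("T", "C"), seed=0)
        assert len(ref) == 50 and len(alt) == 50
        effect = allele_delta(gata_pwm, ref, alt)
        assert effect.delta <= -0.1
        assert effect.call == "loss"

    def test_antisymmetry(self, gata_pwm):
        ref, alt, _ = gen_allelic_sequences(gata_pwm, 10, ("A", "G"), seed=3)
        fwd = allele_delta(gata_pwm, ref, alt)
        rev = allele_delta(gata_pwm, alt, ref)
        assert fwd.delta == pytest.approx(-rev.delta)

    def test_delta_bounded(self, gata_pwm):
        rng = np.random.default_rng(5)
        for seed in range(10):
            ref, alt, _ = gen_allelic_sequences(gata_pwm, 15, ("G", "T"), seed=seed)
            effect = allele_delta(gata_pwm, ref, alt)
            assert -1 <= effect.delta <= 1
            assert effect.delta == pytest.approx(effect.a_alt - effect.a_ref)

    def test_identical_sequences_rejected(self, gata_pwm):
        seq = "A" * 50
        with pytest.raises(ValueError, match="exactly 1"):
            allele_delta(gata_pwm, seq, seq)

    def test_identical_alleles_rejected_by_generator(self, gata_pwm):
        with pytest.raises(ValueError, match="differ"):
            gen_allelic_sequences(gata_pwm, 22, ("T", "T"), seed=0)

    def test_change_outside_best_windows_neutral(self, gata_pwm):
        # variant far from the only motif instance: both alleles score the
        # same best window, so delta is exactly 0
        core = gata_pwm.consensus
        ref = core + "C" * 30
        alt = core + "C" * 29 + "A"
        effect = allele_delta(gata_pwm, ref, alt)
        assert effect.delta == pytest.approx(0.0)
        assert effect.call == "neutral"


class TestEnrichment:
    def test_planted_consensus_absent_from_background_extreme_p(self, gata_pwm):
        window = "C" * 22 + gata_pwm.consensus + "C" * 22
        background = ["C" * 500]
        res = enrichment_test(gata_pwm, window, background, n_perm=99, seed=0)
        assert res.p == pytest.approx(1 / 100)

    def test_window_identical_to_background_ties_give_p_one(self, gata_pwm):
        window = "ACGT" * 12 + "AC"
        res = enrichment_test(gata_pwm, window, [window], n_perm=49, seed=0)
        assert res.p == pytest.approx(1.0)

    def test_p_never_zero_and_monotone(self, gata_pwm):
        rng = np.random.default_rng(8)
        background = ["".join(rng.choice(list(BASES), size=1000)) for _ in range(3)]
        strong = "C" * 22 + gata_pwm.consensus + "C" * 22
        weak = "".join(rng.choice(list(BASES), size=50))
        p_strong = enrichment_test(gata_pwm, strong, background, n_perm=500, seed=1).p
        p_weak = enrichment_test(gata_pwm, weak, background, n_perm=500, seed=1).p
        assert 0 < p_strong <= p_weak <= 1

    def test_deterministic_given_seed(self, gata_pwm):
        rng = np.random.default_rng(9)
        background = ["".join(rng.choice(list(BASES), size=400))]
        window = "".join(rng.choice(list(BASES), size=50))
        a = enrichment_test(gata_pwm, window, background, n_perm=200, seed=7)
        b = enrichment_test(gata_pwm, window, background, n_perm=200, seed=7)
        assert a.p == b.p and a.null_mean == b.null_mean

    def test_insufficient_background_rejected(self, gata_pwm):
        with pytest.raises(ValueError, match="background"):
            enrichment_test(gata_pwm, "A" * 50, ["ACGT"], n_perm=10, seed=0)


class TestIntegration:
    def _effect(self, tf, delta):
        from var2func.motif import AlleleEffect
        call = "loss" if delta <= -0.1 else ("gain" if delta >= 0.1 else "neutral")
        return AlleleEffect(tf, 0, 0, 0.5, 0.5 + delta, delta, call)

    def _enrich(self, tf, p):
        from var2func.motif import MotifEnrichment
        return MotifEnrichment(tf, 0, 0, 1, p, 100, 0)

    def test_three_planted_of_ten_returned_in_delta_order(self):
        effects, enrichments, chip = {}, {}, {}
        deltas = {"tf0": -0.3, "tf1": 0.2, "tf2": -0.15}
        for k in range(10):
            tf = f"tf{k}"
            effects[tf] = self._effect(tf, deltas.get(tf, 0.01))
            enrichments[tf] = self._enrich(tf, 0.01 if tf in deltas else 0.5)
            chip[tf] = tf in deltas
        out = integrate_evidence(effects, enrichments, chip)
        assert list(out["tf_name"]) == ["tf0", "tf1", "tf2"]

    def test_nonsignificant_enrichment_excluded_regardless_of_delta(self):
        effects = {"tf": self._effect("tf", -0.9)}
        enrichments = {"tf": self._enrich("tf", 0.2)}
        out = integrate_evidence(effects, enrichments, {"tf": True})
        assert len(out) == 0

    def test_tf_missing_from_one_input_excluded_with_warning(self):
        effects = {"a": self._effect("a", -0.3), "b": self._effect("b", -0.3)}
        enrichments = {"a": self._enrich("a", 0.01)}
        with pytest.warns(UserWarning, match="excluded"):
            out = integrate_evidence(effects, enrichments, {"a": True, "b": True})
        assert list(out["tf_name"]) == ["a"]
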