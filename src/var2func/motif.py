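"""Allele-specific transcription-factor motif scoring and enrichment.

A position weight matrix (PWM) is scored against a sequence as the sum of
per-position log2 odds ``log2(p_b / bg_b)`` over a window, maximised over
all windows and both strands. To compare the two alleles of a variant the
best score of each allelic sequence is normalised onto [0, 1] by the
PWM's attainable score range, ``a = (s - s_min) / (s_max - s_min)``, and
the affinity delta ``a_alt - a_ref`` is thresholded at +/-0.1 to call a
binding-site gain or loss. Motif enrichment in a window around the
variant is tested against an empirical null of random windows drawn from
background sequences.

The normalised-delta scheme is this package's own; only its sign and the
thresholded gain/loss/neutral classification are comparable to affinity
scores from other tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "AlleleEffect",
    "MotifEnrichment",
    "read_jaspar",
    "reverse_complement",
    "scan_best",
    "allele_delta",
    "enrichment_test",
    "integrate_evidence",
]

_ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Encode ACGT to 0..3; N (or any other symbol) to 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int64)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class PWM:
    """Position weight matrix with background and pseudocount.

    ``probs`` is an (L x 4) row-stochastic matrix over A,C,G,T. The
    pseudocount (default 0.01) is added to each probability column and the
    rows renormalised before taking log-odds, so no cell is -inf.
    """

    tf_name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probabilities must be an (L x 4) matrix")
        if self.probs.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def from_counts(cls, tf_name, counts, background=None, pseudocount: float = 0.01) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        kwargs = {} if background is None else {"background": np.asarray(background, float)}
        return cls(tf_name=tf_name, probs=probs, pseudocount=pseudocount, **kwargs)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L x 5) log2-odds matrix; column 4 scores N as 0 (background)."""
        reg = (self.probs + self.pseudocount)
        reg = reg / reg.sum(axis=1, keepdims=True)
        lo = np.log2(reg / self.background)
        return np.hstack([lo, np.zeros((self.length, 1))])

    @property
    def score_range(self) -> tuple:
        lo = self.log_odds[:, :4]
        return float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    def normalized_affinity(self, score: float) -> float:
        s_min, s_max = self.score_range
        return (score - s_min) / (s_max - s_min)


def read_jaspar(handle_or_path, background=None, pseudocount: float = 0.01) -> list:
    """Read JASPAR-format count matrices into PWM objects (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    def _load(handle):
        return [
            PWM.from_counts(
                m.name or m.matrix_id,
                np.array([[m.counts[b][i] for b in _ALPHABET] for i in range(m.length)]),
                background=background,
                pseudocount=pseudocount,
            )
            for m in bio_motifs.parse(handle, "jaspar")
        ]

    if hasattr(handle_or_path, "read"):
        return _load(handle_or_path)
    with open(handle_or_path) as fh:
        return _load(fh)


def _window_scores(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of every length-L window of each row of ``codes`` (2-D)."""
    length = log_odds.shape[0]
    n_win = codes.shape[1] - length + 1
    scores = np.zeros((codes.shape[0], n_win))
    for pos in range(length):
        scores += log_odds[pos, codes[:, pos:pos + n_win]]
    return scores


def _best_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Best score over all windows and both strands for each row."""
    lo = pwm.log_odds
    fwd = _window_scores(lo, codes).max(axis=1)
    # reverse complement: complement codes (A<->T, C<->G; N fixed) and reverse
    comp = np.array([3, 2, 1, 0, 4])
    rev = comp[codes][:, ::-1]
    bwd = _window_scores(lo, rev).max(axis=1)
    return np.maximum(fwd, bwd)


def scan_best(pwm: PWM, sequence: str) -> float:
    """Best log2-odds score of the motif over all windows and both strands."""
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than motif")
    return float(_best_scores(pwm, _encode(sequence)[None, :])[0])


@dataclass
class AlleleEffect:
    """Allele-specific binding-affinity change for one TF at one variant."""

    tf_name: str
    s_ref: float
    s_alt: float
    a_ref: float
    a_alt: float
    delta: float
    call: str                    # "gain", "loss", or "neutral"
    chip_supported: bool = False


def allele_delta(pwm: PWM, ref_seq: str, alt_seq: str,
                 delta_thresh: float = 0.1, chip_supported: bool = False) -> AlleleEffect:
    """Normalised binding-affinity change between two allelic sequences.

    The sequences must differ at exactly one position (the variant). Each
    allele is scored independently by its best window on either strand, so
    the optimal motif placement may differ between alleles. The delta
    ``a_alt - a_ref`` lies in [-1, 1]; calls are "loss" if
    delta <= -delta_thresh, "gain" if delta >= +delta_thresh, else
    "neutral".
    """
    if len(ref_seq) != len(alt_seq):
        raise ValueError("allelic sequences must have equal length")
    n_diff = sum(a != b for a, b in zip(ref_seq.upper(), alt_seq.upper()))
    if n_diff != 1:
        raise ValueError(f"allelic sequences must differ at exactly 1 position (got {n_diff})")
    s_ref = scan_best(pwm, ref_seq)
    s_alt = scan_best(pwm, alt_seq)
    a_ref = pwm.normalized_affinity(s_ref)
    a_alt = pwm.normalized_affinity(s_alt)
    delta = a_alt - a_ref
    if delta <= -delta_thresh:
        call = "loss"
    elif delta >= delta_thresh:
        call = "gain"
    else:
        call = "neutral"
    return AlleleEffect(tf_name=pwm.tf_name, s_ref=s_ref, s_alt=s_alt,
                        a_ref=a_ref, a_alt=a_alt, delta=delta, call=call,
                        chip_supported=chip_supported)


@dataclass
class MotifEnrichment:
    """Empirical enrichment of a motif in a window versus background."""

    tf_name: str
    observed_score: float
    null_mean: float
    null_sd: float
    p: float
    n_permutations: int
    seed: int


def enrichment_test(pwm: PWM, window_seq: str, background_seqs,
                    n_perm: int = 10_000, seed: int = 0) -> MotifEnrichment:
    """Permutation test of motif enrichment in a fixed window.

    The null distribution is the best motif score of ``n_perm`` windows of
    the same length sampled uniformly (sequence, then offset) from the
    background sequences. The empirical p-value uses the add-one rule
    ``p = (1 + #{null >= observed}) / (n_perm + 1)`` and so is never zero.
    """
    win_len = len(window_seq)
    if win_len < pwm.length:
        raise ValueError("window shorter than motif")
    bgs = [s.upper() for s in background_seqs if len(s) >= win_len]
    if not bgs:
        raise ValueError("no background sequence at least as long as the window")
    rng = np.random.default_rng(seed)
    observed = scan_best(pwm, window_seq)
    seq_idx = rng.integers(0, len(bgs), size=n_perm)
    codes = np.empty((n_perm, win_len), dtype=np.int64)
    encoded = [_encode(s) for s in bgs]
    for k in range(n_perm):
        enc = encoded[seq_idx[k]]
        off = rng.integers(0, enc.size - win_len + 1)
        codes[k] = enc[off:off + win_len]
    null = _best_scores(pwm, codes)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return MotifEnrichment(tf_name=pwm.tf_name, observed_score=observed,
                           null_mean=float(null.mean()), null_sd=float(null.std()),
                           p=float(p), n_permutations=int(n_perm), seed=int(seed))


def integrate_evidence(effects, enrichments, chip_flags,
                       p_thresh: float = 0.05, delta_thresh: float = 0.1) -> pd.DataFrame:
    """Candidate TFs passing all three evidence filters.

    A TF is retained iff its enrichment p <= ``p_thresh``, its affinity
    |delta| >= ``delta_thresh``, and its binding at the locus is supported
    by ChIP evidence. TFs missing from any input are logged and excluded.

    Parameters
    ----------
    effects : mapping tf_name -> AlleleEffect
    enrichments : mapping tf_name -> MotifEnrichment
    chip_flags : mapping tf_name -> bool

    Returns
    -------
    DataFrame of retained TFs sorted by |delta| descending.
    """
    common = set(effects) & set(enrichments) & set(chip_flags)
    for tf in set(effects) | set(enrichments) | set(chip_flags):
        if tf not in common:
            warnings.warn(f"TF {tf!r} present in only some inputs; excluded", stacklevel=2)
    rows = []
    for tf in common:
        eff = effects[tf]
        enr = enrichments[tf]
        if enr.p <= p_thresh and abs(eff.delta) >= delta_thresh and chip_flags[tf]:
            rows.append({"tf_name": tf, "delta": eff.delta, "call": eff.call,
                         "enrichment_p": enr.p, "chip_supported": True})
    frame = pd.DataFrame(rows, columns=["tf_name", "delta", "call",
                                        "enrichment_p", "chip_supported"])
    if len(frame):
        frame = frame.reindex(frame["delta"].abs().sort_values(ascending=False).index)
        frame = frame.reset_index(drop=True)
    return frame
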