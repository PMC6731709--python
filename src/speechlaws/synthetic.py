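"""Synthetic segmented-speech corpora with known ground truth.

The generator emulates the statistical structure of a large
conversational corpus of spontaneous English: lognormal phoneme
durations, a double-power-law word frequency distribution, brevity
coupling between a type's frequency and its size (characters and
phonemes), geometric breath-group sizes (the discrete analogue of the
observed exponential words-per-BG distribution, i.e. a memoryless
pause process), positive serial correlation of successive durations,
and an additive Gaussian bias on recorded BG durations that mimics
boundary-detection error (voice-onset-time effects).

Everything the generator decided is echoed back as :class:`GroundTruth`
so parameter-recovery tests are self-contained.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import ALIGNMENT_COLUMNS, SegmentedCorpus

__all__ = [
    "BrevityCoupling",
    "SyntheticSpec",
    "GroundTruth",
    "double_zipf_pmf",
    "yule_pmf",
    "sample_zipf_double",
    "assign_word_sizes",
    "generate_corpus",
]


# ---------------------------------------------------------------------------
# probability mass functions
# ---------------------------------------------------------------------------


def double_zipf_pmf(
    vocabulary_size: int, alpha1: float, alpha2: float, r_star: int
) -> np.ndarray:
    """Rank pmf with two power-law regimes, continuous at ``r_star``.

    ``p(r) \\propto r^{-alpha1}`` for ``r <= r_star`` and
    ``\\propto r_star^{alpha2-alpha1} r^{-alpha2}`` beyond, so the two
    branches agree at the breakpoint.  Normalisation is exact (direct
    summation over the finite vocabulary).
    """
    if alpha1 <= 0 or alpha2 <= 0:
        raise ValueError("power-law exponents must be > 0")
    if not 1 <= r_star < vocabulary_size:
        raise ValueError("breakpoint rank must satisfy 1 <= r* < vocabulary size")
    r = np.arange(1, vocabulary_size + 1, dtype=float)
    w = np.where(r <= r_star, r ** (-alpha1), r_star ** (alpha2 - alpha1) * r ** (-alpha2))
    return w / w.sum()


def yule_pmf(n_ranks: int, b: float, c: float) -> np.ndarray:
    """Yule rank pmf ``p(r) \\propto r^{-b} c^r`` over ranks ``1..n_ranks``."""
    if not 0 < c <= 1:
        raise ValueError("c must be in (0, 1]")
    r = np.arange(1, n_ranks + 1, dtype=float)
    w = r ** (-b) * c ** r
    return w / w.sum()


def sample_zipf_double(
    vocabulary_size: int,
    alpha1: float,
    alpha2: float,
    r_star: int,
    n_tokens: int,
    seed=None,
) -> np.ndarray:
    """I.i.d. token ranks (1-based) from the double power law."""
    pmf = double_zipf_pmf(vocabulary_size, alpha1, alpha2, r_star)
    rng = np.random.default_rng(seed)
    return rng.choice(vocabulary_size, size=n_tokens, p=pmf) + 1


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BrevityCoupling:
    """Couple a type's size to its probability through optimal coding.

    ``size_r = max(1, round(-log_D(p_r) / lambda_D + eps_r))`` where the
    integer noise ``eps`` is uniform on ``{-w, ..., w}``.  ``lambda_D = 1``
    with no noise is the optimal-code-length limit; smaller values model
    sub-optimal compression.
    """

    lambda_D: float
    alphabet_size: int
    noise_width: int = 1

    def __post_init__(self):
        if not 0 < self.lambda_D <= 1:
            raise ValueError("lambda_D must be in (0, 1]")
        if self.alphabet_size < 2:
            raise ValueError("alphabet size must be >= 2")


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults emulate the study conditions.

    Word frequencies follow the double power law with exponents
    (0.63, 1.41) and breakpoint rank 49; phoneme log-durations are
    N(-2.68, 0.59); pauses occur after each word with probability 1/6 so
    BGs average six words; recorded BG durations get a N(0.14, 0.07)
    positive bias; 3x10^5 word tokens over 40 speakers.
    """

    vocabulary_size: int = 8000
    zipf: tuple = (0.63, 1.41, 49)
    phoneme_count_dist: Sequence[float] | None = None  # pmf over n = 1.. ; or None
    phoneme_coupling: BrevityCoupling = field(
        default_factory=lambda: BrevityCoupling(0.5, 64, 1)
    )
    char_coupling: BrevityCoupling = field(
        default_factory=lambda: BrevityCoupling(0.6, 26, 1)
    )
    phoneme_duration: tuple = (-2.68, 0.59)  # (mu, sigma) in log-seconds
    type_effect_sd: float = 0.1  # per-type offset of mean log-duration
    serial_corr: float = 0.5  # AR(1) coefficient on log-durations within a BG
    pause_prob: float = 1.0 / 6.0  # => geometric BG sizes, mean 6 words
    vot_bias: tuple | None = (0.14, 0.07)  # (mu_xi, sigma_xi) seconds
    pause_duration: tuple = (-0.7, 0.6)  # lognormal (mu, sigma) of pause rows
    phoneme_inventory: int = 64
    phoneme_rank_law: tuple = (0.25, 0.96)  # Yule (b, c) for phoneme labels
    n_tokens: int = 300_000  # word tokens
    n_speakers: int = 40
    seed: int = 0

    def __post_init__(self):
        mu, sigma = self.phoneme_duration
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 < self.pause_prob < 1:
            raise ValueError("pause probability must be in (0, 1)")
        a1, a2, r_star = self.zipf
        if not (a2 > a1 > 0):
            raise ValueError("need alpha2 > alpha1 > 0")
        if not 0 <= self.serial_corr < 1:
            raise ValueError("serial correlation must be in [0, 1)")
        if self.phoneme_count_dist is not None:
            pmf = np.asarray(self.phoneme_count_dist, dtype=float)
            if pmf.ndim != 1 or np.any(pmf < 0) or not np.isclose(pmf.sum(), 1.0):
                raise ValueError("phoneme_count_dist must be a pmf over n >= 1")

    def as_dict(self) -> dict:
        d = asdict(self)
        if self.phoneme_count_dist is not None:
            d["phoneme_count_dist"] = list(map(float, self.phoneme_count_dist))
        return d


@dataclass
class GroundTruth:
    """Per-type generating quantities plus the spec echoed back."""

    types: pd.DataFrame  # label, probability, phoneme_count, char_count, mean_log_duration
    spec: SyntheticSpec

    def as_dict(self) -> dict:
        return {
            "types": self.types.to_dict(orient="list"),
            "spec": self.spec.as_dict(),
        }


# ---------------------------------------------------------------------------
# word sizes
# ---------------------------------------------------------------------------


def assign_word_sizes(
    probabilities: np.ndarray,
    pmf: Sequence[float] | None = None,
    coupling: BrevityCoupling | None = None,
    rng=None,
) -> np.ndarray:
    """Integer size (>= 1) per word type.

    Exactly one of ``pmf`` (sizes sampled i.i.d. from a fixed P(n)) or
    ``coupling`` (sizes tied to type probability through the optimal
    coding relation) must be given.
    """
    if (pmf is None) == (coupling is None):
        raise ValueError("give exactly one of pmf or coupling")
    rng = np.random.default_rng(rng)
    p = np.asarray(probabilities, dtype=float)
    if np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must be positive and sum to 1")
    if pmf is not None:
        pmf = np.asarray(pmf, dtype=float)
        return rng.choice(np.arange(1, len(pmf) + 1), size=len(p), p=pmf / pmf.sum())
    base = -np.log(p) / (coupling.lambda_D * np.log(coupling.alphabet_size))
    w = coupling.noise_width
    eps = rng.integers(-w, w + 1, size=len(p)) if w > 0 else np.zeros(len(p))
    return np.maximum(1, np.round(base + eps)).astype(int)


def _unique_labels(lengths: np.ndarray, rng) -> list[str]:
    """Random lowercase strings with the requested lengths, all distinct.

    A length class is exhausted systematically before falling back to a
    longer string, so realized lengths deviate from the requested ones
    only when the 26^l code capacity is genuinely full -- the same
    capacity constraint a real D-ary code faces.
    """
    letters = np.array(list(string.ascii_lowercase))
    seen: set[str] = set()
    used_per_len: dict[int, int] = {}
    out = []
    for l in lengths:
        l = int(l)
        cand = None
        while True:
            if used_per_len.get(l, 0) < 26**l:
                for _ in range(100):
                    cand = "".join(rng.choice(letters, size=l))
                    if cand not in seen:
                        break
                else:  # nearly full class: deterministic scan
                    import itertools

                    for tup in itertools.product(string.ascii_lowercase, repeat=l):
                        c = "".join(tup)
                        if c not in seen:
                            cand = c
                            break
                    else:
                        cand = None
                if cand is not None and cand not in seen:
                    break
            cand = None
            l += 1  # capacity full: spill into the next length
        seen.add(cand)
        used_per_len[l] = used_per_len.get(l, 0) + 1
        out.append(cand)
    return out


def _ar1_with_resets(eps: np.ndarray, rho: float, sigma: float, reset: np.ndarray) -> np.ndarray:
    """Stationary AR(1) with marginal sd ``sigma``, restarted where ``reset``."""
    if rho == 0.0:
        return sigma * eps
    s = np.empty_like(eps)
    innov = sigma * np.sqrt(1.0 - rho * rho)
    prev = 0.0
    for k in range(eps.shape[0]):  # sequential by nature; ~1e6 steps per second
        if reset[k]:
            prev = sigma * eps[k]
        else:
            prev = rho * prev + innov * eps[k]
        s[k] = prev
    return s


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def generate_corpus(spec: SyntheticSpec) -> tuple[SegmentedCorpus, GroundTruth]:
    """Sample a full three-level corpus under ``spec``.

    Layout: tokens are laid out sequentially per speaker; each word's
    duration is the sum of its phoneme durations; a pause follows each
    word with probability ``pause_prob`` (hence geometric BG sizes);
    recorded BG durations add a truncated-at-zero Gaussian bias draw.
    Deterministic under a fixed seed.
    """
    if spec.n_tokens <= 0:
        raise ValueError("n_tokens must be > 0")
    rng = np.random.default_rng(spec.seed)
    V = spec.vocabulary_size
    pmf = double_zipf_pmf(V, *spec.zipf)

    char_len = assign_word_sizes(pmf, coupling=spec.char_coupling, rng=rng)
    if spec.phoneme_count_dist is not None:
        phon_len = assign_word_sizes(pmf, pmf=spec.phoneme_count_dist, rng=rng)
    else:
        phon_len = assign_word_sizes(pmf, coupling=spec.phoneme_coupling, rng=rng)
    labels = np.array(_unique_labels(char_len, rng))
    char_len = np.array([len(lab) for lab in labels])  # realized lengths
    type_effect = rng.normal(0.0, spec.type_effect_sd, size=V)
    # phonetic transcription per type: symbols drawn from a Yule rank law
    ph_pmf = yule_pmf(spec.phoneme_inventory, *spec.phoneme_rank_law)
    ph_of_type = np.split(
        rng.choice(spec.phoneme_inventory, size=int(phon_len.sum()), p=ph_pmf),
        np.cumsum(phon_len)[:-1],
    )

    mu, sigma = spec.phoneme_duration
    types = rng.choice(V, size=spec.n_tokens, p=pmf)  # 0-based type index
    n_words = spec.n_tokens
    speaker_idx = np.minimum(
        np.arange(n_words) * spec.n_speakers // n_words, spec.n_speakers - 1
    )
    pause_after = rng.random(n_words) < spec.pause_prob
    spk_start = np.empty(n_words, dtype=bool)
    spk_start[0] = True
    spk_start[1:] = speaker_idx[1:] != speaker_idx[:-1]
    bg_start = spk_start.copy()
    bg_start[1:] |= pause_after[:-1]
    bg_id = np.cumsum(bg_start) - 1
    word_id = np.arange(n_words)

    # --- phoneme-level expansion -----------------------------------------
    nph = phon_len[types]
    word_first_ph = np.concatenate([[0], np.cumsum(nph)[:-1]])
    M = int(nph.sum())
    word_of_ph = np.repeat(word_id, nph)
    type_of_ph = types[word_of_ph]
    bg_of_ph = bg_id[word_of_ph]
    reset = np.empty(M, dtype=bool)
    reset[0] = True
    reset[1:] = bg_of_ph[1:] != bg_of_ph[:-1]
    s = _ar1_with_resets(rng.standard_normal(M), spec.serial_corr, sigma, reset)
    ph_dur = np.exp(mu + type_effect[type_of_ph] + s)
    word_dur = np.add.reduceat(ph_dur, word_first_ph)

    # --- timeline ---------------------------------------------------------
    n_pauses = int(pause_after.sum())
    pause_dur_all = np.zeros(n_words)
    pmu, psd = spec.pause_duration
    pause_dur_all[pause_after] = np.exp(rng.normal(pmu, psd, size=n_pauses))
    step = word_dur + pause_dur_all  # advance after each word
    cum = np.cumsum(step) - step
    # restart the clock at each speaker boundary
    offset = np.zeros(n_words)
    starts = np.flatnonzero(spk_start)
    offset[starts] = cum[starts]
    offset = np.maximum.accumulate(offset)
    word_onset = cum - offset
    # within-word phoneme onsets
    within = np.cumsum(ph_dur)
    base = np.repeat(np.concatenate([[0.0], within[word_first_ph[1:] - 1]]), nph)
    ph_onset = word_onset[word_of_ph] + (within - ph_dur) - base

    # --- breath groups ----------------------------------------------------
    n_bgs = int(bg_id[-1]) + 1
    bg_first_word = np.flatnonzero(bg_start)
    bg_words = np.diff(np.append(bg_first_word, n_words))
    bg_span = np.add.reduceat(word_dur, bg_first_word)
    bg_onset = word_onset[bg_first_word]
    bg_rec = bg_span.copy()
    if spec.vot_bias is not None:
        bmu, bsd = spec.vot_bias
        xi = rng.normal(bmu, bsd, size=n_bgs)
        bad = bg_span + xi <= 0
        while bad.any():  # truncate at zero: durations must stay positive
            xi[bad] = rng.normal(bmu, bsd, size=int(bad.sum()))
            bad = bg_span + xi <= 0
        bg_rec = bg_span + xi

    # --- assemble token table ---------------------------------------------
    spk_names = np.array([f"s{i:02d}" for i in range(spec.n_speakers)])
    ph_labels = np.array([f"p{i:02d}" for i in range(spec.phoneme_inventory)])
    ph_symbol = np.concatenate(ph_of_type) if M else np.array([], dtype=int)
    # per-token phoneme symbol: index within word -> symbol of its type
    pos_in_word = np.arange(M) - np.repeat(word_first_ph, nph)
    type_first = np.concatenate([[0], np.cumsum(phon_len)[:-1]])
    ph_symbol_tok = ph_symbol[type_first[type_of_ph] + pos_in_word]

    def _frame(level, spk, label, onset, dur, wid, bid):
        return pd.DataFrame(
            {
                "speaker_id": spk,
                "level": level,
                "label": label,
                "onset_s": onset,
                "duration_s": dur,
                "word_id": pd.array(wid, dtype="Int64"),
                "bg_id": pd.array(bid, dtype="Int64"),
            }
        )

    words_df = _frame(
        "word", spk_names[speaker_idx], labels[types], word_onset, word_dur,
        word_id, bg_id,
    )
    phons_df = _frame(
        "phoneme", spk_names[speaker_idx[word_of_ph]], ph_labels[ph_symbol_tok],
        ph_onset, ph_dur, word_of_ph, bg_of_ph,
    )
    pause_idx = np.flatnonzero(pause_after)
    pauses_df = _frame(
        "pause", spk_names[speaker_idx[pause_idx]],
        np.full(len(pause_idx), "SIL"),
        word_onset[pause_idx] + word_dur[pause_idx],
        pause_dur_all[pause_idx],
        [pd.NA] * len(pause_idx), [pd.NA] * len(pause_idx),
    )
    tokens = pd.concat([words_df, phons_df, pauses_df], ignore_index=True)
    prio = tokens["level"].map({"word": 0, "phoneme": 1, "pause": 2}).to_numpy()
    order = np.lexsort((prio, tokens["onset_s"].to_numpy(), tokens["speaker_id"].to_numpy()))
    tokens = tokens.iloc[order].reset_index(drop=True)

    bg_table = pd.DataFrame(
        {
            "bg_id": np.arange(n_bgs),
            "speaker_id": spk_names[speaker_idx[bg_first_word]],
            "onset_s": bg_onset,
            "duration_s": bg_rec,
            "n_words": bg_words,
        }
    )
    corpus = SegmentedCorpus(tokens, bg_table=bg_table, validate=False)

    truth_types = pd.DataFrame(
        {
            "label": labels,
            "probability": pmf,
            "phoneme_count": phon_len,
            "char_count": char_len,
            "mean_log_duration": mu + type_effect,
        }
    )
    return corpus, GroundTruth(types=truth_types, spec=spec)
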