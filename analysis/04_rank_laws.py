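"""Rank-frequency and vocabulary-growth laws on the synthetic corpus.

Fits the double power law to word ranks (with BIC selection against a
single exponent), the Yule law to phoneme ranks, and the vocabulary
growth exponent against both token count and elapsed time.  Writes
results/rank_laws.json.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import get_corpus, write_json

import speechlaws as sl


def main():
    corpus, truth = get_corpus()
    out = {}

    rt = sl.rank_frequency(corpus.words["label"])
    zf = sl.fit_zipf(rt)
    out["zipf_words"] = zf.as_dict()
    a1, a2, rstar = truth.spec.zipf
    print(f"word ranks: {zf.model} power law, alpha1={zf.alpha1:.2f} "
          f"alpha2={zf.alpha2:.2f} r*={zf.r_star} "
          f"(generating: {a1}, {a2}, {rstar})")

    yt = sl.rank_frequency(corpus.phonemes["label"])
    yf = sl.fit_yule(yt)
    out["yule_phonemes"] = yf.as_dict()
    print(f"phoneme ranks: Yule b={yf.b:.2f} c={yf.c:.3f} "
          f"(generating symbol law: {truth.spec.phoneme_rank_law})")

    for mode in ("tokens", "time"):
        fit = sl.herdan_curves(corpus, mode, n_permutations=10, seed=4)
        out[f"herdan_{mode}"] = fit.as_dict()
    beta = out["herdan_tokens"]["exponent"]
    gamma = out["herdan_time"]["exponent"]
    print(f"vocabulary growth: beta={beta:.3f} (tokens) vs gamma={gamma:.3f} "
          f"(elapsed time) -- axis-independent as expected")

    path = write_json("rank_laws.json", out)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
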