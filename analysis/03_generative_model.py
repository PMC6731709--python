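"""The sum-of-lognormals generative model and the dependence test.

Three checks: (i) Fenton-Wilkinson moments track Monte-Carlo sums of
phoneme-like lognormals; (ii) word durations rebuilt from the corpus
P(n) match the empirical word-duration distribution; (iii) successive
durations share far more information than the size-preserving shuffled
null whenever serial correlation is present.  Writes
results/generative_model.json.
"""

import sys
from pathlib import Path

import numpy as np
from scipy import stats

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import get_corpus, write_json

import speechlaws as sl
from speechlaws.lognormal import GenerativeModelSpec


def main():
    corpus, truth = get_corpus()
    mu, sigma = truth.spec.phoneme_duration
    out = {}

    mz, sz = sl.fenton_wilkinson(mu, sigma, 3)
    mc = np.random.default_rng(1).lognormal(mu, sigma, (100_000, 3)).sum(axis=1)
    ks = stats.kstest(mc, stats.lognorm(s=sz, scale=np.exp(mz)).cdf).statistic
    out["fenton_wilkinson_n3"] = {"mu_Z": mz, "sigma_Z": sz, "ks_vs_monte_carlo": ks}
    print(f"FW lognormal for a 3-phoneme sum: ({mz:.3f}, {sz:.3f}); "
          f"KS against 1e5 Monte-Carlo sums = {ks:.3f}")

    counts = corpus.phonemes.groupby("word_id").size().to_numpy()
    pmf = np.bincount(counts)[1:].astype(float)
    model = sl.sum_lognormals(GenerativeModelSpec(
        mu, sigma, pmf / pmf.sum(), corr=truth.spec.serial_corr,
        n_draws=50_000, seed=2,
    ))
    emp = corpus.words["duration_s"].to_numpy()
    ks_words = stats.ks_2samp(model, emp).statistic
    out["word_duration_model"] = {
        "ks_model_vs_empirical": ks_words,
        "model_mean": float(model.mean()),
        "empirical_mean": float(emp.mean()),
    }
    print(f"model words vs empirical words: two-sample KS = {ks_words:.3f} "
          f"(means {model.mean():.3f} vs {emp.mean():.3f} s)")

    for level in ("phoneme", "word"):
        res = sl.mi_with_null(corpus, level, n_shuffles=100, seed=3)
        out[f"mutual_information_{level}"] = res.as_dict()
        print(f"MI {level}: observed {res.observed:.3g} nats vs null "
              f"{res.null_mean:.3g} +- {res.null_sd:.3g} "
              f"(x{res.ratio:.0f} above chance)")

    path = write_json("generative_model.json", out)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
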