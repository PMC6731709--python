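"""Brevity law in three size measures, and the derived size-rank law.

Spearman tests plus the parametric exponential form f ~ exp(-lambda l)
(continuous, durations) and f ~ D^(-lambda_D l) (discrete, characters
and phonemes), then the size-rank prediction l(r) = (alpha/lambda)
log r + K with slopes fixed by the Zipf and brevity fits.  Writes
results/brevity_size_rank.json.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import get_corpus, write_json

import speechlaws as sl

F_MIN = 10  # estimation floor: keeps log-frequency sampling noise small


def main():
    corpus, truth = get_corpus()
    out = {}
    table = sl.build_type_table(corpus, "word")

    for measure, mode, D in (
        ("duration", "continuous", None),
        ("phonemes", "discrete", truth.spec.phoneme_coupling.alphabet_size),
        ("chars", "discrete", truth.spec.char_coupling.alphabet_size),
    ):
        s, p = sl.spearman_brevity(table, measure)
        fit = sl.fit_brevity(table, measure, mode=mode, alphabet_size=D,
                             f_min=F_MIN)
        out[f"word_{measure}"] = {"spearman_S": s, "spearman_p": p,
                                  **fit.as_dict()}
        lam = f"lambda_D={fit.lambda_:.2f} (D={D})" if D else \
              f"lambda={fit.lambda_:.1f} per second"
        print(f"word {measure:9s}: Spearman S={s:+.2f} (p={p:.1e}), {lam}")

    zf = sl.fit_zipf(sl.rank_frequency(corpus.words["label"]))
    rt = sl.rank_frequency(corpus.words["label"])
    sizes = (
        table.table.set_index("label")["median_duration_s"]
        .reindex(rt.table["label"]).to_numpy()
    )
    lam = out["word_duration"]["lambda"]
    sr = sl.size_rank(rt, sizes, zf.r_star, zf.alpha1, zf.alpha2, lam)
    out["size_rank_duration"] = sr.as_dict()
    print(f"size-rank law: theta1={sr.theta1:.4f}, theta2={sr.theta2:.4f}, "
          f"binned RMSE={sr.rmse_binned:.4f} s")

    path = write_json("brevity_size_rank.json", out)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
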