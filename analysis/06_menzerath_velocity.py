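"""Menzerath-Altmann fits, the mechanistic recursion, speech velocity.

Fits y(n) = a n^b exp(-cn) at both level pairs and in symbolic and
time measures on the synthetic corpus (whose generator encodes no
length-dependent compression, so these fits sit near the order-0
constant regime -- a useful negative control), then works the printed
time-units parameters through the mechanism mapping and the velocity
optimum.  Writes results/menzerath.json.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import get_corpus, write_json

import speechlaws as sl
from speechlaws.menzerath import MALFit, MALMechanism


def main():
    corpus, _ = get_corpus()
    out = {}

    for construct, constituent, measure in (
        ("bg", "word", "duration"),
        ("bg", "word", "phonemes"),
        ("bg", "word", "chars"),
        ("word", "phoneme", "duration"),
    ):
        pts = sl.mal_points(corpus, construct, constituent, measure)
        fit = sl.fit_mal(pts)
        key = f"{construct}_{constituent}_{measure}"
        out[key] = fit.as_dict()
        print(f"{key:26s}: a={fit.a:.3f} b={fit.b:+.3f} c={fit.c:+.4f} "
              f"R2(binned)={fit.r2_binned:.2f}")

    # worked example at the printed BG/word time-units parameters
    a, b, c = 0.364, -0.227, -6.7e-3
    fit = MALFit(a=a, b=b, c=c, r2_binned=0.7, r2_means=0.7,
                 n_star=None, v_max=None)
    vel = sl.speech_velocity(fit)
    kappa2 = 1 + b
    kappa1 = float(np.exp(-c))
    mech = MALMechanism(kappa1, kappa2, t1=a * kappa1, variant="exact")
    a2, b2, c2 = sl.mechanism_to_mal(mech)
    out["printed_time_units"] = {
        "a": a, "b": b, "c": c,
        "n_star_words": vel.n_star,
        "v_max_words_per_s": vel.v_max,
        "v_at_6_words": float(vel.v_at(6)),
        "kappa1": kappa1, "kappa2": kappa2,
        "mechanism_roundtrip_b": b2, "mechanism_roundtrip_c": c2,
    }
    print(f"printed fit: optimum at n*={vel.n_star:.1f} words, "
          f"v_max={vel.v_max:.2f} words/s, v(6)={vel.v_at(6):.2f} words/s")
    print(f"mechanism: kappa1={kappa1:.4f}, kappa2={kappa2:.3f} "
          f"(round-trip b={b2:+.3f}, c={c2:+.4f})")

    path = write_json("menzerath.json", out)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
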