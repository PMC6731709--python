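"""Zipf's law of abbreviation (brevity law) and its exponential form.

More frequent linguistic units tend to be shorter.  Beyond the
qualitative Spearman test, optimal-coding arguments give the law a
parametric form: if a unit with occurrence probability ``p`` were coded
optimally over a D-ary alphabet its description length would be
``-log_D p``; allowing sub-optimal compression by a factor
``lambda_D in (0, 1]`` gives ``l = -(1/lambda_D) log_D p``, i.e.
``f ~ D^{-lambda_D l}``.  With a continuous size measure (seconds)
there is no natural alphabet and the law reads ``f ~ exp(-lambda l)``.

The exponent is estimated by least squares of size on log-frequency --
the orientation of the coding derivation itself.  Sizes are the noisy
measurement here (a type's median duration fluctuates, symbol counts
are quantised), so regressing log-frequency on size would attenuate the
slope; the reverse orientation keeps the noise in the response where
ordinary least squares is unbiased.  The forward-orientation slope is
still reported as a diagnostic, together with the agreement between the
fitted line and log-binned means of the type cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import SegmentedCorpus, character_count
from .durations import bin_series

__all__ = [
    "TypeSizeTable",
    "BrevityFit",
    "build_type_table",
    "spearman_brevity",
    "fit_brevity",
    "SIZE_MEASURES",
]

SIZE_MEASURES = ("duration", "phonemes", "chars")

_MEASURE_COLUMN = {
    "duration": "median_duration_s",
    "phonemes": "median_phoneme_count",
    "chars": "char_count",
}


@dataclass
class TypeSizeTable:
    """Per-type frequency and size measures.

    One row per type with its token frequency, median duration over all
    realizations, median phoneme count (word level; realizations of the
    same word may differ in phoneme count) and orthographic character
    count.
    """

    table: pd.DataFrame
    level: str
    n_tokens: int

    def column(self, measure: str) -> np.ndarray:
        if measure not in _MEASURE_COLUMN:
            raise ValueError(f"unknown size measure {measure!r}")
        col = _MEASURE_COLUMN[measure]
        if col not in self.table.columns:
            raise ValueError(f"measure {measure!r} not available at level {self.level!r}")
        return self.table[col].to_numpy(dtype=float)

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def build_type_table(corpus: SegmentedCorpus, level: str = "word") -> TypeSizeTable:
    """Aggregate token realizations into one row per type.

    Medians are taken over all token realizations of the type (not over
    per-speaker medians).
    """
    if level == "word":
        df = corpus.words
    elif level == "phoneme":
        df = corpus.phonemes
    else:
        raise ValueError("level must be 'word' or 'phoneme'")
    if not len(df):
        raise ValueError(f"corpus has no {level} tokens")
    g = df.groupby("label", sort=False)
    out = pd.DataFrame(
        {
            "frequency": g.size(),
            "median_duration_s": g["duration_s"].median(),
        }
    )
    if level == "word":
        phon = corpus.phonemes
        if len(phon):
            counts = phon.groupby("word_id").size()
            wid_label = df.set_index("word_id")["label"]
            per_word = pd.DataFrame(
                {"label": wid_label.reindex(counts.index), "n": counts.to_numpy()}
            ).dropna()
            out["median_phoneme_count"] = per_word.groupby("label")["n"].median()
        out["char_count"] = [character_count(l) for l in out.index]
    out = out.reset_index().rename(columns={"label": "label"})
    return TypeSizeTable(table=out, level=level, n_tokens=int(len(df)))


def spearman_brevity(
    table: TypeSizeTable, measure: str = "duration", f_min: int = 1
) -> tuple[float, float]:
    """Spearman rank correlation of frequency against size.

    Negative S with a small two-sided p-value is the qualitative brevity
    law.  ``f_min`` restricts to types with at least that many tokens
    (useful at the phoneme level where rare types are noisy).
    """
    f = table.frequencies
    ell = table.column(measure)
    keep = f >= f_min
    if keep.sum() < 10:
        raise ValueError("fewer than 10 types after the frequency cut")
    if np.ptp(ell[keep]) == 0:
        raise ValueError("size column is constant; correlation undefined")
    s, p = stats.spearmanr(f[keep], ell[keep])
    return float(s), float(p)


@dataclass
class BrevityFit:
    """Parametric brevity-law fit.

    ``mode="discrete"`` reports ``lambda_D`` for alphabet size D (values
    near 1 mean near-optimal compression; > 1 is flagged, not an error);
    ``mode="continuous"`` reports ``lambda`` in 1/size-units.  The line
    is estimated on the raw type cloud, not on binned data;
    ``binned_rmse`` measures agreement with log-binned means.
    """

    mode: str
    lambda_: float
    alphabet_size: int | None
    slope: float  # d(size)/d(ln f), the fitted orientation
    intercept: float
    forward_lambda: float  # naive log-frequency-on-size estimate (diagnostic)
    n_types: int
    f_min: int
    measure: str
    brevity_violated: bool
    binned_rmse: float

    @property
    def lambda_D(self) -> float:
        if self.mode != "discrete":
            raise AttributeError("lambda_D is defined for discrete mode only")
        return self.lambda_

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["lambda"] = d.pop("lambda_")
        return d


def fit_brevity(
    table: TypeSizeTable,
    measure: str = "duration",
    mode: str = "continuous",
    alphabet_size: int | None = None,
    f_min: int = 1,
) -> BrevityFit:
    """Estimate the brevity exponent from the per-type cloud.

    Least squares of size on log-frequency: with ``s`` the slope of size
    against ``ln f`` (continuous mode) the exponent is ``lambda = -1/s``;
    in discrete mode the regressor is ``log_D f`` and
    ``lambda_D = -1/s``.  On noiseless data
    ``f = D^{-lambda_D l}`` both orientations agree to machine
    precision.  A positive frequency-size association sets
    ``brevity_violated`` instead of raising.
    """
    if mode not in ("discrete", "continuous"):
        raise ValueError("mode must be 'discrete' or 'continuous'")
    if mode == "discrete":
        if alphabet_size is None or alphabet_size < 2:
            raise ValueError("discrete mode needs an alphabet size D >= 2")
        log_base = np.log(alphabet_size)
    else:
        log_base = 1.0
    f = table.frequencies.astype(float)
    ell = table.column(measure)
    keep = (f >= f_min) & (ell > 0)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 types after the frequency cut")
    f, ell = f[keep], ell[keep]
    x = np.log(f) / log_base  # log_D f (or ln f in continuous mode)
    slope, intercept = np.polyfit(x, ell, 1)
    violated = slope >= 0
    if violated:
        warnings.warn("positive size-frequency slope: brevity law violated")
        lam = np.nan
    else:
        lam = -1.0 / slope
    fwd_slope = np.polyfit(ell, x, 1)[0]
    fwd = -fwd_slope if fwd_slope < 0 else np.nan
    binned = bin_series(f, ell, scheme="log", n_bins=20)
    pred = slope * np.log(binned.bin_centers) / log_base + intercept
    rmse = float(np.sqrt(np.mean((binned.bin_means - pred) ** 2)))
    return BrevityFit(
        mode=mode,
        lambda_=float(lam),
        alphabet_size=alphabet_size,
        slope=float(slope),
        intercept=float(intercept),
        forward_lambda=float(fwd),
        n_types=int(keep.sum()),
        f_min=int(f_min),
        measure=measure,
        brevity_violated=bool(violated),
        binned_rmse=rmse,
    )
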