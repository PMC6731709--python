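"""Rank-frequency laws: Zipf (single/double/Yule) and Herdan growth.

The Zipf fit treats the rank-frequency table as a discrete probability
over the observed ranks and maximises the multinomial likelihood; the
double (two-exponent) variant is constrained to be continuous at the
breakpoint rank, which removes one free parameter, and the breakpoint
itself is chosen by profile likelihood.  Single versus double is
decided by BIC with k = 1 versus k = 3 parameters and N = token count.

Herdan (Heaps) vocabulary growth is measured both against the number of
tokens spoken, V ~ L^beta, and against the elapsed speaking time,
V ~ T^gamma.  Because elapsed time is asymptotically proportional to L
(law of large numbers for the token durations), the two exponents must
coincide, which is what the time-axis variant tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .corpus import SegmentedCorpus
from .durations import bin_series

__all__ = [
    "RankTable",
    "ZipfFit",
    "YuleFit",
    "HerdanFit",
    "SizeRankFit",
    "rank_frequency",
    "fit_zipf",
    "fit_yule",
    "herdan_curves",
    "size_rank",
]


# ---------------------------------------------------------------------------
# rank table
# ---------------------------------------------------------------------------


@dataclass
class RankTable:
    """Types sorted by frequency; ranks are consecutive from 1.

    Ties are broken by first occurrence in the token stream (stable), so
    the table is invariant under relabelings that preserve counts.
    """

    table: pd.DataFrame  # columns: rank, label, frequency
    n_tokens: int

    @property
    def ranks(self) -> np.ndarray:
        return self.table["rank"].to_numpy()

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def rank_frequency(tokens) -> RankTable:
    """Build the rank-frequency table from a token label sequence."""
    labels = pd.Series(list(tokens))
    if labels.empty:
        raise ValueError("empty token sequence")
    codes, uniques = pd.factorize(labels)  # uniques in first-occurrence order
    counts = np.bincount(codes)
    order = np.argsort(-counts, kind="stable")  # stable: ties by first occurrence
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(uniques) + 1),
            "label": np.asarray(uniques)[order],
            "frequency": counts[order],
        }
    )
    return RankTable(table=df, n_tokens=int(counts.sum()))


def rank_table_from_counts(frequencies, labels=None) -> RankTable:
    """Rank table straight from per-type counts (zero counts dropped)."""
    f = np.asarray(frequencies)
    if labels is None:
        labels = np.array([f"t{i}" for i in range(len(f))])
    keep = f > 0
    f, labels = f[keep], np.asarray(labels)[keep]
    order = np.argsort(-f, kind="stable")
    df = pd.DataFrame(
        {
            "rank": np.arange(1, keep.sum() + 1),
            "label": labels[order],
            "frequency": f[order],
        }
    )
    return RankTable(table=df, n_tokens=int(f.sum()))


# ---------------------------------------------------------------------------
# Zipf fits
# ---------------------------------------------------------------------------


@dataclass
class ZipfFit:
    model: str  # "single" or "double", chosen by BIC
    alpha: float  # single-model exponent
    alpha1: float
    alpha2: float
    r_star: int
    loglik_single: float
    loglik_double: float
    bic_single: float
    bic_double: float

    def as_dict(self) -> dict:
        return {k: (float(v) if not isinstance(v, str) else v)
                for k, v in self.__dict__.items()}


def _zipf_suffstats(rank_table: RankTable):
    f = rank_table.frequencies.astype(float)
    r = rank_table.ranks.astype(float)
    lnr = np.log(r)
    return f, lnr, float(f.sum())


def _negll_single(alpha, f, lnr, n):
    if alpha < 0:
        return np.inf
    logw = -alpha * lnr
    z = np.exp(logw).sum()
    return -(np.dot(f, logw) - n * np.log(z))


def _negll_double(params, k, f, lnr, n, c_flnr, c_f):
    a1, a2 = params
    if a1 <= 0 or a2 <= 0:
        return np.inf
    lnk = lnr[k - 1]
    logw_head = -a1 * lnr[:k]
    logw_tail = (a2 - a1) * lnk - a2 * lnr[k:]
    z = np.exp(logw_head).sum() + np.exp(logw_tail).sum()
    s = (
        -a1 * c_flnr[k]
        + (c_f[-1] - c_f[k]) * (a2 - a1) * lnk
        - a2 * (c_flnr[-1] - c_flnr[k])
    )
    return -(s - n * np.log(z))


def fit_zipf(rank_table: RankTable, candidate_step: int | None = None) -> ZipfFit:
    """MLE power-law fits with a BIC choice between one and two regimes.

    The breakpoint search is coarse-to-fine: candidate ranks on a log
    grid first, then every rank around the best candidate.  BIC is
    ``k ln N - 2 lnL`` with N the token count.
    """
    if len(rank_table) < 20:
        raise ValueError("need at least 20 types to fit a Zipf law")
    f, lnr, n = _zipf_suffstats(rank_table)
    R = len(f)
    c_flnr = np.concatenate([[0.0], np.cumsum(f * lnr)])
    c_f = np.concatenate([[0.0], np.cumsum(f)])

    res1 = minimize_scalar(
        _negll_single, bounds=(1e-9, 10.0), args=(f, lnr, n), method="bounded"
    )
    alpha_single = float(res1.x)

    def fit_at(k, x0):
        r = minimize(
            _negll_double,
            x0,
            args=(k, f, lnr, n, c_flnr, c_f),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        return r

    if R <= 60:
        cands = np.arange(2, R)
    else:
        cands = np.unique(
            np.round(np.logspace(np.log10(2), np.log10(R - 1), 50)).astype(int)
        )
    x0 = (max(alpha_single, 0.1), max(alpha_single, 0.1))
    best = None
    for k in cands:
        res = fit_at(int(k), x0)
        if best is None or res.fun < best[1]:
            best = (int(k), res.fun, res.x)
    k0 = best[0]
    for k in range(max(2, k0 - 10), min(R - 1, k0 + 10) + 1):
        res = fit_at(k, best[2])
        if res.fun < best[1]:
            best = (k, res.fun, res.x)

    ll_single = -float(res1.fun)
    ll_double = -float(best[1])
    bic_single = 1 * np.log(n) - 2 * ll_single
    bic_double = 3 * np.log(n) - 2 * ll_double
    return ZipfFit(
        model="double" if bic_double < bic_single else "single",
        alpha=alpha_single,
        alpha1=float(best[2][0]),
        alpha2=float(best[2][1]),
        r_star=int(best[0]),
        loglik_single=ll_single,
        loglik_double=ll_double,
        bic_single=float(bic_single),
        bic_double=float(bic_double),
    )


@dataclass
class YuleFit:
    b: float
    c: float
    loglik: float

    def as_dict(self) -> dict:
        return {"b": self.b, "c": self.c, "loglik": self.loglik}


def fit_yule(rank_table: RankTable) -> YuleFit:
    """MLE of the Yule rank law ``p(r) \\propto r^{-b} c^r``.

    Normalised by direct summation over the observed ranks; a pure power
    law is the ``c = 1`` boundary case, a pure geometric is ``b = 0``.
    """
    if len(rank_table) < 10:
        raise ValueError("need at least 10 types to fit a Yule law")
    f, lnr, n = _zipf_suffstats(rank_table)
    r = rank_table.ranks.astype(float)

    def negll(theta):
        b, c = theta
        if not (0 < c <= 1) or abs(b) > 10:
            return np.inf
        logw = -b * lnr + r * np.log(c)
        z = np.exp(logw).sum()
        return -(np.dot(f, logw) - n * np.log(z))

    best = None
    for x0 in ((0.5, 0.9), (0.1, 0.99), (1.0, 0.999999)):
        res = minimize(
            negll, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("Yule fit did not converge")
    return YuleFit(b=float(best.x[0]), c=float(best.x[1]), loglik=-float(best.fun))


# ---------------------------------------------------------------------------
# Herdan / Heaps growth
# ---------------------------------------------------------------------------


@dataclass
class HerdanFit:
    mode: str  # "tokens" or "time"
    exponent: float  # mean over permutations
    exponents: list = field(default_factory=list)
    window: tuple = (100, None)
    curve_x: np.ndarray | None = None  # first permutation, for plotting
    curve_v: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "exponent": self.exponent,
            "exponents": [float(e) for e in self.exponents],
            "window": list(self.window),
        }


def herdan_curves(
    corpus: SegmentedCorpus,
    mode: str = "tokens",
    n_permutations: int = 10,
    seed: int | None = None,
    min_tokens: int = 100,
    include_pauses: bool = False,
    keep_curve: bool = True,
) -> HerdanFit:
    """Vocabulary growth exponent over speaker-order permutations.

    For each permutation of the speaker concatenation order, V is the
    number of distinct word types seen after each token; the x-axis is
    either the token count L or the elapsed time T (cumulative word
    durations; pauses excluded by default, since the time-axis
    derivation assumes no silences between words).  The exponent is the
    least-squares slope of log V against log x over tokens ``>=
    min_tokens``, past the initial every-word-is-new transient.
    """
    if mode not in ("tokens", "time"):
        raise ValueError("mode must be 'tokens' or 'time'")
    words = corpus.words
    if not len(words):
        raise ValueError("corpus has no word tokens")
    rng = np.random.default_rng(seed)
    speakers = corpus.speakers
    by_speaker = {
        spk: grp.sort_values("onset_s", kind="stable")
        for spk, grp in words.groupby("speaker_id", sort=False)
    }
    pause_by_speaker = None
    if include_pauses and mode == "time":
        pause_by_speaker = {
            spk: grp["duration_s"].sum()
            for spk, grp in corpus.pauses.groupby("speaker_id", sort=False)
        }
    exponents = []
    curve = None
    for p in range(max(1, n_permutations)):
        order = rng.permutation(speakers)
        lab = pd.concat([by_speaker[s]["label"] for s in order], ignore_index=True)
        new = ~lab.duplicated().to_numpy()
        v = np.cumsum(new)
        L = np.arange(1, len(v) + 1)
        if mode == "tokens":
            x = L.astype(float)
        else:
            dur = np.concatenate(
                [by_speaker[s]["duration_s"].to_numpy() for s in order]
            )
            x = np.cumsum(dur)
            if include_pauses:
                # fold each speaker's total pause time in at the hand-over
                off = 0.0
                pos = 0
                xs = x.copy()
                for s in order:
                    n_s = len(by_speaker[s])
                    xs[pos: pos + n_s] += off
                    off += pause_by_speaker.get(s, 0.0)
                    pos += n_s
                x = xs
        sel = L >= min_tokens
        if sel.sum() < 10:
            raise ValueError("fit window is empty; lower min_tokens")
        slope = np.polyfit(np.log(x[sel]), np.log(v[sel]), 1)[0]
        exponents.append(float(slope))
        if keep_curve and curve is None:
            step = max(1, len(v) // 2000)
            curve = (x[::step], v[::step])
    return HerdanFit(
        mode=mode,
        exponent=float(np.mean(exponents)),
        exponents=exponents,
        window=(min_tokens, None),
        curve_x=None if curve is None else curve[0],
        curve_v=None if curve is None else curve[1],
    )


# ---------------------------------------------------------------------------
# size-rank law
# ---------------------------------------------------------------------------


@dataclass
class SizeRankFit:
    """Piecewise-log prediction of type size from rank.

    Combining the (double) Zipf law with the exponential brevity law
    gives ``l(r) = (alpha/lambda) log r + K`` on each side of the Zipf
    breakpoint; the slopes theta are fixed by the two upstream fits and
    only the intercepts are estimated (least squares per segment).
    """

    theta1: float
    theta2: float
    K1: float
    K2: float
    r_star: int
    rmse_binned: float

    def predict(self, ranks) -> np.ndarray:
        r = np.asarray(ranks, dtype=float)
        return np.where(
            r <= self.r_star,
            self.theta1 * np.log(r) + self.K1,
            self.theta2 * np.log(r) + self.K2,
        )

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def size_rank(
    rank_table: RankTable,
    sizes,
    r_star: int,
    alpha1: float,
    alpha2: float,
    lam: float,
) -> SizeRankFit:
    """Fit the size-rank law with slopes tied to the Zipf/brevity fits.

    ``sizes`` is the per-type size (e.g. median duration in seconds)
    aligned with the rank table.  Residual agreement is reported against
    log-binned means of the raw cloud.
    """
    ell = np.asarray(sizes, dtype=float)
    r = rank_table.ranks.astype(float)
    if ell.shape != r.shape:
        raise ValueError("sizes must align with the rank table")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    theta1, theta2 = alpha1 / lam, alpha2 / lam
    head = r <= r_star
    K1 = float(np.mean(ell[head] - theta1 * np.log(r[head]))) if head.any() else np.nan
    tail = ~head
    K2 = float(np.mean(ell[tail] - theta2 * np.log(r[tail]))) if tail.any() else np.nan
    fit = SizeRankFit(
        theta1=float(theta1), theta2=float(theta2), K1=K1, K2=K2,
        r_star=int(r_star), rmse_binned=np.nan,
    )
    binned = bin_series(r, ell, scheme="log", n_bins=20)
    pred = fit.predict(binned.bin_centers)
    fit.rmse_binned = float(np.sqrt(np.mean((binned.bin_means - pred) ** 2)))
    return fit
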