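"""Menzerath-Altmann law (MAL), its mechanistic recursion, and speech velocity.

MAL relates the size ``n`` of a construct (e.g. a breath group in
words) to the mean size ``y`` of its constituents:

    y(n) = a * n^b * exp(-c n)

With both ``b, c < 0`` the curve has a finite minimum at ``n* = b/c``:
below it the classic "the bigger the whole, the smaller the parts"
reading holds, above it the tendency inverts.

The mechanistic model builds a construct of ``n`` constituents by
appending one constituent at a time.  Writing ``t(n)`` for the mean
construct duration, the appended constituent contributes a fraction
``kappa_2`` of the running average, with an overall growth prefactor
``kappa_1 >= 1``:

    t(n) = kappa_1 * (1 + kappa_2 / (n - 1)) * t(n - 1)

Telescoping the product with gamma functions (and their large-n
asymptotics for the order-2 variant) recovers exactly the MAL form with
``b = kappa_2 - 1`` and ``c = -ln kappa_1``, so two parameters suffice
and both exponents are negative -- the two regimes are generic.

When constituent size is measured in seconds, ``v(n) = 1/y(n)`` is the
average speech velocity of an n-word breath group; under MAL it is
maximal at ``n*``, an optimal-efficiency limit in words per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import gammaln

from .corpus import SegmentedCorpus, character_count
from .durations import bin_series

__all__ = [
    "MALPoints",
    "MALFit",
    "MALMechanism",
    "mal_points",
    "fit_mal",
    "mal_curve",
    "mechanism_simulate",
    "closed_form",
    "mechanism_to_mal",
    "speech_velocity",
    "VelocityResult",
]


def mal_curve(n, a, b, c):
    """The MAL form ``y(n) = a n^b exp(-c n)``."""
    n = np.asarray(n, dtype=float)
    return a * n**b * np.exp(-c * n)


# ---------------------------------------------------------------------------
# construct/constituent point clouds
# ---------------------------------------------------------------------------


@dataclass
class MALPoints:
    """One point per construct instance: (n, mean constituent size)."""

    points: pd.DataFrame  # columns: n, y
    construct: str
    constituent: str
    measure: str
    n_skipped: int = 0

    @property
    def n(self) -> np.ndarray:
        return self.points["n"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.points["y"].to_numpy()

    def __len__(self) -> int:
        return len(self.points)


def mal_points(
    corpus: SegmentedCorpus,
    construct: str = "bg",
    constituent: str = "word",
    measure: str = "duration",
) -> MALPoints:
    """Build the grey-dot cloud of construct size vs mean constituent size.

    ``bg``/``word``: one point per breath group, n = words in the BG and
    y = mean word size (duration in seconds, phoneme count or character
    count).  ``word``/``phoneme``: one point per word, n = phonemes in
    the word and y = mean phoneme duration.
    """
    if (construct, constituent) == ("bg", "word"):
        words = corpus.words
        if not len(words) or words["bg_id"].isna().all():
            raise ValueError("corpus has no breath-group structure")
        w = words.dropna(subset=["bg_id"])
        if measure == "duration":
            size = w["duration_s"].to_numpy(dtype=float)
        elif measure == "phonemes":
            counts = corpus.phonemes.groupby("word_id").size()
            size = counts.reindex(w["word_id"]).to_numpy(dtype=float)
        elif measure == "chars":
            size = w["label"].map(character_count).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown measure {measure!r}")
        df = pd.DataFrame({"bg": w["bg_id"].to_numpy(), "size": size}).dropna()
        g = df.groupby("bg")["size"]
        pts = pd.DataFrame({"n": g.size().to_numpy(), "y": g.mean().to_numpy()})
    elif (construct, constituent) == ("word", "phoneme"):
        if measure != "duration":
            raise ValueError("word/phoneme mode is defined for duration")
        phon = corpus.phonemes
        if not len(phon):
            raise ValueError("corpus has no phoneme tokens")
        g = phon.groupby("word_id")["duration_s"]
        pts = pd.DataFrame({"n": g.size().to_numpy(), "y": g.mean().to_numpy()})
    else:
        raise ValueError("supported level pairs: (bg, word) and (word, phoneme)")
    n_skipped = int((pts["n"] == 0).sum())
    pts = pts[pts["n"] >= 1].reset_index(drop=True)
    return MALPoints(
        points=pts, construct=construct, constituent=constituent,
        measure=measure, n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class MALFit:
    a: float
    b: float
    c: float
    r2_binned: float  # on 10-bin linear binned means (the displayed circles)
    r2_means: float  # on the unbinned per-n means
    n_star: float | None  # b/c when both negative, else None
    v_max: float | None  # 1/y(n*), meaningful for time measures
    measure: str = "duration"

    def curve(self, n):
        return mal_curve(n, self.a, self.b, self.c)

    def as_dict(self) -> dict:
        return {
            k: (None if v is None else (v if isinstance(v, str) else float(v)))
            for k, v in self.__dict__.items()
        }


def _r2(y_obs, y_fit) -> float:
    ss_res = np.sum((y_obs - y_fit) ** 2)
    ss_tot = np.sum((y_obs - np.mean(y_obs)) ** 2)
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0


def fit_mal(points: MALPoints, n_bins: int = 10, seed: int = 0) -> MALFit:
    """Levenberg-Marquardt fit of MAL to the per-n mean values.

    The fit runs on the mean constituent size per construct size n (the
    cloud enters through those means); R^2 is reported both on the per-n
    means and on 10-bin linearly binned means of the cloud, the latter
    matching how the relation is usually displayed.  Five jittered
    restarts guard against bad local minima; the initial guess uses the
    small-n log-log slope for b and c = 0.
    """
    nvals, yvals = points.n.astype(float), points.y.astype(float)
    uniq = np.unique(nvals)
    if len(uniq) < 5:
        raise ValueError("need at least 5 distinct construct sizes")
    means = pd.DataFrame({"n": nvals, "y": yvals}).groupby("n")["y"].mean()
    xm, ym = means.index.to_numpy(), means.to_numpy()

    small = xm <= max(10, xm.min() + 4)
    b0 = np.polyfit(np.log(xm[small]), np.log(ym[small]), 1)[0] if small.sum() > 2 else -0.2
    a0 = ym[xm.argmin()] if 1 not in xm else float(means.get(1.0, ym[0]))
    p0 = np.array([max(a0, 1e-6), b0, 0.0])

    rng = np.random.default_rng(seed)
    best = None
    for k in range(5):
        start = p0 if k == 0 else p0 * (1 + 0.3 * rng.standard_normal(3)) + [0, 0.05, 0.01] * rng.standard_normal(3)
        try:
            popt, _ = curve_fit(mal_curve, xm, ym, p0=start, method="lm", maxfev=20000)
        except RuntimeError:
            continue
        sse = np.sum((mal_curve(xm, *popt) - ym) ** 2)
        if np.isfinite(sse) and (best is None or sse < best[0]):
            best = (sse, popt)
    if best is None:
        raise RuntimeError("MAL fit did not converge from any start")
    a, b, c = (float(v) for v in best[1])
    if a < 0:  # sign-degenerate optimum; reflect
        a = abs(a)

    if len(nvals) > len(xm):
        binned = bin_series(nvals, yvals, scheme="linear", n_bins=n_bins)
        r2b = _r2(binned.bin_means, mal_curve(binned.bin_centers, a, b, c))
    else:
        r2b = _r2(ym, mal_curve(xm, a, b, c))
    r2m = _r2(ym, mal_curve(xm, a, b, c))
    n_star = b / c if (b < 0 and c < 0) else None
    v_max = None
    if n_star is not None:
        v_max = float(1.0 / mal_curve(n_star, a, b, c))
    return MALFit(
        a=a, b=b, c=c, r2_binned=r2b, r2_means=r2m,
        n_star=None if n_star is None else float(n_star),
        v_max=v_max, measure=points.measure,
    )


# ---------------------------------------------------------------------------
# mechanistic recursion
# ---------------------------------------------------------------------------

VARIANTS = ("order0", "order1", "order2", "exact")


@dataclass(frozen=True)
class MALMechanism:
    """Parameters of the generative recursion.

    ``kappa2 in (0, 1)`` is the correlation fraction the appended
    constituent inherits from the running average; ``kappa1 >= 1`` an
    overall growth prefactor (values below 1 would eventually shrink
    t(n), which is unphysical); ``t1`` the mean single-constituent
    duration in seconds.  ``order1`` forces ``kappa1 = 1``.
    """

    kappa1: float
    kappa2: float
    t1: float
    variant: str = "order2"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.variant != "order0" and not 0 < self.kappa2 <= 1:
            raise ValueError("kappa2 must be in (0, 1]")
        if self.kappa1 < 1 and self.variant in ("order2", "exact"):
            raise ValueError("kappa1 must be >= 1")
        if self.variant == "order1" and self.kappa1 != 1:
            raise ValueError("order1 requires kappa1 = 1")
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")


def mechanism_simulate(mech: MALMechanism, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the recursion exactly for n = 1..n_max; returns (t, y).

    order0: t(n) = (1 + 1/(n-1)) t(n-1)  -> y constant.
    order1: t(n) = (1 + kappa2/(n-1)) t(n-1).
    order2: t(n) = kappa1 (1 + kappa2/(n-1)) t(n-1).
    exact:  t(n) = kappa1 (1 + 1/(n-1))^kappa2 t(n-1)  (telescopes in
            closed form, no approximation).
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    n = np.arange(1, n_max + 1, dtype=float)
    t = np.empty(n_max)
    t[0] = mech.t1
    for i in range(1, n_max):
        j = n[i - 1]  # = n - 1
        if mech.variant == "order0":
            factor = 1.0 + 1.0 / j
        elif mech.variant == "order1":
            factor = 1.0 + mech.kappa2 / j
        elif mech.variant == "order2":
            factor = mech.kappa1 * (1.0 + mech.kappa2 / j)
        else:
            factor = mech.kappa1 * (1.0 + 1.0 / j) ** mech.kappa2
        t[i] = factor * t[i - 1]
    return t, t / n


def closed_form(mech: MALMechanism, n) -> np.ndarray:
    """Closed-form / asymptotic y(n) for each variant.

    order0: t1.  order1: exact gamma-ratio form
    ``t1 * Gamma(n + k2) / (Gamma(1 + k2) Gamma(n)) / n``.
    order2: large-n asymptotic ``t1 / (k1 Gamma(1 + k2)) * n^{k2-1} k1^n``
    (since ``Gamma(n + k2)/Gamma(n) -> n^{k2}``); expanding
    ``Gamma(1 + k2)`` to first order in ``k2`` gives the equivalent
    small-``k2`` prefactor ``e^{k2 gamma_E}`` with Euler-Mascheroni
    ``gamma_E``.  exact: ``t1/k1 * n^{k2 - 1} k1^n`` with no
    approximation.
    """
    n = np.asarray(n, dtype=float)
    k1, k2, t1 = mech.kappa1, mech.kappa2, mech.t1
    if mech.variant == "order0":
        return np.full_like(n, t1)
    if mech.variant == "order1":
        logt = np.log(t1) + gammaln(n + k2) - gammaln(1 + k2) - gammaln(n)
        return np.exp(logt) / n
    if mech.variant == "order2":
        const = np.exp(-gammaln(1.0 + k2))
        return t1 * const / k1 * n ** (k2 - 1.0) * k1**n
    return t1 / k1 * n ** (k2 - 1.0) * k1**n


def mechanism_to_mal(mech: MALMechanism) -> tuple[float, float, float]:
    """Map (kappa1, kappa2, t1) to the MAL parameters (a, b, c).

    ``b = kappa2 - 1 < 0`` and ``c = -ln kappa1 <= 0`` always, so the
    mechanism generically produces both MAL regimes.  The prefactor is
    ``a = t1 / (kappa1 Gamma(1 + kappa2))`` (order2 asymptotic; to first
    order in kappa2 equivalently ``t1 e^{kappa2 gamma_E} / kappa1``) or
    ``a = t1 / kappa1`` (exact variant).
    """
    k1, k2, t1 = mech.kappa1, mech.kappa2, mech.t1
    b = k2 - 1.0
    c = -np.log(k1)
    if mech.variant == "exact":
        a = t1 / k1
    elif mech.variant == "order2":
        a = t1 / (k1 * np.exp(gammaln(1.0 + k2)))
    elif mech.variant == "order1":
        a = t1 / np.exp(gammaln(1.0 + k2))
        c = 0.0
    else:
        a, b, c = t1, 0.0, 0.0
    assert b <= 0 and c <= 0
    return float(a), float(b), float(c)


# ---------------------------------------------------------------------------
# speech velocity
# ---------------------------------------------------------------------------


@dataclass
class VelocityResult:
    n: np.ndarray
    v: np.ndarray  # constituents per second
    n_star: float | None
    v_max: float | None
    has_optimum: bool

    def v_at(self, n) -> np.ndarray:
        return np.interp(np.asarray(n, dtype=float), self.n, self.v)

    def as_dict(self) -> dict:
        return {
            "n_star": self.n_star,
            "v_max": self.v_max,
            "has_optimum": self.has_optimum,
        }


def speech_velocity(fit: MALFit, n_max: int | None = None, n_points: int = 400) -> VelocityResult:
    """Average speech velocity ``v(n) = 1/y(n)`` under a time-units fit.

    With ``b, c < 0`` the velocity peaks at ``n* = b/c``; ``v_max`` is
    the optimal-efficiency limit in constituents (words) per second.
    Non-negative ``b`` or ``c`` gives a monotone velocity with no
    optimum (reported, not an error).
    """
    has_opt = fit.b < 0 and fit.c < 0
    n_star = fit.b / fit.c if has_opt else None
    if n_max is None:
        n_max = int(np.ceil(2 * n_star)) if has_opt else 100
    n = np.linspace(1.0, float(n_max), n_points)
    v = 1.0 / fit.curve(n)
    v_max = float(1.0 / fit.curve(n_star)) if has_opt else None
    return VelocityResult(
        n=n, v=v,
        n_star=None if n_star is None else float(n_star),
        v_max=v_max, has_optimum=bool(has_opt),
    )
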