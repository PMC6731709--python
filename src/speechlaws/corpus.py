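"""Data model for time-aligned segmented speech.

A corpus is a flat table of tokens at three nested linguistic levels --
phonemes inside words inside breath groups (BGs, maximal stretches of
speech between pauses for breathing or longer).  Every token carries an
onset and a duration in seconds; intervals are half-open
``[onset, onset + duration)``.  Words and phonemes are explicit rows;
BGs are derived from the pause rows and kept in a per-BG table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ALIGNMENT_COLUMNS",
    "PAUSE_LABELS",
    "AlignmentFormatError",
    "ValidationError",
    "SegmentedCorpus",
    "CorpusSummary",
    "LevelStats",
    "read_alignment",
    "write_alignment",
    "segment_breath_groups",
    "summarize",
    "character_count",
]

#: Column order of the long-format alignment TSV dialect.
ALIGNMENT_COLUMNS = [
    "speaker_id",
    "level",
    "label",
    "onset_s",
    "duration_s",
    "word_id",
    "bg_id",
]

#: Reserved labels commonly used for pause rows.  Any row with
#: ``level == "pause"`` delimits BGs regardless of its label text.
PAUSE_LABELS = frozenset({"SIL", "NOISE", "IVER", "VOCNOISE"})

LEVELS = ("phoneme", "word", "pause")


class AlignmentFormatError(ValueError):
    """The alignment table is structurally malformed (e.g. missing column)."""


class ValidationError(ValueError):
    """A row violates a corpus invariant (non-positive duration, orphan
    phoneme, hierarchy overflow beyond tolerance, ...)."""


def character_count(label: str) -> int:
    """Number of orthographic characters of a word label.

    Letters only, case-insensitive; apostrophes, hyphens and any other
    punctuation are stripped.
    """
    return sum(1 for ch in str(label) if ch.isalpha())


# ---------------------------------------------------------------------------
# corpus container
# ---------------------------------------------------------------------------


class SegmentedCorpus:
    """Three-level hierarchy of tokens with onsets/durations in seconds.

    Parameters
    ----------
    tokens
        Long-format table with columns :data:`ALIGNMENT_COLUMNS`.  One row
        per token; ``word_id`` links phonemes to their word, ``bg_id``
        links words to their breath group.
    bg_table
        Optional per-BG table (``bg_id, speaker_id, onset_s, duration_s,
        n_words``).  When absent it is derived from the token rows (BG
        duration = last word end - first word onset).  A generator may
        supply recorded BG durations that exceed the word-duration sum:
        manual boundary detection adds a small positive bias.
    tolerance
        Allowed fractional excess of the summed constituent durations over
        the container duration (manual segmentation gaps exist).
    bg_abs_tolerance
        Additional absolute slack (seconds) for the BG-level check only:
        recorded BG durations carry an additive boundary-detection bias
        of either sign, so a purely fractional tolerance is too strict
        for short BGs.
    """

    def __init__(
        self,
        tokens: pd.DataFrame,
        bg_table: pd.DataFrame | None = None,
        tolerance: float = 0.05,
        bg_abs_tolerance: float = 0.3,
        validate: bool = True,
    ):
        tokens = tokens.reset_index(drop=True)
        self.tokens = tokens
        self.tolerance = float(tolerance)
        self.bg_abs_tolerance = float(bg_abs_tolerance)
        if bg_table is None:
            bg_table = _build_bg_table(tokens)
        self.bg_table = bg_table.reset_index(drop=True)
        if validate:
            self.validate()

    # -- views ------------------------------------------------------------

    @property
    def words(self) -> pd.DataFrame:
        return self.tokens[self.tokens["level"] == "word"]

    @property
    def phonemes(self) -> pd.DataFrame:
        return self.tokens[self.tokens["level"] == "phoneme"]

    @property
    def pauses(self) -> pd.DataFrame:
        return self.tokens[self.tokens["level"] == "pause"]

    @property
    def speakers(self) -> list[str]:
        return sorted(self.tokens["speaker_id"].unique())

    def levels(self) -> set[str]:
        return set(self.tokens["level"].unique())

    def __len__(self) -> int:
        return len(self.tokens)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SegmentedCorpus):
            return NotImplemented
        return self.tokens.equals(other.tokens)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        t = self.tokens
        missing = [c for c in ALIGNMENT_COLUMNS if c not in t.columns]
        if missing:
            raise AlignmentFormatError(f"missing columns: {missing}")
        bad_level = ~t["level"].isin(LEVELS)
        if bad_level.any():
            row = int(np.flatnonzero(bad_level)[0])
            raise ValidationError(f"row {row}: unknown level {t['level'].iloc[row]!r}")
        nonpos = t["duration_s"].to_numpy() <= 0
        if nonpos.any():
            row = int(np.flatnonzero(nonpos)[0])
            raise ValidationError(
                f"row {row}: duration must be > 0, got {t['duration_s'].iloc[row]}"
            )
        phon = t["level"] == "phoneme"
        orphan = phon & t["word_id"].isna()
        if orphan.any():
            row = int(np.flatnonzero(orphan)[0])
            raise ValidationError(f"row {row}: phoneme without word_id")
        word = t["level"] == "word"
        no_bg = word & t["bg_id"].isna()
        if no_bg.any():
            row = int(np.flatnonzero(no_bg)[0])
            raise ValidationError(f"row {row}: word without bg_id")
        # same-level onsets non-decreasing within a speaker
        for (spk, lvl), grp in t.groupby(["speaker_id", "level"], sort=False):
            on = grp["onset_s"].to_numpy()
            if np.any(np.diff(on) < -1e-9):
                raise ValidationError(
                    f"speaker {spk!r}: {lvl} onsets are not non-decreasing"
                )
        self._check_hierarchy()

    def _check_hierarchy(self) -> None:
        tol = 1.0 + self.tolerance
        ph = self.phonemes
        words = self.words
        if len(ph) and len(words):
            psum = ph.groupby("word_id")["duration_s"].sum()
            wdur = words.set_index("word_id")["duration_s"]
            joined = psum.reindex(wdur.index).dropna()
            over = joined > wdur.loc[joined.index] * tol
            if over.any():
                wid = over.idxmax()
                raise ValidationError(
                    f"word {wid}: phoneme durations sum to {joined.loc[wid]:.6f}"
                    f" > word duration {wdur.loc[wid]:.6f} * (1 + tol)"
                )
        if len(words) and len(self.bg_table):
            wsum = words.groupby("bg_id")["duration_s"].sum()
            bdur = self.bg_table.set_index("bg_id")["duration_s"]
            joined = wsum.reindex(bdur.index).dropna()
            over = joined > bdur.loc[joined.index] * tol + self.bg_abs_tolerance
            if over.any():
                bid = over.idxmax()
                raise ValidationError(
                    f"bg {bid}: word durations sum to {joined.loc[bid]:.6f}"
                    f" > bg duration {bdur.loc[bid]:.6f} * (1 + tol)"
                )


def _build_bg_table(tokens: pd.DataFrame) -> pd.DataFrame:
    words = tokens[tokens["level"] == "word"]
    if not len(words) or words["bg_id"].isna().all():
        return pd.DataFrame(
            columns=["bg_id", "speaker_id", "onset_s", "duration_s", "n_words"]
        )
    g = words.groupby("bg_id", sort=True)
    onset = g["onset_s"].min()
    end = (words["onset_s"] + words["duration_s"]).groupby(words["bg_id"]).max()
    out = pd.DataFrame(
        {
            "bg_id": onset.index.to_numpy(),
            "speaker_id": g["speaker_id"].first().to_numpy(),
            "onset_s": onset.to_numpy(),
            "duration_s": (end - onset).to_numpy(),
            "n_words": g.size().to_numpy(),
        }
    )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_alignment(source, tolerance: float = 0.05) -> SegmentedCorpus:
    """Read the long-format alignment TSV into a :class:`SegmentedCorpus`.

    ``source`` is a path or text stream.  The header must contain all of
    :data:`ALIGNMENT_COLUMNS`; empty strings are null ids.  BG assignment
    is taken from the ``bg_id`` column when present, otherwise re-derived
    from pause rows via :func:`segment_breath_groups`.

    A converter from Buckeye-style ``.words``/``.phones`` files would map
    each phone row to a ``phoneme`` token, each word row to a ``word``
    token and every transcribed break (silence, noise, interviewer turn)
    to a ``pause`` token; the conversion itself is out of scope here.
    """
    try:
        df = pd.read_csv(
            source,
            sep="\t",
            dtype={"speaker_id": str, "level": str, "label": str},
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise AlignmentFormatError(str(exc)) from exc
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise AlignmentFormatError(f"missing columns: {missing}")
    df = df[ALIGNMENT_COLUMNS].copy()
    for col in ("onset_s", "duration_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValidationError(f"row {row}: non-numeric {col}")
        df[col] = vals.astype(float)
    for col in ("word_id", "bg_id"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    needs_bg = df.loc[df["level"] == "word", "bg_id"].isna().all()
    if needs_bg and (df["level"] == "word").any():
        df = segment_breath_groups(df)
    return SegmentedCorpus(df, tolerance=tolerance)


def write_alignment(corpus: SegmentedCorpus, target) -> None:
    """Write the token table as UTF-8 TSV (times with 6 decimals)."""
    df = corpus.tokens[ALIGNMENT_COLUMNS].copy()
    for col in ("onset_s", "duration_s"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    for col in ("word_id", "bg_id"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    if isinstance(target, (str,)) or hasattr(target, "__fspath__"):
        df.to_csv(target, sep="\t", index=False)
    else:
        df.to_csv(target, sep="\t", index=False)


# ---------------------------------------------------------------------------
# breath-group segmentation
# ---------------------------------------------------------------------------


def segment_breath_groups(tokens: pd.DataFrame) -> pd.DataFrame:
    """Assign ``bg_id`` to word (and phoneme) rows from pause positions.

    Every maximal pause-free run of words within a speaker becomes one BG;
    ids are global and sequential in (speaker, time) order.  Idempotent:
    re-running replaces any existing assignment with the same partition.
    """
    df = tokens.copy()
    df["bg_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    wp_mask = df["level"].isin(["word", "pause"]).to_numpy()
    if not wp_mask.any():
        return df
    wp = df[wp_mask]
    order = np.lexsort((wp["onset_s"].to_numpy(), wp["speaker_id"].to_numpy()))
    idx = wp.index.to_numpy()[order]
    lvl = wp["level"].to_numpy()[order]
    spk = wp["speaker_id"].to_numpy()[order]
    is_word = lvl == "word"
    after_break = np.empty(len(lvl), dtype=bool)
    after_break[0] = True
    after_break[1:] = (lvl[:-1] == "pause") | (spk[1:] != spk[:-1])
    new_bg = is_word & after_break
    run_id = np.cumsum(new_bg) - 1  # constant across each pause-free run
    df.loc[idx[is_word], "bg_id"] = run_id[is_word]
    # phonemes inherit through their word
    words = df[df["level"] == "word"]
    mapping = words.set_index("word_id")["bg_id"]
    phon = df["level"] == "phoneme"
    df.loc[phon, "bg_id"] = df.loc[phon, "word_id"].map(mapping)
    return df


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------


@dataclass
class LevelStats:
    n: int
    mean: float
    sd: float
    mode: float
    median: float
    p10: float
    p90: float

    def as_dict(self) -> dict:
        return {
            "N": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "mode": self.mode,
            "median": self.median,
            "p10": self.p10,
            "p90": self.p90,
        }


@dataclass
class CorpusSummary:
    """Descriptive statistics per level plus container counts.

    ``durations`` holds the time-duration blocks for phoneme/word/bg;
    ``counts`` holds characters-per-word, phonemes-per-word,
    phonemes-per-bg and words-per-bg.  Character counts are exposed at
    word level only: assigning characters to individual phonemes is
    ambiguous because the same word admits several phonetic realizations.
    """

    durations: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    @property
    def phonemes_per_word_ratio(self) -> float:
        """Mean word duration over mean phoneme duration."""
        return self.durations["word"].mean / self.durations["phoneme"].mean

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name, st in {**{f"duration_{k}": v for k, v in self.durations.items()},
                         **self.counts}.items():
            rows[name] = st.as_dict()
        return pd.DataFrame(rows).T

    def as_dict(self) -> dict:
        return {
            "durations": {k: v.as_dict() for k, v in self.durations.items()},
            "counts": {k: v.as_dict() for k, v in self.counts.items()},
        }


def _log_mode(sample: np.ndarray, n_bins: int = 50) -> float:
    # histogram in log space between the 0.5 and 99.5 percentiles:
    # raw-value modes are unstable for heavy-tailed samples
    logs = np.log(sample)
    lo, hi = np.percentile(logs, [0.5, 99.5])
    if hi <= lo:
        return float(np.exp(lo))
    hist, edges = np.histogram(logs, bins=n_bins, range=(lo, hi))
    k = int(np.argmax(hist))
    return float(np.exp(0.5 * (edges[k] + edges[k + 1])))


def _stats(sample: np.ndarray, discrete: bool = False, n_bins: int = 50) -> LevelStats:
    sample = np.asarray(sample, dtype=float)
    if discrete:
        vals, cnt = np.unique(sample, return_counts=True)
        mode = float(vals[np.argmax(cnt)])
    else:
        mode = _log_mode(sample, n_bins=n_bins)
    p10, med, p90 = np.percentile(sample, [10, 50, 90])
    return LevelStats(
        n=int(sample.size),
        mean=float(sample.mean()),
        sd=float(sample.std(ddof=0)),
        mode=mode,
        median=float(med),
        p10=float(p10),
        p90=float(p90),
    )


def summarize(corpus: SegmentedCorpus, n_bins: int = 50) -> CorpusSummary:
    """Per-level duration and container-count statistics.

    The mode of a duration sample is estimated as the centre of the
    maximal bin of a histogram in log-duration (``n_bins`` bins over the
    [p0.5, p99.5] range).  Absent levels are omitted with a warning.
    """
    if not len(corpus.tokens):
        raise ValidationError("empty corpus")
    out = CorpusSummary()
    frames = {
        "phoneme": corpus.phonemes,
        "word": corpus.words,
        "bg": corpus.bg_table,
    }
    for level, df in frames.items():
        if not len(df):
            warnings.warn(f"level {level!r} absent; block omitted")
            continue
        out.durations[level] = _stats(df["duration_s"].to_numpy(), n_bins=n_bins)
    words, phon = corpus.words, corpus.phonemes
    if len(words):
        chars = words["label"].map(character_count).to_numpy()
        out.counts["characters_per_word"] = _stats(chars, discrete=True)
        if len(phon):
            ppw = phon.groupby("word_id").size().to_numpy()
            out.counts["phonemes_per_word"] = _stats(ppw, discrete=True)
            ppb = phon.dropna(subset=["bg_id"]).groupby("bg_id").size().to_numpy()
            if ppb.size:
                out.counts["phonemes_per_bg"] = _stats(ppb, discrete=True)
        if len(corpus.bg_table):
            out.counts["words_per_bg"] = _stats(
                corpus.bg_table["n_words"].to_numpy(), discrete=True
            )
    return out
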