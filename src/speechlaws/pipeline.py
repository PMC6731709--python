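"""End-to-end analysis pipeline: one config in, one report out.

Runs the duration model selection, the mutual-information dependence
test, Zipf/Yule, Herdan in tokens and in time, brevity in all size
measures, the size-rank law, Menzerath-Altmann at both level pairs and
the speech-velocity summary, each recorded as a block of a single JSON
report.  Blocks fail independently: a missing level skips its block
with a reason instead of aborting the run.  A single global seed fans
out deterministically to per-stage child seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .corpus import SegmentedCorpus, read_alignment, summarize
from .synthetic import SyntheticSpec, generate_corpus
from .durations import select_model
from .lognormal import mi_with_null
from .ranklaws import rank_frequency, fit_zipf, fit_yule, herdan_curves, size_rank
from .brevity import build_type_table, spearman_brevity, fit_brevity
from .menzerath import mal_points, fit_mal, speech_velocity

__all__ = ["AnalysisConfig", "run_all", "load_config"]

STAGES = (
    "summary", "model_selection", "mutual_information", "zipf", "yule",
    "herdan", "brevity", "size_rank", "mal", "velocity",
)


@dataclass
class AnalysisConfig:
    """Input source plus per-law parameter blocks.

    Exactly one of ``input_path`` (alignment TSV) or ``synthetic``
    (generator spec) must be set.
    """

    input_path: str | None = None
    synthetic: SyntheticSpec | None = None
    seed: int = 0
    outdir: str | None = None
    n_shuffles: int = 100
    herdan_permutations: int = 10
    herdan_min_tokens: int = 100
    phoneme_f_min: int = 50
    char_alphabet: int = 26
    phoneme_alphabet: int = 64
    model_selection_max_n: int = 200_000  # subsample cap for the five-family fit

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("set exactly one of input_path or synthetic")


def load_config(path) -> AnalysisConfig:
    """Read a YAML config; the ``synthetic`` block mirrors SyntheticSpec."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    synth = raw.pop("synthetic", None)
    if synth is not None:
        synth = SyntheticSpec(**synth)
    return AnalysisConfig(synthetic=synth, **raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_all(config: AnalysisConfig) -> dict:
    """Execute every analysis stage; returns the JSON-ready report."""
    seeds = dict(zip(STAGES, _child_seeds(config.seed, len(STAGES))))
    report: dict = {
        "schema_version": 1,
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "source": config.input_path or "synthetic",
        },
        "blocks": {},
    }
    blocks = report["blocks"]

    if config.input_path is not None:
        corpus = read_alignment(config.input_path)
    else:
        corpus, truth = generate_corpus(config.synthetic)
        report["provenance"]["synthetic_spec"] = config.synthetic.as_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(report["provenance"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report["provenance"]["config_hash"] = cfg_hash

    def stage(name):
        def wrap(fn):
            try:
                blocks[name] = {"status": "ok", "result": fn()}
            except Exception as exc:
                blocks[name] = {"status": "skipped", "reason": str(exc)}
        return wrap

    @stage("summary")
    def _():
        return summarize(corpus).as_dict()

    @stage("model_selection")
    def _():
        rng = np.random.default_rng(seeds["model_selection"])
        out = {}
        samples = {
            "phoneme": corpus.phonemes["duration_s"].to_numpy(),
            "word": corpus.words["duration_s"].to_numpy(),
            "bg": corpus.bg_table["duration_s"].to_numpy(),
        }
        for level, x in samples.items():
            if x.size < 10:
                out[level] = {"skipped": "too few tokens"}
                continue
            if x.size > config.model_selection_max_n:
                x = rng.choice(x, size=config.model_selection_max_n, replace=False)
            out[level] = select_model(x).as_dict()
        return out

    @stage("mutual_information")
    def _():
        out = {}
        for level in ("phoneme", "word"):
            res = mi_with_null(
                corpus, level=level, n_shuffles=config.n_shuffles,
                seed=seeds["mutual_information"],
            )
            out[level] = res.as_dict()
        return out

    @stage("zipf")
    def _():
        rt = rank_frequency(corpus.words["label"])
        return fit_zipf(rt).as_dict()

    @stage("yule")
    def _():
        rt = rank_frequency(corpus.phonemes["label"])
        return fit_yule(rt).as_dict()

    @stage("herdan")
    def _():
        out = {}
        for mode in ("tokens", "time"):
            fit = herdan_curves(
                corpus, mode=mode, n_permutations=config.herdan_permutations,
                seed=seeds["herdan"], min_tokens=config.herdan_min_tokens,
                keep_curve=False,
            )
            out[mode] = fit.as_dict()
        return out

    @stage("brevity")
    def _():
        out = {}
        words = build_type_table(corpus, "word")
        for measure, mode, D in (
            ("duration", "continuous", None),
            ("phonemes", "discrete", config.phoneme_alphabet),
            ("chars", "discrete", config.char_alphabet),
        ):
            try:
                s, p = spearman_brevity(words, measure)
                fit = fit_brevity(words, measure, mode=mode, alphabet_size=D)
                out[f"word_{measure}"] = {
                    "spearman_S": s, "spearman_p": p, **fit.as_dict()
                }
            except ValueError as exc:
                out[f"word_{measure}"] = {"skipped": str(exc)}
        try:
            phon = build_type_table(corpus, "phoneme")
            s, p = spearman_brevity(phon, "duration", f_min=config.phoneme_f_min)
            fit = fit_brevity(phon, "duration", mode="continuous",
                              f_min=config.phoneme_f_min)
            out["phoneme_duration"] = {"spearman_S": s, "spearman_p": p, **fit.as_dict()}
        except ValueError as exc:
            out["phoneme_duration"] = {"skipped": str(exc)}
        return out

    @stage("size_rank")
    def _():
        zb = blocks.get("zipf", {})
        bb = blocks.get("brevity", {})
        if zb.get("status") != "ok" or bb.get("status") != "ok":
            raise ValueError("requires the zipf and brevity blocks")
        z = zb["result"]
        lam = bb["result"]["word_duration"]["lambda"]
        rt = rank_frequency(corpus.words["label"])
        table = build_type_table(corpus, "word").table.set_index("label")
        sizes = table["median_duration_s"].reindex(rt.table["label"]).to_numpy()
        fit = size_rank(rt, sizes, z["r_star"], z["alpha1"], z["alpha2"], lam)
        return fit.as_dict()

    @stage("mal")
    def _():
        out = {}
        for construct, constituent, measure in (
            ("bg", "word", "duration"),
            ("bg", "word", "phonemes"),
            ("bg", "word", "chars"),
            ("word", "phoneme", "duration"),
        ):
            key = f"{construct}_{constituent}_{measure}"
            try:
                pts = mal_points(corpus, construct, constituent, measure)
                out[key] = fit_mal(pts, seed=seeds["mal"]).as_dict()
            except (ValueError, RuntimeError) as exc:
                out[key] = {"skipped": str(exc)}
        return out

    @stage("velocity")
    def _():
        mb = blocks.get("mal", {})
        if mb.get("status") != "ok":
            raise ValueError("requires the mal block")
        fitd = mb["result"].get("bg_word_duration", {})
        if "skipped" in fitd or fitd.get("b") is None:
            raise ValueError("requires the BG/word duration MAL fit")
        from .menzerath import MALFit
        fit = MALFit(a=fitd["a"], b=fitd["b"], c=fitd["c"],
                     r2_binned=fitd["r2_binned"], r2_means=fitd["r2_means"],
                     n_star=fitd["n_star"], v_max=fitd["v_max"])
        vel = speech_velocity(fit)
        res = vel.as_dict()
        mean_n = float(corpus.bg_table["n_words"].mean())
        res["mean_bg_words"] = mean_n
        res["v_at_mean_n"] = float(vel.v_at(mean_n))
        return res

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
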