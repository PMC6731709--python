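"""Shared study conditions for the numbered analysis drivers.

The drivers run on one synthetic corpus generated at a reduced size
(6 x 10^4 word tokens over 12 speakers) so the whole sequence finishes
in well under a minute; every estimator is identical to what a
full-size run would use.
"""

import json
from pathlib import Path

import numpy as np

import speechlaws as sl

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

CORPUS_SPEC = sl.SyntheticSpec(
    vocabulary_size=4000,
    n_tokens=60_000,
    n_speakers=12,
    seed=42,
)

_cache = {}


def get_corpus():
    if "corpus" not in _cache:
        _cache["corpus"] = sl.generate_corpus(CORPUS_SPEC)
    return _cache["corpus"]


def write_json(name: str, payload: dict) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
    return path


def _default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(type(obj))
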