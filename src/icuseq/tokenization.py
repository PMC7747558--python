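"""Curation-free tokenization of heterogeneous clinical events.

Every event becomes exactly one token, with no variable selection,
outlier removal or unit handling:

* a value that parses as a single finite float is *continuous* and is
  quantized into one of ``B`` equal-frequency (percentile) bins fitted on
  training data only, yielding ``label_b`` with a 1-based bin index;
* an empty value or a missing-value sentinel yields the explicit token
  ``label_NaN`` so the model can exploit informative missingness;
* everything else — free text, codes, malformed numerics such as
  ``7.4.2`` — is *discrete* and kept verbatim as ``label_value``.

Instrument artifacts (e.g. a faulty monitor logging blood pH 5.5) are not
removed; by construction they concentrate in a variable's edge bins, where
the model can learn to discount them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LeakageError",
    "DEFAULT_MISSING_SENTINELS",
    "is_continuous",
    "is_missing",
    "BinningModel",
    "fit_binning",
    "tokenize_event",
    "tokenize_events",
    "Vocabulary",
    "build_vocabulary",
    "TokenizedStay",
    "encode_stay",
    "encode_cohort",
]

DEFAULT_MISSING_SENTINELS = frozenset({"", "nan", "NaN", "NA"})

PAD_TOKEN = "<PAD>"
UNK_TOKEN = "<UNK>"


class LeakageError(RuntimeError):
    """Raised when test-tagged data reaches a fit-time operation."""


def is_missing(value, sentinels=DEFAULT_MISSING_SENTINELS) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return True
    return str(value).strip() in sentinels


def is_continuous(value) -> bool:
    """True iff the trimmed value string is a single finite float.

    Missing sentinels are *not* continuous (they route to the missing
    branch), and malformed numerics with multiple decimal points are
    discrete by design.
    """
    if is_missing(value):
        return False
    try:
        return math.isfinite(float(str(value).strip()))
    except (TypeError, ValueError):
        return False


def _classify(values: pd.Series, sentinels=DEFAULT_MISSING_SENTINELS):
    """Vectorized split into (missing, continuous, numeric floats)."""
    s = values.astype(str).str.strip()
    missing = s.isin(sentinels).to_numpy()
    nums = pd.to_numeric(s, errors="coerce").to_numpy(dtype=float)
    continuous = np.isfinite(nums) & ~missing
    return missing, continuous, nums


@dataclass
class BinningModel:
    """Per-variable percentile cut points fitted on training data only.

    ``cuts[label]`` holds the strictly increasing interior cut points
    (at most ``B - 1``; fewer when training quantiles tie).  Assignment is
    half-open: values below the first cut land in bin 1, values at or
    above cut ``i`` move past it, and values at or above the last cut
    share bin ``B``.
    """

    bins: int
    cuts: dict = field(default_factory=dict)
    n_train: dict = field(default_factory=dict)

    def __contains__(self, label):
        return label in self.cuts

    def assign(self, label: str, value: float) -> int:
        """1-based bin index for a numeric value of a fitted label."""
        return int(np.searchsorted(self.cuts[label], value, side="right")) + 1

    def n_bins_used(self, label: str) -> int:
        return len(self.cuts[label]) + 1

    def to_json(self) -> str:
        payload = {
            "bins": self.bins,
            "n_train": self.n_train,
            # repr round-trips float64 exactly through text
            "cuts": {lab: [repr(float(c)) for c in cs] for lab, cs in self.cuts.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BinningModel":
        payload = json.loads(text)
        return cls(
            bins=int(payload["bins"]),
            cuts={
                lab: np.array([float(c) for c in cs], dtype=float)
                for lab, cs in payload["cuts"].items()
            },
            n_train={k: int(v) for k, v in payload["n_train"].items()},
        )

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path):
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def fit_binning(
    events: pd.DataFrame,
    bins: int = 10,
    split: str = "train",
    sentinels=DEFAULT_MISSING_SENTINELS,
) -> BinningModel:
    """Fit per-label percentile cut points from training events.

    Cut points sit at the ``i/B`` quantiles (``i = 1..B-1``, linear
    interpolation on the sorted training values); duplicate cut points
    arising from heavy ties are collapsed, so integer-dense variables get
    fewer, wider bins.  Labels with no numeric training value are absent
    from the model (their values are always tokenized verbatim).

    ``split`` is a leakage guard: passing data tagged ``"test"`` raises
    :class:`LeakageError`.
    """
    if split == "test":
        raise LeakageError("fit_binning must never see test-tagged data")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    _, continuous, nums = _classify(events["value"], sentinels)
    labels = events["label"].to_numpy()
    model = BinningModel(bins=bins)
    cont = pd.DataFrame({"label": labels[continuous], "x": nums[continuous]})
    for lab, grp in cont.groupby("label", sort=True):
        x = grp["x"].to_numpy()
        q = np.unique(np.quantile(x, np.arange(1, bins) / bins, method="linear"))
        # a cut at or below the sample minimum would leave bin 1 empty
        # (constant variables collapse to a single bin)
        model.cuts[lab] = q[q > x.min()]
        model.n_train[lab] = len(x)
    return model


def tokenize_event(
    label: str,
    value,
    binning: BinningModel,
    sentinels=DEFAULT_MISSING_SENTINELS,
) -> str:
    """Map one (label, raw value) pair to its token string.

    Total by construction: missing -> ``label_NaN``; continuous with a
    fitted label -> ``label_<bin>``; anything else -> ``label_<value>``
    verbatim (including numeric values of labels that had no numeric
    training data).
    """
    if is_missing(value, sentinels):
        return f"{label}_NaN"
    v = str(value).strip()
    if is_continuous(v) and label in binning:
        return f"{label}_{binning.assign(label, float(v))}"
    return f"{label}_{v}"


def tokenize_events(
    events: pd.DataFrame,
    binning: BinningModel,
    sentinels=DEFAULT_MISSING_SENTINELS,
) -> pd.Series:
    """Vectorized :func:`tokenize_event` over an events frame."""
    labels = events["label"].astype(str).to_numpy()
    raw = events["value"].astype(str).str.strip().to_numpy()
    missing, continuous, nums = _classify(events["value"], sentinels)

    out = np.empty(len(events), dtype=object)
    out[missing] = np.char.add(labels[missing].astype(str), "_NaN")

    fitted = np.array([lab in binning for lab in labels], dtype=bool)
    binnable = continuous & fitted
    if binnable.any():
        idx = np.flatnonzero(binnable)
        sub = pd.DataFrame({"label": labels[idx], "x": nums[idx], "i": idx})
        for lab, grp in sub.groupby("label", sort=False):
            b = np.searchsorted(binning.cuts[lab], grp["x"].to_numpy(), side="right") + 1
            out[grp["i"].to_numpy()] = [f"{lab}_{bi}" for bi in b]
    rest = ~missing & ~binnable
    out[rest] = [f"{lab}_{v}" for lab, v in zip(labels[rest], raw[rest])]
    return pd.Series(out, index=events.index, name="token")


@dataclass
class Vocabulary:
    """Dense bijection between token strings and integer indices.

    Index 0 is the reserved PAD/empty-hour token (its embedding is pinned
    to the zero vector) and index 1 the shared UNK for tokens first seen
    outside training.
    """

    index_to_token: list

    def __post_init__(self):
        self.token_to_index = {t: i for i, t in enumerate(self.index_to_token)}

    def __len__(self):
        return len(self.index_to_token)

    @property
    def pad_index(self):
        return 0

    @property
    def unk_index(self):
        return 1

    def encode(self, token: str) -> int:
        return self.token_to_index.get(token, self.unk_index)

    def encode_many(self, tokens) -> np.ndarray:
        get = self.token_to_index.get
        return np.fromiter((get(t, 1) for t in tokens), dtype=np.int64, count=len(tokens))

    def decode(self, index: int) -> str:
        return self.index_to_token[index]

    def to_json(self) -> str:
        return json.dumps({"tokens": self.index_to_token}, indent=0)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        return cls(index_to_token=list(json.loads(text)["tokens"]))

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path):
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def build_vocabulary(tokens, split: str = "train") -> Vocabulary:
    """Vocabulary of every token observed in the training corpus.

    The domain is *observed* tokens (not the combinatorial label x bin
    maximum).  Ordering is sorted for determinism, after the two reserved
    entries.
    """
    if split == "test":
        raise LeakageError("build_vocabulary must never see test-tagged data")
    uniq = sorted(set(map(str, tokens)))
    return Vocabulary(index_to_token=[PAD_TOKEN, UNK_TOKEN] + uniq)


@dataclass
class TokenizedStay:
    """One stay as ``window`` hourly lists of vocabulary indices."""

    stay_id: str
    outcome: int
    hours: list  # length == window; each entry an int64 array, time-ordered

    @property
    def n_events(self):
        return int(sum(len(h) for h in self.hours))

    def to_json(self) -> str:
        return json.dumps(
            {
                "stay_id": self.stay_id,
                "outcome": int(self.outcome),
                "hours": [np.asarray(h).tolist() for h in self.hours],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TokenizedStay":
        d = json.loads(text)
        return cls(
            stay_id=d["stay_id"],
            outcome=int(d["outcome"]),
            hours=[np.asarray(h, dtype=np.int64) for h in d["hours"]],
        )


def encode_stay(
    stay_events: pd.DataFrame,
    outcome: int,
    stay_id: str,
    binning: BinningModel,
    vocab: Vocabulary,
    window: int = 48,
) -> TokenizedStay:
    """Encode one stay's truncated, hour-annotated events.

    Empty hours produce empty index lists; the model maps those to the
    zero PAD embedding downstream.
    """
    hours = [np.empty(0, dtype=np.int64) for _ in range(window)]
    if len(stay_events):
        toks = tokenize_events(stay_events, binning)
        idx = vocab.encode_many(toks.to_numpy())
        hr = stay_events["hour"].to_numpy(dtype=int)
        for t in range(window):
            hours[t] = idx[hr == t]
    return TokenizedStay(stay_id=stay_id, outcome=int(outcome), hours=hours)


def encode_cohort(cohort, binning: BinningModel, vocab: Vocabulary, stay_ids=None):
    """Encode a cohort (or a subset of its stays) to :class:`TokenizedStay`.

    Tokenization of the full events frame is done once, vectorized, then
    split per stay; within-hour order follows event time order.
    """
    ids = cohort.stay_ids if stay_ids is None else list(stay_ids)
    ev = cohort.events[cohort.events["stay_id"].isin(ids)]
    window = cohort.window_hours
    groups = {}
    if len(ev):
        toks = tokenize_events(ev, binning)
        codes = vocab.encode_many(toks.to_numpy())
        hrs = ev["hour"].to_numpy(dtype=int)
        groups = ev.reset_index(drop=True).groupby("stay_id", sort=False).indices
    out = []
    for sid in ids:
        hours = [np.empty(0, dtype=np.int64) for _ in range(window)]
        pos = groups.get(sid)
        if pos is not None and len(pos):
            c, h = codes[pos], hrs[pos]
            for t in np.unique(h):
                hours[int(t)] = c[h == t]
        out.append(
            TokenizedStay(
                stay_id=sid,
                outcome=int(cohort.stays.loc[sid, "outcome"]),
                hours=hours,
            )
        )
    return out
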