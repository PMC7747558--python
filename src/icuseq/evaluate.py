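"""Dynamic performance measurement and per-patient trajectory reports.

AUROC is the probability that a randomly chosen stay ending in death is
scored above a randomly chosen survivor (Mann-Whitney formulation, ties
at half credit).  The headline output is AUROC as a function of hours
since ICU admission, with percentile-bootstrap confidence bands computed
by resampling the test set and rescoring with the fold-averaged
cross-validated model probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import forward, forward_batch, pack_stays
from .tokenization import encode_cohort

__all__ = [
    "UndefinedAUROCError",
    "auroc",
    "score_stays",
    "fold_mean_scores",
    "auroc_over_time",
    "bootstrap_ci",
    "EvalCurve",
    "eval_curve",
    "TrajectoryReport",
    "trajectory_report",
    "SAPS_II_AUROC",
    "OASIS_AUROC",
]

# literature comparator constants (24 h severity scores); never computed here
SAPS_II_AUROC = 0.72
OASIS_AUROC = 0.76


class UndefinedAUROCError(ValueError):
    """AUROC is undefined when only one outcome class is present."""


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUROCError("need at least one positive and one negative label")
    r = rankdata(s)  # average ranks give ties half credit
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def score_stays(stays, params, config) -> np.ndarray:
    """(n_stays, T) probability matrix for a list of tokenized stays."""
    tokens, seg, _ = pack_stays(stays, config.window)
    probs, _ = forward_batch(tokens, seg, len(stays), params, config, training_mode=False)
    return probs


def fold_mean_scores(fold_models, cohort, stay_ids):
    """Per-stay, per-hour scores averaged over the cross-validated models.

    Each fold encodes the stays with its *own* binning and vocabulary
    (tokens unseen by that fold map to UNK), then the fold probabilities
    are averaged.  Returns ``(scores (n, T), per_fold (F, n, T), y (n,))``.
    """
    per_fold = []
    y = None
    for fm in fold_models:
        stays = encode_cohort(cohort, fm.binning, fm.vocab, stay_ids)
        if y is None:
            y = np.array([s.outcome for s in stays], dtype=int)
        per_fold.append(score_stays(stays, fm.params, fm.config))
    per_fold = np.stack(per_fold)
    return per_fold.mean(axis=0), per_fold, y


def auroc_over_time(fold_models, cohort, stay_ids):
    """Point AUROC at every hour from fold-averaged test scores.

    Returns ``(aurocs (T,), scores (n, T), y)``; hours where only one
    class is present propagate :class:`UndefinedAUROCError`.
    """
    scores, _, y = fold_mean_scores(fold_models, cohort, stay_ids)
    T = scores.shape[1]
    return np.array([auroc(scores[:, t], y) for t in range(T)]), scores, y


def bootstrap_ci(scores, labels, n_resamples=10000, level=0.95, seed=0):
    """Percentile bootstrap CI for AUROC over test-set resamples.

    ``scores`` may be (n,) fold-averaged scores or (F, n) per-fold
    scores, which are averaged before ranking.  Resamples that draw a
    single outcome class are redrawn (and counted).  Returns
    ``(lower, upper, n_redrawn)``.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim == 2:
        s = s.mean(axis=0)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    n_redrawn = 0
    while True:
        pos = y[idx].sum(axis=1)
        bad = (pos == 0) | (pos == n)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    yy = y[idx]
    r = rankdata(s[idx], axis=1)
    n_pos = yy.sum(axis=1)
    n_neg = n - n_pos
    stats = ((r * yy).sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi), n_redrawn


@dataclass
class EvalCurve:
    """Per-hour AUROC with bootstrap confidence bands."""

    hours: np.ndarray
    auroc: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_stays: int
    n_resamples: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hour": self.hours, "auroc": self.auroc,
             "ci_lower": self.ci_lower, "ci_upper": self.ci_upper}
        )

    def to_json(self) -> str:
        return json.dumps(
            {"hours": self.hours.tolist(), "auroc": self.auroc.tolist(),
             "ci_lower": self.ci_lower.tolist(), "ci_upper": self.ci_upper.tolist(),
             "n_stays": self.n_stays, "n_resamples": self.n_resamples,
             "seed": self.seed},
            indent=1,
        )

    def save(self, csv_path=None, json_path=None):
        if csv_path:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path:
            with open(json_path, "w", encoding="utf-8") as fh:
                fh.write(self.to_json())


def eval_curve(fold_models, cohort, stay_ids, n_resamples=10000, level=0.95, seed=0):
    """AUROC-over-time with per-hour bootstrap bands on the test stays."""
    aurocs, scores, y = auroc_over_time(fold_models, cohort, stay_ids)
    T = scores.shape[1]
    lo = np.empty(T)
    hi = np.empty(T)
    for t in range(T):
        lo[t], hi[t], _ = bootstrap_ci(scores[:, t], y, n_resamples, level, seed + t)
    return EvalCurve(
        hours=np.arange(T), auroc=aurocs, ci_lower=lo, ci_upper=hi,
        n_stays=len(y), n_resamples=n_resamples, seed=seed,
    )


@dataclass
class TrajectoryReport:
    """Hour-by-hour mortality probability with ranked contributing events."""

    stay_id: str
    probs: np.ndarray
    top_events: list  # per hour: [(rank, token, percentile_range_or_None), ...]

    def to_json(self) -> str:
        return json.dumps(
            {"stay_id": self.stay_id, "probs": self.probs.tolist(),
             "top_events": [
                 [{"rank": r, "token": tok, "percentile": pct} for r, tok, pct in hour]
                 for hour in self.top_events
             ]},
            indent=1,
        )


def _percentile_range(token, binning):
    """Nominal percentile range of a continuous bin token, else None."""
    label, _, suffix = token.rpartition("_")
    if label not in binning.cuts or not suffix.isdigit():
        return None
    b = int(suffix)
    nb = binning.n_bins_used(label)
    if not 1 <= b <= nb:
        return None
    lo = round(100.0 * (b - 1) / nb)
    hi = round(100.0 * b / nb)
    return f"{lo}-{hi}%"


def trajectory_report(fold_model, stay, top_k=5) -> TrajectoryReport:
    """Per-hour probability and the top-k tokens by aggregation weight.

    Continuous bin tokens are annotated with their bin expressed as a
    nominal percentile range of the training distribution; discrete and
    missingness tokens carry no range.  Hours with fewer than ``top_k``
    events report what is present; empty hours report an empty ranking
    but still a probability.
    """
    traj = forward(stay, fold_model.params, fold_model.config, training_mode=False)
    top_events = []
    for idx, wts in zip(traj.hour_tokens, traj.hour_weights):
        if idx.size == 0:
            top_events.append([])
            continue
        toks = [fold_model.vocab.decode(int(i)) for i in idx]
        order = sorted(range(len(toks)), key=lambda j: (-wts[j], toks[j]))[:top_k]
        hour = []
        for rank, j in enumerate(order, start=1):
            hour.append((rank, toks[j], _percentile_range(toks[j], fold_model.binning)))
        top_events.append(hour)
    return TrajectoryReport(stay_id=stay.stay_id, probs=traj.probs, top_events=top_events)


def plot_eval_curve(curve: EvalCurve, path=None, show_comparators=True):
    """AUROC-over-time figure with the 24 h severity-score constants."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(curve.hours, curve.auroc, color="C0", label="model")
    ax.fill_between(curve.hours, curve.ci_lower, curve.ci_upper, alpha=0.25, color="C0")
    if show_comparators:
        ax.scatter([24], [SAPS_II_AUROC], color="C1", marker="s", label="SAPS II (24 h)")
        ax.scatter([24], [OASIS_AUROC], color="C2", marker="^", label="OASIS (24 h)")
    ax.set_xlabel("hours since ICU admission")
    ax.set_ylabel("AUROC")
    ax.set_ylim(0.4, 1.0)
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_trajectory(report: TrajectoryReport, path=None):
    """Per-patient mortality-probability trajectory figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(np.arange(len(report.probs)), report.probs, color="C3")
    ax.set_xlabel("hours since ICU admission")
    ax.set_ylabel("P(in-hospital mortality)")
    ax.set_ylim(0, 1)
    ax.set_title(f"stay {report.stay_id}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
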