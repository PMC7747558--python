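"""Training protocol: stratified splits, cross-validation, early stopping.

Mirrors a standard ICU-prediction regime: stays are split into a 90%
training pool and a 10% held-out test set, stratified by outcome; each
cross-validation fold carves a fixed-size, outcome-stratified validation
set out of the pool; the tokenizer (binning + vocabulary) is refitted on
each fold's training stays only; training uses Adam (lr 0.0005, batch
128) and stops once the validation AUROC has failed to improve on its
running best for more than five consecutive epochs, returning the
parameters from the best epoch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split

from .evaluate import auroc
from .model import Adam, ModelConfig, forward_batch, init_params, loss_and_grads, pack_stays
from .tokenization import LeakageError, build_vocabulary, encode_cohort, fit_binning, tokenize_events

__all__ = [
    "SplitPlan",
    "TrainRecord",
    "OptimSettings",
    "FoldModel",
    "EarlyStopper",
    "make_splits",
    "train_fold",
    "cross_validate",
    "grid_search",
]


@dataclass
class SplitPlan:
    """Test/fold assignment of stay ids, reproducible from its seed."""

    test_ids: list
    folds: list  # [(train_ids, val_ids), ...]
    seed: int
    val_size: int

    @property
    def n_folds(self):
        return len(self.folds)


def make_splits(stay_ids, outcomes, n_folds=10, val_size=None, test_frac=0.1, seed=0):
    """Build the stratified test split and per-fold train/validation splits.

    ``val_size`` defaults to 1000 stays, scaled down to at most a tenth
    of the training pool for small cohorts.  Validation sets are
    outcome-stratified, so their prevalence tracks the pool's within one
    stay per class.
    """
    ids = np.asarray(stay_ids)
    y = np.asarray(outcomes, dtype=int)
    if len(ids) != len(y):
        raise ValueError("stay_ids and outcomes length mismatch")
    pool_size = int(round(len(ids) * (1 - test_frac)))
    if val_size is None:
        val_size = min(1000, max(1, pool_size // 10))
    if val_size >= pool_size:
        raise ValueError(
            f"cohort too small: validation size {val_size} >= training pool {pool_size}"
        )
    if min(np.bincount(y, minlength=2)) < max(2, n_folds):
        raise ValueError("cohort too small for stratified splitting")

    pool_ids, test_ids, pool_y, _ = train_test_split(
        ids, y, test_size=test_frac, stratify=y, random_state=seed
    )
    splitter = StratifiedShuffleSplit(
        n_splits=n_folds, test_size=val_size, random_state=seed + 1
    )
    folds = []
    for tr, va in splitter.split(pool_ids, pool_y):
        folds.append((list(pool_ids[tr]), list(pool_ids[va])))
    return SplitPlan(test_ids=list(test_ids), folds=folds, seed=seed, val_size=val_size)


@dataclass
class TrainRecord:
    """Per-epoch bookkeeping for one fold."""

    train_losses: list = field(default_factory=list)
    val_aurocs: list = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_epoch: int = 0

    @property
    def best_val_auroc(self):
        return max(self.val_aurocs) if self.val_aurocs else float("nan")


class EarlyStopper:
    """Stop once validation AUROC plateaus for more than ``patience`` epochs.

    An epoch improves when it beats the running best by at least
    ``min_delta``; after more than ``patience`` consecutive
    non-improving epochs training stops and the best epoch's parameters
    are kept.
    """

    def __init__(self, patience=5, min_delta=1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0

    def update(self, value, epoch):
        """Record epoch (1-based); returns True when training should stop."""
        if value >= self.best + self.min_delta or self.best_epoch == 0:
            self.best = value
            self.best_epoch = epoch
            self.epochs_since_best = 0
        else:
            self.epochs_since_best += 1
        return self.epochs_since_best > self.patience


@dataclass
class OptimSettings:
    lr: float = 5e-4
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 5
    min_delta: float = 1e-4


def _final_hour_scores(stays, params, config):
    tokens, seg, _ = pack_stays(stays, config.window)
    probs, _ = forward_batch(tokens, seg, len(stays), params, config, training_mode=False)
    return probs[:, -1]


def train_fold(train_stays, val_stays, vocab_size, config: ModelConfig,
               optim: OptimSettings = None, seed: int = 0):
    """Train one fold with early stopping on validation final-hour AUROC.

    Returns ``(best_params, TrainRecord)``; parameters come from the epoch
    with the best validation AUROC, never a later one.
    """
    optim = optim or OptimSettings()
    rng = np.random.default_rng(seed)
    params = init_params(config, vocab_size, rng)
    opt = Adam(params, lr=optim.lr)
    stopper = EarlyStopper(patience=optim.patience, min_delta=optim.min_delta)
    record = TrainRecord()
    best_params = params.copy()

    # pre-pack per stay once; batches concatenate slices
    packed = [pack_stays([s], config.window) for s in train_stays]
    outcomes = np.array([s.outcome for s in train_stays], dtype=float)
    n = len(train_stays)

    for epoch in range(1, optim.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, optim.batch_size):
            sel = order[start:start + optim.batch_size]
            toks, segs = [], []
            for b_pos, s_i in enumerate(sel):
                t, g, _ = packed[s_i]
                toks.append(t)
                segs.append(g + b_pos * config.window)
            tokens = np.concatenate(toks) if toks else np.empty(0, dtype=np.int64)
            seg = np.concatenate(segs) if segs else np.empty(0, dtype=np.int64)
            L, grads = loss_and_grads(tokens, seg, outcomes[sel], params, config,
                                      training_mode=True, rng=rng)
            if not np.isfinite(L):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting fold"
                )
            opt.step(params, grads)
            epoch_loss += L
            n_batches += 1
        record.train_losses.append(epoch_loss / max(n_batches, 1))

        val_scores = _final_hour_scores(val_stays, params, config)
        val_y = np.array([s.outcome for s in val_stays], dtype=int)
        va = auroc(val_scores, val_y)
        record.val_aurocs.append(va)
        stop = stopper.update(va, epoch)
        if stopper.best_epoch == epoch:
            best_params = params.copy()
        if stop:
            break
    record.best_epoch = stopper.best_epoch
    record.stopped_epoch = epoch
    return best_params, record


@dataclass
class FoldModel:
    """Everything needed to score new stays with one fold's model."""

    params: object
    config: ModelConfig
    binning: object
    vocab: object
    record: TrainRecord


def _fit_fold_tokenizer(cohort, train_ids, bins):
    ev = cohort.events[cohort.events["stay_id"].isin(train_ids)]
    binning = fit_binning(ev, bins=bins, split="train")
    tokens = tokenize_events(ev, binning)
    vocab = build_vocabulary(tokens, split="train")
    return binning, vocab


def cross_validate(cohort, plan: SplitPlan, config: ModelConfig,
                   optim: OptimSettings = None, seed: int = 0):
    """Train one model per fold, refitting binning/vocabulary per fold.

    Test stays never reach ``fit_binning``/``build_vocabulary`` or the
    optimizer; they are encoded per fold only at evaluation time.
    """
    test = set(plan.test_ids)
    results = []
    for k, (train_ids, val_ids) in enumerate(plan.folds):
        if test & set(train_ids) or test & set(val_ids):
            raise LeakageError(f"fold {k} overlaps the held-out test set")
        try:
            binning, vocab = _fit_fold_tokenizer(cohort, train_ids, config.bins)
            train_stays = encode_cohort(cohort, binning, vocab, train_ids)
            val_stays = encode_cohort(cohort, binning, vocab, val_ids)
            params, record = train_fold(
                train_stays, val_stays, len(vocab), config, optim, seed=seed + k
            )
        except Exception as exc:
            raise RuntimeError(f"fold {k} failed: {exc}") from exc
        results.append(FoldModel(params=params, config=config, binning=binning,
                                 vocab=vocab, record=record))
    return results


def grid_search(cohort, plan: SplitPlan, base_config: ModelConfig, grid: dict,
                optim: OptimSettings = None, seed: int = 0):
    """Exhaustive grid search selecting by mean validation AUROC across folds.

    ``grid`` maps ModelConfig field names to candidate value lists.  One
    global configuration is selected for all folds.  Returns
    ``(best_config, table)`` where ``table`` rows log every (config, fold)
    run.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    keys = sorted(grid)
    table = []
    best_cfg, best_mean = None, -np.inf
    for values in itertools.product(*(grid[k] for k in keys)):
        cfg = ModelConfig.from_dict({**base_config.to_dict(), **dict(zip(keys, values))})
        fold_aurocs = []
        for k, (train_ids, val_ids) in enumerate(plan.folds):
            binning, vocab = _fit_fold_tokenizer(cohort, train_ids, cfg.bins)
            train_stays = encode_cohort(cohort, binning, vocab, train_ids)
            val_stays = encode_cohort(cohort, binning, vocab, val_ids)
            _, record = train_fold(train_stays, val_stays, len(vocab), cfg, optim,
                                   seed=seed + k)
            fold_aurocs.append(record.best_val_auroc)
            table.append({**dict(zip(keys, values)), "fold": k,
                          "val_auroc": record.best_val_auroc})
        mean_auroc = float(np.mean(fold_aurocs))
        if mean_auroc > best_mean:
            best_mean, best_cfg = mean_auroc, cfg
    return best_cfg, table
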