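"""Shared fixtures: small synthetic cohorts and trained pipeline runs."""

import pytest

from icuseq.evaluate import auroc_over_time
from icuseq.ingest import build_cohort
from icuseq.model import ModelConfig
from icuseq.synth import bayes_reference_auroc, generate_cohort, preset
from icuseq.train import OptimSettings, cross_validate, make_splits


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small strong-signal cohort for unit tests (fast to generate)."""
    cfg = preset("strong-signal", n_stays=120)
    events, stays, gt = generate_cohort(cfg, seed=7)
    cohort = build_cohort(stays, events)
    return {"cfg": cfg, "events": events, "stays": stays, "gt": gt, "cohort": cohort}


def run_pipeline_once(preset_name, seed, test_frac=0.1, max_epochs=40, overrides=None):
    """One full generate -> ingest -> train -> score run; returns a dict."""
    cfg = preset(preset_name, **(overrides or {}))
    events, stays, gt = generate_cohort(cfg, seed=seed)
    cohort = build_cohort(stays, events)
    plan = make_splits(cohort.stay_ids, cohort.outcomes(), n_folds=1,
                       test_frac=test_frac, seed=seed)
    mcfg = ModelConfig(embedding_dim=16, hidden_units=32, embedding_dropout=0.1)
    folds = cross_validate(cohort, plan, mcfg, OptimSettings(max_epochs=max_epochs),
                           seed=seed)
    aurocs, scores, y = auroc_over_time(folds, cohort, plan.test_ids)
    return {"cfg": cfg, "gt": gt, "cohort": cohort, "plan": plan, "folds": folds,
            "aurocs": aurocs, "scores": scores, "y": y, "events": events,
            "stays": stays}


@pytest.fixture(scope="session")
def strong_runs():
    """Five seeded strong-signal training runs plus the Bayes ceiling."""
    runs = {seed: run_pipeline_once("strong-signal", seed) for seed in range(1, 6)}
    bayes = bayes_reference_auroc(preset("strong-signal"), n_mc=100_000, seed=0)
    return {"runs": runs, "bayes": bayes}
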