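"""Experiment scenarios: baseline, iterative fine-tuning, site onboarding.

* **baseline** — the untrained backend evaluated on every mapped concept.
* **iterative** — a fixed 10% hold-out is set aside; for each training
  fraction f in a grid, f of the remaining pool is sampled, a fresh backend
  is fine-tuned on it, and metrics are computed on both the unsampled
  remainder (validation) and the hold-out.  Repeated ``repeats`` times per
  fraction; results aggregate to mean +/- sample sd.
* **onboarding** — leave-one-site-out: for each site, train on every other
  site's validated mappings and evaluate on the held-out site, aggregating
  across sites by the concept-weighted mean.  This emulates switching the
  system on for a hospital whose naming conventions were never seen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import METRIC_NAMES, MetricSet, holdout_split, rank_sources
from .models import MappingRecord, MappingStatus, Vocabulary
from .training import TrainingConfig, train_model

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "baseline_scenario",
    "iterative_scenario",
    "onboarding_scenario",
]

BackendFactory = Callable[[], "object"]


@dataclass(frozen=True)
class ScenarioConfig:
    fractions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    repeats: int = 5
    holdout_fraction: float = 0.10
    seed: int = 7
    training: TrainingConfig = field(default_factory=TrainingConfig)


@dataclass
class ScenarioResult:
    """Per-cell metric sets plus the scenario aggregate.

    ``cells`` is keyed by ``(cell, repeat)`` where cell is a training
    fraction (iterative) or a held-out site id (onboarding); each value maps
    a split name (``holdout``/``validation``/``test``) to a
    :class:`MetricSet` (or None when the split was empty).  ``aggregate``
    maps cell -> split -> metric -> (mean, sd); onboarding additionally
    carries the concept-weighted mean under the cell key ``"weighted"``.
    """

    scenario: str
    cells: dict
    aggregate: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cell, rep), splits in self.cells.items():
            for split, ms in splits.items():
                if ms is None:
                    continue
                for metric, value in ms.as_dict().items():
                    rows.append(
                        {
                            "scenario": self.scenario,
                            "cell": cell,
                            "repeat": rep,
                            "split": split,
                            "metric": metric,
                            "value": value,
                        }
                    )
        return pd.DataFrame(rows)


def _mapped_gold(gold: Sequence[MappingRecord], vocabulary: Vocabulary):
    return [
        r
        for r in gold
        if r.status is MappingStatus.MAPPED and r.target.concept_id in vocabulary
    ]


def _evaluate(backend, records, vocabulary) -> Optional[MetricSet]:
    if not records:
        return None
    ev = rank_sources(
        backend, [r.source for r in records], [r.target for r in records], vocabulary
    )
    return ev.metrics() if len(ev.ranks) else None


def _aggregate_cell(metric_sets: Sequence[Optional[MetricSet]]) -> Optional[dict]:
    present = [m for m in metric_sets if m is not None]
    if not present:
        return None
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in present])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[name] = (float(np.mean(vals)), sd)
    return out


def baseline_scenario(
    gold: Sequence[MappingRecord],
    vocabulary: Vocabulary,
    backend_factory: BackendFactory,
) -> ScenarioResult:
    """Untrained-backend performance on every mapped concept."""
    records = _mapped_gold(gold, vocabulary)
    ms = _evaluate(backend_factory(), records, vocabulary)
    return ScenarioResult(
        scenario="baseline",
        cells={("all", 0): {"test": ms}},
        aggregate={"all": {"test": _aggregate_cell([ms])}},
    )


def _cell_seed(seed: int, fraction: float, repeat: int) -> int:
    ss = np.random.SeedSequence([seed, int(round(fraction * 100)), repeat])
    return int(ss.generate_state(1)[0] % (2**31))


def iterative_scenario(
    gold: Sequence[MappingRecord],
    vocabulary: Vocabulary,
    backend_factory: BackendFactory,
    config: ScenarioConfig = ScenarioConfig(),
) -> ScenarioResult:
    """Hold-out learning curve over increasing training fractions.

    Fraction 0 is the untrained baseline (a single deterministic run);
    every other fraction is repeated ``config.repeats`` times with seeds
    derived from ``(seed, fraction, repeat)``.  At fraction 1.0 the
    validation split is empty and its metrics are absent.
    """
    records = _mapped_gold(gold, vocabulary)
    pool, holdout = holdout_split(
        records, fraction=config.holdout_fraction, seed=config.seed
    )
    cells: dict = {}
    for f in config.fractions:
        repeats = 1 if f == 0.0 else config.repeats
        for rep in range(repeats):
            if f == 0.0:
                backend = backend_factory()
                train_set: list[MappingRecord] = []
                validation = pool
            else:
                rng = np.random.default_rng(_cell_seed(config.seed, f, rep))
                n_train = int(round(f * len(pool)))
                idx = set(rng.choice(len(pool), size=n_train, replace=False).tolist())
                train_set = [r for i, r in enumerate(pool) if i in idx]
                validation = [r for i, r in enumerate(pool) if i not in idx]
                backend = backend_factory()
                if train_set:
                    run_cfg = replace(
                        config.training, seed=_cell_seed(config.seed + 1, f, rep)
                    )
                    train_model(backend, train_set, vocabulary, run_cfg)
            cells[(f, rep)] = {
                "holdout": _evaluate(backend, holdout, vocabulary),
                "validation": _evaluate(backend, validation, vocabulary),
            }
    aggregate = {
        f: {
            split: _aggregate_cell(
                [cells[key][split] for key in cells if key[0] == f]
            )
            for split in ("holdout", "validation")
        }
        for f in config.fractions
    }
    return ScenarioResult(scenario="iterative", cells=cells, aggregate=aggregate)


def onboarding_scenario(
    gold: Sequence[MappingRecord],
    vocabulary: Vocabulary,
    backend_factory: BackendFactory,
    config: ScenarioConfig = ScenarioConfig(),
) -> ScenarioResult:
    """Leave-one-site-out evaluation with concept-weighted aggregation."""
    records = _mapped_gold(gold, vocabulary)
    sites = sorted({r.source.site_id for r in records})
    if len(sites) < 2:
        raise ValueError("onboarding evaluation needs at least two sites")
    cells: dict = {}
    weights: dict[str, int] = {}
    for si, site in enumerate(sites):
        train_set = [r for r in records if r.source.site_id != site]
        test_set = [r for r in records if r.source.site_id == site]
        backend = backend_factory()
        if train_set:
            run_cfg = replace(config.training, seed=_cell_seed(config.seed, 1.0, si))
            train_model(backend, train_set, vocabulary, run_cfg)
        ms = _evaluate(backend, test_set, vocabulary)
        cells[(site, 0)] = {"test": ms}
        weights[site] = ms.n if ms is not None else 0
    aggregate: dict = {
        site: {"test": _aggregate_cell([cells[(site, 0)]["test"]])} for site in sites
    }
    total = sum(weights.values())
    weighted = {}
    for name in METRIC_NAMES:
        value = (
            sum(
                weights[s] * getattr(cells[(s, 0)]["test"], name)
                for s in sites
                if cells[(s, 0)]["test"] is not None
            )
            / total
        )
        weighted[name] = (float(value), math.nan)
    aggregate["weighted"] = {"test": weighted}
    return ScenarioResult(scenario="onboarding", cells=cells, aggregate=aggregate)
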