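"""Repeated-run experiment execution and the statistical layer.

``run_experiment`` realizes one benchmark configuration: per repeat it
splits the dataset (or reuses one split), augments the training side only,
trains the classifier and scores the held-out test side.  Accuracies are
collected in percent over repeats; group comparisons use one-way ANOVA with
Benjamini–Hochberg FDR adjustment across each family of tests and Cohen's d
(pooled SD) for effect size; distributions are summarized as mean, median
and interquartile range (linear-interpolation quantiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import cascade as cascade_mod
from . import generative as generative_mod
from . import model as model_mod
from . import splitting as splitting_mod
from .containers import CLASSES, EpochSet
from .transforms import GENERATIVE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "RunStats",
    "StatsComparison",
    "run_experiment",
    "confusion_matrix",
    "accuracy_from_confusion",
    "one_way_anova",
    "bh_fdr",
    "cohens_d",
    "summarize",
    "compare_to_baseline",
    "run_single_method_benchmark",
    "tidy_results",
    "summary_table",
]


@dataclass
class RunStats:
    """Accuracy samples (%) over repeats plus per-run confusion matrices."""

    accuracies: list[float]
    confusions: list[np.ndarray]
    seeds: list[int]
    n_failed: int = 0
    strategy: str = ""
    augmentation: str = "none"

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def median(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.accuracies, [25, 75])
        return float(q3 - q1)


@dataclass
class StatsComparison:
    name: str
    p_raw: float
    p_adjusted: float
    cohens_d: float
    family: str = ""


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(true_labels: Sequence[str], predicted: Sequence[str],
                     classes: Sequence[str] = CLASSES) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    classes = list(classes)
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted):
        m[classes.index(str(t)), classes.index(str(p))] += 1
    return m


def accuracy_from_confusion(cm: np.ndarray) -> float:
    """Fraction correct = trace / total."""
    total = cm.sum()
    return float(np.trace(cm) / total) if total else 0.0


# ---------------------------------------------------------------------------
# statistics


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Standard between/within variance decomposition; returns (F, p).

    Degenerate input with zero between-group variance (identical group
    means) returns F = 0, p = 1 rather than scipy's NaN warning path.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    means = [float(np.mean(g)) for g in groups]
    if np.ptp(means) == 0.0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def summarize(samples: Sequence[float]) -> dict[str, float]:
    """Mean, median and IQR (linear-interpolation quantiles), in percent."""
    x = np.asarray(samples, dtype=float)
    q1, q3 = np.percentile(x, [25, 75])
    return {"mean": float(x.mean()), "median": float(np.median(x)), "iqr": float(q3 - q1)}


def compare_to_baseline(named_groups: dict[str, Sequence[float]], baseline: str,
                        family: str = "") -> list[StatsComparison]:
    """ANOVA of every group against the baseline, BH-adjusted as one family."""
    if baseline not in named_groups:
        raise ValueError(f"baseline {baseline!r} not among groups")
    base = named_groups[baseline]
    names = [n for n in named_groups if n != baseline]
    raw = []
    ds = []
    for n in names:
        _, p = one_way_anova([named_groups[n], base])
        raw.append(p)
        ds.append(cohens_d(named_groups[n], base))
    adj = bh_fdr(raw)
    return [StatsComparison(n, float(p), float(q), float(d), family)
            for n, p, q, d in zip(names, raw, adj, ds)]


# ---------------------------------------------------------------------------
# experiment execution

#: ``classifier_factory(train_set, seed) -> predict`` where ``predict``
#: maps an EpochSet to an array of label strings.
ClassifierFactory = Callable[[EpochSet, int], Callable[[EpochSet], np.ndarray]]


def _default_factory(model_config: model_mod.EEGNetConfig) -> ClassifierFactory:
    def factory(train_set: EpochSet, seed: int):
        cfg = replace(model_config, seed=seed)
        net = model_mod.build_model(cfg)
        model_mod.train(net, train_set, cfg)

        def predict(epochs: EpochSet) -> np.ndarray:
            return model_mod.predict(net, epochs)[0]

        return predict

    return factory


def _train_generators(train_set: EpochSet, spec: cascade_mod.CascadeSpec,
                      seed: int) -> cascade_mod.CascadeSpec:
    """Inject trained generators into generative stages lacking one."""
    stages = []
    for stage in spec.stages:
        if stage.name in GENERATIVE_NAMES and "generator" not in stage.params:
            cfg = stage.params.get("config") or generative_mod.GenerativeConfig(
                kind={"cvae": "CVAE", "cgan": "CGAN"}[stage.name]
            )
            cfg = replace(cfg, kind={"cvae": "CVAE", "cgan": "CGAN"}[stage.name], seed=seed)
            gen = generative_mod.train_generator(train_set, cfg)
            params = {k: v for k, v in stage.params.items() if k != "config"}
            params["generator"] = gen
            stage = replace(stage, params=params)
        stages.append(stage)
    return replace(spec, stages=stages)


def run_experiment(
    dataset: EpochSet,
    split_strategy: str,
    cascade_spec: cascade_mod.CascadeSpec | None,
    model_config: model_mod.EEGNetConfig | None = None,
    n_repeats: int = 50,
    seed: int = 0,
    train_frac: float = 0.8,
    resplit_each_run: bool = True,
    classifier_factory: ClassifierFactory | None = None,
) -> RunStats:
    """Run one benchmark configuration for ``n_repeats`` repeats.

    Per repeat: split (fresh split per repeat unless ``resplit_each_run``
    is False), augment the training side only, train, and score the test
    side; accuracy is ``correct / total × 100``.  A repeat that raises is
    recorded as failed and excluded with a warning.  Fully seeded.
    """
    if classifier_factory is None:
        classifier_factory = _default_factory(model_config or model_mod.EEGNetConfig())
    root = np.random.SeedSequence([seed, 0xEE])
    repeat_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_repeats)]

    accuracies: list[float] = []
    confusions: list[np.ndarray] = []
    used_seeds: list[int] = []
    n_failed = 0
    fixed_split = None
    for r, rseed in enumerate(repeat_seeds):
        try:
            if resplit_each_run or fixed_split is None:
                sp = splitting_mod.split(dataset, split_strategy, train_frac, seed=rseed if resplit_each_run else seed)
                if not resplit_each_run:
                    fixed_split = sp
            else:
                sp = fixed_split
            train_set = dataset.select(sp.train_idx)
            test_set = dataset.select(sp.test_idx)
            if cascade_spec is not None:
                spec = replace(cascade_spec, seed=rseed)
                spec = _train_generators(train_set, spec, rseed)
                train_set = cascade_mod.augment_training_set(train_set, spec)
            predictor = classifier_factory(train_set, rseed)
            predicted = predictor(test_set)
            cm = confusion_matrix(test_set.labels, predicted)
            accuracies.append(accuracy_from_confusion(cm) * 100.0)
            confusions.append(cm)
            used_seeds.append(rseed)
        except Exception:
            n_failed += 1
            logger.warning("repeat %d failed", r, exc_info=True)
    if n_failed:
        logger.warning("%d of %d repeats failed and were excluded", n_failed, n_repeats)
    if not accuracies:
        raise RuntimeError("every repeat failed")
    return RunStats(
        accuracies=accuracies,
        confusions=confusions,
        seeds=used_seeds,
        n_failed=n_failed,
        strategy=split_strategy,
        augmentation="none" if cascade_spec is None else "+".join(s.name for s in cascade_spec.stages),
    )


# ---------------------------------------------------------------------------
# benchmark driver and tidy outputs


def run_single_method_benchmark(
    dataset: EpochSet,
    method_names: Sequence[str],
    strategies: Sequence[str] = splitting_mod.STRATEGIES,
    ratio: float = 1.0,
    n_repeats: int = 3,
    model_config: model_mod.EEGNetConfig | None = None,
    seed: int = 0,
    generative_config_overrides: dict | None = None,
    classifier_factory: ClassifierFactory | None = None,
) -> dict[tuple[str, str], RunStats]:
    """Baseline plus every named single-stage augmenter under every split.

    Returns ``{(strategy, method): RunStats}`` where method "none" is the
    unaugmented baseline.  ``generative_config_overrides`` maps "cvae"/
    "cgan" to a GenerativeConfig used at this benchmark's scale.
    """
    from .transforms import AugmenterSpec

    results: dict[tuple[str, str], RunStats] = {}
    overrides = generative_config_overrides or {}
    for strategy in strategies:
        for name in ["none", *method_names]:
            if name == "none":
                spec = None
            else:
                params = {}
                if name in overrides:
                    params["config"] = overrides[name]
                spec = cascade_mod.CascadeSpec(stages=[AugmenterSpec(name, params)], ratio=ratio, seed=seed)
            results[(strategy, name)] = run_experiment(
                dataset, strategy, spec, model_config,
                n_repeats=n_repeats, seed=seed, classifier_factory=classifier_factory,
            )
    return results


def tidy_results(results: dict[tuple[str, str], RunStats]) -> pd.DataFrame:
    """One row per repeat: strategy, augmentation, repeat, seed, accuracy (%)."""
    rows = []
    for (strategy, method), rs in results.items():
        for i, (acc, s) in enumerate(zip(rs.accuracies, rs.seeds)):
            rows.append({"strategy": strategy, "augmentation": method,
                         "repeat": i, "seed": s, "accuracy_pct": acc})
    return pd.DataFrame(rows)


def summary_table(results: dict[tuple[str, str], RunStats]) -> pd.DataFrame:
    """Per-strategy summary with mean accuracy and 'Median (IQR)' columns."""
    rows = []
    for (strategy, method), rs in results.items():
        s = summarize(rs.accuracies)
        rows.append({
            "Strategy": strategy,
            "Augmentation": method,
            "Mean Acc. [%]": round(s["mean"], 2),
            "Median (IQR)": f"{s['median']:.2f} ({s['iqr']:.2f})",
        })
    return pd.DataFrame(rows)
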