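"""Hybrid filter–wrapper feature subset selection (FSS).

Three stages, run on the 28-feature table:

1. *Filter* — per-feature Welch two-sample t-test (benign vs. malignant);
   features with p >= alpha are removed.  (A paired test is impossible for
   independent groups of unequal size, so the unpaired unequal-variance
   form is the one implemented.)
2. *Wrapper* — a genetic algorithm searches binary feature-inclusion
   chromosomes; fitness is the cross-validated accuracy of an RBF-kernel
   SVM on the encoded subset.
3. *Ablation* — greedy backward elimination: while the cheapest single-
   feature omission costs no more than ``ablation_epsilon`` CV accuracy,
   drop that feature.

`HybridFeatureSelector` implements the scikit-learn selector protocol
(fit / transform / get_support); `run_hybrid_fss` is the functional
wrapper returning the per-step `SelectionTrace`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "SelectionConfig",
    "SelectionTrace",
    "REFERENCE_CASCADE",
    "cascade_arithmetic",
    "ttest_filter",
    "ga_wrapper_select",
    "ablation_prune",
    "run_hybrid_fss",
    "HybridFeatureSelector",
]


# The published reference cascade this selector mirrors: 28 features in,
# 4 removed by the filter, 11 by the wrapper, 6 by ablation, 7 retained.
# Names are registry-canonical; the source table lists "difference average"
# twice in its wrapper step — the second occurrence is recorded here as
# difference_variance (the one member of the texture group otherwise absent).
REFERENCE_CASCADE: dict[str, tuple[str, ...]] = {
    "removed_step2": ("heterogeneity", "extent", "elongation", "eccentricity"),
    "removed_step3": ("fractal_dimension", "circularity", "spiculation", "area",
                      "correlation", "contrast", "sum_variance", "sum_entropy",
                      "difference_average", "difference_variance",
                      "difference_entropy"),
    "removed_step4": ("compactness", "solidity", "radial_length_entropy",
                      "asm", "sum_average", "info_correlation_2"),
    "final_subset": ("adc", "slope", "ser", "age", "entropy",
                     "inverse_difference", "info_correlation_1"),
}


def cascade_arithmetic(cascade: dict[str, tuple[str, ...]] | None = None) -> dict[str, int]:
    """Step counts and the implied final-subset size of an FSS cascade.

    Verifies the partition property (steps are disjoint and their union is
    the full input set) and returns the count bookkeeping
    n_final = n_input − n_step2 − n_step3 − n_step4.
    """
    cascade = cascade or REFERENCE_CASCADE
    lists = [cascade["removed_step2"], cascade["removed_step3"],
             cascade["removed_step4"], cascade["final_subset"]]
    flat = [name for lst in lists for name in lst]
    if len(flat) != len(set(flat)):
        raise ValueError("cascade steps are not disjoint")
    n_input = len(flat)
    counts = {
        "n_input": n_input,
        "n_removed_step2": len(lists[0]),
        "n_removed_step3": len(lists[1]),
        "n_removed_step4": len(lists[2]),
        "n_final": len(lists[3]),
    }
    assert counts["n_final"] == (n_input - counts["n_removed_step2"]
                                 - counts["n_removed_step3"] - counts["n_removed_step4"])
    counts["n_after_step2"] = n_input - counts["n_removed_step2"]
    counts["n_after_step3"] = counts["n_after_step2"] - counts["n_removed_step3"]
    return counts


@dataclass
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    elitism_count: int = 2
    tournament_size: int = 3
    fitness_cv_folds: int = 5
    seed: int = 0


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    ga: GAConfig = field(default_factory=GAConfig)
    ablation_epsilon: float = 0.005  # max tolerated absolute accuracy drop

    def validate(self) -> list[str]:
        errs = []
        if not (0.0 < self.alpha < 1.0):
            errs.append("alpha must lie in (0, 1)")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self.ga, name)
            if not (0.0 <= v <= 1.0):
                errs.append(f"ga.{name} must lie in [0, 1]")
        if self.ga.population_size < 2:
            errs.append("ga.population_size must be >= 2")
        if self.ga.generations < 1:
            errs.append("ga.generations must be >= 1")
        if self.ga.fitness_cv_folds < 2:
            errs.append("ga.fitness_cv_folds must be >= 2")
        return errs


@dataclass
class SelectionTrace:
    removed_step2: list[str]
    removed_step3: list[str]
    removed_step4: list[str]
    final_subset: list[str]
    p_values: pd.Series
    fitness_history: list[float]
    ablation_report: list[dict]

    def as_dict(self) -> dict:
        return {
            "removed_step2": list(self.removed_step2),
            "removed_step3": list(self.removed_step3),
            "removed_step4": list(self.removed_step4),
            "final_subset": list(self.final_subset),
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "fitness_history": [float(v) for v in self.fitness_history],
            "ablation_report": self.ablation_report,
        }

    def check_partition(self, input_names: list[str]) -> None:
        parts = (self.removed_step2 + self.removed_step3
                 + self.removed_step4 + self.final_subset)
        if sorted(parts) != sorted(input_names) or len(parts) != len(set(parts)):
            raise AssertionError("selection trace does not partition the input features")


# ---------------------------------------------------------------------------
# step 2: t-test filter
# ---------------------------------------------------------------------------


def ttest_filter(table: pd.DataFrame, labels: pd.Series | np.ndarray,
                 alpha: float = 0.05) -> tuple[list[str], pd.Series]:
    """Welch t-test filter: keep features with p < alpha.

    Returns (surviving feature names in table order, p-values for all
    features).  Constant features in both groups get p = 1 and are removed.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    g0 = table.loc[y == classes[0]]
    g1 = table.loc[y == classes[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("both classes need >= 2 samples")
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise ValueError("feature table contains non-finite values")
    pvals = {}
    for name in table.columns:
        a, b = g0[name].to_numpy(float), g1[name].to_numpy(float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            pvals[name] = 1.0 if a.mean() == b.mean() else 0.0
            continue
        pvals[name] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    p = pd.Series(pvals)
    surviving = [name for name in table.columns if p[name] < alpha]
    return surviving, p


# ---------------------------------------------------------------------------
# wrapper SVM fitness
# ---------------------------------------------------------------------------


def _wrapper_model() -> object:
    # fixed RBF hyperparameters: tuning inside every GA fitness evaluation
    # would multiply cost without changing subset ranking at these n
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale"))


def _subset_fitness(X: np.ndarray, y: np.ndarray, chromosome: np.ndarray,
                    cv_folds: int, seed: int, cache: dict) -> float:
    key = chromosome.tobytes()
    if key in cache:
        return cache[key]
    if not chromosome.any():
        cache[key] = 0.0
        return 0.0
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    score = float(cross_val_score(_wrapper_model(), X[:, chromosome], y,
                                  cv=cv, scoring="accuracy").mean())
    cache[key] = score
    return score


# ---------------------------------------------------------------------------
# step 3: GA wrapper
# ---------------------------------------------------------------------------


def ga_wrapper_select(table: pd.DataFrame, labels, config: GAConfig | None = None,
                      return_history: bool = False):
    """Genetic-algorithm wrapper subset search over the surviving features.

    Binary inclusion chromosomes; fitness = mean ``fitness_cv_folds``-fold
    CV accuracy of the wrapper SVM; tournament selection, uniform crossover,
    per-bit mutation, elitism.  The initial population contains every
    singleton (so the result can never underperform the best single
    feature) plus random chromosomes.  Fully deterministic for a fixed
    seed.
    """
    config = config or GAConfig()
    names = list(table.columns)
    p = len(names)
    if p < 2:
        raise ValueError("need >= 2 surviving features for the wrapper")
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(config.seed)
    cache: dict = {}

    pop_size = max(config.population_size, min(p, config.population_size))
    population = np.zeros((pop_size, p), dtype=bool)
    for i in range(min(p, pop_size)):
        population[i, i] = True
    if pop_size > p:
        population[p:] = rng.random((pop_size - p, p)) < 0.5
    for i in range(pop_size):
        if not population[i].any():
            population[i, rng.integers(p)] = True

    def fitness(ch: np.ndarray) -> float:
        return _subset_fitness(X, y, ch, config.fitness_cv_folds, config.seed, cache)

    history: list[float] = []
    scores = np.array([fitness(ch) for ch in population])
    for _ in range(config.generations):
        order = np.argsort(-scores, kind="stable")
        elite = population[order[:config.elitism_count]].copy()
        children = [e for e in elite]
        while len(children) < pop_size:
            idx = rng.integers(0, pop_size, size=(2, config.tournament_size))
            pa = population[idx[0][np.argmax(scores[idx[0]])]].copy()
            pb = population[idx[1][np.argmax(scores[idx[1]])]].copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(p) < 0.5
                pa[swap], pb[swap] = pb[swap], pa[swap].copy()
            for child in (pa, pb):
                flip = rng.random(p) < config.mutation_rate
                child[flip] = ~child[flip]
                if len(children) < pop_size:
                    children.append(child)
        population = np.array(children)
        if not population.any():
            logger.warning("GA population collapsed to all-zero; reseeding singletons")
            for i in range(pop_size):
                population[i, i % p] = True
        scores = np.array([fitness(ch) for ch in population])
        history.append(float(scores.max()))

    best = population[int(np.argmax(scores))]
    subset = [names[i] for i in range(p) if best[i]]
    logger.info("GA wrapper: %d fitness evaluations, best=%.4f, |subset|=%d",
                len(cache), max(history) if history else float(scores.max()), len(subset))
    if return_history:
        return subset, history
    return subset


# ---------------------------------------------------------------------------
# step 4: ablation pruning
# ---------------------------------------------------------------------------


def ablation_prune(table: pd.DataFrame, labels, subset: list[str],
                   config: SelectionConfig | None = None,
                   p_values: pd.Series | None = None):
    """Greedy backward elimination of negligible-contribution features.

    Repeatedly evaluate the CV accuracy of the current subset with each
    feature omitted; if the *least* costly omission loses no more than
    ``ablation_epsilon`` accuracy, remove that feature and repeat.  Ties
    are broken toward the feature with the larger filter p-value (the one
    with weaker univariate evidence).  Never returns an empty subset.
    """
    config = config or SelectionConfig()
    if not subset:
        raise ValueError("subset must be non-empty")
    y = np.asarray(labels)
    current = list(subset)
    cache: dict = {}
    names_all = list(table.columns)
    X = table.to_numpy(dtype=float)

    def score(feats: list[str]) -> float:
        ch = np.array([n in feats for n in names_all])
        return _subset_fitness(X, y, ch, config.ga.fitness_cv_folds,
                               config.ga.seed, cache)

    report: list[dict] = []
    while len(current) > 1:
        base = score(current)
        deltas = []
        for name in current:
            omitted = [n for n in current if n != name]
            deltas.append((base - score(omitted), name))
        min_delta = min(d for d, _ in deltas)
        if min_delta > config.ablation_epsilon:
            report.append({"kept": list(current), "base_accuracy": base,
                           "deltas": {n: float(d) for d, n in deltas}})
            break
        candidates = [n for d, n in deltas if d == min_delta]
        if p_values is not None and len(candidates) > 1:
            candidates.sort(key=lambda n: -float(p_values.get(n, 0.0)))
        removed = candidates[0]
        report.append({"removed": removed, "delta": float(min_delta),
                       "base_accuracy": base})
        current = [n for n in current if n != removed]
    return current, report


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------


class HybridFeatureSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector running the full filter → GA → ablation cascade.

    Parameters
    ----------
    alpha : float
        Filter significance level (Welch t-test), default 0.05.
    ga : GAConfig or None
        Genetic-algorithm hyperparameters; defaults to the full-size search
        (population 50, 100 generations, 5-fold fitness CV).
    ablation_epsilon : float
        Maximum tolerated CV-accuracy drop for an omission to count as
        negligible.

    Attributes
    ----------
    support_ : bool ndarray over input columns
    trace_ : SelectionTrace with per-step removals, p-values, fitness history
    feature_names_in_ : input column names
    """

    def __init__(self, alpha: float = 0.05, ga: GAConfig | None = None,
                 ablation_epsilon: float = 0.005):
        self.alpha = alpha
        self.ga = ga
        self.ablation_epsilon = ablation_epsilon

    def _config(self) -> SelectionConfig:
        cfg = SelectionConfig(alpha=self.alpha, ga=self.ga or GAConfig(),
                              ablation_epsilon=self.ablation_epsilon)
        errs = cfg.validate()
        if errs:
            raise ValueError("invalid SelectionConfig: " + "; ".join(errs))
        return cfg

    def fit(self, X, y):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            table = X.copy()
        else:
            table = pd.DataFrame(np.asarray(X, float),
                                 columns=[f"x{i}" for i in range(np.shape(X)[1])])
        names = list(table.columns)
        y = np.asarray(y)

        surviving, pvals = ttest_filter(table, y, cfg.alpha)
        removed2 = [n for n in names if n not in surviving]
        logger.info("filter: %d -> %d features", len(names), len(surviving))

        if len(surviving) < 2:
            # nothing for the wrapper to search; pass the survivors through
            subset3, history = list(surviving), []
        else:
            subset3, history = ga_wrapper_select(table[surviving], y, cfg.ga,
                                                 return_history=True)
        removed3 = [n for n in surviving if n not in subset3]

        if subset3:
            final, report = ablation_prune(table, y, subset3, cfg, pvals)
        else:
            final, report = [], []
        removed4 = [n for n in subset3 if n not in final]

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.support_ = np.array([n in final for n in names])
        self.trace_ = SelectionTrace(
            removed_step2=removed2, removed_step3=removed3,
            removed_step4=removed4, final_subset=final,
            p_values=pvals, fitness_history=history, ablation_report=report)
        self.trace_.check_partition(names)
        return self

    def _get_support_mask(self):
        return self.support_

    def _more_tags(self):
        return {"requires_y": True, "allow_nan": False}


def run_hybrid_fss(table: pd.DataFrame, labels,
                   config: SelectionConfig | None = None) -> SelectionTrace:
    """Run the full hybrid FSS cascade and return its per-step trace."""
    config = config or SelectionConfig()
    selector = HybridFeatureSelector(alpha=config.alpha, ga=config.ga,
                                     ablation_epsilon=config.ablation_epsilon)
    selector.fit(table, labels)
    return selector.trace_
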