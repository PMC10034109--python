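"""Feature screening and genetic-algorithm wrapper selection.

The screen is a per-feature one-way ANOVA between responders and
non-responders.  The wrapper is a plain binary-mask GA - tournament
selection, uniform crossover, bit-flip mutation - whose fitness is the mean
stratified inner-CV accuracy of a classifier on the masked features, softly
penalized toward a target cardinality (12 features by default, matching the
reported selection size).  When the wrapper is disabled, the fallback
cardinality is floor(sqrt(n_features)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable


@dataclass(frozen=True)
class GAConfig:
    population: int = 50
    generations: int = 100
    crossover_p: float = 0.8
    mutation_p: float = 0.02
    target_k: int = 12
    inner_folds: int = 3
    tournament: int = 3
    cardinality_penalty: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_p, self.mutation_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.target_k < 1:
            raise ValueError("target_k must be >= 1")


@dataclass
class ScreenResult:
    table: pd.DataFrame  # index: feature; columns: F, p, keep

    @property
    def keep_mask(self) -> pd.Series:
        return self.table["keep"]

    def kept_features(self) -> list[str]:
        return list(self.table.index[self.table["keep"]])


def anova_screen(table: FeatureTable, alpha: float = 0.05) -> ScreenResult:
    """One-way ANOVA of every feature between the R and NR groups."""
    groups = table.groups
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError("screen expects exactly two groups")
    if min((groups == g).sum() for g in names) < 3:
        raise ValueError("need at least 3 subjects per group")
    rows = {}
    for col in table.features.columns:
        a = table.features.loc[groups == names[0], col].to_numpy()
        b = table.features.loc[groups == names[1], col].to_numpy()
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            warnings.warn(f"zero-variance feature {col!r}; excluded from keep mask", RuntimeWarning)
            rows[col] = (0.0, 1.0)
            continue
        F, p = stats.f_oneway(a, b)
        rows[col] = (float(F), float(p))
    df = pd.DataFrame(rows, index=["F", "p"]).T
    df["keep"] = df["p"] < alpha
    return ScreenResult(table=df)


def sqrt_rule(n_features: int) -> int:
    """Fallback feature count: floor of the square root of the total."""
    return max(int(math.isqrt(n_features)), 1)


def _inner_cv_accuracy(
    X: np.ndarray, y: np.ndarray, mask: np.ndarray, clf_factory, folds: int, rng_seed: int
) -> float:
    from sklearn.model_selection import StratifiedKFold

    Xm = X[:, mask]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    acc = 0.0
    for tr, te in skf.split(Xm, y):
        mu = Xm[tr].mean(axis=0)
        sd = Xm[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = clf_factory()
        clf.fit((Xm[tr] - mu) / sd, y[tr])
        acc += float((clf.predict((Xm[te] - mu) / sd) == y[te]).mean())
    return acc / folds


def ga_select(
    table: FeatureTable,
    cfg: GAConfig | None = None,
    clf_spec=None,
    return_history: bool = False,
):
    """GA wrapper selection; returns exactly ``target_k`` feature names.

    Fitness of a mask = mean stratified inner-CV accuracy of ``clf_spec``
    (default: the RBF-SVM used for the headline classification) on the
    masked, z-scored features, minus ``cardinality_penalty * |k - target_k|``.
    Deterministic for a fixed config seed.  If the best mask is not exactly
    the target size it is trimmed/extended by the per-feature ANOVA F rank.
    """
    from .classify import ClassifierSpec, make_estimator

    cfg = cfg or GAConfig()
    spec = clf_spec or ClassifierSpec(kind="svm", svm_kernel="rbf", sigma=0.7)
    X = table.features.to_numpy(dtype=float)
    y = (table.groups == "R").to_numpy().astype(int)
    n_feat = X.shape[1]
    if cfg.target_k > n_feat:
        raise ValueError("target_k exceeds the number of available features")
    rng = np.random.default_rng(cfg.seed)

    def factory():
        return make_estimator(spec, seed=cfg.seed)

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        if not mask.any():
            return 0.0
        key = mask.tobytes()
        if key not in cache:
            acc = _inner_cv_accuracy(X, y, mask, factory, cfg.inner_folds, cfg.seed)
            cache[key] = acc - cfg.cardinality_penalty * abs(int(mask.sum()) - cfg.target_k)
        return cache[key]

    # init: biased Bernoulli so typical cardinality starts near target_k
    p_on = min(max(cfg.target_k / n_feat, 0.02), 0.5)
    pop = rng.random((cfg.population, n_feat)) < p_on
    for i in range(cfg.population):
        if not pop[i].any():
            pop[i, rng.integers(n_feat)] = True
    fits = np.array([fitness(m) for m in pop])
    history = [float(fits.max())]

    for _ in range(cfg.generations):
        elite = pop[int(np.argmax(fits))].copy()
        new = [elite]
        while len(new) < cfg.population:
            # tournament pick of two parents
            parents = []
            for _ in range(2):
                idx = rng.integers(0, cfg.population, cfg.tournament)
                parents.append(pop[idx[np.argmax(fits[idx])]])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < cfg.crossover_p:
                swap = rng.random(n_feat) < 0.5
                a[swap], b[swap] = b[swap], a[swap]
            for child in (a, b):
                flip = rng.random(n_feat) < cfg.mutation_p
                child[flip] = ~child[flip]
                if not child.any():
                    child[rng.integers(n_feat)] = True
                new.append(child)
        pop = np.array(new[: cfg.population])
        fits = np.array([fitness(m) for m in pop])
        history.append(float(fits.max()))

    best = pop[int(np.argmax(fits))]
    names = _coerce_cardinality(table, best, cfg.target_k)
    if return_history:
        return names, history
    return names


def _coerce_cardinality(table: FeatureTable, mask: np.ndarray, k: int) -> list[str]:
    cols = np.array(table.features.columns)
    screen = anova_screen(table, alpha=1.1).table  # F scores only, no filtering
    F = screen["F"].reindex(cols).to_numpy()
    active = list(cols[mask])
    if len(active) > k:
        active.sort(key=lambda c: -screen.loc[c, "F"])
        active = active[:k]
    elif len(active) < k:
        inactive = [c for c in cols[np.argsort(-F)] if c not in active]
        active += inactive[: k - len(active)]
    return [c for c in cols if c in set(active)]


@dataclass
class SelectionReport:
    selected: list[str]
    best_fitness_per_generation: list[float]
    anova: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "best_fitness_per_generation": self.best_fitness_per_generation,
            "anova": self.anova.reset_index().rename(columns={"index": "feature"}).to_dict("records"),
        }


def select_with_report(table: FeatureTable, cfg: GAConfig | None = None, clf_spec=None) -> SelectionReport:
    names, history = ga_select(table, cfg, clf_spec, return_history=True)
    return SelectionReport(
        selected=names,
        best_fitness_per_generation=history,
        anova=anova_screen(table).table,
    )
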