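"""Descriptor-matrix assembly, GA feature selection and validation stats.

The descriptor matrix stacks three named blocks — pharmacophore fit
values, binary contact fingerprints, physicochemical descriptors — with
log(1/IC50) as the response.  A genetic algorithm searches descriptor
subsets for a pluggable regressor (MLR / nu-SVR / RF / plugin), scored by
leave-20%-out q2 on the training split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "GASettings",
    "RegressorSpec",
    "ValidationReport",
    "assemble_matrix",
    "split_train_test",
    "fit_regressor",
    "mlr_equation_eval",
    "load_reference_mlr_equation",
    "cv_r2",
    "r_press",
    "gfa_select",
    "validate_model",
]


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors with ordered named blocks and activities."""

    values: pd.DataFrame  # index: compound_id
    blocks: List[Tuple[str, List[str]]]
    activity: pd.Series  # log(1/IC50), aligned with values.index

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("descriptor matrix contains missing values")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if not self.values.index.equals(self.activity.index):
            raise ValueError("activity index does not match matrix rows")

    @property
    def compound_ids(self) -> List[str]:
        return list(self.values.index)

    def subset(self, columns: Sequence[str]) -> pd.DataFrame:
        return self.values[list(columns)]


@dataclass(frozen=True)
class GASettings:
    population_size: int = 200
    max_generations: int = 1000
    survivor_fraction: float = 0.40
    tournament_size: int = 2
    elitism_rate: float = 0.10
    crossover_rate: float = 0.60
    mutation_rate: float = 0.01
    seed: int = 0
    min_features: int = 3
    max_features: int = 10
    patience: Optional[int] = None  # generations without improvement before stop

    def __post_init__(self) -> None:
        for name in ("survivor_fraction", "elitism_rate", "crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 1 <= self.min_features <= self.max_features:
            raise ValueError("need 1 <= min_features <= max_features")


@dataclass(frozen=True)
class SVRSettings:
    nu: float = 0.664
    gamma: float = 0.0  # 0 -> LibSVM auto convention, 1/n_features
    epsilon_termination: float = 0.001
    cache: float = 40.0
    loss: float = 0.1  # recorded but inert under nu-SVR

    def __post_init__(self) -> None:
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must be in (0, 1]")


@dataclass(frozen=True)
class RegressorSpec:
    method: str = "MLR"  # MLR | SVR | RF | plugin
    svr: SVRSettings = field(default_factory=SVRSettings)
    rf_trees: int = 100
    seed: int = 0
    plugin_factory: Optional[Callable[[], object]] = None


@dataclass
class ValidationReport:
    r2_resub: float
    r2_loo: float
    r2_l20: float
    r2_press: float
    SD: float
    PRESS: float
    selected_descriptors: List[str]


# ---------------------------------------------------------------------------
# assembly and splitting


def _as_indexed(table: pd.DataFrame) -> pd.DataFrame:
    if "compound_id" in table.columns:
        table = table.set_index("compound_id")
    return table


def assemble_matrix(
    fit_table: pd.DataFrame,
    lrcf_table: pd.DataFrame,
    physchem_table: pd.DataFrame,
    activities: pd.Series,
) -> DescriptorMatrix:
    """Stack fit | LRCF | physchem blocks row-aligned by compound id."""
    tables = {
        "fits": _as_indexed(fit_table),
        "lrcf": _as_indexed(lrcf_table),
        "physchem": _as_indexed(physchem_table),
    }
    ref_ids = set(tables["fits"].index)
    offenders = []
    for name, tab in tables.items():
        diff = ref_ids.symmetric_difference(tab.index)
        if diff:
            offenders.append(f"{name}: {sorted(diff)}")
    act = activities if isinstance(activities, pd.Series) else pd.Series(activities)
    diff = ref_ids.symmetric_difference(act.index)
    if diff:
        offenders.append(f"activities: {sorted(diff)}")
    if offenders:
        raise ValueError("compound id mismatch across blocks — " + "; ".join(offenders))
    order = list(tables["fits"].index)
    parts = [tables[name].loc[order] for name in ("fits", "lrcf", "physchem")]
    values = pd.concat(parts, axis=1).astype(float)
    values.index.name = "compound_id"
    blocks = [
        (name, list(tables[name].columns)) for name in ("fits", "lrcf", "physchem")
    ]
    return DescriptorMatrix(values, blocks, act.loc[order].astype(float))


def split_train_test(matrix: DescriptorMatrix) -> Tuple[List[str], List[str]]:
    """Rank by potency (lowest IC50 = highest activity first) and send every
    fifth compound, starting at the top, into the test set."""
    act = matrix.activity
    order = sorted(
        act.index, key=lambda cid: (-act[cid], cid)
    )  # most potent first; ties by compound id
    test = [order[i] for i in range(0, len(order), 5)]
    test_set = set(test)
    train = [cid for cid in order if cid not in test_set]
    return train, test


# ---------------------------------------------------------------------------
# regressors


class _ZScoredModel:
    """Wraps an estimator with train-set z-scoring (stored with the model)."""

    def __init__(self, estimator, mean: np.ndarray, scale: np.ndarray):
        self._est = estimator
        self._mean = mean
        self._scale = scale

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._est.predict((X - self._mean) / self._scale)


def fit_regressor(X, y, spec: RegressorSpec = RegressorSpec()):
    """Fit the requested regressor; returns an object supporting predict."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if spec.method == "MLR":
        if X.shape[0] < X.shape[1] + 1:
            raise ValueError(
                f"MLR needs more samples ({X.shape[0]}) than descriptors "
                f"({X.shape[1]}); select fewer descriptors"
            )
        design = np.column_stack([np.ones(X.shape[0]), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "singular MLR design matrix; select fewer or less collinear descriptors"
            )
        from sklearn.linear_model import LinearRegression

        model = LinearRegression()
        model.fit(X, y)
        return model
    if spec.method == "SVR":
        from sklearn.svm import NuSVR

        gamma = spec.svr.gamma if spec.svr.gamma > 0 else "auto"
        est = NuSVR(
            nu=spec.svr.nu,
            kernel="rbf",
            gamma=gamma,
            tol=spec.svr.epsilon_termination,
            cache_size=spec.svr.cache,
        )
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        est.fit((X - mean) / scale, y)
        return _ZScoredModel(est, mean, scale)
    if spec.method == "RF":
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(
            n_estimators=spec.rf_trees, random_state=spec.seed
        )
        model.fit(X, y)
        return model
    if spec.method == "plugin":
        if spec.plugin_factory is None:
            raise ValueError("plugin method requires a plugin_factory")
        model = spec.plugin_factory()
        model.fit(X, y)
        return model
    raise ValueError(f"unknown regression method {spec.method!r}")


def mlr_equation_eval(
    coefficients: Mapping[str, float],
    intercept: float,
    descriptor_values: Mapping[str, float],
) -> float:
    """Evaluate a named linear equation; every coefficient must find its
    descriptor."""
    total = intercept
    for name, coef in coefficients.items():
        if name not in descriptor_values:
            raise KeyError(f"descriptor {name!r} missing from supplied values")
        total += coef * descriptor_values[name]
    return total


def load_reference_mlr_equation() -> Tuple[Dict[str, float], float]:
    """Bundled reference GFA-MLR equation: (coefficients, intercept)."""
    import json
    from importlib.resources import files

    payload = json.loads(
        (files("phoreqsar.data") / "gfa_mlr_reference.json").read_text()
    )
    return dict(payload["coefficients"]), float(payload["intercept"])


# ---------------------------------------------------------------------------
# validation statistics


def _stripe_folds(y: np.ndarray, n_folds: int) -> List[np.ndarray]:
    """Disjoint folds by rank-striping on y (descending; ties by index)."""
    order = sorted(range(len(y)), key=lambda i: (-y[i], i))
    folds = [[] for _ in range(n_folds)]
    for rank, idx in enumerate(order):
        folds[rank % n_folds].append(idx)
    return [np.array(f, dtype=int) for f in folds]


def cv_r2(X, y, spec: RegressorSpec = RegressorSpec(), scheme: str = "LOO") -> float:
    """Pooled cross-validated q2 = 1 - PRESS / SS_tot(full y).

    LOO uses n folds; L20 uses 5 disjoint folds striped by activity rank,
    so the partition is deterministic and activity-stratified.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 5:
        raise ValueError("cross-validation needs at least 5 samples")
    if scheme == "LOO":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "L20":
        folds = _stripe_folds(y, 5)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    press = 0.0
    for held in folds:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        model = fit_regressor(X[mask], y[mask], spec)
        pred = model.predict(X[held])
        press += float(np.sum((pred - y[held]) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y")
    return 1.0 - press / ss_tot


def r_press(y_test, y_pred, train_mean: float) -> float:
    """(SD - PRESS) / SD with SD referenced to the training-set mean."""
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_test.shape != y_pred.shape or y_test.size < 1:
        raise ValueError("y_test and y_pred must be equal-length and non-empty")
    sd = float(np.sum((y_test - train_mean) ** 2))
    if sd == 0:
        raise ValueError("SD is zero: test activities all equal the training mean")
    press = float(np.sum((y_test - y_pred) ** 2))
    return (sd - press) / sd


# ---------------------------------------------------------------------------
# genetic feature selection


def _repair(mask: np.ndarray, rng: np.random.Generator, lo: int, hi: int) -> np.ndarray:
    mask = mask.copy()
    on = np.flatnonzero(mask)
    off = np.flatnonzero(~mask)
    if on.size > hi:
        drop = rng.choice(on, size=on.size - hi, replace=False)
        mask[drop] = False
    elif on.size < lo:
        add = rng.choice(off, size=lo - on.size, replace=False)
        mask[add] = True
    return mask


def gfa_select(
    matrix: DescriptorMatrix,
    spec: RegressorSpec = RegressorSpec(),
    ga: GASettings = GASettings(),
    fitness: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
) -> Tuple[List[str], object, List[Tuple[int, float, float]]]:
    """GA search over descriptor subsets on (already train-split) data.

    Chromosomes are column masks repaired into [min_features, max_features].
    Fitness defaults to leave-20%-out q2 under ``spec``; ties prefer fewer
    descriptors.  Returns (best subset, fitted model, trace of
    (generation, best fitness, mean fitness)).  Deterministic given the GA
    seed.
    """
    columns = list(matrix.values.columns)
    n_cols = len(columns)
    if ga.max_features > n_cols:
        raise ValueError(
            f"max_features={ga.max_features} exceeds column count {n_cols}"
        )
    X_full = matrix.values.to_numpy(dtype=float)
    y = matrix.activity.to_numpy(dtype=float)
    rng = np.random.default_rng(ga.seed)

    if fitness is None:
        def fitness(Xs: np.ndarray, ys: np.ndarray) -> float:
            try:
                return cv_r2(Xs, ys, spec, scheme="L20")
            except ValueError:
                return -math.inf

    cache: Dict[bytes, float] = {}

    def evaluate(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = fitness(X_full[:, mask], y)
        return cache[key]

    def sort_key(item):
        mask, score = item
        return (-score, int(mask.sum()), mask.tobytes())

    population = []
    for _ in range(ga.population_size):
        k = int(rng.integers(ga.min_features, ga.max_features + 1))
        mask = np.zeros(n_cols, dtype=bool)
        mask[rng.choice(n_cols, size=k, replace=False)] = True
        population.append(mask)

    n_elite = max(1, int(round(ga.elitism_rate * ga.population_size)))
    n_survive = max(2, int(round(ga.survivor_fraction * ga.population_size)))
    trace: List[Tuple[int, float, float]] = []
    best_mask: Optional[np.ndarray] = None
    best_score = -math.inf
    stall = 0

    for gen in range(ga.max_generations):
        scored = [(m, evaluate(m)) for m in population]
        scored.sort(key=sort_key)
        gen_best = scored[0][1]
        gen_mean = float(np.mean([s for _, s in scored]))
        if gen_best > best_score + 1e-9 or (
            best_mask is None
        ) or (
            abs(gen_best - best_score) <= 1e-9
            and scored[0][0].sum() < best_mask.sum()
        ):
            if gen_best > best_score + 1e-9:
                stall = 0
            best_mask = scored[0][0].copy()
            best_score = max(best_score, gen_best)
        else:
            stall += 1
        trace.append((gen, best_score, gen_mean))
        if ga.patience is not None and stall >= ga.patience:
            break
        if gen == ga.max_generations - 1:
            break

        survivors = [m for m, _ in scored[:n_survive]]
        next_pop = [m.copy() for m, _ in scored[:n_elite]]

        def tournament() -> np.ndarray:
            picks = rng.integers(0, len(survivors), size=ga.tournament_size)
            contenders = [(survivors[i], evaluate(survivors[i])) for i in picks]
            contenders.sort(key=sort_key)
            return contenders[0][0]

        while len(next_pop) < ga.population_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < ga.crossover_rate:
                take = rng.random(n_cols) < 0.5
                child = np.where(take, p1, p2)
            else:
                child = p1.copy()
            flips = rng.random(n_cols) < ga.mutation_rate
            child = np.logical_xor(child, flips)
            child = _repair(child, rng, ga.min_features, ga.max_features)
            next_pop.append(child)
        population = next_pop

    assert best_mask is not None
    if not math.isfinite(best_score):
        raise ValueError(
            "no feasible descriptor subset: every evaluated chromosome failed "
            "fitness evaluation (likely collinear or constant descriptors)"
        )
    subset = [columns[i] for i in np.flatnonzero(best_mask)]
    model = fit_regressor(X_full[:, best_mask], y, spec)
    return subset, model, trace


def validate_model(
    matrix: DescriptorMatrix,
    split: Tuple[Sequence[str], Sequence[str]],
    subset: Sequence[str],
    spec: RegressorSpec = RegressorSpec(),
) -> ValidationReport:
    """Resubstitution r2, LOO/L20 q2 on the train split and predictive r2
    on the test split (train-mean referenced)."""
    if not subset:
        raise ValueError("empty descriptor subset")
    missing = [c for c in subset if c not in matrix.values.columns]
    if missing:
        raise ValueError(f"subset columns not in matrix: {missing}")
    train_ids, test_ids = split
    X_train = matrix.values.loc[list(train_ids), list(subset)].to_numpy(dtype=float)
    y_train = matrix.activity.loc[list(train_ids)].to_numpy(dtype=float)
    X_test = matrix.values.loc[list(test_ids), list(subset)].to_numpy(dtype=float)
    y_test = matrix.activity.loc[list(test_ids)].to_numpy(dtype=float)

    from sklearn.metrics import r2_score

    model = fit_regressor(X_train, y_train, spec)
    r2_resub = float(r2_score(y_train, model.predict(X_train)))
    r2_loo = cv_r2(X_train, y_train, spec, scheme="LOO")
    r2_l20 = cv_r2(X_train, y_train, spec, scheme="L20")
    train_mean = float(y_train.mean())
    y_pred = np.asarray(model.predict(X_test), dtype=float)
    sd = float(np.sum((y_test - train_mean) ** 2))
    press = float(np.sum((y_test - y_pred) ** 2))
    r2p = r_press(y_test, y_pred, train_mean)
    return ValidationReport(
        r2_resub=r2_resub,
        r2_loo=r2_loo,
        r2_l20=r2_l20,
        r2_press=r2p,
        SD=sd,
        PRESS=press,
        selected_descriptors=list(subset),
    )
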