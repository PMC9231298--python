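"""Descriptor pruning, data splitting and GA-MLR model selection.

Model building follows the classical GA-MLR recipe: prune redundant
descriptors (near-constant columns and highly inter-correlated pairs),
split the data randomly into training and external sets, then search
fixed-size descriptor subsets with a genetic algorithm whose fitness is
the leave-one-out cross-validated determination coefficient Q2_LOO.
Model size is chosen by the "breaking point": the size beyond which an
additional descriptor no longer improves Q2_LOO by more than a small
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ordinary least squares + leave-one-out machinery
# ---------------------------------------------------------------------------

@dataclass
class LinearModel:
    """A fitted multi-linear regression on named descriptors."""

    descriptor_names: list[str]
    coefficients: np.ndarray  # shape (p,)
    intercept: float
    coefficient_se: np.ndarray  # shape (p + 1,): intercept SE first
    n_training: int
    metadata: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.descriptor_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    def as_dict(self) -> dict:
        return {
            "descriptor_names": self.descriptor_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "coefficient_se": self.coefficient_se.tolist(),
            "n_training": self.n_training,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            descriptor_names=list(d["descriptor_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            coefficient_se=np.asarray(d["coefficient_se"], dtype=float),
            n_training=int(d["n_training"]),
            metadata=dict(d.get("metadata", {})),
        )


def _design(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{i}" for i in range(arr.shape[1])]
    return np.column_stack([np.ones(len(arr)), arr]), names


def fit_mlr(X: pd.DataFrame | np.ndarray, y: Sequence[float]) -> LinearModel:
    """Ordinary least squares with intercept and coefficient standard errors."""
    design, names = _design(X)
    y = np.asarray(y, dtype=float)
    n, p1 = design.shape
    p = p1 - 1
    if n <= p + 1:
        raise ModelError(f"need n > p + 1 (n={n}, p={p})")
    rank = np.linalg.matrix_rank(design)
    if rank < p1:
        # identify offending columns via QR pivoting on the descriptors
        _, r = np.linalg.qr(design)
        bad = [names[j - 1] for j in range(1, p1) if abs(r[j, j]) < 1e-10 * abs(r[0, 0])]
        raise ModelError(f"design matrix is rank deficient (collinear: {bad or 'intercept'})")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ beta
    rss = float(residuals @ residuals)
    sigma2 = rss / (n - p - 1)
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    return LinearModel(
        descriptor_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        coefficient_se=se,
        n_training=n,
    )


def hat_diagonal(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Leverages h_ii of the hat matrix for the design with intercept."""
    design, _ = _design(X)
    q, _ = np.linalg.qr(design)
    return np.einsum("ij,ij->i", q, q)


def loo_predictions(X: pd.DataFrame | np.ndarray, y: Sequence[float]) -> np.ndarray:
    """Closed-form leave-one-out predictions from one OLS fit.

    Uses the identity ``e_i^loo = e_i / (1 - h_ii)``; errors on
    degenerate leverage (h_ii -> 1), where the closed form blows up.
    """
    design, _ = _design(X)
    y = np.asarray(y, dtype=float)
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    h = hat_diagonal(X)
    if np.any(h >= 1.0 - 1e-12):
        raise ModelError("degenerate leverage h_ii = 1; LOO residual undefined")
    return y - (y - fitted) / (1.0 - h)


def q2_loo(X: pd.DataFrame | np.ndarray, y: Sequence[float]) -> float:
    """Leave-one-out cross-validated determination coefficient.

    ``1 - PRESS/TSS`` with PRESS from closed-form LOO residuals and TSS
    about the training mean.
    """
    y = np.asarray(y, dtype=float)
    pred = loo_predictions(X, y)
    press = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ModelError("zero variance in y")
    return 1.0 - press / tss


# ---------------------------------------------------------------------------
# pruning and splitting
# ---------------------------------------------------------------------------

def prune(
    matrix: DescriptorMatrix,
    y: Sequence[float],
    corr_cutoff: float = 0.95,
    constancy_cutoff: float = 0.98,
) -> DescriptorMatrix:
    """Drop near-constant and highly inter-correlated descriptors.

    A column is near-constant when a single value occupies more than
    ``constancy_cutoff`` of the molecules.  Among remaining columns no
    pairwise |Pearson R| above ``corr_cutoff`` survives; from each
    violating pair the column less correlated (in absolute value) with
    the response is dropped, ties broken lexicographically by name.
    The result does not depend on the input column order.
    """
    df = matrix.data
    if len(df) < 2:
        raise ModelError("pruning needs at least 2 molecules")
    y = np.asarray(y, dtype=float)

    keep_const = []
    n = len(df)
    for name in df.columns:
        top_freq = df[name].value_counts().iloc[0] / n
        if top_freq <= constancy_cutoff:
            keep_const.append(name)
    if not keep_const:
        return matrix.select([])

    sub = df[keep_const]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_y = {}
        for name in keep_const:
            c = np.corrcoef(sub[name].to_numpy(dtype=float), y)[0, 1]
            corr_y[name] = abs(c) if np.isfinite(c) else 0.0
        corr = sub.corr().abs().fillna(1.0)

    # canonical priority: strongest |corr to y| first, then name
    order = sorted(keep_const, key=lambda nm: (-corr_y[nm], nm))
    kept: list[str] = []
    for name in order:
        if all(corr.loc[name, other] <= corr_cutoff for other in kept):
            kept.append(name)
    kept_in_input_order = [nm for nm in df.columns if nm in set(kept)]
    return matrix.select(kept_in_input_order)


@dataclass
class SplitSpec:
    """A reproducible training/external partition of molecule ids."""

    fraction_training: float
    seed: int
    training_ids: list[str]
    external_ids: list[str]

    def as_dict(self) -> dict:
        return {
            "fraction_training": self.fraction_training,
            "seed": self.seed,
            "training_ids": self.training_ids,
            "external_ids": self.external_ids,
        }


def split(ids: Sequence[str], fraction_training: float = 0.8, seed: int = 0) -> SplitSpec:
    """Randomly partition ids into training and external sets.

    The training size is ``round-half-up(fraction * n)``; the partition
    is a seeded permutation, identical for identical seeds.
    """
    n = len(ids)
    if n < 5:
        raise ModelError("need at least 5 molecules to split")
    if not 0.0 < fraction_training < 1.0:
        raise ModelError(f"fraction_training must be in (0,1), got {fraction_training}")
    n_train = int(math.floor(fraction_training * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ModelError("degenerate split: empty training or external set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = list(ids)
    training = sorted(ids[i] for i in perm[:n_train])
    external = sorted(ids[i] for i in perm[n_train:])
    return SplitSpec(fraction_training, seed, training, external)


# ---------------------------------------------------------------------------
# genetic-algorithm subset selection
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    """Hyperparameters for the GA subset search.

    The fitness is always Q2_LOO.  ``generations`` caps the search;
    ``patience`` stops it early once the best fitness has not improved
    for that many consecutive generations (set to None to disable).
    """

    subset_size: int = 7
    population_size: int = 50
    generations: int = 10_000
    mutation_rate: float = 0.1
    crossover_rate: float = 0.8
    tournament_size: int = 3
    elitism: int = 1
    patience: Optional[int] = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= rate <= 1.0:
                raise ModelError(f"GA rates must be in [0,1], got {rate}")


def _subset_fitness(df: pd.DataFrame, y: np.ndarray, subset: tuple[int, ...],
                    cache: dict) -> float:
    if subset in cache:
        return cache[subset]
    cols = df.iloc[:, list(subset)]
    try:
        fit = q2_loo(cols, y)
    except ModelError:
        fit = -np.inf
    cache[subset] = fit
    return fit


def ga_select(
    matrix: DescriptorMatrix,
    y: Sequence[float],
    config: GAConfig,
) -> LinearModel:
    """Evolve fixed-size descriptor subsets maximising Q2_LOO.

    Tournament selection, uniform crossover over the union of parent
    genes, point mutation swapping one descriptor for one outside the
    subset, and elitism (so the best fitness is non-decreasing across
    generations).  Fully reproducible for a fixed seed.  The returned
    model carries ``metadata['q2_loo']`` and the per-generation best
    fitness in ``metadata['history']``.
    """
    df = matrix.data
    y = np.asarray(y, dtype=float)
    n_desc = df.shape[1]
    s = config.subset_size
    if not 1 <= s < n_desc:
        raise ModelError(f"subset_size {s} infeasible for {n_desc} descriptors")
    if len(df) <= s + 1:
        raise ModelError(f"need more molecules ({len(df)}) than descriptors + 1")

    rng = np.random.default_rng(config.seed)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(ind: tuple[int, ...]) -> float:
        return _subset_fitness(df, y, ind, cache)

    def random_individual() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(n_desc, size=s, replace=False)))

    def tournament(pop: list, fits: list) -> tuple[int, ...]:
        idx = rng.integers(0, len(pop), size=config.tournament_size)
        best = max(idx, key=lambda i: fits[i])
        return pop[best]

    def crossover(a: tuple, b: tuple) -> tuple[int, ...]:
        union = sorted(set(a) | set(b))
        if len(union) == s:
            return tuple(union)
        shared = sorted(set(a) & set(b))
        pool = [g for g in union if g not in shared]
        need = s - len(shared)
        picked = rng.choice(len(pool), size=need, replace=False)
        return tuple(sorted(shared + [pool[i] for i in picked]))

    def mutate(ind: tuple) -> tuple[int, ...]:
        inside = list(ind)
        outside = [g for g in range(n_desc) if g not in ind]
        if not outside:
            return ind
        i = rng.integers(0, len(inside))
        j = rng.integers(0, len(outside))
        inside[i] = outside[j]
        return tuple(sorted(inside))

    population = [random_individual() for _ in range(config.population_size)]
    fits = [fitness(ind) for ind in population]
    history: list[float] = []
    best_ind = population[int(np.argmax(fits))]
    best_fit = max(fits)
    stall = 0
    for _ in range(config.generations):
        order = np.argsort(fits)[::-1]
        next_pop = [population[i] for i in order[: config.elitism]]
        while len(next_pop) < config.population_size:
            parent_a = tournament(population, fits)
            if rng.random() < config.crossover_rate:
                parent_b = tournament(population, fits)
                child = crossover(parent_a, parent_b)
            else:
                child = parent_a
            if rng.random() < config.mutation_rate:
                child = mutate(child)
            next_pop.append(child)
        # random immigrant: keep exploration alive after convergence
        if config.population_size > config.elitism + 1:
            next_pop[-1] = random_individual()
        population = next_pop
        fits = [fitness(ind) for ind in population]
        gen_best = max(fits)
        if gen_best > best_fit:
            best_fit = gen_best
            best_ind = population[int(np.argmax(fits))]
            stall = 0
        else:
            stall += 1
        history.append(best_fit)
        if config.patience is not None and stall >= config.patience:
            break

    names = [df.columns[i] for i in best_ind]
    model = fit_mlr(df[names], y)
    model.metadata.update(
        {"q2_loo": best_fit, "history": history, "seed": config.seed,
         "subset_size": s, "n_evaluations": len(cache)}
    )
    return model


@dataclass
class BreakingPoint:
    """Best Q2_LOO per model size, and the size chosen by the plateau rule."""

    chosen_size: int
    sizes: list[int]
    q2_curve: list[float]
    models: list[LinearModel]

    @property
    def chosen_model(self) -> LinearModel:
        return self.models[self.sizes.index(self.chosen_size)]


def breaking_point(
    matrix: DescriptorMatrix,
    y: Sequence[float],
    config: GAConfig,
    max_size: int = 10,
    delta: float = 0.01,
) -> BreakingPoint:
    """Grow model size until Q2_LOO stops improving.

    Runs the GA once per subset size 1..max_size (each size seeded
    deterministically from ``config.seed``) and picks the smallest size
    ``s`` whose increment ``Q2(s+1) - Q2(s)`` falls below ``delta``;
    if every increment exceeds delta the maximum size is chosen.
    """
    if max_size < 2:
        raise ModelError("max_size must be >= 2")
    max_size = min(max_size, matrix.data.shape[1] - 1, len(matrix.data) - 2)
    sizes, curve, models = [], [], []
    from dataclasses import replace as _replace

    for s in range(1, max_size + 1):
        cfg = _replace(config, subset_size=s, seed=config.seed + s)
        model = ga_select(matrix, y, cfg)
        sizes.append(s)
        curve.append(model.metadata["q2_loo"])
        models.append(model)
    chosen = sizes[-1]
    for i in range(len(sizes) - 1):
        if curve[i + 1] - curve[i] < delta:
            chosen = sizes[i]
            break
    return BreakingPoint(chosen_size=chosen, sizes=sizes, q2_curve=curve, models=models)
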