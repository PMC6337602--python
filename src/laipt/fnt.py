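"""Flexible neural tree (FNT) classifier.

An FNT is a tree-structured neural model (Chen's flexible neural tree).
Leaves read raw feature values; each internal (function) node of arity r
computes a weighted sum of its children,

    net = sum_j w_j * y_j,

and passes it through a two-parameter Gaussian activation

    out = exp(-((net - m) / n_act)^2),

so every function node — including the root, whose output is the
classification score — returns a value in (0, 1].  Scores are thresholded
at 0.5 for hard labels; ROC evaluation uses the raw score.

Training separates the two search problems, as is canonical for FNTs:
tree *structure* is searched with genetic programming (tournament selection,
subtree crossover, subtree/point mutation, elitism) and the *parameters*
(w_j, m, n_act) of candidate structures are tuned with particle swarm
optimization.  The two stages alternate; everything is a pure function of
(data, config, seed), with the master seed split into named substreams so
each stage is independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .metrics import roc_auc

__all__ = [
    "FNTNode",
    "FNTModel",
    "TrainConfig",
    "eval_tree",
    "tree_depth",
    "random_tree",
    "init_population",
    "evolve_structure",
    "optimize_parameters",
    "train_fnt",
    "predict",
]

#: Smallest admissible |n_act|: keeps the Gaussian width away from zero.
N_ACT_EPS = 1e-6


@dataclass(eq=False)
class FNTNode:
    kind: Literal["function", "leaf"]
    children: list["FNTNode"] = field(default_factory=list)
    weights: np.ndarray | None = None
    m: float = 0.0
    n_act: float = 1.0
    feature_index: int = 0

    def __post_init__(self) -> None:
        if self.kind == "function":
            if len(self.children) < 2:
                raise ValueError("function nodes need arity >= 2")
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.children),):
                raise ValueError("one weight per child required")
        elif self.kind == "leaf":
            if self.feature_index < 0:
                raise ValueError("feature_index must be non-negative")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    def clone(self) -> "FNTNode":
        if self.kind == "leaf":
            return FNTNode(kind="leaf", feature_index=self.feature_index)
        return FNTNode(
            kind="function",
            children=[c.clone() for c in self.children],
            weights=self.weights.copy(),
            m=self.m,
            n_act=self.n_act,
        )

    def to_dict(self) -> dict:
        if self.kind == "leaf":
            return {"kind": "leaf", "feature_index": int(self.feature_index)}
        return {
            "kind": "function",
            "arity": len(self.children),
            "weights": [float(w) for w in self.weights],
            "m": float(self.m),
            "n_act": float(self.n_act),
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FNTNode":
        if d["kind"] == "leaf":
            return cls(kind="leaf", feature_index=d["feature_index"])
        return cls(
            kind="function",
            children=[cls.from_dict(c) for c in d["children"]],
            weights=np.asarray(d["weights"], dtype=float),
            m=d["m"],
            n_act=d["n_act"],
        )


def tree_depth(node: FNTNode) -> int:
    """Number of function-node layers on the deepest path (leaf-only = 0)."""
    if node.kind == "leaf":
        return 0
    return 1 + max(tree_depth(c) for c in node.children)


def _leaves(node: FNTNode) -> list[FNTNode]:
    if node.kind == "leaf":
        return [node]
    return [leaf for c in node.children for leaf in _leaves(c)]


def _function_nodes(node: FNTNode) -> list[FNTNode]:
    if node.kind == "leaf":
        return []
    return [node] + [f for c in node.children for f in _function_nodes(c)]


def _all_nodes(node: FNTNode) -> list[FNTNode]:
    if node.kind == "leaf":
        return [node]
    return [node] + [x for c in node.children for x in _all_nodes(c)]


def eval_tree(model_or_node, features: np.ndarray) -> np.ndarray | float:
    """Evaluate a tree (or model) on one sample or a sample matrix.

    Returns a scalar for a 1-D feature vector, else one value per row.
    Root outputs of a function node lie in (0, 1].
    """
    node = model_or_node.root if isinstance(model_or_node, FNTModel) else model_or_node
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[np.newaxis, :]
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    out = _eval(node, X, path="root")
    return float(out[0]) if single else out


def _eval(node: FNTNode, X: np.ndarray, path: str) -> np.ndarray:
    if node.kind == "leaf":
        if node.feature_index >= X.shape[1]:
            raise IndexError(
                f"leaf at {path} references feature {node.feature_index} "
                f"but input has {X.shape[1]} features"
            )
        return X[:, node.feature_index]
    net = np.zeros(X.shape[0])
    for j, (w, child) in enumerate(zip(node.weights, node.children)):
        net += w * _eval(child, X, f"{path}.{j}")
    if not np.isfinite(net).all():
        raise FloatingPointError(f"non-finite weighted sum at node {path}")
    width = node.n_act if abs(node.n_act) >= N_ACT_EPS else math.copysign(N_ACT_EPS, node.n_act or 1.0)
    # cap the exponent so the activation never underflows to exactly 0
    z = np.minimum(((net - node.m) / width) ** 2, 700.0)
    return np.exp(-z)


@dataclass
class TrainConfig:
    """Hyperparameters for the alternating GP + PSO search.

    The defaults are sized for a few hundred training windows with a few
    hundred features; scale ``population_size`` / ``generations`` /
    ``swarm_iters`` up for larger problems.
    """

    function_arities: tuple[int, ...] = (2, 3)
    population_size: int = 24
    generations: int = 8
    tournament_size: int = 3
    crossover_rate: float = 0.5
    mutation_rate: float = 0.4
    swarm_size: int = 16
    swarm_iters: int = 20
    fitness: Literal["rmse", "one_minus_auc"] = "rmse"
    max_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("population_size", "generations", "tournament_size",
                     "swarm_size", "swarm_iters", "max_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fitness not in ("rmse", "one_minus_auc"):
            raise ValueError(f"unknown fitness {self.fitness!r}")
        if any(a < 2 for a in self.function_arities):
            raise ValueError("function arities must be >= 2")


@dataclass(eq=False)
class FNTModel:
    root: FNTNode
    feature_dim: int
    threshold: float = 0.5
    training_config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.root.kind != "function":
            raise ValueError("model root must be a function node")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        for leaf in _leaves(self.root):
            if leaf.feature_index >= self.feature_dim:
                raise ValueError("leaf feature index exceeds feature dimension")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "root": self.root.to_dict(),
            "feature_dim": self.feature_dim,
            "threshold": self.threshold,
            "training_config": self.training_config,
            "seed": self.seed,
        }
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FNTModel":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            s = str(source).strip()
            text = s if s.startswith("{") else Path(s).read_text()
        d = json.loads(text)
        return cls(
            root=FNTNode.from_dict(d["root"]),
            feature_dim=d["feature_dim"],
            threshold=d["threshold"],
            training_config=d.get("training_config", {}),
            seed=d.get("seed"),
        )


# ---------------------------------------------------------------------------
# random trees and genetic-programming operators


def random_tree(
    config: TrainConfig, feature_dim: int, rng: np.random.Generator, depth: int = 1
) -> FNTNode:
    """Grow a random function node; children are leaves with probability 0.5
    until the depth cap forces them."""
    arity = int(rng.choice(config.function_arities))
    children = []
    for _ in range(arity):
        if depth >= config.max_depth or rng.random() < 0.5:
            children.append(FNTNode(kind="leaf", feature_index=int(rng.integers(feature_dim))))
        else:
            children.append(random_tree(config, feature_dim, rng, depth + 1))
    return FNTNode(
        kind="function",
        children=children,
        weights=rng.uniform(-1.0, 1.0, size=arity),
        m=float(rng.uniform(0.0, 1.0)),
        n_act=float(rng.uniform(0.1, 1.0)),
    )


def init_population(
    config: TrainConfig, feature_dim: int, rng: np.random.Generator
) -> list[FNTNode]:
    if feature_dim < 1:
        raise ValueError("feature_dim must be >= 1")
    return [random_tree(config, feature_dim, rng) for _ in range(config.population_size)]


def _tournament(
    fitnesses: Sequence[float], config: TrainConfig, rng: np.random.Generator
) -> int:
    contenders = rng.integers(len(fitnesses), size=config.tournament_size)
    return int(min(contenders, key=lambda i: fitnesses[i]))


def _crossover(
    a: FNTNode, b: FNTNode, config: TrainConfig, rng: np.random.Generator
) -> FNTNode:
    """Graft a random subtree of b onto a random edge of a; depth-capped."""
    child = a.clone()
    donors = _all_nodes(b)
    hosts = _function_nodes(child)
    for _ in range(8):  # rejection sampling against the depth cap
        host = hosts[int(rng.integers(len(hosts)))]
        slot = int(rng.integers(len(host.children)))
        graft = donors[int(rng.integers(len(donors)))].clone()
        old = host.children[slot]
        host.children[slot] = graft
        if tree_depth(child) <= config.max_depth:
            return child
        host.children[slot] = old
    return child


def _mutate(
    tree: FNTNode,
    config: TrainConfig,
    feature_dim: int,
    rng: np.random.Generator,
) -> FNTNode:
    child = tree.clone()
    choice = rng.random()
    if choice < 1 / 3:  # point mutation of parameters
        node = _function_nodes(child)[int(rng.integers(len(_function_nodes(child))))]
        node.weights = node.weights + rng.normal(0.0, 0.3, size=node.weights.shape)
        node.m += float(rng.normal(0.0, 0.3))
        node.n_act += float(rng.normal(0.0, 0.3))
        if abs(node.n_act) < N_ACT_EPS:
            node.n_act = N_ACT_EPS
    elif choice < 2 / 3:  # leaf retargeting
        leaf = _leaves(child)[int(rng.integers(len(_leaves(child))))]
        leaf.feature_index = int(rng.integers(feature_dim))
    else:  # subtree replacement
        hosts = _function_nodes(child)
        host = hosts[int(rng.integers(len(hosts)))]
        slot = int(rng.integers(len(host.children)))
        depth_here = 1 + _node_depth(child, host)
        if depth_here >= config.max_depth or rng.random() < 0.5:
            host.children[slot] = FNTNode(kind="leaf", feature_index=int(rng.integers(feature_dim)))
        else:
            host.children[slot] = random_tree(config, feature_dim, rng, depth=depth_here + 1)
    return child


def _node_depth(root: FNTNode, target: FNTNode, depth: int = 1) -> int:
    if root is target:
        return depth
    if root.kind == "function":
        for c in root.children:
            d = _node_depth(c, target, depth + 1)
            if d >= 0:
                return d
    return -1


def evolve_structure(
    population: list[FNTNode],
    fitness_fn: Callable[[FNTNode], float],
    config: TrainConfig,
    rng: np.random.Generator,
    feature_dim: int,
) -> list[FNTNode]:
    """One generation: elitism + tournament-selected crossover/mutation."""
    if not population:
        raise ValueError("population is empty")
    fitnesses = [fitness_fn(t) for t in population]
    best = population[int(np.argmin(fitnesses))].clone()
    offspring: list[FNTNode] = [best]
    while len(offspring) < len(population):
        parent = population[_tournament(fitnesses, config, rng)]
        if rng.random() < config.crossover_rate:
            mate = population[_tournament(fitnesses, config, rng)]
            child = _crossover(parent, mate, config, rng)
        else:
            child = parent.clone()
        if rng.random() < config.mutation_rate:
            child = _mutate(child, config, feature_dim, rng)
        offspring.append(child)
    return offspring


# ---------------------------------------------------------------------------
# parameter optimization (particle swarm)


def _flatten_params(tree: FNTNode) -> np.ndarray:
    parts = []
    for node in _function_nodes(tree):
        parts.append(node.weights)
        parts.append([node.m, node.n_act])
    return np.concatenate(parts)


def _write_params(tree: FNTNode, vector: np.ndarray) -> None:
    i = 0
    for node in _function_nodes(tree):
        r = len(node.children)
        node.weights = vector[i : i + r].copy()
        node.m = float(vector[i + r])
        n_act = float(vector[i + r + 1])
        node.n_act = n_act if abs(n_act) >= N_ACT_EPS else math.copysign(N_ACT_EPS, n_act or 1.0)
        i += r + 2


def fitness_function(
    tree: FNTNode, X: np.ndarray, y: np.ndarray, kind: str = "rmse"
) -> float:
    """Training fitness, minimized: RMSE of the score against 0/1 labels,
    or 1 - AUC for rank-based training on imbalanced data."""
    scores = eval_tree(tree, X)
    if kind == "rmse":
        return float(np.sqrt(np.mean((scores - y) ** 2)))
    return 1.0 - roc_auc(scores, y).auc


def optimize_parameters(
    tree: FNTNode,
    features: np.ndarray,
    labels: Sequence[int],
    config: TrainConfig,
    rng: np.random.Generator,
) -> FNTNode:
    """Tune all (w, m, n_act) of a fixed structure by particle swarm.

    The incumbent parameter vector seeds the swarm, so the returned tree is
    never worse on the training fitness than the input tree.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("parameter optimization needs both classes present")

    tree = tree.clone()
    x0 = _flatten_params(tree)
    dim = x0.size

    def cost(vec: np.ndarray) -> float:
        _write_params(tree, vec)
        return fitness_function(tree, X, y, config.fitness)

    # standard constriction-free PSO: inertia 0.72, both pulls 1.49
    pos = x0 + rng.normal(0.0, 0.5, size=(config.swarm_size, dim))
    pos[0] = x0
    vel = rng.normal(0.0, 0.1, size=(config.swarm_size, dim))
    pbest = pos.copy()
    pbest_cost = np.array([cost(p) for p in pos])
    g = int(np.argmin(pbest_cost))
    gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])

    for _ in range(config.swarm_iters):
        r1 = rng.random(size=(config.swarm_size, dim))
        r2 = rng.random(size=(config.swarm_size, dim))
        vel = 0.72 * vel + 1.49 * r1 * (pbest - pos) + 1.49 * r2 * (gbest - pos)
        np.clip(vel, -1.0, 1.0, out=vel)
        pos = pos + vel
        for i in range(config.swarm_size):
            c = cost(pos[i])
            if c < pbest_cost[i]:
                pbest[i] = pos[i].copy()
                pbest_cost[i] = c
        g = int(np.argmin(pbest_cost))
        if pbest_cost[g] < gbest_cost:
            gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])

    _write_params(tree, gbest)
    return tree


# ---------------------------------------------------------------------------
# training


def train_fnt(
    features: np.ndarray,
    labels: Sequence[int],
    config: TrainConfig | None = None,
) -> FNTModel:
    """Fit an FNT by alternating structure evolution and swarm tuning.

    Each generation evolves the population by genetic programming, then
    polishes the current best structure's parameters with PSO; the best
    (structure, parameters) pair ever seen becomes the model.  Fully
    reproducible from ``config.seed``.
    """
    config = config or TrainConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D sample x feature matrix")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training requires both classes present")
    if counts.min() < 2:
        raise ValueError("training requires at least 2 samples per class")

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_evolve, rng_swarm = (np.random.default_rng(s) for s in ss.spawn(3))

    def fit_of(tree: FNTNode) -> float:
        return fitness_function(tree, X, y, config.fitness)

    population = init_population(config, X.shape[1], rng_init)
    best_tree = min(population, key=fit_of).clone()
    best_cost = fit_of(best_tree)

    for _ in range(config.generations):
        population = evolve_structure(population, fit_of, config, rng_evolve, X.shape[1])
        gen_best = min(population, key=fit_of)
        tuned = optimize_parameters(gen_best, X, y, config, rng_swarm)
        if fit_of(tuned) < fit_of(gen_best):
            population[population.index(gen_best)] = tuned
            gen_best = tuned
        cost = fit_of(gen_best)
        if cost < best_cost:
            best_tree, best_cost = gen_best.clone(), cost

    return FNTModel(
        root=best_tree,
        feature_dim=X.shape[1],
        threshold=0.5,
        training_config=asdict(config) | {"function_arities": list(config.function_arities)},
        seed=config.seed,
    )


def predict(model: FNTModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores in (0, 1] and hard labels (positive iff score >= threshold)."""
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[np.newaxis, :]
    if X.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {model.feature_dim}"
        )
    scores = eval_tree(model.root, X)
    labels = (scores >= model.threshold).astype(int)
    if single:
        return scores[0], labels[0]
    return scores, labels
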