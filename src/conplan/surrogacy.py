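"""Surrogacy analysis: how well one feature set prioritizes for another.

A surrogacy run ranks the landscape using only the *surrogate* features
(positive weight) while the *target* features ride along with weight 0;
the target's performance curve on that ranking measures the surrogate's
value.  The curve is judged against two baselines: the *optimal* curve
(the target prioritized for itself) and the *random* curve (the mean
target curve over many rankings driven by iid uniform noise surrogates).
The species accumulation index condenses this into one number:

    SAI = (S - R) / (O - R)

with S, R, O the areas under the target-under-surrogate, random and
optimal mean curves.  SAI ranges from -inf to 1: 1 is the best possible
performance, 0 is random, negative is worse than random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import PerformanceCurve, auc_of_mean_curve, performance_curves
from .grids import FeatureStack
from .prioritize import PrioritizerConfig, rank_abf


class DegenerateBaselineError(ZeroDivisionError):
    """Optimal and random baselines coincide; the SAI is undefined."""


@dataclass
class SurrogacyResult:
    """Areas S (surrogate), R (random), O (optimal) and the SAI."""

    S: float
    R: float
    O: float
    sai: float
    n_random_runs: int
    surrogate: list[str]
    target: list[str]
    random_envelope: tuple[np.ndarray, np.ndarray] | None = None  # (min, max)

    def as_dict(self) -> dict:
        return {
            "S": self.S, "R": self.R, "O": self.O, "sai": self.sai,
            "n_random_runs": self.n_random_runs,
            "surrogate": self.surrogate, "target": self.target,
        }


def compute_sai(S: float, R: float, O: float) -> float:
    """SAI = (S - R) / (O - R); 1 = optimal, 0 = random, < 0 worse than random."""
    if np.isclose(O, R, atol=1e-12, rtol=0.0):
        raise DegenerateBaselineError(
            "optimal and random AUCs coincide (O == R); SAI is undefined"
        )
    return float((S - R) / (O - R))


def _surrogacy_weights(stack: FeatureStack, surrogate: list[str]) -> np.ndarray:
    """Weight 1 per surrogate feature, 0 for targets/others; built-up layers
    keep their cumulative -1 (split over members)."""
    weights = np.zeros(stack.n_features)
    for name in surrogate:
        weights[stack.index(name)] = 1.0
    builtup = [i for i, g in enumerate(stack.groups) if g == "builtup"]
    for i in builtup:
        weights[i] = -1.0 / len(builtup)
    return weights


def surrogacy_run(
    stack: FeatureStack,
    surrogate_features: list[str],
    target_features: list[str],
    cfg: PrioritizerConfig | None = None,
) -> PerformanceCurve:
    """Rank on the surrogate set only; return the full performance curve
    (target curves are read off it, targets never influence the ranking)."""
    if not surrogate_features:
        raise ValueError("surrogate feature set is empty")
    if not target_features:
        raise ValueError("target feature set is empty")
    for name in list(surrogate_features) + list(target_features):
        stack.index(name)  # raises KeyError on unknown names
    weighted = stack.with_weights(_surrogacy_weights(stack, surrogate_features))
    rank = rank_abf(weighted, cfg)
    return performance_curves(rank, stack)


def random_baseline(
    stack: FeatureStack,
    target_features: list[str],
    n_runs: int = 100,
    seed: int = 0,
    cfg: PrioritizerConfig | None = None,
    n_random_layers: int = 1,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Mean target curve over rankings driven by uniform-noise surrogates.

    Each run adds ``n_random_layers`` iid uniform(0,1) layers on the valid
    cells as the only positively weighted features (built-up layers keep
    their negative weights) and evaluates the mean curve of the target
    features on the resulting ranking.

    Returns ``(fractions, mean_curve, (envelope_min, envelope_max))``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    runs = []
    fractions = None
    for _ in range(n_runs):
        noise = [rng.uniform(size=stack.shape) * stack.valid
                 for _ in range(n_random_layers)]
        names = [f"__random_{k}" for k in range(n_random_layers)]
        aug = FeatureStack(
            np.concatenate([np.stack(noise), stack.data]),
            names + list(stack.names),
            ["random"] * n_random_layers + list(stack.groups),
            np.concatenate([np.ones(n_random_layers), np.zeros(stack.n_features)]),
            stack.valid, stack.cell_size, stack.origin,
        )
        aug = aug.with_weights(_surrogacy_weights(aug, names))
        rank = rank_abf(aug, cfg)
        curve = performance_curves(rank, stack)
        runs.append(curve.mean(target_features))
        fractions = curve.fractions_lost
    arr = np.stack(runs)
    return fractions, arr.mean(axis=0), (arr.min(axis=0), arr.max(axis=0))


def surrogacy_analysis(
    stack: FeatureStack,
    surrogate_features: list[str],
    target_features: list[str],
    n_random: int = 100,
    seed: int = 0,
    cfg: PrioritizerConfig | None = None,
    random_curve: tuple[np.ndarray, np.ndarray, tuple] | None = None,
) -> SurrogacyResult:
    """One full surrogacy assessment: S, R, O and the SAI for one direction.

    A precomputed ``random_baseline`` result may be passed to share the
    random curve between analyses of the same target set.
    """
    surr_curve = surrogacy_run(stack, surrogate_features, target_features, cfg)
    S = auc_of_mean_curve(surr_curve, target_features)
    opt_curve = surrogacy_run(stack, target_features, target_features, cfg)
    O = auc_of_mean_curve(opt_curve, target_features)
    if random_curve is None:
        random_curve = random_baseline(stack, target_features, n_random, seed, cfg)
    fractions, mean_rand, envelope = random_curve
    R = float(np.trapezoid(mean_rand, fractions))
    return SurrogacyResult(
        S=S, R=R, O=O, sai=compute_sai(S, R, O),
        n_random_runs=n_random,
        surrogate=list(surrogate_features), target=list(target_features),
        random_envelope=envelope,
    )


def reciprocal_surrogacy(
    stack: FeatureStack,
    group_a: list[str],
    group_b: list[str],
    n_random: int = 100,
    seed: int = 0,
    cfg: PrioritizerConfig | None = None,
) -> tuple[SurrogacyResult, SurrogacyResult]:
    """Surrogacy in both directions (a -> b and b -> a).

    Each target set gets its own shared random baseline; the two results
    carry all three areas each.
    """
    if not group_a or not group_b:
        raise ValueError("both feature groups must be non-empty")
    rand_b = random_baseline(stack, group_b, n_random, seed, cfg)
    rand_a = random_baseline(stack, group_a, n_random, seed + 1, cfg)
    a_for_b = surrogacy_analysis(stack, group_a, group_b, n_random, seed, cfg,
                                 random_curve=rand_b)
    b_for_a = surrogacy_analysis(stack, group_b, group_a, n_random, seed, cfg,
                                 random_curve=rand_a)
    return a_for_b, b_for_a
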