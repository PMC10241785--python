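"""Synthetic population-response generator.

Emulates the statistical structure of block-design response estimates in an
object-selective region (and of network-layer activation matrices): per-unit
positive tuning to single-object conditions, pair responses produced by a
configurable combination rule, and additive run-level measurement noise that
controls split-half reliability.

Combination rules
-----------------
``weighted_sum``      pair = c * (r_top + r_bottom); c = 0.5 is perfect
                      averaging (slope 0.5 against the summed singles),
                      c = 1 is summation.
``weighted_average``  pair = w * r_top + (1 - w) * r_bottom; location-weighted
                      mean with w in [0, 1].
``max``               pair = max(r_top, r_bottom); winner-take-all.

Determinism
-----------
Each subject's data are a pure function of ``(config.seed, subject_index)``.
Within a subject the draw order is fixed: unit gains, single-condition
tuning means, per-unit combination coefficients, then run noise — so adding
subjects or changing downstream analyses never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .dataset import ResponseDataset
from .design import ConditionTable, constituent_indices, enumerate_conditions

CombinationRule = Literal["weighted_sum", "weighted_average", "max"]


@dataclass(frozen=True)
class DistributionSpec:
    """Nonnegative-valued distribution for per-unit single-condition means."""

    family: Literal["lognormal", "gamma", "uniform", "constant"]
    params: dict[str, float]

    def __post_init__(self) -> None:
        expected = {
            "lognormal": {"mean", "sigma"},
            "gamma": {"shape", "scale"},
            "uniform": {"low", "high"},
            "constant": {"value"},
        }[self.family]
        if set(self.params) != expected:
            raise ValueError(f"{self.family} spec needs params {sorted(expected)}")
        if self.family == "uniform" and not 0 <= self.params["low"] <= self.params["high"]:
            raise ValueError("uniform spec needs 0 <= low <= high")
        if self.family == "gamma" and (self.params["shape"] <= 0 or self.params["scale"] <= 0):
            raise ValueError("gamma spec needs positive shape and scale")
        if self.family == "constant" and self.params["value"] < 0:
            raise ValueError("constant spec must be nonnegative")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        p = self.params
        if self.family == "lognormal":
            return rng.lognormal(p["mean"], p["sigma"], size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        return np.full(size, p["value"], dtype=float)

    def variance(self) -> float:
        """Population variance; used by closed-form attenuation predictions."""
        p = self.params
        if self.family == "lognormal":
            s2 = p["sigma"] ** 2
            return (math.exp(s2) - 1.0) * math.exp(2.0 * p["mean"] + s2)
        if self.family == "gamma":
            return p["shape"] * p["scale"] ** 2
        if self.family == "uniform":
            return (p["high"] - p["low"]) ** 2 / 12.0
        return 0.0


def lognormal_tuning(mean: float = 0.0, sigma: float = 0.5) -> DistributionSpec:
    return DistributionSpec("lognormal", {"mean": mean, "sigma": sigma})


@dataclass(frozen=True)
class CoefficientSpec:
    """Per-unit combination coefficient: a constant or a clipped normal.

    For ``weighted_average`` the realized weights are clipped to [0, 1]; for
    ``weighted_sum`` they are clipped at 0.
    """

    kind: Literal["constant", "normal", "uniform"]
    value: float = 0.5
    mean: float = 0.5
    sd: float = 0.0
    low: float = 0.0
    high: float = 1.0

    def sample(self, rng: np.random.Generator, n: int, rule: CombinationRule) -> np.ndarray:
        if self.kind == "constant":
            c = np.full(n, self.value, dtype=float)
        elif self.kind == "normal":
            c = rng.normal(self.mean, self.sd, n)
        else:
            c = rng.uniform(self.low, self.high, n)
        if rule == "weighted_average":
            return np.clip(c, 0.0, 1.0)
        return np.clip(c, 0.0, None)


def constant_coefficient(value: float) -> CoefficientSpec:
    return CoefficientSpec(kind="constant", value=value)


def normal_coefficient(mean: float, sd: float) -> CoefficientSpec:
    return CoefficientSpec(kind="normal", mean=mean, sd=sd)


def apply_combination_rule(r_top, r_bottom, rule: CombinationRule, param=None):
    """Combine two single-object responses into a pair response.

    Accepts scalars or broadcastable arrays; ``param`` is the weighted-sum
    coefficient c or the weighted-average top weight w (ignored for ``max``).
    """
    r_top = np.asarray(r_top, dtype=float)
    r_bottom = np.asarray(r_bottom, dtype=float)
    if rule == "max":
        return np.maximum(r_top, r_bottom)
    if param is None:
        raise ValueError(f"rule {rule!r} requires a coefficient parameter")
    param = np.asarray(param, dtype=float)
    if rule == "weighted_sum":
        if np.any(param < 0):
            raise ValueError("weighted_sum coefficients must be >= 0")
        return param * (r_top + r_bottom)
    if rule == "weighted_average":
        if np.any((param < 0) | (param > 1)):
            raise ValueError("weighted_average weights must lie in [0, 1]")
        return param * r_top + (1.0 - param) * r_bottom
    raise ValueError(f"unknown combination rule {rule!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generator.

    ``n_runs = 0`` produces a run-axis-free activation matrix (requires
    ``noise_sd = 0``); otherwise ``n_runs`` must be even so the split-half
    analyses are well defined.  ``unit_gain_sigma > 0`` draws a lognormal
    multiplicative gain per unit, modelling the large overall-responsiveness
    differences between measured units that make the across-unit regression
    robust to run noise.
    """

    n_categories: int = 4
    n_locations: int = 2
    n_units: int = 200
    n_runs: int = 10
    n_subjects: int = 10
    tuning: DistributionSpec = field(default_factory=lognormal_tuning)
    combination_rule: CombinationRule = "weighted_sum"
    coefficient: CoefficientSpec = field(default_factory=lambda: constant_coefficient(0.5))
    noise_sd: float = 0.0
    unit_gain_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_subjects < 1:
            raise ValueError("n_units and n_subjects must be positive")
        if self.n_runs < 0:
            raise ValueError("n_runs must be >= 0")
        if self.n_runs == 0 and self.noise_sd != 0:
            raise ValueError("run-free datasets must be noiseless (noise_sd = 0)")
        if self.n_runs > 0 and self.n_runs % 2 != 0:
            raise ValueError("n_runs must be even (split-half analyses)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.unit_gain_sigma < 0:
            raise ValueError("unit_gain_sigma must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    def condition_table(self) -> ConditionTable:
        return enumerate_conditions(self.n_categories, self.n_locations)


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities behind one generated subject (for recovery tests)."""

    single_means: np.ndarray  # (n_units, n_singles), gain applied
    condition_means: np.ndarray  # (n_units, n_conditions), noise-free
    coefficients: np.ndarray | None  # per-unit rule parameter (None for max)
    gains: np.ndarray


def _true_condition_means(
    config: GeneratorConfig, table: ConditionTable, rng: np.random.Generator
) -> tuple[np.ndarray, GroundTruth]:
    n_singles = len(table.singles)
    gains = (
        rng.lognormal(0.0, config.unit_gain_sigma, config.n_units)
        if config.unit_gain_sigma > 0
        else np.ones(config.n_units)
    )
    singles = config.tuning.sample(rng, (config.n_units, n_singles)) * gains[:, None]

    means = np.zeros((config.n_units, len(table)))
    means[:, :n_singles] = singles  # singles occupy the leading columns

    coeffs: np.ndarray | None = None
    if len(table.pairs) > 0:
        pair_idx, top_idx, bottom_idx = constituent_indices(table)
        if config.combination_rule == "max":
            means[:, pair_idx] = np.maximum(means[:, top_idx], means[:, bottom_idx])
        else:
            coeffs = config.coefficient.sample(rng, config.n_units, config.combination_rule)
            means[:, pair_idx] = apply_combination_rule(
                means[:, top_idx], means[:, bottom_idx], config.combination_rule, coeffs[:, None]
            )
    truth = GroundTruth(
        single_means=singles, condition_means=means, coefficients=coeffs, gains=gains
    )
    return means, truth


def generate_dataset(
    config: GeneratorConfig,
    subject_index: int = 0,
    table: ConditionTable | None = None,
    return_truth: bool = False,
):
    """Generate one subject's (or one layer's) ResponseDataset.

    The dataset is bit-reproducible from ``(config.seed, subject_index)``.
    With ``return_truth=True`` also returns the latent GroundTruth.
    """
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    if table is None:
        table = config.condition_table()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))
    means, truth = _true_condition_means(config, table, rng)

    if config.n_runs == 0:
        values = means
    else:
        noise = rng.normal(0.0, config.noise_sd, (config.n_units, len(table), config.n_runs))
        values = means[:, :, None] + noise

    ds = ResponseDataset(values=values, table=table, subject_id=f"s{subject_index:02d}")
    return (ds, truth) if return_truth else ds


def generate_cohort(config: GeneratorConfig, return_truth: bool = False):
    """Generate ``config.n_subjects`` statistically independent subjects."""
    table = config.condition_table()
    out = [
        generate_dataset(config, i, table=table, return_truth=return_truth)
        for i in range(config.n_subjects)
    ]
    return out


# ---------------------------------------------------------------------------
# Presets: the two study conditions the analyses contrast.
# ---------------------------------------------------------------------------

def brain_like(seed: int = 0, n_units: int = 150, n_subjects: int = 10) -> GeneratorConfig:
    """Voxel-cohort-like condition.

    Tight per-unit coefficients around the primate-IT reference slope 0.55,
    broad per-unit gains, and run noise calibrated so that mean split-half
    unit reliability is about 0.2 (see docs/methods.md for the calibration).
    """
    return GeneratorConfig(
        n_units=n_units,
        n_runs=10,
        n_subjects=n_subjects,
        combination_rule="weighted_sum",
        coefficient=normal_coefficient(0.55, 0.04),
        noise_sd=3.0,
        unit_gain_sigma=0.8,
        seed=seed,
    )


def layer_like(seed: int = 0, n_units: int = 500, n_subjects: int = 1) -> GeneratorConfig:
    """Network-layer-like condition: noiseless, run-free activation matrices
    with widely heterogeneous per-unit combination coefficients."""
    return GeneratorConfig(
        n_units=n_units,
        n_runs=0,
        n_subjects=n_subjects,
        combination_rule="weighted_sum",
        coefficient=normal_coefficient(0.5, 0.3),
        noise_sd=0.0,
        unit_gain_sigma=0.8,
        seed=seed,
    )


def expected_abscissa_reliability(tuning_variance: float, noise_sd: float, n_runs: int) -> float:
    """Closed-form reliability of the per-unit summed-singles regressor.

    For iid tuning (no unit gain) the pair-averaged summed-single abscissa has
    signal variance tau^2 / 2 and noise variance sigma^2 / (2 * n_runs) for
    any category count, so its reliability is tau^2 / (tau^2 + sigma^2 /
    n_runs).  The expected measured population slope is the generative
    coefficient attenuated by this factor (errors-in-variables).
    """
    if n_runs < 1:
        return 1.0
    tau2 = float(tuning_variance)
    return tau2 / (tau2 + noise_sd**2 / n_runs)
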