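"""Synthetic marker data with a known logistic structure.

One replicate is a triple (y, x, x_star): a Bernoulli(pi) outcome and two
unit-variance normal markers whose means shift by (mu, mu_star) among
subjects with y = 1.  Markers are either independent given the outcome or
correlated with coefficient rho.  Because the class-conditional densities
are normal with common variance, the induced regression of y on x is
exactly logistic with slope mu and intercept -mu^2/2 + logit(pi), which
makes the generator self-validating.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "MarkerDataset",
    "generate_outcomes",
    "generate_markers_independent",
    "generate_markers_dependent",
    "generate_dataset",
    "true_coefficients",
]


class ConfigurationError(ValueError):
    """Raised for parameter values outside their valid domain."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation cell plus seeding coordinates.

    Parameters
    ----------
    n : int
        Subjects per replicate (>= 10).
    prevalence : float
        Marginal outcome probability pi, in (0, 1).
    mu, mu_star : float
        Mean shifts of the established and new marker among y = 1.
    rho : float
        Conditional correlation between the markers, |rho| < 1.
        rho = 0 gives the independent scheme.
    seed : int
        Master seed; together with the cell coordinates and
        ``replicate_index`` it pins down the replicate's stream.
    replicate_index : int
        Which replicate of the cell this configuration addresses.
    """

    n: int
    prevalence: float
    mu: float = 0.0
    mu_star: float = 0.0
    rho: float = 0.0
    seed: int = 0
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ConfigurationError(f"n must be >= 10, got {self.n}")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError(
                f"prevalence must lie in (0, 1), got {self.prevalence}"
            )
        if not -1.0 < self.rho < 1.0:
            raise ConfigurationError(f"|rho| must be < 1, got {self.rho}")
        if self.seed < 0 or self.replicate_index < 0:
            raise ConfigurationError("seed and replicate_index must be >= 0")

    def replicate(self, index: int) -> "SimulationConfig":
        """Same cell, different replicate index."""
        return dataclasses.replace(self, replicate_index=index)

    def spawn_rng(self, attempt: int = 0) -> np.random.Generator:
        """Deterministic per-replicate stream.

        The entropy pool mixes the master seed, every cell coordinate and
        the replicate index, so equal configs give bit-identical data and
        distinct cells / replicates get independent streams.  ``attempt``
        is bumped when a degenerate draw has to be discarded.
        """
        ss = np.random.SeedSequence(
            entropy=[
                int(self.seed),
                int(self.n),
                _quantize(self.prevalence),
                _quantize(self.mu),
                _quantize(self.mu_star),
                _quantize(self.rho),
                int(self.replicate_index),
                int(attempt),
            ]
        )
        return np.random.default_rng(ss)


def _quantize(value: float) -> int:
    # non-negative integer encoding of a parameter in [-8, 8) at 1e-6 grain
    return int(round((value + 8.0) * 1_000_000))


@dataclass(frozen=True)
class MarkerDataset:
    """One replicate's outcome and marker vectors.

    Attributes
    ----------
    y : ndarray of 0/1, shape (n,)
    x : ndarray, shape (n,)
        Established marker X.
    x_star : ndarray, shape (n,)
        Candidate new marker X*.
    redraws : int
        How many degenerate draws (single-class y) were discarded before
        this dataset was produced.
    """

    y: np.ndarray
    x: np.ndarray
    x_star: np.ndarray
    redraws: int = 0

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if not (len(y) == len(self.x) == len(self.x_star)):
            raise ValueError("y, x and x_star must have identical length")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be a 0/1 vector")

    @property
    def n(self) -> int:
        return len(self.y)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"y": self.y, "x": self.x, "x_star": self.x_star})

    def to_csv(self, path) -> None:
        """Write columns y,x,x_star with a header row, one subject per line."""
        self.to_dataframe().to_csv(path, index=False)


def generate_outcomes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the binary outcome vector: y = 1 where U(0,1) < pi."""
    return (rng.random(config.n) < config.prevalence).astype(np.int8)


def generate_markers_independent(
    y: np.ndarray, mu: float, mu_star: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Markers independent given the outcome.

    X | y=1 ~ N(mu, 1), X* | y=1 ~ N(mu_star, 1); both N(0, 1) for y=0.
    """
    return generate_markers_dependent(y, mu, mu_star, 0.0, rng)


def generate_markers_dependent(
    y: np.ndarray,
    mu: float,
    mu_star: float,
    rho: float,
    rng: np.random.Generator,
    *,
    center: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated markers, drawn sequentially.

    X is drawn exactly as in the independent scheme; X* is then drawn
    conditionally with variance 1 - rho^2 and mean

    * literal recipe (default): mu_star * y + rho * X, so among y = 1 the
      marginal mean of X* is mu_star + rho * mu, not mu_star, whenever both
      mu and rho are nonzero;
    * ``center=True``: mu_star * y + rho * (X - mu * y), which keeps the
      class-conditional mean of X* at mu_star for every rho.

    Both give unit unconditional variance and corr(X, X*) = rho within
    each outcome class.
    """
    if not -1.0 < rho < 1.0:
        raise ConfigurationError(f"|rho| must be < 1, got {rho}")
    y = np.asarray(y)
    n = len(y)
    x = rng.standard_normal(n) + mu * y
    conditional_mean = mu_star * y + rho * (x - mu * y if center else x)
    x_star = conditional_mean + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return x, x_star


def generate_dataset(
    config: SimulationConfig, *, center: bool = False, max_redraws: int = 1000
) -> MarkerDataset:
    """One replicate under ``config``, discarding single-class draws.

    A draw in which every subject has the same outcome cannot be analysed
    (the logistic likelihood has no interior maximum), so it is discarded
    and redrawn from the next derived stream; the count is recorded on the
    returned dataset.  At n >= 100 and pi >= 0.05 this is vanishingly rare.
    """
    for attempt in range(max_redraws + 1):
        rng = config.spawn_rng(attempt)
        y = generate_outcomes(config, rng)
        if 0 < int(y.sum()) < config.n:
            x, x_star = generate_markers_dependent(
                y, config.mu, config.mu_star, config.rho, rng, center=center
            )
            return MarkerDataset(y=y, x=x, x_star=x_star, redraws=attempt)
    raise RuntimeError(
        f"no two-class outcome vector in {max_redraws} draws; "
        f"n={config.n}, prevalence={config.prevalence} is degenerate"
    )


def true_coefficients(mu: float, prevalence: float) -> tuple[float, float]:
    """Exact logistic coefficients induced by the generation scheme.

    With X | y=1 ~ N(mu, 1) and X | y=0 ~ N(0, 1), Bayes' rule gives

        logit P(y=1 | x) = [log(pi/(1-pi)) - mu^2/2] + mu * x,

    so beta1 = mu and beta0 = -mu^2/2 + logit(pi).  (The quadratic terms of
    the two normal log-densities cancel because the variances are equal;
    the surviving constant is -mu^2/2, with a minus sign.)
    """
    if not 0.0 < prevalence < 1.0:
        raise ConfigurationError(f"prevalence must lie in (0, 1), got {prevalence}")
    beta0 = -0.5 * mu * mu + math.log(prevalence / (1.0 - prevalence))
    return beta0, mu
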