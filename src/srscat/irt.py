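"""Graded response model (GRM) core.

The GRM models an ordered K-category item response X in {0..K-1} through
cumulative logistic curves sharing one discrimination a:

    P*(X >= k | theta) = logistic(a * (theta - b_k)),   k = 1..K-1,

with P*(X >= 0) = 1 and P*(X >= K) = 0; category probabilities are adjacent
differences of the P*.  On top of the model this module provides Fisher
information (for adaptive item selection), the response log-likelihood,
expected a posteriori (EAP) latent-trait estimation on a quadrature grid, and
the conversion of a latent score to an expected raw total over any item set -
the mechanism that places an adaptive administration on the full-instrument
raw-score metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .bank import ItemBank, ItemParameters
from .errors import (
    CategoryRangeError,
    DomainError,
    IncompleteAdministrationError,
    NumericalUnderflowError,
    SrsCatError,
)

__all__ = [
    "QuadratureGrid",
    "NormalPrior",
    "DIFFUSE_PRIOR",
    "STANDARD_PRIOR",
    "LatentPosterior",
    "make_grid",
    "category_probability",
    "category_probabilities",
    "item_information",
    "response_loglikelihood",
    "eap_estimate",
    "expected_item_score",
    "expected_test_score",
    "raw_total_score",
    "sample_response",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature rule over the latent trait: strictly increasing nodes
    with non-negative weights summing to a positive value."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if nodes.ndim != 1 or nodes.size < 2 or np.any(np.diff(nodes) <= 0):
            raise SrsCatError("grid nodes must be a strictly increasing vector")
        if weights.shape != nodes.shape or np.any(weights < 0):
            raise SrsCatError("grid weights must be non-negative, aligned to nodes")
        total = weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise SrsCatError("grid weights must sum to a positive finite value")


def make_grid(lo: float = -6.0, hi: float = 6.0, n_nodes: int = 121) -> QuadratureGrid:
    """Equally spaced grid on [lo, hi] with rectangle weights."""
    nodes = np.linspace(lo, hi, n_nodes)
    step = (hi - lo) / (n_nodes - 1)
    return QuadratureGrid(nodes=nodes, weights=np.full(n_nodes, step))


DEFAULT_GRID = make_grid()


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior over the latent trait; sd=10 is effectively flat on the
    default [-6, 6] grid ("diffuse"), sd=1 is the population-scaled prior."""

    mean: float = 0.0
    sd: float = 10.0

    def __post_init__(self):
        if self.sd <= 0:
            raise SrsCatError("prior sd must be positive")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return norm.logpdf(x, loc=self.mean, scale=self.sd)


DIFFUSE_PRIOR = NormalPrior(0.0, 10.0)
STANDARD_PRIOR = NormalPrior(0.0, 1.0)


@dataclass(frozen=True)
class LatentPosterior:
    """Discretized posterior over the latent trait.

    ``eap`` and ``se`` are the posterior mean and SD by quadrature;
    ``reliability`` is the empirical reliability 1 - se^2 (clipped to [0, 1]),
    meaningful on a unit-variance latent metric.
    """

    grid: QuadratureGrid
    posterior_mass: np.ndarray
    eap: float
    se: float
    reliability: float


# ---------------------------------------------------------------------------
# model primitives


def _cumulative(item: ItemParameters, theta) -> np.ndarray:
    """P*(X >= k | theta) for k = 1..K-1; shape (..., K-1)."""
    theta = np.asarray(theta, dtype=float)
    return expit(item.discrimination * (theta[..., None] - np.asarray(item.thresholds)))


def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """All category probabilities P(X = k | theta), shape (..., K)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise DomainError("theta must be finite")
    star = _cumulative(item, theta)
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    full = np.concatenate([ones, star, zeros], axis=-1)
    return full[..., :-1] - full[..., 1:]


def category_probability(item: ItemParameters, theta: float, k: int) -> float:
    """P(X = k | theta) for a single category."""
    k = int(k)
    if not 0 <= k <= item.n_categories - 1:
        raise CategoryRangeError(
            f"category {k} outside 0..{item.n_categories - 1} for item {item.item_id}"
        )
    return float(category_probabilities(item, theta)[..., k])


def item_information(item: ItemParameters, theta) -> float | np.ndarray:
    """GRM Fisher information at theta.

    I(theta) = sum_k (dP_k/dtheta)^2 / P_k with
    dP_k/dtheta = a * [w_k - w_{k+1}], w_k = P*_k (1 - P*_k) (w_0 = w_K = 0).
    """
    theta_arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta_arr)):
        raise DomainError("theta must be finite")
    star = _cumulative(item, theta_arr)
    w = star * (1.0 - star)
    zeros = np.zeros(theta_arr.shape + (1,))
    w_full = np.concatenate([zeros, w, zeros], axis=-1)
    dp = item.discrimination * (w_full[..., :-1] - w_full[..., 1:])
    p = category_probabilities(item, theta_arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(p > 1e-300, dp * dp / p, 0.0)
    info = contrib.sum(axis=-1)
    return float(info) if np.isscalar(theta) or np.asarray(theta).ndim == 0 else info


def response_loglikelihood(
    responses: Mapping, bank: ItemBank, group: str | None, theta
) -> float | np.ndarray:
    """Sum of log category probabilities over the answered items only.

    ``responses`` maps item id -> observed category (already in keyed
    orientation).  Missing items are simply absent, as in a partial adaptive
    administration.  ``theta`` may be a scalar or a vector of grid nodes.
    """
    theta_arr = np.asarray(theta, dtype=float)
    total = np.zeros(theta_arr.shape)
    for item_id, k in responses.items():
        item = bank.item(item_id, group)
        k = int(k)
        if not 0 <= k <= item.n_categories - 1:
            raise CategoryRangeError(
                f"response {k} outside 0..{item.n_categories - 1} "
                f"for item {item_id}"
            )
        p = category_probabilities(item, theta_arr)[..., k]
        total = total + np.log(np.clip(p, 1e-300, None))
    return float(total) if theta_arr.ndim == 0 else total


def eap_estimate(
    responses: Mapping,
    bank: ItemBank,
    group: str | None = None,
    prior: NormalPrior = DIFFUSE_PRIOR,
    grid: QuadratureGrid | None = None,
) -> LatentPosterior:
    """Expected-a-posteriori latent-trait estimate on a quadrature grid.

    The posterior mass at each node is proportional to prior density x
    likelihood x quadrature weight, computed in log space.  With no responses
    the EAP recovers the prior mean.
    """
    grid = DEFAULT_GRID if grid is None else grid
    nodes = grid.nodes
    log_post = (
        prior.logpdf(nodes)
        + np.log(grid.weights)
        + response_loglikelihood(responses, bank, group, nodes)
    )
    peak = np.max(log_post)
    if not np.isfinite(peak):
        raise NumericalUnderflowError("posterior mass underflowed on every node")
    mass = np.exp(log_post - peak)
    total = mass.sum()
    if not np.isfinite(total) or total <= 0:
        raise NumericalUnderflowError("posterior mass underflowed on every node")
    mass = mass / total
    eap = float(np.dot(mass, nodes))
    var = float(np.dot(mass, (nodes - eap) ** 2))
    se = float(np.sqrt(var))
    reliability = float(np.clip(1.0 - var, 0.0, 1.0))
    return LatentPosterior(grid=grid, posterior_mass=mass, eap=eap, se=se,
                           reliability=reliability)


# ---------------------------------------------------------------------------
# score conversion


def expected_item_score(item: ItemParameters, theta) -> float | np.ndarray:
    """E[X | theta] = sum_k k P(X=k|theta) = sum_k P*(X>=k|theta); in [0, K-1],
    non-decreasing in theta."""
    star = _cumulative(item, theta)
    out = star.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def expected_test_score(
    posterior_or_theta: LatentPosterior | float,
    bank: ItemBank,
    group: str | None = None,
    item_set: Sequence | None = None,
) -> float:
    """Model-implied raw total over ``item_set`` at the EAP point estimate.

    This is the conversion that places a latent score on the observed raw
    metric (0-195 over the full 65-item bank): the expected test score "as if
    the respondent had completed every item".  ``item_set`` defaults to the
    full bank.
    """
    if isinstance(posterior_or_theta, LatentPosterior):
        theta = posterior_or_theta.eap
    else:
        theta = float(posterior_or_theta)
        if not np.isfinite(theta):
            raise DomainError("theta must be finite")
    ids = tuple(bank.item_ids if item_set is None else item_set)
    if not ids:
        raise SrsCatError("item_set must be non-empty")
    return float(sum(expected_item_score(bank.item(i, group), theta) for i in ids))


def raw_total_score(
    responses: Mapping, bank: ItemBank, form: str = "full"
) -> int:
    """Raw total for a complete administration of ``form`` ('full' or 'short').

    Reverse-coded items contribute K-1-k; every item of the form must be
    answered, otherwise :class:`IncompleteAdministrationError` names the
    missing ids.
    """
    ids = bank.item_ids_for(form)
    missing = [i for i in ids if i not in responses or responses[i] is None]
    if missing:
        raise IncompleteAdministrationError(missing)
    kmax = bank.n_categories - 1
    total = 0
    for i in ids:
        k = int(responses[i])
        if not 0 <= k <= kmax:
            raise CategoryRangeError(f"response {k} outside 0..{kmax} for item {i}")
        total += (kmax - k) if i in bank.reverse_mask else k
    return total


def sample_response(item: ItemParameters, theta: float, rng: np.random.Generator) -> int:
    """Draw one keyed category from the GRM at true theta (inverse-CDF)."""
    star = _cumulative(item, float(theta))
    return int(np.sum(rng.random() < star))
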