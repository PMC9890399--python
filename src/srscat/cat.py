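"""Computerized adaptive testing (CAT) engine.

Administration loop: select the unadministered item with maximum Fisher
information at the current EAP, obtain the response, update the posterior,
then evaluate the stopping rules.  An administration stops only after a
minimum number of items (default 10) and then as soon as either the precision
criterion holds (SE < 0.3, i.e. empirical reliability > 0.90) or score
equilibrium is reached (|change in EAP between two consecutive items| < 0.05);
otherwise it runs until the item cap.  The final EAP is converted to an
expected test score over the full bank - the "CAT-predicted score" on the
0-195 raw metric.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .bank import ItemBank
from .errors import BankExhaustedError, CategoryRangeError, SrsCatError
from .irt import (
    DIFFUSE_PRIOR,
    DEFAULT_GRID,
    NormalPrior,
    QuadratureGrid,
    eap_estimate,
    expected_test_score,
    item_information,
    sample_response,
)

__all__ = [
    "CATConfig",
    "CATState",
    "StopDecision",
    "CATResult",
    "select_next_item",
    "check_stop",
    "administer",
    "lookup_provider",
    "simulated_provider",
    "simulate_cat_study",
]


@dataclass(frozen=True)
class CATConfig:
    """Stopping rules and engine settings.

    ``precision_metric`` chooses between the two equivalent parameterizations
    of the precision rule: ``"se"`` stops when SE < ``se_threshold``;
    ``"reliability"`` stops when 1 - SE^2 > ``reliability_threshold``.  With
    the default pair (0.3, 0.90) both select the same stop step.
    """

    min_items: int = 10
    max_items: int = 65
    se_threshold: float = 0.3
    reliability_threshold: float = 0.90
    delta_eap_threshold: float = 0.05
    selection_rule: str = "max_information"
    precision_metric: str = "se"
    prior: NormalPrior = DIFFUSE_PRIOR
    grid: QuadratureGrid = DEFAULT_GRID
    seed: int | None = None

    def __post_init__(self):
        if self.min_items < 1 or self.max_items < self.min_items:
            raise SrsCatError(
                f"need 1 <= min_items <= max_items, got "
                f"({self.min_items}, {self.max_items})"
            )
        if self.se_threshold <= 0 or self.delta_eap_threshold <= 0:
            raise SrsCatError("stopping thresholds must be positive")
        if not 0 < self.reliability_threshold < 1:
            raise SrsCatError("reliability_threshold must lie in (0, 1)")
        if self.selection_rule != "max_information":
            raise SrsCatError(f"unknown selection rule {self.selection_rule!r}")
        if self.precision_metric not in ("se", "reliability"):
            raise SrsCatError("precision_metric must be 'se' or 'reliability'")


@dataclass
class CATState:
    """Trajectory of one administration; all lists share length = items given.
    ``delta_eap[0]`` is NaN (the change is defined from the second item on)."""

    administered: list = field(default_factory=list)
    responses: list = field(default_factory=list)
    eap_trajectory: list = field(default_factory=list)
    se_trajectory: list = field(default_factory=list)
    delta_eap: list = field(default_factory=list)

    @property
    def n_items(self) -> int:
        return len(self.administered)


@dataclass(frozen=True)
class StopDecision:
    stop: bool
    reason: str | None = None


@dataclass(frozen=True)
class CATResult:
    state: CATState
    final_eap: float
    final_se: float
    stop_reason: str
    n_items: int
    cat_predicted_score: float


def select_next_item(
    state: CATState, bank: ItemBank, group: str | None, current_eap: float
):
    """Unadministered item with maximum Fisher information at ``current_eap``;
    ties broken by the lowest item id (bank order)."""
    given = set(state.administered)
    best_id, best_info = None, -np.inf
    for item_id in bank.item_ids:  # bank order = ascending id, so first win = lowest
        if item_id in given:
            continue
        info = item_information(bank.item(item_id, group), current_eap)
        if info > best_info:
            best_id, best_info = item_id, info
    if best_id is None:
        raise BankExhaustedError("no unadministered items remain")
    return best_id


def check_stop(state: CATState, config: CATConfig) -> StopDecision:
    """Evaluate the stopping rules after the latest item.

    Never stops before ``min_items``.  Thereafter, precision first
    (reason ``"reliability"``), then score equilibrium on the latest
    |delta EAP| (reason ``"equilibrium"``), then the item cap
    (reason ``"max_items"``).
    """
    n = state.n_items
    if n < 1:
        raise SrsCatError("check_stop requires at least one administered item")
    if n < config.min_items:
        return StopDecision(False)
    se = state.se_trajectory[-1]
    if config.precision_metric == "se":
        precise = se < config.se_threshold
    else:
        precise = (1.0 - se * se) > config.reliability_threshold
    if precise:
        return StopDecision(True, "reliability")
    if n >= 2 and np.isfinite(state.delta_eap[-1]) \
            and abs(state.delta_eap[-1]) < config.delta_eap_threshold:
        return StopDecision(True, "equilibrium")
    if n >= config.max_items:
        return StopDecision(True, "max_items")
    return StopDecision(False)


def administer(
    respondent: Callable[[object], int],
    bank: ItemBank,
    group: str | None = None,
    config: CATConfig | None = None,
) -> CATResult:
    """Run one adaptive administration.

    ``respondent`` is called with an item id and must return a raw category
    0..K-1 - either a simulated examinee or a lookup into a recorded response
    vector.  Raw responses to reverse-coded items are re-keyed before entering
    the likelihood.  Deterministic given the provider and config.
    """
    config = config or CATConfig()
    cap = min(config.max_items, bank.n_items)
    if cap < config.min_items:
        raise SrsCatError(
            f"bank of {bank.n_items} items cannot satisfy min_items={config.min_items}"
        )
    kmax = bank.n_categories - 1
    state = CATState()
    responses: dict = {}
    posterior = None
    eap = config.prior.mean
    while True:
        item_id = select_next_item(state, bank, group, eap)
        raw = respondent(item_id)
        if raw is None or not 0 <= int(raw) <= kmax:
            raise CategoryRangeError(
                f"provider returned invalid category {raw!r} for item {item_id}"
            )
        keyed = (kmax - int(raw)) if item_id in bank.reverse_mask else int(raw)
        responses[item_id] = keyed
        posterior = eap_estimate(responses, bank, group, config.prior, config.grid)
        delta = (
            abs(posterior.eap - state.eap_trajectory[-1])
            if state.eap_trajectory
            else float("nan")
        )
        state.administered.append(item_id)
        state.responses.append(keyed)
        state.eap_trajectory.append(posterior.eap)
        state.se_trajectory.append(posterior.se)
        state.delta_eap.append(delta)
        eap = posterior.eap
        decision = check_stop(state, replace(config, max_items=cap))
        if decision.stop:
            reason = decision.reason
            break
        if state.n_items >= cap:
            reason = "max_items"
            break
    score = expected_test_score(posterior, bank, group)
    return CATResult(
        state=state,
        final_eap=posterior.eap,
        final_se=posterior.se,
        stop_reason=reason,
        n_items=state.n_items,
        cat_predicted_score=score,
    )


def lookup_provider(responses: dict) -> Callable:
    """Provider replaying a recorded (raw-orientation) response vector."""

    def provide(item_id):
        if item_id not in responses or responses[item_id] is None:
            raise SrsCatError(f"recorded responses lack item {item_id}")
        return int(responses[item_id])

    return provide


def simulated_provider(
    bank: ItemBank,
    theta: float,
    rng: np.random.Generator,
    group: str | None = None,
) -> Callable:
    """GRM examinee at true ``theta``: samples a keyed category on demand and
    returns it in raw orientation (reverse-coded items are un-keyed, matching
    what a real form would record)."""
    kmax = bank.n_categories - 1

    def provide(item_id):
        keyed = sample_response(bank.item(item_id, group), theta, rng)
        return (kmax - keyed) if item_id in bank.reverse_mask else keyed

    return provide


def simulate_cat_study(
    bank: ItemBank,
    thetas: Sequence[float],
    config: CATConfig | None = None,
    seed: int | None = None,
    group: str | None = None,
) -> tuple[list[CATResult], dict]:
    """Adaptive administrations for simulated examinees at each true theta.

    Returns per-respondent results and a summary of the test-length
    distribution and stop reasons.  Deterministic given ``seed`` (falls back
    to ``config.seed``).
    """
    config = config or CATConfig()
    thetas = np.asarray(thetas, dtype=float)
    if not np.all(np.isfinite(thetas)):
        raise SrsCatError("thetas must be finite")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    results = [
        administer(simulated_provider(bank, th, rng, group), bank, group, config)
        for th in thetas
    ]
    lengths = np.array([r.n_items for r in results])
    summary = {
        "n_respondents": len(results),
        "mean_n_items": float(lengths.mean()) if len(results) else float("nan"),
        "min_n_items": int(lengths.min()) if len(results) else 0,
        "max_n_items": int(lengths.max()) if len(results) else 0,
        "stop_reasons": dict(Counter(r.stop_reason for r in results)),
        "mean_final_se": float(np.mean([r.final_se for r in results]))
        if results
        else float("nan"),
    }
    return results, summary
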