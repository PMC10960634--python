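"""Dual-hypothesis Monte-Carlo co-localization test.

Two one-sided hypotheses are evaluated against property-informed simulated
nulls:

* H01 — the number of F1 motifs found inside F2 exceeds chance
  (metric: distinct F1 motifs with a qualifying overlap);
* H02 — the number of F2 motifs found inside F1 exceeds chance.

Both significant at level alpha means co-localization via reciprocal
occurrence; exactly one means one-sided co-occurrence; neither means no
association. The Monte-Carlo p-value uses the add-one estimator
``(1 + #{null >= observed}) / (1 + N)``, so the attainable minimum is
exactly ``1/(N+1)`` and ties count against rejection.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace

import numpy as np

from .core import Genome, MotifLibrary
from .overlap import count_overlapping
from .simulate import SimulationConfig, SimulationResult, ToleranceSchedule, simulate_library

__all__ = [
    "ColocalizationResult",
    "HypothesisResult",
    "TestConfig",
    "VERDICT_NONE",
    "VERDICT_ONE_SIDED",
    "VERDICT_RECIPROCAL",
    "mc_pvalue",
    "run_test",
]

VERDICT_RECIPROCAL = "colocalization_reciprocal"
VERDICT_ONE_SIDED = "cooccurrence_one_sided"
VERDICT_NONE = "none"


def mc_pvalue(observed: float, null_values: Sequence[float] | np.ndarray) -> float:
    """Upper-tail Monte-Carlo p-value with add-one correction.

    ``p = (1 + #{null >= observed}) / (1 + N)``; bounded below by
    ``1/(N+1)`` and above by 1, with ties counting toward the null.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null_values must be non-empty")
    return float((1 + np.count_nonzero(null >= observed)) / (1 + null.size))


@dataclass(frozen=True)
class TestConfig:
    """Test-level knobs: replicate count, level, threshold, simulation target.

    ``simulate`` chooses which feature is re-placed to build the nulls:
    ``"f1"`` (default) or ``"f2"`` re-place one designated feature and
    evaluate both metrics against it; ``"both"`` re-places each feature for
    the hypothesis that counts its motifs (bi-directional style).
    """

    n_simulations: int = 100
    alpha: float = 0.05
    min_overlap: int = 1
    simulate: str = "f1"

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.simulate not in {"f1", "f2", "both"}:
            raise ValueError('simulate must be "f1", "f2" or "both"')


@dataclass(frozen=True)
class HypothesisResult:
    """Observed metric, simulated null metrics and p-value for one hypothesis."""

    name: str
    counted_feature: str
    observed: int
    null_values: np.ndarray
    p_value: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if self.null_values.size > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.name,
            "counted_feature": self.counted_feature,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_simulations": int(self.null_values.size),
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class ColocalizationResult:
    """Joint outcome of the reciprocal test."""

    h01: HypothesisResult
    h02: HypothesisResult
    alpha: float
    verdict: str
    direction: str | None
    simulation: SimulationResult | None = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "verdict": self.verdict,
            "direction": self.direction,
            "h01": self.h01.to_dict(),
            "h02": self.h02.to_dict(),
        }


def _verdict(p1: float, p2: float, alpha: float) -> tuple[str, str | None]:
    s1, s2 = p1 <= alpha, p2 <= alpha
    if s1 and s2:
        return VERDICT_RECIPROCAL, None
    if s1:
        return VERDICT_ONE_SIDED, "f1_in_f2"
    if s2:
        return VERDICT_ONE_SIDED, "f2_in_f1"
    return VERDICT_NONE, None


def _derived_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence((seed, salt)).generate_state(1)[0] % (2**31))


def run_test(
    f1: MotifLibrary,
    f2: MotifLibrary,
    genome: Genome,
    sim_config: SimulationConfig | None = None,
    schedule: ToleranceSchedule | None = None,
    test_config: TestConfig | None = None,
) -> ColocalizationResult:
    """Run the reciprocal co-localization test.

    Observed metrics are the distinct-motif overlap counts in both
    directions; nulls come from ``test_config.n_simulations`` simulated
    libraries (see :class:`TestConfig` for which feature is simulated).
    """
    sim_config = sim_config or SimulationConfig()
    schedule = schedule or ToleranceSchedule()
    test_config = test_config or TestConfig()
    if f1.count == 0 or f2.count == 0:
        raise ValueError("both libraries must be non-empty")

    t = test_config.min_overlap
    obs1 = count_overlapping(f1, f2, t, pivot_label="F1").n_pivot_overlapped
    obs2 = count_overlapping(f2, f1, t, pivot_label="F2").n_pivot_overlapped

    n = test_config.n_simulations
    sim_result: SimulationResult | None = None
    if test_config.simulate in {"f1", "f2"}:
        target, other = (f1, f2) if test_config.simulate == "f1" else (f2, f1)
        cfg = replace(sim_config, n_replicates=n)
        sim_result = simulate_library(genome, target, schedule, cfg)
        if test_config.simulate == "f1":
            null1 = [count_overlapping(rep, f2, t).n_pivot_overlapped
                     for rep in sim_result.replicates]
            null2 = [count_overlapping(f2, rep, t).n_pivot_overlapped
                     for rep in sim_result.replicates]
        else:
            null1 = [count_overlapping(f1, rep, t).n_pivot_overlapped
                     for rep in sim_result.replicates]
            null2 = [count_overlapping(rep, f1, t).n_pivot_overlapped
                     for rep in sim_result.replicates]
    else:  # "both": each hypothesis re-places the feature it counts
        cfg1 = replace(sim_config, n_replicates=n,
                       seed=_derived_seed(sim_config.seed, 1))
        cfg2 = replace(sim_config, n_replicates=n,
                       seed=_derived_seed(sim_config.seed, 2))
        sims1 = simulate_library(genome, f1, schedule, cfg1)
        sims2 = simulate_library(genome, f2, schedule, cfg2)
        null1 = [count_overlapping(rep, f2, t).n_pivot_overlapped
                 for rep in sims1.replicates]
        null2 = [count_overlapping(rep, f1, t).n_pivot_overlapped
                 for rep in sims2.replicates]
        sim_result = sims1

    p1 = mc_pvalue(obs1, null1)
    p2 = mc_pvalue(obs2, null2)
    verdict, direction = _verdict(p1, p2, test_config.alpha)
    return ColocalizationResult(
        h01=HypothesisResult("H01", "F1", obs1, np.asarray(null1), p1),
        h02=HypothesisResult("H02", "F2", obs2, np.asarray(null2), p2),
        alpha=test_config.alpha,
        verdict=verdict,
        direction=direction,
        simulation=sim_result,
    )
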