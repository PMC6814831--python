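"""Stochastic simulation of prey-depletion predation trials.

The generative model is an event-driven (Gillespie-style) pure-death
process on the current prey count ``N``: a single predator kills at the
instantaneous rate

    lambda(N) = a * N / (1 + a * h * N)

and each kill removes one prey.  Integrating the deterministic limit of
this process over a trial of length ``T`` recovers exactly the random
predator equation, so the maximum-likelihood machinery in
:mod:`bioticres.functional_response` is correctly specified on data drawn
from this simulator.  A two-prey variant with competing event rates

    lambda_j(N) = a_j * N_j / (1 + sum_k a_k * h_k * N_k)

drives the prey-preference (switching) experiment.

Time is measured in experimental periods: one period is one trial
(the study's 6-h feeding window), and handling times are fractions of it.

All operations take explicit seeds; batch generators derive per-trial
sub-seeds from the master seed via ``numpy.random.SeedSequence`` spawning,
so whole datasets are reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "FRDesign",
    "SwitchDesign",
    "simulate_fr_trial",
    "simulate_fr_experiment",
    "simulate_switch_trial",
    "simulate_switch_experiment",
    "generate_study_dataset",
    "DEFAULT_GROUP_PARAMS",
]

# Ground-truth (attack rate, handling time) per predator x prey group used
# by the default study generator; values are the study-scale estimates for
# three cyclopoid copepods feeding on invasive (Aedes albopictus) and
# native (Culex pipiens) mosquito larvae.
DEFAULT_GROUP_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("M. albidus", "A. albopictus"): (2.507, 0.200),
    ("M. albidus", "C. pipiens"): (1.820, 0.214),
    ("M. fuscus", "A. albopictus"): (3.726, 0.112),
    ("M. fuscus", "C. pipiens"): (5.285, 0.166),
    ("M. viridis", "A. albopictus"): (2.549, 0.122),
    ("M. viridis", "C. pipiens"): (1.139, 0.204),
}


@dataclass(frozen=True)
class SimParams:
    """Kinetic parameters of one predator-prey pairing.

    attack_rate : per unit prey density per experimental period (> 0 for an
        active predator; 0 models an inert control).
    handling_time : experimental periods spent per prey item (>= 0).
    duration : trial length in experimental periods (> 0), default one
        full trial.
    """

    attack_rate: float
    handling_time: float
    duration: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.attack_rate) or self.attack_rate < 0:
            raise ValueError("attack rate must be finite and >= 0")
        if not np.isfinite(self.handling_time) or self.handling_time < 0:
            raise ValueError("handling time must be finite and >= 0")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError("duration must be finite and > 0")


@dataclass(frozen=True)
class FRDesign:
    """Single-prey functional-response design (densities x replicates)."""

    densities: tuple[int, ...] = (2, 4, 7, 10, 15)
    replicates: int = 5
    control_replicates: int = 1

    def __post_init__(self):
        if len(self.densities) == 0:
            raise ValueError("design needs at least one density level")
        if any(d < 1 for d in self.densities):
            raise ValueError("densities must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.control_replicates < 0:
            raise ValueError("control replicates must be >= 0")


@dataclass(frozen=True)
class SwitchDesign:
    """Two-prey switching design (availability ratios x replicates)."""

    ratios: tuple[tuple[int, int], ...] = ((2, 18), (5, 15), (10, 10), (15, 5), (18, 2))
    replicates: int = 3
    control_replicates: int = 1

    def __post_init__(self):
        if len(self.ratios) == 0:
            raise ValueError("design needs at least one availability ratio")
        if any(ni < 0 or nn < 0 or ni + nn == 0 for ni, nn in self.ratios):
            raise ValueError("ratio counts must be >= 0 and sum > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_fr_trial(params: SimParams, n0: int, seed) -> int:
    """Simulate one single-prey trial; returns the number of prey eaten.

    Event-driven: exponential waiting times at rate
    ``a N / (1 + a h N)`` on the current count, until the trial clock
    exceeds the duration or the arena is empty.
    """
    if n0 < 0:
        raise ValueError("initial prey count must be >= 0")
    rng = np.random.default_rng(seed)
    a, h, T = params.attack_rate, params.handling_time, params.duration
    n = int(n0)
    if a == 0.0 or n == 0:
        return 0
    t = 0.0
    eaten = 0
    while n > 0:
        rate = a * n / (1.0 + a * h * n)
        t += rng.exponential(1.0 / rate)
        if t > T:
            break
        n -= 1
        eaten += 1
    return eaten


def simulate_switch_trial(
    params_invader: tuple[float, float],
    params_native: tuple[float, float],
    n_i0: int,
    n_n0: int,
    T: float = 1.0,
    seed=None,
) -> tuple[int, int]:
    """Simulate one two-prey trial; returns (invader eaten, native eaten).

    Competing-risks extension of the single-prey process: at state
    ``(N_i, N_n)`` kills of type j occur at rate
    ``a_j N_j / (1 + a_i h_i N_i + a_n h_n N_n)``.
    """
    a_i, h_i = params_invader
    a_n, h_n = params_native
    for val in (a_i, h_i, a_n, h_n, T):
        if not np.isfinite(val) or val < 0:
            raise ValueError("parameters must be finite and >= 0")
    if T <= 0:
        raise ValueError("duration must be > 0")
    if n_i0 < 0 or n_n0 < 0:
        raise ValueError("initial counts must be >= 0")
    rng = np.random.default_rng(seed)
    ni, nn = int(n_i0), int(n_n0)
    ri = rn = 0
    t = 0.0
    while ni + nn > 0:
        denom = 1.0 + a_i * h_i * ni + a_n * h_n * nn
        rate_i = a_i * ni / denom
        rate_n = a_n * nn / denom
        total = rate_i + rate_n
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > T:
            break
        if rng.random() < rate_i / total:
            ni -= 1
            ri += 1
        else:
            nn -= 1
            rn += 1
    return ri, rn


def _spawn_seeds(seed, n):
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(seed).spawn(n)


def simulate_fr_experiment(
    params_by_group: dict[tuple[str, str], SimParams],
    design: FRDesign = FRDesign(),
    seed=None,
) -> pd.DataFrame:
    """Simulate a full single-prey experiment over a factorial design.

    Returns a tidy table with one row per trial: ``predator, prey,
    density, eaten, is_control, replicate_id``.  Control rows (no
    predator) always record zero deaths, mirroring the study outcome that
    100% of control prey survived.
    """
    if not params_by_group:
        raise ValueError("at least one (predator, prey) group is required")
    rows = []
    groups = sorted(params_by_group)
    n_trials = len(groups) * len(design.densities) * design.replicates
    seeds = iter(_spawn_seeds(seed, n_trials))
    for predator, prey in groups:
        params = params_by_group[(predator, prey)]
        for density in design.densities:
            for rep in range(1, design.replicates + 1):
                eaten = simulate_fr_trial(params, density, next(seeds))
                rows.append(
                    {
                        "predator": predator,
                        "prey": prey,
                        "density": density,
                        "eaten": eaten,
                        "is_control": 0,
                        "replicate_id": rep,
                    }
                )
            for rep in range(1, design.control_replicates + 1):
                rows.append(
                    {
                        "predator": "none",
                        "prey": prey,
                        "density": density,
                        "eaten": 0,
                        "is_control": 1,
                        "replicate_id": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_switch_experiment(
    params_by_predator: dict[str, dict[str, tuple[float, float]]],
    design: SwitchDesign = SwitchDesign(),
    T: float = 1.0,
    seed=None,
) -> pd.DataFrame:
    """Simulate a two-prey switching experiment.

    ``params_by_predator`` maps predator label to
    ``{"invader": (a, h), "native": (a, h)}``.  Returns a tidy table:
    ``predator, prop_invader, n_invader_0, n_native_0, eaten_invader,
    eaten_native, is_control, replicate_id``.
    """
    if not params_by_predator:
        raise ValueError("at least one predator is required")
    rows = []
    predators = sorted(params_by_predator)
    n_trials = len(predators) * len(design.ratios) * design.replicates
    seeds = iter(_spawn_seeds(seed, n_trials))
    for predator in predators:
        pi = params_by_predator[predator]["invader"]
        pn = params_by_predator[predator]["native"]
        for n_i0, n_n0 in design.ratios:
            prop = n_i0 / (n_i0 + n_n0)
            for rep in range(1, design.replicates + 1):
                ri, rn = simulate_switch_trial(pi, pn, n_i0, n_n0, T=T, seed=next(seeds))
                rows.append(
                    {
                        "predator": predator,
                        "prop_invader": round(prop, 6),
                        "n_invader_0": n_i0,
                        "n_native_0": n_n0,
                        "eaten_invader": ri,
                        "eaten_native": rn,
                        "is_control": 0,
                        "replicate_id": rep,
                    }
                )
            for rep in range(1, design.control_replicates + 1):
                rows.append(
                    {
                        "predator": "none",
                        "prop_invader": round(prop, 6),
                        "n_invader_0": n_i0,
                        "n_native_0": n_n0,
                        "eaten_invader": 0,
                        "eaten_native": 0,
                        "is_control": 1,
                        "replicate_id": rep,
                    }
                )
    return pd.DataFrame(rows)


def generate_study_dataset(
    group_params: dict[tuple[str, str], tuple[float, float]] | None = None,
    invader_prey: str = "A. albopictus",
    fr_design: FRDesign = FRDesign(),
    switch_design: SwitchDesign = SwitchDesign(),
    T: float = 1.0,
    seed=None,
):
    """Emulate the full study: FR trials, switching trials, ground truth.

    Uses each predator's (a, h) towards the invader and the native prey for
    both the single-prey and the two-prey simulations.  Returns
    ``(fr_table, switch_table, ground_truth)`` where ``ground_truth`` is a
    JSON-serialisable record of the generating parameters, designs and
    seed, kept for parameter-recovery tests.
    """
    if group_params is None:
        group_params = DEFAULT_GROUP_PARAMS
    preys = sorted({prey for _, prey in group_params})
    predators = sorted({pred for pred, _ in group_params})
    if invader_prey not in preys:
        raise ValueError(f"invader prey {invader_prey!r} absent from group parameters")
    for pred in predators:
        for prey in preys:
            if (pred, prey) not in group_params:
                raise ValueError(f"missing parameters for group ({pred!r}, {prey!r})")

    ss_fr, ss_switch = np.random.SeedSequence(seed).spawn(2)
    sim_params = {
        key: SimParams(attack_rate=a, handling_time=h, duration=T)
        for key, (a, h) in group_params.items()
    }
    fr_table = simulate_fr_experiment(sim_params, fr_design, seed=ss_fr)

    natives = [p for p in preys if p != invader_prey]
    if len(natives) != 1:
        raise ValueError("exactly one native prey is required for the switching design")
    native_prey = natives[0]
    switch_params = {
        pred: {
            "invader": group_params[(pred, invader_prey)],
            "native": group_params[(pred, native_prey)],
        }
        for pred in predators
    }
    switch_table = simulate_switch_experiment(switch_params, switch_design, T=T, seed=ss_switch)

    ground_truth = {
        "seed": None if seed is None else int(seed),
        "duration": T,
        "invader_prey": invader_prey,
        "native_prey": native_prey,
        "groups": {
            f"{pred}|{prey}": {"attack_rate": a, "handling_time": h}
            for (pred, prey), (a, h) in sorted(group_params.items())
        },
        "fr_design": {
            "densities": list(fr_design.densities),
            "replicates": fr_design.replicates,
            "control_replicates": fr_design.control_replicates,
        },
        "switch_design": {
            "ratios": [list(r) for r in switch_design.ratios],
            "replicates": switch_design.replicates,
            "control_replicates": switch_design.control_replicates,
        },
    }
    return fr_table, switch_table, ground_truth
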