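"""Canned study conditions for the switching-state simulator.

These presets pin down the simulated geometry used throughout the package's
examples and validation runs: 68 regions, 100 volumes at TR = 3 s, block
states built on the packaged 5-module atlas (SSM/TIL/TPN/TNN/VIS), moderate
measurement noise, and Markov switching with dwell times of a few to a few
tens of volumes.

Two state families are provided:

* ``recovery_states`` — a 2-module and a 3-module state whose super-groupings
  of the five base modules differ, so that every pair of base modules is
  separated in at least one state.  Consensus co-assignment over a cohort
  then recovers all five base modules, and the per-window module count
  tracks which state is active.
* ``contrast_states`` — a "posterior-strong" and an "anterior-strong" state
  that move the posterior versus anterior DMN sub-networks above or below
  the average within-module strength of the task-negative module, emulating
  the direction of the patient-versus-control dwell-time contrast.
"""

from __future__ import annotations

import numpy as np

from . import atlas
from .synthetic_bold import CohortSubject, StateSpec, generate_cohort

__all__ = [
    "recovery_states",
    "contrast_states",
    "two_state_transition",
    "recovery_cohort",
    "contrast_cohort",
]

DEFAULT_RHO_IN = 0.8
DEFAULT_RHO_OUT = -0.25
DEFAULT_NOISE_SD = 0.25
DEFAULT_RELAX_RATE = 0.1


def _relabel(groups: dict, base: np.ndarray) -> np.ndarray:
    """Map base-module labels to state community labels via ``groups``."""
    out = np.empty_like(base)
    for community, base_labels in groups.items():
        for b in base_labels:
            out[base == b] = community
    return out


def recovery_states(rho_in: float = DEFAULT_RHO_IN, rho_out: float = DEFAULT_RHO_OUT) -> list:
    """A 2-module and a 3-module state over the atlas's five base modules.

    State 1 groups {SSM, TIL, TNN} against {TPN, VIS}; state 2 groups
    {SSM, TPN} / {TIL, VIS} / {TNN}.  Every base-module pair is split in at
    least one state, so co-assignment pooled over both distinguishes all
    five.
    """
    base = atlas.final_assignment()
    s1 = _relabel({1: [1, 2, 4], 2: [3, 5]}, base)
    s2 = _relabel({1: [1, 3], 2: [2, 5], 3: [4]}, base)
    return [
        StateSpec(state_id=1, community_map=s1, rho_in=rho_in, rho_out=rho_out),
        StateSpec(state_id=2, community_map=s2, rho_in=rho_in, rho_out=rho_out),
    ]


def contrast_states(rho_in: float = DEFAULT_RHO_IN, rho_out: float = DEFAULT_RHO_OUT) -> list:
    """A posterior-strong and an anterior-strong DMN state.

    In the posterior-strong state the posterior/dorsal/ventral DMN nodes
    (42-53) form a tight community with the visual module, lifting their
    within-TNN strength above the TNN average; in the anterior-strong state
    the anterior DMN and cingulate nodes (54-60) cohere with TIL while nodes
    42-47 and 48-53 are split apart, putting the anterior composite z above
    zero instead.
    """
    node = np.arange(1, 69)
    base = atlas.final_assignment()
    post = np.where(((node >= 42) & (node <= 53)) | (base == 5), 1, 2)
    ant = np.full(68, 3)
    ant[np.isin(base, [2]) | ((node >= 54) & (node <= 60))] = 1
    ant[(base == 1) | ((node >= 42) & (node <= 47))] = 2
    return [
        StateSpec(state_id=1, community_map=post, rho_in=rho_in, rho_out=rho_out),
        StateSpec(state_id=2, community_map=ant, rho_in=rho_in, rho_out=rho_out),
    ]


def two_state_transition(occupancy_first: float = 0.7, relax_rate: float = DEFAULT_RELAX_RATE) -> np.ndarray:
    """2-state Markov transition with stationary occupancy ``occupancy_first``.

    ``relax_rate`` sets how fast the chain forgets its state (expected dwell
    in state 1 is ``1 / (relax_rate * (1 - occupancy_first))`` volumes).
    """
    if not 0 < occupancy_first < 1:
        raise ValueError("occupancy_first must lie in (0, 1)")
    p12 = relax_rate * (1.0 - occupancy_first)
    p21 = relax_rate * occupancy_first
    return np.array([[1.0 - p12, p12], [p21, 1.0 - p21]])


def recovery_cohort(
    n_subjects: int = 20,
    occupancy_two_module: float = 0.7,
    T: int = 100,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> list:
    """Single-group cohort switching between the 2- and 3-module recovery states."""
    transition = two_state_transition(occupancy_two_module)
    return generate_cohort(
        n_per_group={"sim": n_subjects},
        group_transitions={"sim": transition},
        specs=recovery_states(),
        initial=np.array([occupancy_two_module, 1.0 - occupancy_two_module]),
        T=T,
        noise_sd=noise_sd,
        seed=seed,
    )


def contrast_cohort(
    n_per_group: dict | None = None,
    posterior_occupancy: dict | None = None,
    T: int = 100,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> list:
    """Two-group cohort with a planted shift in anterior- vs posterior-strong occupancy.

    Default: group "CN" occupies the posterior-strong state 70% of the time,
    group "AD" 30% — i.e. AD dwells more in the anterior-strong state.
    """
    n_per_group = n_per_group or {"CN": 10, "AD": 10}
    posterior_occupancy = posterior_occupancy or {"CN": 0.7, "AD": 0.3}
    transitions = {g: two_state_transition(occ) for g, occ in posterior_occupancy.items()}
    return generate_cohort(
        n_per_group=n_per_group,
        group_transitions=transitions,
        specs=contrast_states(),
        initial=np.array([0.5, 0.5]),
        T=T,
        noise_sd=noise_sd,
        seed=seed,
    )
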