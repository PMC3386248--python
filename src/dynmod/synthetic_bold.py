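"""Switching-state ROI time-series simulator.

Generates cohorts of band-limited, BOLD-like multivariate signals whose
instantaneous correlation structure switches among a small set of modular
"brain states".  Each state is a block-equicorrelated matrix: regions that
share a community correlate at ``rho_in``, regions in different communities
at ``rho_out``.  The latent state sequence is a first-order Markov chain, so
dwell in a state is governed by its self-transition probability.

Every generated subject carries its :class:`SwitchingGroundTruth` — the
latent sequence, the state specifications and the realized per-state
occupancy — so downstream dwell-time and meta-module estimates can be scored
against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StateSpec",
    "SwitchingGroundTruth",
    "RoiTimeSeries",
    "CohortSubject",
    "generate_state_sequence",
    "generate_bold",
    "generate_cohort",
]

_PSD_TOL = 1e-10


def _block_correlation(community_map: np.ndarray, rho_in: float, rho_out: float) -> np.ndarray:
    same = community_map[:, None] == community_map[None, :]
    corr = np.where(same, rho_in, rho_out)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass(frozen=True)
class StateSpec:
    """One modular brain state: a community map plus its two correlation levels.

    ``community_map`` holds per-node community labels, contiguous integers
    starting at 1.  ``rho_in`` is the within-community correlation in (0, 1);
    ``rho_out`` the between-community correlation in (-1, 0].  The implied
    N x N correlation matrix must be positive semi-definite; construction
    fails otherwise.
    """

    state_id: int
    community_map: np.ndarray
    rho_in: float
    rho_out: float

    def __post_init__(self) -> None:
        cmap = np.asarray(self.community_map, dtype=int)
        object.__setattr__(self, "community_map", cmap)
        if cmap.ndim != 1 or cmap.size < 2:
            raise ValueError("community_map must be a 1-D array with at least 2 nodes")
        labels = np.unique(cmap)
        if not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ValueError(
                "community labels must be contiguous integers starting at 1, "
                f"got {labels.tolist()}"
            )
        if not (0.0 < self.rho_in < 1.0):
            raise ValueError(f"rho_in must lie in (0, 1), got {self.rho_in}")
        if not (-1.0 < self.rho_out <= 0.0):
            raise ValueError(f"rho_out must lie in (-1, 0], got {self.rho_out}")
        corr = _block_correlation(cmap, self.rho_in, self.rho_out)
        min_eig = float(np.linalg.eigvalsh(corr)[0])
        if min_eig < -_PSD_TOL:
            raise ValueError(
                f"state {self.state_id}: correlation structure is not positive "
                f"semi-definite (min eigenvalue {min_eig:.3e}); "
                "reduce |rho_out| or rho_in"
            )

    @property
    def n_nodes(self) -> int:
        return int(self.community_map.size)

    @property
    def n_communities(self) -> int:
        return int(self.community_map.max())

    def correlation(self) -> np.ndarray:
        """The N x N block-equicorrelated correlation matrix of this state."""
        return _block_correlation(self.community_map, self.rho_in, self.rho_out)

    def to_dict(self) -> dict:
        return {
            "state_id": self.state_id,
            "community_map": self.community_map.tolist(),
            "rho_in": self.rho_in,
            "rho_out": self.rho_out,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StateSpec":
        return cls(
            state_id=int(d["state_id"]),
            community_map=np.asarray(d["community_map"], dtype=int),
            rho_in=float(d["rho_in"]),
            rho_out=float(d["rho_out"]),
        )


@dataclass(frozen=True)
class SwitchingGroundTruth:
    """Latent state sequence, state specs and realized occupancy for one subject."""

    state_sequence: np.ndarray
    specs: tuple
    occupancy: dict

    def __post_init__(self) -> None:
        seq = np.asarray(self.state_sequence, dtype=int)
        object.__setattr__(self, "state_sequence", seq)
        object.__setattr__(self, "specs", tuple(self.specs))
        known = {s.state_id for s in self.specs}
        present = set(np.unique(seq).tolist())
        if not present <= known:
            raise ValueError(f"state_sequence contains unknown state ids {sorted(present - known)}")
        total = sum(self.occupancy.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy must sum to 1, sums to {total}")

    @classmethod
    def from_sequence(cls, seq: np.ndarray, specs: Sequence[StateSpec]) -> "SwitchingGroundTruth":
        seq = np.asarray(seq, dtype=int)
        ids, counts = np.unique(seq, return_counts=True)
        occ = {int(i): float(c) / seq.size for i, c in zip(ids, counts)}
        return cls(state_sequence=seq, specs=tuple(specs), occupancy=occ)

    @property
    def n_nodes(self) -> int:
        return self.specs[0].n_nodes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "state_sequence": self.state_sequence.tolist(),
            "specs": [s.to_dict() for s in self.specs],
            "occupancy": {str(k): v for k, v in self.occupancy.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SwitchingGroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            state_sequence=np.asarray(payload["state_sequence"], dtype=int),
            specs=tuple(StateSpec.from_dict(d) for d in payload["specs"]),
            occupancy={int(k): float(v) for k, v in payload["occupancy"].items()},
        )


@dataclass
class RoiTimeSeries:
    """One subject's volumes x regions signal block with its sampling interval."""

    data: np.ndarray
    tr_seconds: float
    region_ids: list
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (volumes x regions)")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise ValueError(f"need at least 2 volumes and 2 regions, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.region_ids = [str(r) for r in self.region_ids]
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match number of regions")
        if len(set(self.region_ids)) != n:
            raise ValueError("region_ids must be unique")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortSubject:
    """A simulated subject: its series, group label and generative ground truth."""

    timeseries: RoiTimeSeries
    group: str
    truth: SwitchingGroundTruth


def _validate_transition(transition: np.ndarray, n_states: int) -> np.ndarray:
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (n_states, n_states):
        raise ValueError(f"transition table must be {n_states}x{n_states}, got {transition.shape}")
    if np.any(transition < 0):
        raise ValueError("transition probabilities must be non-negative")
    row_sums = transition.sum(axis=1)
    bad = np.where(np.abs(row_sums - 1.0) > 1e-9)[0]
    if bad.size:
        raise ValueError(
            f"transition rows {bad.tolist()} are not stochastic (sums {row_sums[bad].tolist()})"
        )
    return transition


def generate_state_sequence(
    T: int,
    transition: np.ndarray,
    initial: np.ndarray,
    seed: int | np.random.Generator,
    state_ids: Sequence[int] | None = None,
) -> np.ndarray:
    """Sample a length-``T`` Markov state sequence.

    The first entry is drawn from ``initial``; entry ``t+1`` from the
    transition row of entry ``t``.  ``state_ids`` maps chain indices to
    state ids (default ``1..K``).  Identical seed gives an identical
    sequence.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    initial = np.asarray(initial, dtype=float)
    k = initial.size
    if abs(initial.sum() - 1.0) > 1e-9 or np.any(initial < 0):
        raise ValueError("initial distribution must be non-negative and sum to 1")
    transition = _validate_transition(transition, k)
    ids = np.arange(1, k + 1) if state_ids is None else np.asarray(state_ids, dtype=int)
    if ids.size != k:
        raise ValueError("state_ids length must match transition size")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = np.empty(T, dtype=int)
    idx[0] = rng.choice(k, p=initial)
    for t in range(1, T):
        idx[t] = rng.choice(k, p=transition[idx[t - 1]])
    return ids[idx]


def _moving_average(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Symmetric moving average over the time axis, edges renormalized."""
    if halfwidth <= 0:
        return x
    w = 2 * halfwidth + 1
    kernel = np.ones(w)
    t = x.shape[0]
    counts = np.convolve(np.ones(t), kernel, mode="same")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(x[:, j], kernel, mode="same") / counts
    return out


def generate_bold(
    truth: SwitchingGroundTruth,
    noise_sd: float = 0.5,
    smoothing_halfwidth: int = 1,
    seed: int | np.random.Generator = 0,
    tr_seconds: float = 3.0,
    subject_id: str = "sim",
    region_ids: Sequence[str] | None = None,
) -> RoiTimeSeries:
    """Emit a BOLD-like series realizing ``truth``'s switching correlation structure.

    At each volume a zero-mean multivariate normal draw with the active
    state's block correlation is taken, white noise at ``noise_sd`` is added,
    and a symmetric moving-average smoother of the given halfwidth (in
    volumes) is applied to mimic the temporal autocorrelation of band-limited
    signals.  Deterministic under ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = truth.n_nodes
    for s in truth.specs:
        if s.n_nodes != n:
            raise ValueError("all states must share the same node count")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chol = {s.state_id: np.linalg.cholesky(s.correlation() + 1e-9 * np.eye(n)) for s in truth.specs}
    T = truth.state_sequence.size
    z = rng.standard_normal((T, n))
    data = np.empty((T, n))
    for t, sid in enumerate(truth.state_sequence):
        data[t] = chol[int(sid)] @ z[t]
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal((T, n))
    data = _moving_average(data, smoothing_halfwidth)
    if region_ids is None:
        region_ids = [f"roi{i + 1}" for i in range(n)]
    return RoiTimeSeries(data=data, tr_seconds=tr_seconds, region_ids=list(region_ids), subject_id=subject_id)


def generate_cohort(
    n_per_group: Mapping[str, int],
    group_transitions: Mapping[str, np.ndarray],
    specs: Sequence[StateSpec],
    initial: np.ndarray | None = None,
    T: int = 100,
    tr_seconds: float = 3.0,
    noise_sd: float = 0.5,
    smoothing_halfwidth: int = 1,
    seed: int = 0,
) -> list:
    """Simulate a labelled cohort sharing one StateSpec list.

    Each group has its own state-transition table (over the shared states),
    which is how between-group occupancy contrasts are planted.  Per-subject
    seeds are spawned deterministically from the master ``seed``.
    """
    specs = tuple(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    n = specs[0].n_nodes
    for s in specs:
        if s.n_nodes != n:
            raise ValueError("all StateSpecs must share the same node count")
    k = len(specs)
    ids = [s.state_id for s in specs]
    if len(set(ids)) != k:
        raise ValueError("state ids must be unique")
    if set(n_per_group) != set(group_transitions):
        raise ValueError("n_per_group and group_transitions must have the same group labels")
    if initial is None:
        initial = np.full(k, 1.0 / k)
    ss = np.random.SeedSequence(seed)
    total = sum(n_per_group.values())
    children = ss.spawn(total)
    subjects: list[CohortSubject] = []
    i = 0
    for group in sorted(n_per_group):
        transition = _validate_transition(group_transitions[group], k)
        for j in range(n_per_group[group]):
            rng = np.random.default_rng(children[i])
            seq = generate_state_sequence(T, transition, initial, rng, state_ids=ids)
            truth = SwitchingGroundTruth.from_sequence(seq, specs)
            ts = generate_bold(
                truth,
                noise_sd=noise_sd,
                smoothing_halfwidth=smoothing_halfwidth,
                seed=rng,
                tr_seconds=tr_seconds,
                subject_id=f"{group}{j + 1:03d}",
            )
            subjects.append(CohortSubject(timeseries=ts, group=group, truth=truth))
            i += 1
    return subjects
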