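"""Sub-network dwell time under a fixed modular assignment and two-group tests.

A sub-network (e.g. the four anterior-DMN nodes inside the task-negative
module) "strongly contributes" to a windowed brain state when its composite
within-module degree Z-score — the mean z of its nodes, computed under the
fixed final 5-module assignment — is strictly positive.  The percentage of a
subject's windows in which that holds is the sub-network's dwell time.
Group contrasts use the two-sided Wilcoxon rank-sum test (exact enumeration
when the combined sample is small and tie-free) and the chi-squared test for
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dynamics import DwellTimeProfile
from .signed_modularity import within_module_degree_z
from .windows import ConnectivityMatrix, DynamicConnectivity

__all__ = [
    "SubnetworkDefinition",
    "GroupComparisonResult",
    "subnetwork_composite_z",
    "subnetwork_dwell_time",
    "compare_groups",
    "compare_proportions",
]


@dataclass(frozen=True)
class SubnetworkDefinition:
    """A named 4-node sub-network, identified by 1-based node ids."""

    name: str
    node_ids: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_ids", tuple(int(i) for i in self.node_ids))
        if len(self.node_ids) != 4:
            raise ValueError(f"sub-network {self.name} must have exactly 4 nodes")
        if len(set(self.node_ids)) != 4:
            raise ValueError(f"sub-network {self.name} has duplicate nodes")


@dataclass
class GroupComparisonResult:
    """Medians with quartiles per group, plus the two-group p-value."""

    group_medians_iqr: dict  # label -> (median, q1, q3)
    p_value: float
    test_name: str
    statistic: float = float("nan")


def _median_iqr(values: np.ndarray) -> tuple:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def subnetwork_composite_z(
    graph: ConnectivityMatrix,
    fixed_labels: np.ndarray,
    subnet: SubnetworkDefinition,
    weight_mode: str = "signed",
) -> float:
    """Mean within-module degree Z-score of the sub-network's 4 nodes.

    Z-scores are computed under the fixed module assignment (not the
    window's own detected partition), so a positive composite means the
    sub-network is an above-average hub within its module in this window.
    """
    fixed_labels = np.asarray(fixed_labels, dtype=int)
    n = graph.n_nodes
    if fixed_labels.size != n:
        raise ValueError("fixed_labels must cover all nodes")
    idx = np.asarray(subnet.node_ids, dtype=int) - 1
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError(f"sub-network {subnet.name} has node ids outside the partition")
    z = within_module_degree_z(graph, fixed_labels, weight_mode=weight_mode).within_module_z
    return float(z[idx].mean())


def subnetwork_dwell_time(
    dyn: DynamicConnectivity,
    fixed_labels: np.ndarray,
    subnets: Sequence[SubnetworkDefinition],
    weight_mode: str = "signed",
    per_window_partitions: Sequence | None = None,
) -> DwellTimeProfile:
    """Percentage of windows in which each sub-network strongly contributes.

    "Strong" is composite z strictly greater than 0; a composite of exactly 0
    does not count.  Each sub-network's percentage is computed independently,
    so the values do not sum to 100.

    By default z-scores are taken under the fixed module assignment; passing
    ``per_window_partitions`` (one detected :class:`Partition` per window)
    instead standardizes each window under its own partition, as a
    sensitivity analysis.
    """
    if dyn.n_windows == 0:
        raise ValueError("dynamic connectivity has no windows")
    if per_window_partitions is not None and len(per_window_partitions) != dyn.n_windows:
        raise ValueError("per_window_partitions must have one partition per window")
    fixed_labels = np.asarray(fixed_labels, dtype=int)
    n = dyn.graphs[0].n_nodes
    idx = {}
    for subnet in subnets:
        ids = np.asarray(subnet.node_ids, dtype=int) - 1
        if ids.min() < 0 or ids.max() >= n:
            raise ValueError(f"sub-network {subnet.name} has node ids outside the partition")
        idx[subnet.name] = ids
    strong = {name: 0 for name in idx}
    for w, g in enumerate(dyn.graphs):
        labels = (
            per_window_partitions[w].labels if per_window_partitions is not None else fixed_labels
        )
        z = within_module_degree_z(g, labels, weight_mode=weight_mode).within_module_z
        for name, ids in idx.items():
            if z[ids].mean() > 0.0:
                strong[name] += 1
    pct = {name: 100.0 * c / dyn.n_windows for name, c in strong.items()}
    return DwellTimeProfile(subject_id=dyn.subject_id, percentages=pct)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    labels: tuple = ("A", "B"),
) -> GroupComparisonResult:
    """Two-sided Wilcoxon rank-sum comparison of two independent samples.

    Uses exact enumeration of the rank-sum distribution when the combined
    sample size is at most 20 and there are no ties; otherwise the normal
    approximation with tie correction (no continuity correction, so two
    identical samples give p = 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        test_name = "wilcoxon-rank-sum-exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        test_name = "wilcoxon-rank-sum-normal"
    return GroupComparisonResult(
        group_medians_iqr={labels[0]: _median_iqr(a), labels[1]: _median_iqr(b)},
        p_value=float(min(res.pvalue, 1.0)),
        test_name=test_name,
        statistic=float(res.statistic),
    )


def compare_proportions(
    count_a: tuple,
    count_b: tuple,
    correction: bool = False,
) -> GroupComparisonResult:
    """Chi-squared test on a 2x2 table of successes/totals (no continuity
    correction by default)."""
    sa, ta = int(count_a[0]), int(count_a[1])
    sb, tb = int(count_b[0]), int(count_b[1])
    if ta < 1 or tb < 1:
        raise ValueError("totals must be >= 1")
    if not (0 <= sa <= ta and 0 <= sb <= tb):
        raise ValueError("successes must lie between 0 and the total")
    table = np.array([[sa, ta - sa], [sb, tb - sb]], dtype=float)
    if sa / ta == sb / tb:
        # identical proportions: statistic is exactly 0 by construction
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    pa, pb = sa / ta, sb / tb
    return GroupComparisonResult(
        group_medians_iqr={"A": (pa, pa, pa), "B": (pb, pb, pb)},
        p_value=float(p),
        test_name="chi-squared" + ("-yates" if correction else ""),
        statistic=float(chi2),
    )
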