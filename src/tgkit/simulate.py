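"""Synthetic fixtures with planted structure.

Generators emulating the matrix shapes that transmission-inference tools
export, each paired with a :class:`PlantedTruth` recording exactly which
pairs were planted as related:

- SNP-distance-like symmetric matrices with cleanly separated clusters
  (within-cluster values below ``within_max``, between-cluster above
  ``between_min``), so any threshold in the gap recovers the planted
  clusters exactly;
- asymmetric directed-transmission-probability matrices with between-cluster
  entries imputed as exactly zero and independent per-direction draws
  within clusters;
- IBD-fraction matrices in [0, 1] with planted clonal pairs near 1 against
  a near-zero background, so a 0.2 relatedness cutoff recovers the clonal
  pairs exactly;
- categorical metadata tables (e.g. geographic region, resistance class).

Separation between planted-related and unrelated value ranges is enforced
by construction, not probabilistic: the recovery contracts these fixtures
back are exact, never flaky. Values are structural stand-ins — no sequence
evolution or epidemic process is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .convert import PairwiseTable
from .errors import SimulationParameterError


@dataclass
class PlantedTruth:
    """Ground truth for a simulated matrix.

    ``membership`` maps node id → planted cluster index. ``related_pairs``
    is the exact set of pairs meant to pass the target comparison: frozenset
    pairs for symmetric fixtures, (source, target) tuples for directed ones.
    ``params`` echoes the generation parameters including the seed.
    """

    membership: dict[str, int] = field(default_factory=dict)
    related_pairs: set = field(default_factory=set)
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.membership.values()))

    def cluster_members(self) -> list[list[str]]:
        """Planted clusters as id lists, largest first (ties by smallest id)."""
        by_index: dict[int, list[str]] = {}
        for nid, idx in self.membership.items():
            by_index.setdefault(idx, []).append(nid)
        clusters = [sorted(m) for m in by_index.values()]
        clusters.sort(key=lambda m: (-len(m), m[0]))
        return clusters


def _labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def _cluster_assignment(n_nodes: int, n_clusters: int) -> list[int]:
    if n_clusters < 1 or n_clusters > n_nodes:
        raise SimulationParameterError(
            f"n_clusters must be in [1, {n_nodes}], got {n_clusters}"
        )
    # contiguous blocks, as even as possible
    base, extra = divmod(n_nodes, n_clusters)
    assignment: list[int] = []
    for k in range(n_clusters):
        assignment.extend([k] * (base + (1 if k < extra else 0)))
    return assignment


def simulate_distance_matrix(
    n_nodes: int,
    n_clusters: int,
    within_max: float,
    between_min: float,
    seed: int,
) -> tuple[PairwiseTable, PlantedTruth]:
    """Symmetric distance matrix with enforced cluster separation.

    Within-cluster pair values are uniform on [0, ``within_max``];
    between-cluster on [``between_min``, 2·``between_min``]. Requires
    ``within_max < between_min`` so that every threshold in the gap
    reproduces the planted clusters exactly. Zero diagonal; deterministic
    per seed.
    """
    if within_max >= between_min:
        raise SimulationParameterError(
            f"within_max ({within_max}) must be < between_min ({between_min})"
        )
    rng = np.random.default_rng(seed)
    labels = _labels(n_nodes)
    assignment = _cluster_assignment(n_nodes, n_clusters)
    values = np.zeros((n_nodes, n_nodes))
    related: set[frozenset[str]] = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if assignment[i] == assignment[j]:
                v = rng.uniform(0.0, within_max)
                related.add(frozenset((labels[i], labels[j])))
            else:
                v = rng.uniform(between_min, 2.0 * between_min)
            values[i, j] = values[j, i] = v
    truth = PlantedTruth(
        membership=dict(zip(labels, assignment)),
        related_pairs=related,
        params={
            "kind": "distance",
            "n_nodes": n_nodes,
            "n_clusters": n_clusters,
            "within_max": within_max,
            "between_min": between_min,
            "seed": seed,
        },
    )
    return PairwiseTable(labels=labels, values=values), truth


def simulate_probability_matrix(
    n_nodes: int,
    n_clusters: int,
    seed: int,
) -> tuple[PairwiseTable, PlantedTruth]:
    """Asymmetric directed-transmission-probability matrix.

    Within-cluster ordered pairs draw a probability independently per
    direction on the open interval (0, 1); between-cluster entries are
    exactly 0 (zero-imputed, as when per-cluster inference never considers
    cross-cluster transmission). Zero diagonal.
    """
    rng = np.random.default_rng(seed)
    labels = _labels(n_nodes)
    assignment = _cluster_assignment(n_nodes, n_clusters)
    values = np.zeros((n_nodes, n_nodes))
    related: set[tuple[str, str]] = set()
    eps = 1e-9
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and assignment[i] == assignment[j]:
                values[i, j] = rng.uniform(eps, 1.0 - eps)
                related.add((labels[i], labels[j]))
    truth = PlantedTruth(
        membership=dict(zip(labels, assignment)),
        related_pairs=related,
        params={
            "kind": "probability",
            "n_nodes": n_nodes,
            "n_clusters": n_clusters,
            "seed": seed,
        },
    )
    return PairwiseTable(labels=labels, values=values), truth


def simulate_ibd_matrix(
    n_nodes: int,
    n_clonal_pairs: int,
    seed: int,
) -> tuple[PairwiseTable, PlantedTruth]:
    """Symmetric IBD-fraction matrix in [0, 1] with planted clonal pairs.

    Clonal pairs draw a relatedness on [0.9, 1.0]; every other pair stays in
    the [0, 0.1] background, so a relatedness cutoff of 0.2 recovers exactly
    the planted pairs. The diagonal is 1 (every isolate is clonal with
    itself). Requires ``n_clonal_pairs ≤ n_nodes // 2`` (pairs are disjoint).
    """
    if n_clonal_pairs < 0 or n_clonal_pairs > n_nodes // 2:
        raise SimulationParameterError(
            f"n_clonal_pairs must be in [0, {n_nodes // 2}], got {n_clonal_pairs}"
        )
    rng = np.random.default_rng(seed)
    labels = _labels(n_nodes)
    order = rng.permutation(n_nodes)
    values = rng.uniform(0.0, 0.1, size=(n_nodes, n_nodes))
    values = (values + values.T) / 2.0
    related: set[frozenset[str]] = set()
    membership = {label: -1 for label in labels}
    for k in range(n_clonal_pairs):
        i, j = int(order[2 * k]), int(order[2 * k + 1])
        v = rng.uniform(0.9, 1.0)
        values[i, j] = values[j, i] = v
        related.add(frozenset((labels[i], labels[j])))
        membership[labels[i]] = membership[labels[j]] = k
    np.fill_diagonal(values, 1.0)
    truth = PlantedTruth(
        membership=membership,
        related_pairs=related,
        params={
            "kind": "ibd",
            "n_nodes": n_nodes,
            "n_clonal_pairs": n_clonal_pairs,
            "seed": seed,
        },
    )
    return PairwiseTable(labels=labels, values=values), truth


def simulate_metadata(
    node_ids: Sequence[str],
    categorical_specs: Mapping[str, Sequence[str]],
    seed: int,
) -> pd.DataFrame:
    """Categorical metadata: one row per node id, values drawn uniformly.

    ``categorical_specs`` maps attribute name → candidate values, e.g.
    ``{"region": ["Tierralta", "Other"]}``.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, list] = {"id": [str(nid) for nid in node_ids]}
    for name, choices in categorical_specs.items():
        choices = list(choices)
        if not choices:
            raise SimulationParameterError(f"categorical spec {name!r} has no values")
        data[name] = [choices[int(k)] for k in rng.integers(0, len(choices), len(node_ids))]
    return pd.DataFrame(data)
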