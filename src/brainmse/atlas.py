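"""Resting-state-network atlas: node-to-network membership.

Ships the 90-node / 14-network functional parcellation used throughout
the analysis (Stanford FIND lab functional ROIs), expressed as contiguous
1-based node-index ranges per network, plus a uniform synthetic atlas for
cohorts with other node counts.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RsnAtlas", "STANFORD_RSN_RANGES", "stanford_atlas", "uniform_atlas"]

# (network name, first node, last node), 1-based inclusive ranges.
STANFORD_RSN_RANGES: tuple[tuple[str, int, int], ...] = (
    ("auditory", 1, 3),
    ("basal_ganglia", 4, 7),
    ("dorsal_DMN", 8, 17),
    ("primary_visual", 18, 19),
    ("language", 20, 26),
    ("LECN", 27, 32),
    ("sensorimotor", 33, 38),
    ("posterior_salience", 39, 50),
    ("precuneus", 51, 54),
    ("higher_visual", 55, 56),
    ("RECN", 57, 62),
    ("anterior_salience", 63, 69),
    ("ventral_DMN", 70, 79),
    ("visuospatial", 80, 90),
)


@dataclass(frozen=True)
class RsnAtlas:
    """Ordered node labels and their resting-state-network membership.

    ``membership`` maps the 1-based node index to a network name; every
    node belongs to exactly one network.
    """

    node_labels: tuple[str, ...]
    membership: dict[int, str]
    network_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.node_labels)
        if set(self.membership) != set(range(1, n + 1)):
            raise ValueError("every node must be mapped to exactly one network")
        unknown = set(self.membership.values()) - set(self.network_names)
        if unknown:
            raise ValueError(f"membership references unknown networks: {unknown}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def nodes_in(self, network: str) -> list[int]:
        """1-based indices of the nodes belonging to ``network``."""
        return [i for i, net in sorted(self.membership.items()) if net == network]


def stanford_atlas() -> RsnAtlas:
    """The embedded 90-node, 14-RSN atlas."""
    membership: dict[int, str] = {}
    for name, lo, hi in STANFORD_RSN_RANGES:
        for node in range(lo, hi + 1):
            membership[node] = name
    labels = tuple(f"node{i:03d}" for i in range(1, 91))
    names = tuple(name for name, _, _ in STANFORD_RSN_RANGES)
    return RsnAtlas(node_labels=labels, membership=membership, network_names=names)


def uniform_atlas(n_nodes: int, n_networks: int = 4) -> RsnAtlas:
    """Synthetic atlas splitting ``n_nodes`` into near-equal contiguous networks."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    n_networks = min(n_networks, n_nodes)
    bounds = [round(k * n_nodes / n_networks) for k in range(n_networks + 1)]
    membership: dict[int, str] = {}
    names = tuple(f"net{k + 1:02d}" for k in range(n_networks))
    for k in range(n_networks):
        for node in range(bounds[k] + 1, bounds[k + 1] + 1):
            membership[node] = names[k]
    labels = tuple(f"node{i:03d}" for i in range(1, n_nodes + 1))
    return RsnAtlas(node_labels=labels, membership=membership, network_names=names)
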