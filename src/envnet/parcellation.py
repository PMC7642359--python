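"""The 32-node / six-RSN parcellation used for the connectome.

Nodes are grouped into six canonical resting-state networks: dorsal attention
(DAN, 6 nodes), ventral attention (VAN, 5), default mode (DMN, 7), primary
visual (pVIS, 2: left and right V1), sensorimotor (MOT, 6) and language
(LAN, 6).  The pVIS network consists of the single left-V1 / right-V1
connection, so its "network mean" is that single matrix entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations


@dataclass(frozen=True)
class Parcellation:
    """Ordered networks, each an ordered tuple of node labels."""

    networks: tuple  # of (network-name, (node labels...))
    _label_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = [lab for _, labs in self.networks for lab in labs]
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique across networks")
        object.__setattr__(
            self, "_label_index", {lab: i for i, lab in enumerate(labels)}
        )

    @property
    def labels(self) -> list:
        return [lab for _, labs in self.networks for lab in labs]

    @property
    def n_nodes(self) -> int:
        return len(self._label_index)

    @property
    def network_names(self) -> list:
        return [name for name, _ in self.networks]

    @property
    def node_to_network(self) -> dict:
        """Map node index -> network name."""
        out = {}
        for name, labs in self.networks:
            for lab in labs:
                out[self._label_index[lab]] = name
        return out

    def network_indices(self, name: str) -> list:
        for net, labs in self.networks:
            if net == name:
                return [self._label_index[lab] for lab in labs]
        raise KeyError(f"unknown network {name!r}")

    def within_pairs(self, name: str) -> list:
        """Unordered node-index pairs internal to one network."""
        return list(combinations(self.network_indices(name), 2))

    def all_pairs(self) -> list:
        return list(combinations(range(self.n_nodes), 2))

    def cross_pairs(self) -> list:
        within = {p for net in self.network_names for p in self.within_pairs(net)}
        return [p for p in self.all_pairs() if p not in within]


def default_parcellation() -> Parcellation:
    """The default 32-node parcellation (DAN 6, VAN 5, DMN 7, pVIS 2, MOT 6, LAN 6).

    Labels are standard region names; no coordinates are attached — the
    parcellation only fixes node ordering and network membership.
    """
    return Parcellation(networks=(
        ("DAN", ("L_FEF", "R_FEF", "L_pIPS", "R_pIPS", "L_MT", "R_MT")),
        ("VAN", ("L_TPJ", "R_TPJ", "R_VFC", "R_IFG_van", "R_MFG")),
        ("DMN", ("PCC", "MPFC", "L_AG", "R_AG", "L_MTG", "R_MTG", "PREC")),
        ("pVIS", ("L_V1", "R_V1")),
        ("MOT", ("L_M1", "R_M1", "L_S1", "R_S1", "L_SMA", "R_SMA")),
        ("LAN", ("L_IFG", "R_IFG", "L_STG", "R_STG", "L_SMG", "R_SMG")),
    ))
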