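"""The 19-channel international 10-20 montage and its electrode adjacency graph.

Cluster-level inference groups supra-threshold electrodes into spatially
connected sets, so the montage ships with a fixed, documented neighbour table
(plain-text edge list under ``comareact/data``).  Neighbourhood is nearest
scalp neighbours along the standard 10-20 grid (e.g. C3 ~ {F3, T3, Cz, P3}).
"""

from __future__ import annotations

from importlib import resources

import networkx as nx

#: Electrode order used throughout the package (frontal to occipital).
ELECTRODES: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

ELECTRODE_SET = frozenset(ELECTRODES)


def load_adjacency() -> nx.Graph:
    """Return the 10-20 electrode adjacency graph.

    The graph is undirected, has no self loops, and is connected over the
    full 19-electrode montage.
    """
    graph = nx.Graph()
    graph.add_nodes_from(ELECTRODES)
    text = (
        resources.files("comareact.data")
        .joinpath("adjacency_1020_19.txt")
        .read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()
        if a not in ELECTRODE_SET or b not in ELECTRODE_SET:
            raise ValueError(f"unknown electrode in adjacency table: {line!r}")
        if a == b:
            raise ValueError(f"self loop in adjacency table: {line!r}")
        graph.add_edge(a, b)
    return graph


def validate_channels(labels) -> None:
    """Raise ``ValueError`` unless *labels* is exactly the 19-channel montage."""
    labels = list(labels)
    unknown = [lab for lab in labels if lab not in ELECTRODE_SET]
    if unknown:
        raise ValueError(f"unknown channel label(s): {', '.join(unknown)}")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels")
    if len(labels) != len(ELECTRODES):
        raise ValueError(
            f"expected {len(ELECTRODES)} channels of the 10-20 montage, "
            f"got {len(labels)}"
        )
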