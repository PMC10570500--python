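"""Rich-club, feeder and local edge classes and their connectivity sums.

Given an a-priori rich-club node set, every nonzero edge of a thresholded FC
network falls into exactly one class: *rich* when both endpoints are rich-club
nodes, *feeder* when exactly one is, and *local* when neither is.  The three
connectivity values are the sums of edge weights within each class (each
undirected edge counted once), so they always add up to the network's overall
strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fc import FCMatrix

__all__ = ["EdgeClassMap", "RichClubSummary", "classify_edges",
           "connectivity_sums", "richclub_summary"]

CLASSES = ("rich", "feeder", "local")


@dataclass(frozen=True)
class EdgeClassMap:
    """Class label per nonzero upper-triangle edge."""

    i: np.ndarray
    j: np.ndarray
    weight: np.ndarray
    label: np.ndarray  # str array over CLASSES

    @property
    def n_edges(self) -> int:
        return self.i.size


@dataclass(frozen=True)
class RichClubSummary:
    rich_connectivity: float
    feeder_connectivity: float
    local_connectivity: float

    @property
    def total(self) -> float:
        return self.rich_connectivity + self.feeder_connectivity + self.local_connectivity


def classify_edges(fc: FCMatrix, rich_nodes) -> EdgeClassMap:
    """Label every nonzero edge rich / feeder / local."""
    rich_nodes = np.asarray(sorted(int(r) for r in rich_nodes), dtype=int)
    n = fc.n_nodes
    if rich_nodes.size and (rich_nodes[0] < 0 or rich_nodes[-1] >= n):
        raise IndexError("rich node index out of range")
    is_rich = np.zeros(n, dtype=bool)
    is_rich[rich_nodes] = True
    i, j, w = fc.edges()
    n_rich_ends = is_rich[i].astype(int) + is_rich[j].astype(int)
    label = np.where(n_rich_ends == 2, "rich", np.where(n_rich_ends == 1, "feeder", "local"))
    return EdgeClassMap(i=i, j=j, weight=w, label=label)


def connectivity_sums(classes: EdgeClassMap) -> RichClubSummary:
    """Weight sum per edge class; rich + feeder + local = overall strength."""
    return RichClubSummary(
        rich_connectivity=float(classes.weight[classes.label == "rich"].sum()),
        feeder_connectivity=float(classes.weight[classes.label == "feeder"].sum()),
        local_connectivity=float(classes.weight[classes.label == "local"].sum()),
    )


def richclub_summary(fc: FCMatrix, rich_nodes) -> RichClubSummary:
    """Convenience: classify and sum in one call."""
    return connectivity_sums(classify_edges(fc, rich_nodes))
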