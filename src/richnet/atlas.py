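"""Parcellation region tables, subnetwork affiliations and the rich-club node set.

The node set of every network in this package is defined by a region table: one
row per parcellation region carrying a unique short label (e.g. ``INS.L``), a
subnetwork affiliation label (e.g. ``SN`` for the salience network) and a
boolean rich-club flag.  The packaged default table covers the 90-region
cortical/subcortical AAL parcellation with an a-priori rich club of 14 regions:
bilateral dorsolateral superior frontal gyrus, insula, hippocampus, precuneus,
superior parietal gyrus, putamen and thalamus.  The default subnetwork
assignment is a standard-style seven-label stand-in (DMN, SN, FPN, SMN, SCN,
visual, attention); it only labels output and can be replaced by any
user-supplied TSV.

Region indices are 0-based everywhere in memory; TSV files on disk use 1-based
indices in their ``index`` column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "RegionTable",
    "load_region_table",
    "partition_nodes",
    "pair_affiliations",
    "DEFAULT_RICH_CLUB_BASES",
]

#: Base labels (without hemisphere suffix) of the 14 a-priori rich-club regions.
DEFAULT_RICH_CLUB_BASES = ("SFGdor", "INS", "HIP", "PCUN", "SPG", "PUT", "THA")


@dataclass(frozen=True)
class RegionTable:
    """Immutable region table for one parcellation.

    Parameters
    ----------
    names : tuple of str
        Unique region labels, position = 0-based region index.
    subnetwork : tuple of str
        Subnetwork affiliation label per region.
    rich_club_member : numpy.ndarray of bool
        Per-region flag marking membership in the a-priori rich club.
    """

    names: tuple
    subnetwork: tuple
    rich_club_member: np.ndarray = field(repr=False)

    def __post_init__(self):
        names = tuple(str(n) for n in self.names)
        subnet = tuple(str(s) for s in self.subnetwork)
        rich = np.asarray(self.rich_club_member, dtype=bool)
        if len(names) == 0:
            raise ValueError("region table must contain at least one region")
        if len(set(names)) != len(names):
            dupes = [n for n, c in Counter(names).items() if c > 1]
            raise ValueError(f"duplicate region names: {dupes}")
        if len(subnet) != len(names) or rich.shape != (len(names),):
            raise ValueError("names, subnetwork and rich_club_member lengths differ")
        if any(s == "" or s.lower() == "nan" for s in subnet):
            raise ValueError("every region needs a subnetwork label")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "subnetwork", subnet)
        object.__setattr__(self, "rich_club_member", rich)

    @property
    def n_regions(self) -> int:
        return len(self.names)

    @property
    def rich_indices(self) -> np.ndarray:
        """0-based indices of rich-club regions, ascending."""
        return np.flatnonzero(self.rich_club_member)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame with a 1-based ``index`` column."""
        return pd.DataFrame(
            {
                "index": np.arange(1, self.n_regions + 1),
                "name": self.names,
                "subnetwork": self.subnetwork,
                "rich_club": self.rich_club_member.astype(int),
            }
        )


def _default_table_path():
    return resources.files("richnet").joinpath("data/aal90_regions.tsv")


def load_region_table(path=None) -> RegionTable:
    """Load a region table from TSV, or the packaged 90-region default.

    The TSV must have columns ``index`` (1-based, contiguous), ``name`` and
    ``subnetwork``; an optional ``rich_club`` column (0/1) flags rich-club
    membership and defaults to all-zero when absent.
    """
    if path is None:
        with resources.as_file(_default_table_path()) as p:
            return load_region_table(p)
    df = pd.read_csv(path, sep="\t")
    required = {"index", "name", "subnetwork"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    df = df.sort_values("index")
    idx = df["index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(df) + 1)):
        raise ValueError("region 'index' column must be 1-based and contiguous")
    if "rich_club" in df.columns:
        rich = df["rich_club"].to_numpy().astype(bool)
    else:
        rich = np.zeros(len(df), dtype=bool)
    return RegionTable(
        names=tuple(df["name"]), subnetwork=tuple(df["subnetwork"]), rich_club_member=rich
    )


def partition_nodes(table: RegionTable):
    """Split node indices into (rich, peripheral) sets.

    Returns two disjoint frozensets of 0-based indices whose union covers all
    regions; peripheral simply means not flagged as a rich-club member.
    """
    rich = frozenset(int(i) for i in table.rich_indices)
    peripheral = frozenset(range(table.n_regions)) - rich
    return rich, peripheral


def pair_affiliations(edges, table: RegionTable) -> dict:
    """Count edges per unordered subnetwork-affiliation pair.

    Parameters
    ----------
    edges : iterable of (i, j)
        Edge list over 0-based node indices.
    table : RegionTable

    Returns
    -------
    dict mapping ``(label_a, label_b)`` (lexicographically sorted) to the number
    of edges joining a region of ``label_a`` with one of ``label_b``.  Counts
    sum to the number of input edges.
    """
    counts: dict = {}
    n = table.n_regions
    for i, j in edges:
        i, j = int(i), int(j)
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"edge ({i},{j}) out of range for {n} regions")
        key = tuple(sorted((table.subnetwork[i], table.subnetwork[j])))
        counts[key] = counts.get(key, 0) + 1
    return counts
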