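"""Distance-0 clump detection and the per-cell context feature.

Two retained cells belong to one clump iff their regions are in contact.
Because the seeded watershed separates touching cells by construction,
"distance 0" is mapped to adjacency of the dilated-by-one regions: labels
whose pixels come within a Chebyshev distance of 2 are connected.  Clumps are
the connected components of this region-adjacency graph; a single cell is a
clump of size 1.  Clumps never span fields (border cells were removed and
fields are non-contiguous acquisitions).
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .segmentation import LabelMask

logger = logging.getLogger(__name__)

CLUMP_COLUMNS = ("well", "field", "clump_id", "clump_size", "members")

#: Chebyshev radius within which two labels count as "in contact".
ADJACENCY_RADIUS = 2


class ClumpIntegrityError(ValueError):
    """Object/clump memberships are inconsistent."""


def label_adjacency_pairs(labels: np.ndarray, radius: int = ADJACENCY_RADIUS
                          ) -> set[tuple[int, int]]:
    """Unordered pairs of distinct labels with pixels within ``radius``."""
    labels = np.asarray(labels)
    pairs: set[tuple[int, int]] = set()
    for dr, dc in product(range(0, radius + 1), range(-radius, radius + 1)):
        if dr == 0 and dc <= 0:
            continue  # half-plane of shifts covers all pairs by symmetry
        a = labels[dr:, max(dc, 0):labels.shape[1] + min(dc, 0)]
        b = labels[:labels.shape[0] - dr,
                   max(-dc, 0):labels.shape[1] + min(-dc, 0)]
        touching = (a > 0) & (b > 0) & (a != b)
        if touching.any():
            for x, y in zip(a[touching].ravel(), b[touching].ravel()):
                pairs.add((min(int(x), int(y)), max(int(x), int(y))))
    return pairs


def detect_clumps(cells: LabelMask, well: str, field: int) -> pd.DataFrame:
    """Partition the retained cells of one field into contact clumps.

    Returns a ClumpTable: one row per clump with its size and member object
    ids (semicolon-joined).  Clump ids are 1-based and ordered by their
    smallest member label.
    """
    ids = cells.label_ids()
    if ids.size == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in CLUMP_COLUMNS})
    n = int(ids.max())
    pairs = label_adjacency_pairs(cells.labels)
    if pairs:
        rows, cols = zip(*pairs)
        graph = coo_matrix(
            (np.ones(len(pairs)), (np.asarray(rows) - 1, np.asarray(cols) - 1)),
            shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    _, component = connected_components(graph, directed=False)

    records = []
    present = set(map(int, ids))
    for comp in pd.unique(component[np.asarray(sorted(present)) - 1]):
        members = [lid for lid in sorted(present)
                   if component[lid - 1] == comp]
        records.append((well, int(field), 0, len(members),
                        ";".join(str(m) for m in members)))
    records.sort(key=lambda r: int(r[4].split(";")[0]))
    df = pd.DataFrame(records, columns=CLUMP_COLUMNS)
    df["clump_id"] = np.arange(1, len(df) + 1)
    if int(df["clump_size"].sum()) != len(present):
        raise ClumpIntegrityError("clump sizes do not sum to the cell count")
    return df


def clump_members(clump_table: pd.DataFrame) -> pd.DataFrame:
    """Long form: one row per (well, field, clump_id, object_id, clump_size)."""
    if not len(clump_table):
        return pd.DataFrame(columns=["well", "field", "clump_id", "object_id",
                                     "clump_size"])
    out = clump_table.copy()
    out["object_id"] = out["members"].map(
        lambda s: [int(x) for x in str(s).split(";")])
    out = out.explode("object_id", ignore_index=True)
    out["object_id"] = out["object_id"].astype(int)
    return out[["well", "field", "clump_id", "object_id", "clump_size"]]


def annotate_clump_size(table: pd.DataFrame, clumps: pd.DataFrame) -> pd.DataFrame:
    """Tag each retained cell with its clump's size (the context feature)."""
    out = table.copy()
    if not len(out):
        return out
    members = clump_members(clumps)
    merged = out.merge(
        members[["well", "field", "object_id", "clump_size"]],
        on=["well", "field", "object_id"], how="left", validate="one_to_one")
    if merged["clump_size"].isna().any():
        missing = merged.loc[merged["clump_size"].isna(),
                             ["well", "field", "object_id"]]
        raise ClumpIntegrityError(
            f"{len(missing)} retained cells missing from the clump table, "
            f"e.g. {missing.iloc[0].tolist()}")
    out["n_per_clump"] = merged["clump_size"].astype(int).to_numpy()
    return out


def clump_size_histogram(clumps: pd.DataFrame, well: str | None = None) -> pd.Series:
    """Counts of clumps per size (zero-count sizes omitted)."""
    sub = clumps if well is None else clumps[clumps["well"] == well]
    if not len(sub):
        return pd.Series(dtype=int, name="n_clumps")
    hist = sub["clump_size"].astype(int).value_counts().sort_index()
    hist.name = "n_clumps"
    hist.index.name = "clump_size"
    return hist
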