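"""Cell skeleton container with SWC semantics.

A skeleton is a rooted tree of 3D nodes with radii. Node type 1 marks soma
nodes; everything else is process. Coordinates and radii are in micrometres.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOMA_TYPE = 1

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


@dataclass
class CellSkeleton:
    """Rooted tree of 3D nodes with radii (SWC semantics).

    Parameters
    ----------
    ids : int array, node identifiers (unique).
    types : int array, SWC structure type per node (1 = soma).
    xyz : (n, 3) float array, node positions in µm.
    radius : float array, node radii in µm.
    parent : int array, parent node *id* per node; -1 for the root.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    cell_id: str | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self.validate()

    # ------------------------------------------------------------------
    # construction / export
    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cell_id: str | None = None) -> "CellSkeleton":
        return cls(
            ids=df["id"].to_numpy(),
            types=df["type"].to_numpy(),
            xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
            radius=df["radius"].to_numpy(dtype=float),
            parent=df["parent"].to_numpy(),
            cell_id=cell_id,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "type": self.types,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "radius": self.radius,
                "parent": self.parent,
            }
        )

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        """Check unique ids, a single root, existing parents, no cycles."""
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("duplicate node ids in skeleton")
        if np.any(self.radius < 0):
            raise ValueError("negative radius in skeleton")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        for k, p in enumerate(self.parent):
            if p == -1:
                continue
            if int(p) not in self._index:
                raise ValueError(f"node {self.ids[k]} has missing parent {p}")
            if int(p) == int(self.ids[k]):
                raise ValueError(f"node {self.ids[k]} is its own parent")
        # cycle check by walking each node to the root
        for k in range(len(self.ids)):
            seen = set()
            cur = k
            while self.parent[cur] != -1:
                if cur in seen:
                    raise ValueError("cycle detected in skeleton parent links")
                seen.add(cur)
                cur = self._index[int(self.parent[cur])]

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def soma_mask(self) -> np.ndarray:
        return self.types == SOMA_TYPE

    def soma_center(self) -> np.ndarray:
        """Centroid of soma nodes, or root position if no node is soma-typed."""
        m = self.soma_mask
        if m.any():
            return self.xyz[m].mean(axis=0)
        return self.xyz[self.root_index]

    def children_map(self) -> dict[int, list[int]]:
        """Map positional node index -> positional indices of children."""
        ch: dict[int, list[int]] = {k: [] for k in range(self.n_nodes)}
        for k, p in enumerate(self.parent):
            if p != -1:
                ch[self._index[int(p)]].append(k)
        return ch

    def segments(self, include_soma_internal: bool = False) -> np.ndarray:
        """(m, 2) array of (parent_index, child_index) process segments.

        Segments joining two soma nodes are excluded unless requested; a
        segment from a soma node to a process node is a process segment.
        """
        pairs = []
        soma = self.soma_mask
        for k, p in enumerate(self.parent):
            if p == -1:
                continue
            pk = self._index[int(p)]
            if not include_soma_internal and soma[k] and soma[pk]:
                continue
            pairs.append((pk, k))
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    def segment_lengths(self) -> np.ndarray:
        seg = self.segments()
        if len(seg) == 0:
            return np.zeros(0)
        d = self.xyz[seg[:, 1]] - self.xyz[seg[:, 0]]
        return np.linalg.norm(d, axis=1)

    def scale(self, s: float) -> "CellSkeleton":
        """Uniformly scaled copy (coordinates and radii multiplied by ``s``)."""
        return CellSkeleton(
            ids=self.ids.copy(),
            types=self.types.copy(),
            xyz=self.xyz * s,
            radius=self.radius * s,
            parent=self.parent.copy(),
            cell_id=self.cell_id,
        )
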