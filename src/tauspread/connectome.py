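"""Weighted brain-network containers and region-label utilities.

A :class:`Connectome` is a labelled, symmetric, non-negative weight matrix with
zero diagonal, optionally carrying region centroid coordinates (used as edge
lengths by the spreading simulator).  Similarity-type networks (gene
co-expression, receptor similarity, ...) carry no geometry; their edges default
to unit length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

#: The four mechanistic rates a regional factor may modulate, in the fixed
#: tie-break order used throughout the package.
RATES: tuple[str, ...] = ("synthesis", "clearance", "spread", "misfold")


@dataclass
class RegionalFactor:
    """One value per region (e.g. a gene-expression or receptor-density map)."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("factor values must be a 1-D regional vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"factor {self.name!r} contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Connectome:
    """Symmetric non-negative weighted network over labelled brain regions."""

    weights: np.ndarray
    labels: list[str]
    centroids: np.ndarray | None = None
    name: str = "connectome"

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        if not np.allclose(W, W.T, rtol=1e-10, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")
        W = W.copy()
        np.fill_diagonal(W, 0.0)
        self.weights = W
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != W.shape[0]:
            raise ValueError("label count must match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        if self.centroids is not None:
            C = np.asarray(self.centroids, dtype=float)
            if C.shape != (W.shape[0], 3):
                raise ValueError("centroids must be an (n_regions, 3) array")
            self.centroids = C

    # -- basic graph measures -------------------------------------------------

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def strengths(self) -> np.ndarray:
        """Nodal strength: sum of incident edge weights per region."""
        return self.weights.sum(axis=1)

    def degrees(self) -> np.ndarray:
        """Binary degree: number of incident edges per region."""
        return (self.weights > 0).sum(axis=1)

    def n_edges(self) -> int:
        return int((np.triu(self.weights, 1) > 0).sum())

    def edge_lengths(self) -> np.ndarray:
        """Pairwise edge lengths: Euclidean centroid distance, or 1 without geometry."""
        if self.centroids is not None:
            L = squareform(pdist(self.centroids))
        else:
            L = np.ones_like(self.weights)
        np.fill_diagonal(L, 0.0)
        return L

    def is_connected(self) -> bool:
        n_comp, _ = connected_components((self.weights > 0).astype(int), directed=False)
        return bool(n_comp == 1)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, keep: Sequence[str]) -> "Connectome":
        """Restrict to the given region labels, preserving their order."""
        idx = [self.index(lbl) for lbl in keep]
        return Connectome(
            self.weights[np.ix_(idx, idx)],
            [self.labels[i] for i in idx],
            None if self.centroids is None else self.centroids[idx],
            name=self.name,
        )

    # -- text I/O -------------------------------------------------------------

    def write_tsv(self, path: str | Path, centroid_path: str | Path | None = None) -> None:
        df = pd.DataFrame(self.weights, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t")
        if centroid_path is not None and self.centroids is not None:
            pd.DataFrame(self.centroids, index=self.labels, columns=["x", "y", "z"]).to_csv(
                centroid_path, sep="\t"
            )

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        centroid_path: str | Path | None = None,
        name: str | None = None,
    ) -> "Connectome":
        df = pd.read_csv(path, sep="\t", index_col=0)
        centroids = None
        if centroid_path is not None:
            centroids = pd.read_csv(centroid_path, sep="\t", index_col=0).to_numpy()
        return cls(
            df.to_numpy(float),
            list(df.columns),
            centroids,
            name=name or Path(path).stem,
        )


def nodal_strength(connectome: Connectome) -> np.ndarray:
    """Row sums of the weight matrix (nodal strength)."""
    return connectome.strengths()


# 31 cortical parcels per hemisphere in a Desikan-Killiany-style naming scheme,
# plus hippocampus and amygdala, giving the 66-region set the tau tables use.
_CORTICAL_PARCELS: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "transversetemporal",
)


def default_region_labels(include_subcortical: bool = True) -> list[str]:
    """The 66-region label set (31 cortical parcels + hippocampus + amygdala,
    per hemisphere), or the 62-region cortical subset."""
    parcels = list(_CORTICAL_PARCELS)
    if include_subcortical:
        parcels += ["hippocampus", "amygdala"]
    return [f"{parcel}_{hemi}" for hemi in ("L", "R") for parcel in parcels]


def restrict_regions(
    labels: Iterable[str],
    exclude: tuple[str, ...] = ("hippocampus", "amygdala"),
) -> list[str]:
    """Drop regions whose label contains any excluded structure name.

    Used to restrict 66-region tables to the 62 cortical regions available for
    every connectome (bilateral hippocampus and amygdala removed).
    """
    return [lbl for lbl in labels if not any(e in lbl.lower() for e in exclude)]


def braak_stage_table(assignment: Mapping[str, str], labels: Sequence[str]) -> pd.Series:
    """Align a region -> Braak-stage mapping with a region ordering."""
    stages = []
    valid = {"I", "II", "III", "IV", "V", "VI", "unassigned"}
    for lbl in labels:
        stage = assignment.get(lbl, "unassigned")
        if stage not in valid:
            raise ValueError(f"invalid Braak stage {stage!r} for region {lbl!r}")
        stages.append(stage)
    return pd.Series(stages, index=list(labels), name="braak_stage")
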