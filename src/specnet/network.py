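"""Per-subject network reconstruction and binarization.

A subject's network has one node per spectral bin; the weight of the link
between bins i and j is the disease probability of the pair of values,
computed under the trained dual-class model.  Both ordered directions are
evaluated and combined (arithmetic mean by default), yielding a symmetric
weighted network; thresholding that network gives the binary adjacency on
which the structural metrics are evaluated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .pairmodel import DualClassModel, weight_matrix

SYMMETRIZATIONS = ("mean", "max", "directed")

#: the default analysis threshold on link weights
DEFAULT_THRESHOLD = 0.65


@dataclass
class SubjectNetwork:
    """Weighted network of one subject: symmetric weights in [0, 1], hollow diagonal."""

    subject_id: str
    weights: np.ndarray
    node_labels: np.ndarray
    degenerate_mask: np.ndarray
    directed_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight diagonal must be zero")
        off = W[~np.eye(len(W), dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("link weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryNetwork:
    """Thresholded adjacency: symmetric, hollow, 0/1."""

    adjacency: np.ndarray
    node_labels: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        A = self.adjacency
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def reconstruct(
    subject_values: np.ndarray,
    model: DualClassModel,
    *,
    symmetrization: str = "mean",
    subject_id: str = "X",
) -> SubjectNetwork:
    """Build the weighted network of one subject from all bin pairs.

    Both ordered weights w(i->j) and w(j->i) are computed and combined per
    the symmetrization rule; ``"directed"`` keeps the ordered matrix for
    export while metrics still operate on the mean-symmetrized form.
    """
    if symmetrization not in SYMMETRIZATIONS:
        raise ValueError(f"symmetrization must be one of {SYMMETRIZATIONS}")
    W = weight_matrix(model, subject_values)
    if symmetrization == "max":
        S = np.maximum(W, W.T)
    else:
        S = 0.5 * (W + W.T)
    np.fill_diagonal(S, 0.0)
    n = model.n_bins
    labels = model.bin_axis if model.bin_axis is not None else np.arange(n, dtype=float)
    deg = model.degenerate | model.degenerate.T
    return SubjectNetwork(
        subject_id=subject_id,
        weights=S,
        node_labels=np.asarray(labels, dtype=float),
        degenerate_mask=deg,
        directed_weights=W if symmetrization == "directed" else None,
    )


def binarize(network: SubjectNetwork, threshold: float) -> BinaryNetwork:
    """Keep links whose weight is strictly greater than ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    A = (network.weights > threshold).astype(np.int8)
    np.fill_diagonal(A, 0)
    return BinaryNetwork(
        adjacency=A,
        node_labels=network.node_labels,
        threshold_used=float(threshold),
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def to_networkx(network: SubjectNetwork) -> nx.Graph:
    g = nx.from_numpy_array(network.weights)
    for i, pos in enumerate(network.node_labels):
        g.nodes[i]["axis_position"] = float(pos)
    return g


def write_graphml(network: SubjectNetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(network), str(path))


def write_edge_list(network: SubjectNetwork, path: str | Path) -> None:
    """Upper-triangle (i, j, weight) rows as TSV; directed weights if kept."""
    W = network.directed_weights
    path = Path(path)
    with path.open("w", newline="") as fh:
        out = csv.writer(fh, delimiter="\t")
        out.writerow(["i", "j", "weight"])
        n = network.n_nodes
        if W is None:
            for i in range(n):
                for j in range(i + 1, n):
                    out.writerow([i, j, repr(float(network.weights[i, j]))])
        else:
            for i in range(n):
                for j in range(n):
                    if i != j:
                        out.writerow([i, j, repr(float(W[i, j]))])


def write_adjacency_csv(matrix: np.ndarray, node_labels: np.ndarray, path: str | Path) -> None:
    header = ",".join(repr(float(v)) for v in node_labels)
    np.savetxt(path, matrix, delimiter=",", header=header, comments="")
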