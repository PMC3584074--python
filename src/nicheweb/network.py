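"""Bipartite binary interaction networks: container, I/O, sorting, descriptors.

A network records which consumers (pollinators, parasites, herbivores)
interact with which resources (plants, hosts).  The adjacency matrix is
oriented rows = resources, columns = consumers, so entry ``A[j, i]`` is 1
when consumer ``i`` takes resource ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteNetwork",
    "NetworkFormatError",
    "read_network",
    "write_network",
    "sort_by_marginals",
    "connectance_empirical",
]


class NetworkFormatError(ValueError):
    """Raised when an input file or matrix violates the binary bipartite contract."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """Binary consumer-resource network.

    Parameters
    ----------
    adjacency
        ``(S_R, S_C)`` array of 0/1 entries; rows are resources, columns
        are consumers.
    resource_labels, consumer_labels
        Unique identifiers for the rows and columns respectively.
    """

    adjacency: np.ndarray
    resource_labels: tuple[str, ...] = field(default=())
    consumer_labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2:
            raise NetworkFormatError("adjacency must be a 2-D matrix")
        if not np.isin(a, (0, 1)).all():
            raise NetworkFormatError("adjacency entries must all be 0 or 1")
        a = a.astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        s_r, s_c = a.shape
        rl = tuple(self.resource_labels) or tuple(f"R{j + 1}" for j in range(s_r))
        cl = tuple(self.consumer_labels) or tuple(f"C{i + 1}" for i in range(s_c))
        if len(rl) != s_r or len(cl) != s_c:
            raise NetworkFormatError("label count does not match matrix shape")
        if len(set(rl)) != len(rl) or len(set(cl)) != len(cl):
            raise NetworkFormatError("labels must be unique within each side")
        object.__setattr__(self, "resource_labels", rl)
        object.__setattr__(self, "consumer_labels", cl)

    @property
    def s_r(self) -> int:
        return self.adjacency.shape[0]

    @property
    def s_c(self) -> int:
        return self.adjacency.shape[1]

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    @property
    def consumer_degrees(self) -> np.ndarray:
        """Number of resources taken by each consumer (column sums)."""
        return self.adjacency.sum(axis=0)

    @property
    def resource_degrees(self) -> np.ndarray:
        """Number of consumers taking each resource (row sums)."""
        return self.adjacency.sum(axis=1)

    def zero_degree_species(self) -> dict[str, list[str]]:
        """Labels of isolated species on each side (kept, but flagged)."""
        return {
            "resources": [l for l, d in zip(self.resource_labels, self.resource_degrees) if d == 0],
            "consumers": [l for l, d in zip(self.consumer_labels, self.consumer_degrees) if d == 0],
        }


def _validate_for_analysis(net: BipartiteNetwork) -> None:
    if net.n_links < 1:
        raise NetworkFormatError("network has zero links (degenerate input)")


def read_network(path, format: str = "adjacency-csv") -> BipartiteNetwork:
    """Read a network from disk.

    ``adjacency-csv`` files carry a header row of consumer labels and a
    leading column of resource labels, with 0/1 cells.  ``edgelist-tsv``
    files carry two tab-separated columns ``resource_label<TAB>consumer_label``;
    lines beginning with ``#`` are comments; duplicate edges are collapsed.
    """
    if format == "adjacency-csv":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise NetworkFormatError(f"{path}: non-binary cell values")
        net = BipartiteNetwork(
            values.astype(np.int8),
            resource_labels=tuple(str(x) for x in df.index),
            consumer_labels=tuple(str(x) for x in df.columns),
        )
    elif format == "edgelist-tsv":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["resource", "consumer"], dtype=str,
        )
        if df.isna().any().any():
            raise NetworkFormatError(f"{path}: malformed edge list row")
        edges = list(dict.fromkeys(zip(df["resource"], df["consumer"])))
        resources = list(dict.fromkeys(r for r, _ in edges))
        consumers = list(dict.fromkeys(c for _, c in edges))
        a = np.zeros((len(resources), len(consumers)), dtype=np.int8)
        r_ix = {r: j for j, r in enumerate(resources)}
        c_ix = {c: i for i, c in enumerate(consumers)}
        for r, c in edges:
            a[r_ix[r], c_ix[c]] = 1
        net = BipartiteNetwork(a, tuple(resources), tuple(consumers))
    else:
        raise ValueError(f"unknown format {format!r}")
    _validate_for_analysis(net)
    return net


def write_network(net: BipartiteNetwork, path, format: str = "adjacency-csv") -> None:
    """Write a network; inverse of :func:`read_network` for the CSV dialect."""
    if format == "adjacency-csv":
        df = pd.DataFrame(
            net.adjacency, index=list(net.resource_labels), columns=list(net.consumer_labels)
        )
        df.to_csv(path)
    elif format == "edgelist-tsv":
        with open(path, "w") as fh:
            fh.write("# resource\tconsumer\n")
            rows, cols = np.nonzero(net.adjacency)
            for j, i in zip(rows, cols):
                fh.write(f"{net.resource_labels[j]}\t{net.consumer_labels[i]}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def sort_by_marginals(net: BipartiteNetwork) -> BipartiteNetwork:
    """Reorder rows and columns by descending marginal totals.

    Ties keep their original relative order (stable sort), so the
    operation is a pure permutation: degrees and link count are unchanged.
    """
    row_order = np.argsort(-net.resource_degrees, kind="stable")
    col_order = np.argsort(-net.consumer_degrees, kind="stable")
    return BipartiteNetwork(
        net.adjacency[np.ix_(row_order, col_order)],
        tuple(net.resource_labels[j] for j in row_order),
        tuple(net.consumer_labels[i] for i in col_order),
    )


def connectance_empirical(net: BipartiteNetwork) -> float:
    """Realized fraction of possible links, L / (S_C * S_R)."""
    return net.n_links / (net.s_c * net.s_r)
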