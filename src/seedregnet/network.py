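"""TF -> structural-gene regulatory network inference.

An edge is called when three pieces of evidence coincide: a strong
positive Pearson correlation between the TF's and the gene's expression
(signed r above ``r_min``), a two-sided p-value below ``p_max`` from
the Student-t transform ``t = r * sqrt((n-2) / (1-r^2))``, and a
predicted binding site of the TF in the gene's 2 kb promoter.

Two inference regimes are supported:

``cluster_seed``
    sample-level correlation over the 16 seed samples, r_min = 0.95,
    candidate pairs restricted to TF/gene pairs in the same temporal
    cluster;
``multi_tissue``
    correlation of group means over the 8 groups (4 seed stages + 4
    tissues), r_min = 0.8, no cluster constraint.

No multiple-testing correction is applied to edge p-values; the raw
p < 0.05 convention of correlation-based network building is kept (a
documented caveat, not an oversight).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterAssignment
from .errors import DegenerateInputError, ParameterError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: preset thresholds per inference regime
REGIMES: dict[str, dict] = {
    "cluster_seed": dict(r_min=0.95, p_max=0.05, aggregate_groups=False),
    "multi_tissue": dict(r_min=0.8, p_max=0.05, aggregate_groups=True),
}


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p-value (t distribution with n-2 df).

    Perfect correlations (|r| = 1) return p = 0.  Constant input raises
    :class:`DegenerateInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    n = x.shape[0]
    if n < 3:
        raise ParameterError("pearson_test needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("constant vector in correlation test")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:
        return (1.0 if r > 0 else -1.0), 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


@dataclass(frozen=True)
class RegulatoryEdge:
    """A directed TF -> gene edge with its supporting evidence."""

    tf_id: str
    gene_id: str
    pcc: float
    p_value: float
    n_obs: int
    tfbs_present: bool
    family: str = ""


@dataclass
class RegulatoryNetwork:
    """Directed TF -> structural-gene network under one regime."""

    edges: list[RegulatoryEdge]
    tf_nodes: set[str]
    gene_nodes: set[str]
    regime: str
    thresholds: tuple[float, float]  # (r_min, p_max)
    tf_families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(e.tf_id, e.gene_id) for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (tf, gene) edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> set[str]:
        return self.tf_nodes | self.gene_nodes

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.tf_id, e.gene_id) for e in self.edges}

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for tf in self.tf_nodes:
            g.add_node(tf, kind="TF", family=self.tf_families.get(tf, ""))
        for sg in self.gene_nodes:
            g.add_node(sg, kind="structural_gene")
        for e in self.edges:
            g.add_edge(
                e.tf_id, e.gene_id, pcc=e.pcc, p_value=e.p_value,
                n_obs=e.n_obs, tfbs=bool(e.tfbs_present), family=e.family,
            )
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    tf_id=e.tf_id, gene_id=e.gene_id, pcc=e.pcc,
                    p_value=e.p_value, n_obs=e.n_obs,
                    tfbs_present=int(e.tfbs_present), family=e.family,
                )
                for e in self.edges
            ],
            columns=[
                "tf_id", "gene_id", "pcc", "p_value",
                "n_obs", "tfbs_present", "family",
            ],
        )


def build_network(
    tf_expr: ExpressionMatrix,
    sg_expr: ExpressionMatrix,
    presence: pd.DataFrame,
    r_min: float,
    p_max: float = 0.05,
    same_cluster: ClusterAssignment | None = None,
    aggregate_groups: bool = False,
    tf_families: Mapping[str, str] | None = None,
    regime: str = "custom",
) -> RegulatoryNetwork:
    """Assemble the TF -> gene network from correlation + TFBS evidence.

    Candidate pairs are all (TF, gene) combinations, optionally
    restricted to pairs sharing a cluster label in `same_cluster`.
    With `aggregate_groups` the correlation is computed on group means
    (multi-tissue regime); otherwise on sample-level values.  An edge
    is kept iff ``pcc > r_min`` and ``p < p_max`` and the TF's motif is
    present in the gene's promoter.
    """
    if tf_expr.sample_ids != sg_expr.sample_ids:
        raise ValidationError("TF and structural-gene matrices must share samples")
    if aggregate_groups:
        tf_vals = tf_expr.group_means()
        sg_vals = sg_expr.group_means()
    else:
        tf_vals = tf_expr.values
        sg_vals = sg_expr.values
    n_obs = tf_vals.shape[1]
    if n_obs < 3:
        raise ParameterError(f"need >= 3 observations, got {n_obs}")
    families = dict(tf_families or {})

    labels = same_cluster.labels if same_cluster is not None else None
    if labels is not None:
        missing = [
            f for f in list(tf_vals.index) + list(sg_vals.index) if f not in labels.index
        ]
        if missing:
            raise ValidationError(f"features without cluster labels: {missing[:5]}")

    T = tf_vals.to_numpy(dtype=float)
    S = sg_vals.to_numpy(dtype=float)
    t_sd = T.std(axis=1, ddof=1)
    s_sd = S.std(axis=1, ddof=1)
    for name, sd in ((tf_vals.index, t_sd), (sg_vals.index, s_sd)):
        for f in np.asarray(name)[sd == 0]:
            logger.info("feature %s constant across observations; its pairs skipped", f)
    Tz = (T - T.mean(axis=1, keepdims=True))
    Sz = (S - S.mean(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Tz @ Sz.T) / (
            np.outer(t_sd, s_sd) * (n_obs - 1)
        )
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = R * np.sqrt((n_obs - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(tstat), df=n_obs - 2)
    P[np.abs(R) >= 1.0 - 1e-14] = 0.0

    edges: list[RegulatoryEdge] = []
    tf_ids = list(tf_vals.index)
    sg_ids = list(sg_vals.index)
    for i, tf in enumerate(tf_ids):
        if t_sd[i] == 0:
            continue
        in_presence = tf in presence.index
        if not in_presence:
            logger.warning("TF %s absent from the TFBS presence map", tf)
        for j, sg in enumerate(sg_ids):
            if sg == tf or s_sd[j] == 0:
                continue
            if labels is not None and labels[tf] != labels[sg]:
                continue
            present = bool(
                in_presence and sg in presence.columns and presence.at[tf, sg] == 1
            )
            r, p = float(R[i, j]), float(P[i, j])
            if np.isnan(r):
                continue
            if r > r_min and p < p_max and present:
                edges.append(
                    RegulatoryEdge(tf, sg, r, p, n_obs, True, families.get(tf, ""))
                )
    tf_nodes = {e.tf_id for e in edges}
    gene_nodes = set(sg_ids)
    return RegulatoryNetwork(
        edges, tf_nodes, gene_nodes, regime, (r_min, p_max), families
    )


def subnetwork(net: RegulatoryNetwork, focal_genes: Iterable[str]) -> RegulatoryNetwork:
    """Edges touching any focal gene, with induced nodes.

    Focal genes with no edges remain as isolated structural-gene nodes.
    """
    focal = set(focal_genes)
    unknown = focal - net.nodes
    if unknown:
        raise ValidationError(f"focal ids not in network: {sorted(unknown)[:5]}")
    edges = [e for e in net.edges if e.tf_id in focal or e.gene_id in focal]
    tf_nodes = {e.tf_id for e in edges}
    gene_nodes = {e.gene_id for e in edges} | (focal & net.gene_nodes)
    return RegulatoryNetwork(
        edges, tf_nodes, gene_nodes, net.regime, net.thresholds, net.tf_families
    )


def family_summary(net: RegulatoryNetwork) -> pd.DataFrame:
    """TF count and edge count per TF family among edge-bearing TFs.

    Sorted by TF count descending, ties alphabetical by family.
    """
    tfs_per_family: dict[str, set[str]] = {}
    edges_per_family: dict[str, int] = {}
    for e in net.edges:
        fam = e.family or net.tf_families.get(e.tf_id, "")
        if not fam:
            raise ValidationError(f"TF {e.tf_id} has no family label")
        tfs_per_family.setdefault(fam, set()).add(e.tf_id)
        edges_per_family[fam] = edges_per_family.get(fam, 0) + 1
    rows = [
        dict(family=fam, n_tfs=len(tfs), n_edges=edges_per_family[fam])
        for fam, tfs in tfs_per_family.items()
    ]
    df = pd.DataFrame(rows, columns=["family", "n_tfs", "n_edges"])
    return df.sort_values(
        ["n_tfs", "family"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(net: RegulatoryNetwork, path: str | Path, format: str = "edge-TSV") -> None:
    """Write the network as SIF, GraphML, or a round-trippable edge TSV."""
    path = Path(path)
    if format == "SIF":
        with open(path, "w") as fh:
            for e in net.edges:
                fh.write(f"{e.tf_id} regulates {e.gene_id}\n")
    elif format == "GraphML":
        nx.write_graphml(net.to_graph(), path)
    elif format == "edge-TSV":
        df = net.to_frame().copy()
        df["pcc"] = [f"{v:.12g}" for v in df["pcc"]]
        df["p_value"] = [f"{v:.12g}" for v in df["p_value"]]
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ParameterError(f"unknown export format {format!r}")


def read_edge_tsv(path: str | Path, regime: str = "custom",
                  thresholds: tuple[float, float] = (0.0, 1.0)) -> RegulatoryNetwork:
    """Re-import an edge TSV written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t")
    edges = [
        RegulatoryEdge(
            str(r.tf_id), str(r.gene_id), float(r.pcc), float(r.p_value),
            int(r.n_obs), bool(r.tfbs_present),
            "" if pd.isna(r.family) else str(r.family),
        )
        for r in df.itertuples()
    ]
    families = {e.tf_id: e.family for e in edges if e.family}
    return RegulatoryNetwork(
        edges, {e.tf_id for e in edges}, {e.gene_id for e in edges},
        regime, thresholds, families,
    )
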