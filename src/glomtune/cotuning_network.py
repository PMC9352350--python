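"""Odorant correlation, co-tuning matrices, and the co-tuning network.

Because each odorant activates only a few glomeruli, rank correlations
between odorant response columns mostly reflect co-tuning of individual
glomeruli to odorant pairs.  Three pairwise summaries are computed per OB
and averaged across OBs:

* Spearman's rho between odorant response columns;
* co-tuning probability: the fraction of an OB's responsive glomeruli that
  respond (at any magnitude, after upstream thresholding) to both odorants;
* co-tuning count: the number of glomeruli responsive to both odorants.

Thresholding the mean count matrix at 0.875 co-tuned glomeruli per OB (at
least one co-tuned glomerulus in 7 of 8 OBs) yields a weighted, undirected
odorant network whose nodes are panel odorants ordered by structural class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ResponseDataset

logger = logging.getLogger(__name__)


def odorant_correlation(dataset: ResponseDataset) -> pd.DataFrame:
    """Mean (across OBs) Spearman rho between odorant response columns.

    Pairs involving a zero-variance column in an OB are undefined for that OB
    and excluded from the average (logged), not zero-filled.
    """
    odorants = dataset.odorants
    acc = np.zeros((len(odorants), len(odorants)))
    cnt = np.zeros_like(acc)
    for ob in dataset:
        if ob.responses.shape[0] < 2:
            raise ValueError(f"OB {ob.ob_id}: Spearman needs >= 2 glomeruli")
        values = ob.responses.to_numpy(dtype=float)
        # pandas ranks then correlates per pair, yielding NaN for pairs with a
        # zero-variance column instead of collapsing the whole matrix
        rho = ob.responses.corr(method="spearman").to_numpy()
        const = values.std(axis=0) == 0
        if const.any():
            logger.info(
                "OB %s: %d zero-variance odorant columns excluded from rho average",
                ob.ob_id, int(const.sum()),
            )
            rho[const, :] = np.nan
            rho[:, const] = np.nan
        ok = ~np.isnan(rho)
        acc[ok] += rho[ok]
        cnt += ok
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(mean, index=odorants, columns=odorants)


def _binary_support(ob) -> np.ndarray:
    return (ob.responses.to_numpy(dtype=float) > 0)


def cotuning_probability(dataset: ResponseDataset) -> pd.DataFrame:
    """Mean probability of a glomerulus responding to each odorant pair:
    per OB, (# glomeruli responsive to both) / (# responsive glomeruli in
    the OB), averaged across OBs.  OBs without responsive glomeruli are
    excluded (logged)."""
    odorants = dataset.odorants
    mats = []
    for ob in dataset:
        b = _binary_support(ob)
        n_responsive = int(b.any(axis=1).sum())
        if n_responsive == 0:
            logger.warning("OB %s has no responsive glomeruli; excluded", ob.ob_id)
            continue
        mats.append(b.astype(float).T @ b.astype(float) / n_responsive)
    if not mats:
        raise ValueError("no OB with responsive glomeruli")
    return pd.DataFrame(np.mean(mats, axis=0), index=odorants, columns=odorants)


def cotuning_count(dataset: ResponseDataset) -> pd.DataFrame:
    """Mean number of co-tuned glomeruli per OB for each odorant pair."""
    odorants = dataset.odorants
    mats = [
        _binary_support(ob).astype(float).T @ _binary_support(ob).astype(float)
        for ob in dataset
    ]
    return pd.DataFrame(np.mean(mats, axis=0), index=odorants, columns=odorants)


@dataclass
class CoTuningNetwork:
    """Weighted undirected odorant graph of thresholded mean co-tuning counts."""

    graph: nx.Graph
    threshold: float
    #: node order for circular layout export (panel classification order)
    node_order: list[str]

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {
                "odorant_i": u,
                "odorant_j": v,
                "weight": d["weight"],
                "class_i": self.graph.nodes[u]["structural_class"],
                "class_j": self.graph.nodes[v]["structural_class"],
                "color_class": d["color_class"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


def build_network(
    counts: pd.DataFrame,
    classes: dict[str, str],
    threshold: float = 0.875,
) -> CoTuningNetwork:
    """Threshold the mean co-tuning count matrix into an odorant network.

    Edges keep pairs with weight >= ``threshold`` (0.875 corresponds to one
    co-tuned glomerulus per OB in at least 7 of 8 OBs, and the boundary value
    itself passes).  Nodes carry structural-class labels and are ordered by
    class for circular layout export; cross-class edges are color-keyed to
    the endpoint class with more connected members.
    """
    if not np.allclose(counts.to_numpy(), counts.to_numpy().T, equal_nan=True):
        raise ValueError("co-tuning count matrix must be symmetric")
    g = nx.Graph()
    odorants = list(counts.index)
    for o in odorants:
        g.add_node(o, structural_class=classes.get(o, "MIXED"))
    arr = counts.to_numpy()
    for i in range(len(odorants)):
        for j in range(i + 1, len(odorants)):
            w = arr[i, j]
            if not np.isnan(w) and w >= threshold:
                g.add_edge(odorants[i], odorants[j], weight=float(w))

    # connected members per class (nodes with >= 1 edge)
    members = {}
    for n in g.nodes:
        if g.degree(n) > 0:
            members[g.nodes[n]["structural_class"]] = (
                members.get(g.nodes[n]["structural_class"], 0) + 1
            )
    for u, v, d in g.edges(data=True):
        cu, cv = g.nodes[u]["structural_class"], g.nodes[v]["structural_class"]
        d["color_class"] = cu if members.get(cu, 0) >= members.get(cv, 0) else cv

    # node order: group by class in panel order, MIXED last
    class_rank: dict[str, int] = {}
    for o in odorants:
        c = classes.get(o, "MIXED")
        if c not in class_rank:
            class_rank[c] = len(class_rank)
    class_rank["MIXED"] = len(class_rank) + 1
    order = sorted(
        odorants, key=lambda o: (class_rank[classes.get(o, "MIXED")], odorants.index(o))
    )
    return CoTuningNetwork(graph=g, threshold=threshold, node_order=order)
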