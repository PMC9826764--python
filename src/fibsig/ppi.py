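"""Module-induced interaction subnetworks and degree-centrality hubs."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .types import GeneSet, InteractionNetwork


@dataclass
class HubReport:
    """Degree-ranked genes with a hub flag and the rule that produced it.

    ``table`` is indexed by gene with columns ``degree`` (incident edge
    count), ``rank`` (dense rank, degree descending) and ``is_hub``; rows
    are ordered by decreasing degree with ties broken by symbol.
    """

    table: pd.DataFrame
    cutoff_rule: dict

    @property
    def hubs(self) -> GeneSet:
        return GeneSet("hubs", list(self.table.index[self.table["is_hub"]]))


def induced_subnetwork(
    network: InteractionNetwork, genes: GeneSet
) -> InteractionNetwork:
    """Subnetwork on a gene set; members absent from any retained edge stay
    as isolated degree-0 nodes."""
    g = nx.Graph()
    g.add_nodes_from(genes.genes)
    for a, b, d in network.graph.edges(data=True):
        if a in genes and b in genes:
            g.add_edge(a, b, score=d["score"])
    return InteractionNetwork(g)


def degree_centrality(network: InteractionNetwork) -> HubReport:
    """Degrees with deterministic dense ranks (no hub flag yet)."""
    degrees = dict(network.graph.degree())
    genes = sorted(degrees, key=lambda g: (-degrees[g], g))
    table = pd.DataFrame({"degree": [degrees[g] for g in genes]}, index=genes)
    table["rank"] = (
        table["degree"].rank(method="dense", ascending=False).astype(int)
    )
    table["is_hub"] = False
    return HubReport(table=table, cutoff_rule={"rule": "none"})


def select_hubs(report: HubReport, rule: str = "mean_plus_sd",
                k: int | None = None, threshold: int | None = None) -> HubReport:
    """Flag hub genes by one of three rules.

    ``mean_plus_sd``: degree > mean + 1·sd of the node degrees (default).
    ``top_k``: the k highest-degree genes; ties at the boundary are all
    included (k may be exceeded; recorded in ``cutoff_rule``).
    ``degree_ge``: degree >= threshold.
    """
    table = report.table.copy()
    degrees = table["degree"]
    if rule == "mean_plus_sd":
        cut = float(degrees.mean() + degrees.std(ddof=0))
        table["is_hub"] = degrees > cut
        meta = {"rule": rule, "cutoff": cut}
    elif rule == "top_k":
        if k is None or k <= 0:
            raise ValueError("top_k requires k > 0")
        if k >= len(table):
            table["is_hub"] = True
            meta = {"rule": rule, "k": k, "boundary_tie": False}
        else:
            boundary = degrees.iloc[k - 1]
            table["is_hub"] = degrees >= boundary
            meta = {
                "rule": rule,
                "k": k,
                "boundary_tie": int(table["is_hub"].sum()) > k,
                "n_selected": int(table["is_hub"].sum()),
            }
    elif rule == "degree_ge":
        if threshold is None or threshold < 0:
            raise ValueError("degree_ge requires threshold >= 0")
        table["is_hub"] = degrees >= threshold
        meta = {"rule": rule, "threshold": threshold}
    else:
        raise ValueError(f"unknown hub rule {rule!r}")
    return HubReport(table=table, cutoff_rule=meta)
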