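"""Genus-flavor correlation networks and the three-criterion core screen.

A genus is called functional-core when it (i) correlates strongly with
at least one amino acid AND at least one volatile compound, (ii) has
VIP_pred >= 1.00 in the cross-block latent model, and (iii) has at least
16 flavor partners in the |r| > 0.7 network.  Edge inclusion is strictly
greater than the cutoff (an |r| exactly at the threshold is out), while
the VIP and partner-count screens are inclusive ("at least").

No multiple-testing control is applied in the screen — it is a pure
|r|-magnitude filter; an informational Benjamini-Hochberg q-value column
can be attached to edge exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, FlavorTable, to_relative_abundance

__all__ = [
    "CorrelationNetwork",
    "CoreScreeningReport",
    "correlate",
    "threshold_network",
    "partner_summary",
    "genus_lists",
    "screen_core",
    "export_network",
    "read_edge_tsv",
]


@dataclass
class CorrelationNetwork:
    edges: pd.DataFrame  # columns: genus, flavor, r, sign
    threshold: float
    method: str

    def __post_init__(self) -> None:
        required = {"genus", "flavor", "r", "sign"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edge frame must have columns {sorted(required)}")
        if self.edges.duplicated(subset=["genus", "flavor"]).any():
            raise ValueError("duplicate (genus, flavor) edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def genus_degree(self) -> pd.Series:
        return self.edges.groupby("genus").size()


@dataclass
class CoreScreeningReport:
    table: pd.DataFrame  # per-genus record
    core: list  # genus ids passing all three criteria
    vip_cut: float
    partner_cut: int


def correlate(
    x: AbundanceTable | pd.DataFrame,
    y: FlavorTable | pd.DataFrame,
    method: str = "pearson",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Genus x flavor correlation matrix on aligned samples.

    Computed on relative abundances (counts are normalised first) against
    raw flavor intensities; ``log_transform`` applies log10(v + pc) with
    pc = half the smallest positive value, per block.  A constant genus or
    flavor column yields NaN (undefined), never a silent zero.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if isinstance(x, AbundanceTable):
        xdf = (x if x.proportions else to_relative_abundance(x)).data
    else:
        xdf = x
    ydf = y.data if isinstance(y, FlavorTable) else y
    if list(xdf.index) != list(ydf.index):
        raise ValueError("sample ids of the two blocks do not match")
    n = len(xdf)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation")

    xv = xdf.to_numpy(dtype=float)
    yv = ydf.to_numpy(dtype=float)
    if log_transform:
        xv = _log_pc(xv)
        yv = _log_pc(yv)
    if method == "spearman":
        xv = stats.rankdata(xv, axis=0)
        yv = stats.rankdata(yv, axis=0)
    xc = xv - xv.mean(axis=0)
    yc = yv - yv.mean(axis=0)
    xs = xc.std(axis=0)
    ys = yc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / n / np.outer(xs, ys)
    r[np.outer(xs == 0, np.ones(len(ys), bool))] = np.nan
    r[np.outer(np.ones(len(xs), bool), ys == 0)] = np.nan
    r = np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame(r, index=xdf.columns, columns=ydf.columns)


def _log_pc(v: np.ndarray) -> np.ndarray:
    pos = v[v > 0]
    pc = pos.min() / 2.0 if len(pos) else 1.0
    return np.log10(v + pc)


def threshold_network(
    r_matrix: pd.DataFrame, cutoff: float = 0.7, method: str = "pearson"
) -> CorrelationNetwork:
    """Signed bipartite network of entries with |r| strictly above ``cutoff``."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    mask = r_matrix.abs() > cutoff  # NaN compares False: undefined entries excluded
    rows = []
    for genus in r_matrix.index:
        hits = r_matrix.columns[mask.loc[genus]]
        for flavor in hits:
            r = r_matrix.at[genus, flavor]
            rows.append(
                {"genus": genus, "flavor": flavor, "r": r,
                 "sign": "positive" if r > 0 else "negative"}
            )
    edges = pd.DataFrame(rows, columns=["genus", "flavor", "r", "sign"])
    return CorrelationNetwork(edges=edges, threshold=cutoff, method=method)


def partner_summary(net: CorrelationNetwork, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-genus partner counts (total, AA, VF) from a thresholded network.

    Raises if an edge references a flavor id absent from the annotation.
    Also usable for the genus lists "correlates with >= 1 AA / VF / both".
    """
    unknown = [f for f in net.edges["flavor"].unique() if f not in annotation.index]
    if unknown:
        raise ValueError(f"unannotated flavor ids in network: {unknown}")
    genera = net.edges["genus"].unique()
    rows = {}
    for genus in genera:
        flavors = net.edges.loc[net.edges["genus"] == genus, "flavor"]
        kinds = annotation.loc[flavors, "kind"]
        rows[genus] = {
            "n_partners": len(flavors),
            "n_aa": int((kinds == "AA").sum()),
            "n_vf": int((kinds == "VF").sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if len(out) == 0:
        out = pd.DataFrame(columns=["n_partners", "n_aa", "n_vf"], dtype=int)
    out.index.name = "genus"
    return out.sort_index()


def genus_lists(summary: pd.DataFrame) -> dict:
    """Genus sets correlating with >= 1 AA, >= 1 VF, and with both."""
    aa = set(summary.index[summary["n_aa"] >= 1])
    vf = set(summary.index[summary["n_vf"] >= 1])
    return {"AA": aa, "VF": vf, "both": aa & vf}


def screen_core(
    summary: pd.DataFrame,
    vip: pd.Series,
    vip_cut: float = 1.00,
    partner_cut: int = 16,
) -> CoreScreeningReport:
    """Apply the three-criterion functional-core screen.

    ``summary`` is the per-genus partner table at the 0.7 network (genera
    with no strong partner may be absent; they fail i and iii by
    definition).  Every genus in the summary must have a VIP value.
    Criteria: (i) >= 1 AA partner and >= 1 VF partner; (ii) VIP >=
    ``vip_cut`` (inclusive); (iii) total partners >= ``partner_cut``
    (inclusive).  Core = i and ii and iii.
    """
    missing = [g for g in summary.index if g not in vip.index]
    if missing:
        raise ValueError(f"genera in summary missing from VIP vector: {missing}")
    full = summary.reindex(vip.index).fillna(0).astype(
        {"n_partners": int, "n_aa": int, "n_vf": int}
    )
    crit_i = (full["n_aa"] >= 1) & (full["n_vf"] >= 1)
    crit_ii = vip >= vip_cut
    crit_iii = full["n_partners"] >= partner_cut
    table = pd.DataFrame(
        {
            "correlates_with_AA": full["n_aa"] >= 1,
            "correlates_with_VF": full["n_vf"] >= 1,
            "criterion_i": crit_i,
            "VIP_pred": vip,
            "criterion_ii": crit_ii,
            "n_flavor_partners": full["n_partners"],
            "criterion_iii": crit_iii,
            "core": crit_i & crit_ii & crit_iii,
        }
    )
    table.index.name = "genus"
    core = sorted(table.index[table["core"]])
    return CoreScreeningReport(table=table, core=core, vip_cut=vip_cut, partner_cut=partner_cut)


def export_network(
    net: CorrelationNetwork,
    path,
    format: str = "edge_tsv",
    annotation: pd.DataFrame | None = None,
) -> None:
    """Write a network as a flat edge TSV or as bipartite GraphML.

    GraphML nodes carry ``side`` (genus/flavor) and, when an annotation is
    supplied, the flavor kind and category; edges carry r and sign.
    """
    if format == "edge_tsv":
        net.edges.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.Graph(threshold=net.threshold, method=net.method)
        for _, e in net.edges.iterrows():
            attrs = {"side": "flavor"}
            if annotation is not None and e["flavor"] in annotation.index:
                attrs["kind"] = str(annotation.at[e["flavor"], "kind"])
                attrs["category"] = str(annotation.at[e["flavor"], "category"])
            g.add_node(f"genus::{e['genus']}", side="genus")
            g.add_node(f"flavor::{e['flavor']}", **attrs)
            g.add_edge(
                f"genus::{e['genus']}", f"flavor::{e['flavor']}",
                r=float(e["r"]), sign=str(e["sign"]),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_edge_tsv(path, threshold: float, method: str = "pearson") -> CorrelationNetwork:
    edges = pd.read_csv(path, sep="\t")
    return CorrelationNetwork(edges=edges, threshold=threshold, method=method)
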