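"""Direct/indirect transfer classification over the breeding pedigree.

A haplotype segment shared between an ancestor and a final cultivar was
transferred *directly* when a single parent->offspring cross connects
them, and *indirectly* when the material passed through at least one
intermediate cultivar.  "Direct" means a literal parent edge even when
the ancestor's material also reaches the descendant through other
routes.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .io import PedigreeGraph


def classify_path(ped: PedigreeGraph, ancestor: str, descendant: str) -> str:
    """Classify the transfer path: 'direct', 'indirect' or 'none'.

    direct   -- edge ancestor -> descendant exists
    indirect -- a directed path of >= 2 edges exists (and no direct edge)
    none     -- descendant is not reachable from ancestor
    """
    g = ped.graph
    if ancestor == descendant:
        raise ValueError("ancestor and descendant must differ")
    for node in (ancestor, descendant):
        if node not in g:
            raise KeyError(f"{node!r} not in pedigree")
    if g.has_edge(ancestor, descendant):
        return "direct"
    if nx.has_path(g, ancestor, descendant):
        return "indirect"
    return "none"


def expected_contribution(ped: PedigreeGraph, ancestor: str, descendant: str) -> float:
    """Theoretical genome fraction transmitted from ancestor to descendant.

    Each cross halves the expected contribution, so the fraction is the
    sum over all directed pedigree paths of (1/2)^(path length).  Returns
    0.0 when no path exists.  Selection and undocumented parents are
    ignored.
    """
    g = ped.graph
    for node in (ancestor, descendant):
        if node not in g:
            raise KeyError(f"{node!r} not in pedigree")
    if ancestor == descendant:
        raise ValueError("ancestor and descendant must differ")
    total = 0.0
    for path in nx.all_simple_paths(g, ancestor, descendant):
        total += 0.5 ** (len(path) - 1)
    return total


def aggregate_transfer(records: pd.DataFrame, ped: PedigreeGraph) -> pd.DataFrame:
    """Attach path types to per-pair IBD summaries and add subtotal rows.

    ``records`` needs columns ``ancestor``, ``descendant``, ``n_ibd``,
    ``total_size_mb`` (an optional ``pedigree`` column is carried
    through; otherwise the descendant name labels the pedigree).

    Returns one row per input pair plus, per (pedigree, path_type), a
    subtotal row with ``ancestor`` set to "<path_type> subtotal".  Pairs
    not connected in the pedigree are flagged ``path_type='none'`` and
    excluded from subtotals.
    """
    required = {"ancestor", "descendant", "n_ibd", "total_size_mb"}
    lacking = required - set(records.columns)
    if lacking:
        raise ValueError(f"records lack columns {sorted(lacking)}")
    rows = []
    for _, r in records.iterrows():
        pedigree = r.get("pedigree", r["descendant"])
        try:
            ptype = classify_path(ped, r["ancestor"], r["descendant"])
        except KeyError:
            ptype = "absent"
        rows.append(
            {
                "pedigree": pedigree,
                "ancestor": r["ancestor"],
                "descendant": r["descendant"],
                "path_type": ptype,
                "n_ibd": int(r["n_ibd"]),
                "total_size_mb": float(r["total_size_mb"]),
            }
        )
    out = pd.DataFrame(rows)
    subtotals = []
    if not out.empty:
        valid = out[out["path_type"].isin(["direct", "indirect"])]
        for (pedigree, ptype), grp in valid.groupby(["pedigree", "path_type"], sort=True):
            subtotals.append(
                {
                    "pedigree": pedigree,
                    "ancestor": f"{ptype} subtotal",
                    "descendant": grp["descendant"].iloc[0],
                    "path_type": ptype,
                    "n_ibd": int(grp["n_ibd"].sum()),
                    "total_size_mb": round(float(grp["total_size_mb"].sum()), 6),
                }
            )
    return pd.concat([out, pd.DataFrame(subtotals)], ignore_index=True)


def transfer_subtotals(table: pd.DataFrame) -> dict:
    """Extract {(pedigree, path_type): (n_ibd, total_size_mb)} subtotals
    from an :func:`aggregate_transfer` table."""
    subs = table[table["ancestor"].str.endswith("subtotal", na=False)]
    return {
        (r["pedigree"], r["path_type"]): (int(r["n_ibd"]), float(r["total_size_mb"]))
        for _, r in subs.iterrows()
    }
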