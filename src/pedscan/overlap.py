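"""QTL x IBD intersection, candidate-gene nomination and selection
annotation.

A QTL counts as "in IBD" when any base pair of its interval overlaps any
IBD segment of the pedigree's pairs (no minimum overlap).  Candidate
genes must lie fully inside an overlap region by default (a flag
relaxes this to any overlap) and are joined with the pedigree path of
the IBD pair's ancestor member to name the donor lineage, e.g. a gene
transferred Shengliyoucai -> Chuanyou2 -> Ningyou7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from intervaltree import IntervalTree

from .io import FeatureInterval, PedigreeGraph
from .ibd import IBDSegment

logger = logging.getLogger(__name__)


@dataclass
class OverlapRecord:
    """A nonempty intersection between one QTL and one IBD segment."""

    qtl_id: str
    trait: str
    chromosome: str
    start_bp: int
    end_bp: int
    pair: tuple[str, str]
    pedigree_label: str | None = None

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def intersect_qtl_ibd(
    qtls: Sequence[FeatureInterval],
    segments: Sequence[IBDSegment],
    pedigree_label: str | None = None,
) -> list[OverlapRecord]:
    """Interval-tree intersection of QTL intervals with IBD segments.

    One record per overlapping (QTL, segment) pair, sorted by
    (chromosome, start, qtl, pair).
    """
    trees: dict[str, IntervalTree] = {}
    for seg in segments:
        # half-open tree coordinates over 1-based inclusive segments
        trees.setdefault(seg.chromosome, IntervalTree()).addi(
            seg.start_bp, seg.end_bp + 1, seg
        )
    records: list[OverlapRecord] = []
    for q in qtls:
        if q.kind != "QTL":
            raise ValueError(f"{q.feature_id} is not a QTL interval")
        tree = trees.get(q.chromosome)
        if tree is None:
            continue
        for hit in tree.overlap(q.start, q.end + 1):
            seg: IBDSegment = hit.data
            records.append(
                OverlapRecord(
                    qtl_id=q.feature_id,
                    trait=q.trait,
                    chromosome=q.chromosome,
                    start_bp=max(q.start, seg.start_bp),
                    end_bp=min(q.end, seg.end_bp),
                    pair=(seg.sample_a, seg.sample_b),
                    pedigree_label=pedigree_label,
                )
            )
    records.sort(key=lambda r: (r.chromosome, r.start_bp, r.qtl_id, r.pair))
    return records


def qtl_in_ibd_tally(
    qtls: Sequence[FeatureInterval], records: Sequence[OverlapRecord]
) -> pd.DataFrame:
    """Per-trait 'x of y QTL fall in IBD' tallies."""
    in_ibd = {r.qtl_id for r in records}
    rows = []
    traits = sorted({q.trait for q in qtls})
    for trait in traits:
        members = [q for q in qtls if q.trait == trait]
        rows.append(
            {
                "trait": trait,
                "n_qtl": len(members),
                "n_in_ibd": sum(q.feature_id in in_ibd for q in members),
            }
        )
    return pd.DataFrame(rows, columns=["trait", "n_qtl", "n_in_ibd"])


def _donor_chains(ped: PedigreeGraph, ancestor: str, descendant: str) -> list[str]:
    """All pedigree paths ancestor -> descendant as 'A -> B -> C' strings."""
    g = ped.graph
    if ancestor not in g or descendant not in g:
        return []
    chains = []
    for path in nx.all_simple_paths(g, ancestor, descendant):
        chains.append(" -> ".join(path))
    return chains


def candidate_genes(
    overlaps: Sequence[OverlapRecord],
    genes: Sequence[FeatureInterval],
    ped: PedigreeGraph | None = None,
    require_containment: bool = True,
) -> pd.DataFrame:
    """Genes inside QTL x IBD overlap regions, with donor lineage.

    By default a gene must be fully contained in the overlap interval;
    with ``require_containment=False`` any base-pair overlap suffices.
    The donor chain lists every pedigree path from the IBD pair's
    ancestor member to its descendant member (both orientations are
    tried; the one with a path wins).
    """
    rows = []
    for rec in overlaps:
        for g in genes:
            if g.kind != "gene" or g.chromosome != rec.chromosome:
                continue
            if require_containment:
                hit = g.start >= rec.start_bp and g.end <= rec.end_bp
            else:
                hit = g.start <= rec.end_bp and g.end >= rec.start_bp
            if not hit:
                continue
            chains: list[str] = []
            if ped is not None:
                a, b = rec.pair
                chains = _donor_chains(ped, a, b) or _donor_chains(ped, b, a)
            rows.append(
                {
                    "gene_id": g.feature_id,
                    "trait": g.trait,
                    "chromosome": g.chromosome,
                    "gene_start_bp": g.start,
                    "gene_end_bp": g.end,
                    "qtl_id": rec.qtl_id,
                    "pair": f"{rec.pair[0]}|{rec.pair[1]}",
                    "donor_chain": "; ".join(chains),
                    "pedigree_label": rec.pedigree_label,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "trait", "chromosome", "gene_start_bp", "gene_end_bp",
                 "qtl_id", "pair", "donor_chain", "pedigree_label"],
    )
    return df.drop_duplicates().reset_index(drop=True)


def selection_annotate(
    gene_table: pd.DataFrame,
    scan: pd.DataFrame,
    convention: str = "main_text",
) -> pd.DataFrame:
    """Attach each gene's selection-timing quadrant.

    A gene inherits (D, Hs) from the scan window whose midpoint is
    nearest to the gene midpoint on the same chromosome (ties broken
    toward the lower coordinate).  Genes on chromosomes without windows,
    or whose nearest window has undefined D, stay unannotated (logged).
    """
    from .scan import classify_selection

    out = gene_table.copy()
    quadrants, d_vals, hs_vals = [], [], []
    for _, row in out.iterrows():
        mid = (int(row["gene_start_bp"]) + int(row["gene_end_bp"])) // 2
        windows = scan[scan["chromosome"] == row["chromosome"]]
        if windows.empty:
            logger.info("gene %s: no scan windows on %s", row["gene_id"], row["chromosome"])
            quadrants.append(None)
            d_vals.append(float("nan"))
            hs_vals.append(float("nan"))
            continue
        dist = (windows["midpoint_bp"] - mid).abs()
        # stable idxmin on (distance, coordinate) implements the tie rule
        order = windows.assign(_dist=dist).sort_values(
            ["_dist", "midpoint_bp"], kind="mergesort"
        )
        w = order.iloc[0]
        d_vals.append(float(w["D"]))
        hs_vals.append(float(w["Hs"]))
        if pd.isna(w["D"]):
            quadrants.append(None)
            continue
        quadrant, _ = classify_selection(float(w["D"]), float(w["Hs"]), convention)
        quadrants.append(quadrant)
    out["D"] = d_vals
    out["Hs"] = hs_vals
    out["quadrant"] = quadrants
    return out


def quadrant_counts(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-quadrant, per-trait gene counts from an annotated table."""
    sub = annotated.dropna(subset=["quadrant"])
    if sub.empty:
        return pd.DataFrame(columns=["quadrant", "trait", "n_genes"])
    counts = (
        sub.groupby(["quadrant", "trait"], sort=True)["gene_id"]
        .nunique()
        .reset_index(name="n_genes")
    )
    return counts
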