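"""Readers and writers for the standard input/output formats.

Conventions
-----------
* Marker positions are 1-based bp throughout the library; exported BED is
  0-based half-open, matching each format's dominant convention.
* Genotype calls are coded ``0`` (reference allele), ``1`` (alternate
  allele) and ``-1`` (missing).  Lines are inbred and treated as
  homozygous, so one code per line per marker suffices; residual
  heterozygous calls in a VCF are set to missing and counted in the QC
  summary rather than rejected.
* Chromosome names follow the *Brassica napus* convention A01..A10 /
  C01..C09; the first character assigns the marker to the A or C
  subgenome.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: Valid chromosome names for the allotetraploid AC genome.
CHROMOSOMES = tuple(f"A{i:02d}" for i in range(1, 11)) + tuple(
    f"C{i:02d}" for i in range(1, 10)
)


def subgenome(chromosome: str) -> str:
    """Subgenome label ('A' or 'C') from a chromosome name."""
    sg = chromosome[0].upper()
    if sg not in ("A", "C"):
        raise ValueError(f"chromosome {chromosome!r} maps to no subgenome")
    return sg


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Physical map of SNP markers: id, chromosome and 1-based bp position.

    Markers are stored in map order: grouped by chromosome, strictly
    increasing position within each chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker_id", "chromosome", "position"]
        missing_cols = [c for c in required if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"marker map lacks columns {missing_cols}")
        self.df = self.df[required].reset_index(drop=True)
        self.df["position"] = self.df["position"].astype(np.int64)
        if self.df["marker_id"].duplicated().any():
            dups = self.df["marker_id"][self.df["marker_id"].duplicated()]
            raise ValueError(f"duplicate marker ids: {sorted(set(dups))[:5]}")
        bad = sorted(set(self.df["chromosome"]) - set(CHROMOSOMES))
        if bad:
            raise ValueError(f"unknown chromosomes: {bad}")
        for chrom, sub in self.df.groupby("chromosome", sort=False):
            pos = sub["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"positions on {chrom} are not strictly increasing"
                )
        self._index = {m: i for i, m in enumerate(self.df["marker_id"])}

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.df["marker_id"])

    @property
    def chromosomes(self) -> list[str]:
        """Chromosomes in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.df["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]

    def chrom_indices(self, chromosome: str) -> np.ndarray:
        """Column indices of the markers on one chromosome, in map order."""
        return np.flatnonzero(
            (self.df["chromosome"] == chromosome).to_numpy()
        )

    def positions(self, chromosome: str | None = None) -> np.ndarray:
        if chromosome is None:
            return self.df["position"].to_numpy()
        return self.df["position"].to_numpy()[self.chrom_indices(chromosome)]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class QCSummary:
    """Counts of cells/sites altered or dropped while loading genotypes."""

    n_het_to_missing: int = 0
    n_sites_dropped_nonbiallelic: int = 0
    n_unknown_markers: int = 0
    per_sample_missing: dict = field(default_factory=dict)


@dataclass
class GenotypeMatrix:
    """Samples x markers call matrix over {0, 1, MISSING}, aligned to a map."""

    sample_ids: list[str]
    markers: MarkerMap
    calls: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        bad = set(np.unique(self.calls)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"invalid call codes: {sorted(bad)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, sample: str) -> np.ndarray:
        try:
            return self.calls[self._sample_index[sample]]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def missing_rate(self) -> pd.Series:
        """Fraction of missing calls per sample."""
        frac = (self.calls == MISSING).mean(axis=1)
        return pd.Series(frac, index=self.sample_ids, name="missing_rate")

    def write_tsv(self, path: str | Path) -> None:
        """Rows = samples, header = marker ids, cells in {0,1,NA}."""
        df = pd.DataFrame(
            self.calls, index=self.sample_ids, columns=self.markers.marker_ids
        ).astype(object)
        df[df == -1] = "NA"
        df.to_csv(path, sep="\t", index_label="sample")


def read_genotypes(path: str | Path, marker_map: MarkerMap) -> tuple[GenotypeMatrix, QCSummary]:
    """Read a genotype matrix (TSV or VCF) aligned to ``marker_map`` order.

    TSV layout: one row per sample, first column ``sample``, remaining
    columns named by marker id with cells in {0, 1, NA}.  VCF: biallelic
    sites whose ID matches a mapped marker; heterozygous calls become
    MISSING (counted), non-biallelic sites are dropped (counted).

    Raises ``ValueError`` listing offenders when the TSV header contains
    marker ids absent from the map.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_genotypes_vcf(path, marker_map)
    return _read_genotypes_tsv(path, marker_map)


def _read_genotypes_tsv(path: Path, marker_map: MarkerMap) -> tuple[GenotypeMatrix, QCSummary]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=object)
    unknown = [m for m in df.columns if m not in marker_map._index]
    if unknown:
        raise ValueError(f"unknown marker ids in genotype file: {unknown}")
    qc = QCSummary()
    n = len(df.index)
    calls = np.full((n, len(marker_map)), MISSING, dtype=np.int8)
    col_pos = {m: j for j, m in enumerate(df.columns)}
    raw = df.to_numpy()
    for m, j in col_pos.items():
        target = marker_map.index_of(m)
        col = raw[:, j]
        for i, v in enumerate(col):
            if pd.isna(v):
                continue
            calls[i, target] = np.int8(int(v))
    gm = GenotypeMatrix(list(df.index.astype(str)), marker_map, calls)
    qc.per_sample_missing = gm.missing_rate().to_dict()
    return gm, qc


def _read_genotypes_vcf(path: Path, marker_map: MarkerMap) -> tuple[GenotypeMatrix, QCSummary]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    qc = QCSummary()
    calls = np.full((len(samples), len(marker_map)), MISSING, dtype=np.int8)
    unknown: list[str] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            qc.n_sites_dropped_nonbiallelic += 1
            continue
        vid = variant.ID
        if vid is None or vid not in marker_map._index:
            unknown.append(vid or f"{variant.CHROM}:{variant.POS}")
            continue
        j = marker_map.index_of(vid)
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        for i, gt in enumerate(variant.gt_types):
            if gt == 0:
                calls[i, j] = 0
            elif gt == 2:
                calls[i, j] = 1
            elif gt == 1:
                qc.n_het_to_missing += 1
    if unknown:
        qc.n_unknown_markers = len(unknown)
        raise ValueError(f"unknown marker ids in VCF: {unknown[:10]}")
    gm = GenotypeMatrix(samples, marker_map, calls)
    qc.per_sample_missing = gm.missing_rate().to_dict()
    return gm, qc


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


class PedigreeGraph:
    """Directed acyclic cross graph over cultivars.

    Edges run parent -> offspring and carry a breeding-cycle index.
    Founders are the in-degree-0 nodes.  Nodes may carry a ``species``
    tag ('AC' allotetraploid or 'A' diploid).
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()
        self.validate()

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"pedigree contains a cycle: {cycle}")
        for node in self.graph.nodes:
            if self.graph.in_degree(node) > 2:
                parents = list(self.graph.predecessors(node))
                raise ValueError(f"{node} has >2 parents: {parents}")

    def add_cross(self, parent: str, offspring: str, cycle: int = 0) -> None:
        self.graph.add_edge(parent, offspring, cycle=cycle)
        self.validate()

    @property
    def founders(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def parents(self, node: str) -> list[str]:
        return sorted(self.graph.predecessors(node))

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.graph))

    def species(self, node: str) -> str:
        return self.graph.nodes[node].get("species", "AC")

    def set_species(self, node: str, species: str) -> None:
        if species not in ("AC", "A"):
            raise ValueError(f"species must be 'AC' or 'A', got {species!r}")
        self.graph.nodes[node]["species"] = species

    @classmethod
    def read_csv(cls, path: str | Path) -> "PedigreeGraph":
        """CSV edge list ``parent,offspring,cycle`` (header optional)."""
        g = nx.DiGraph()
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                if row[0].strip().lower() == "parent":  # header
                    continue
                parent, offspring = row[0].strip(), row[1].strip()
                cycle = int(row[2]) if len(row) > 2 and row[2].strip() else 0
                g.add_edge(parent, offspring, cycle=cycle)
        return cls(g)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["parent", "offspring", "cycle"])
            for u, v, d in sorted(self.graph.edges(data=True)):
                w.writerow([u, v, d.get("cycle", 0)])


def read_pedigree(path: str | Path) -> PedigreeGraph:
    return PedigreeGraph.read_csv(path)


# ---------------------------------------------------------------------------
# Feature intervals (QTL / genes)
# ---------------------------------------------------------------------------

TRAITS = (
    "flowering_time",
    "oil",
    "glucosinolate",
    "erucic_acid",
    "protein",
    "root_P",
)


@dataclass(frozen=True)
class FeatureInterval:
    """A QTL or gene interval with a trait label; 1-based inclusive bp."""

    feature_id: str
    kind: str  # {"QTL", "gene"}
    trait: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.feature_id}: start > end")
        if self.kind not in ("QTL", "gene"):
            raise ValueError(f"{self.feature_id}: kind must be QTL or gene")
        if self.trait not in TRAITS:
            raise ValueError(
                f"{self.feature_id}: trait {self.trait!r} not in {TRAITS}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def read_features_bed(path: str | Path, kind: str) -> list[FeatureInterval]:
    """BED-like TSV: chrom, start(0-based), end, feature_id, trait.

    Coordinates convert to the library's 1-based inclusive convention.
    """
    feats: list[FeatureInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, fid, trait = line.split("\t")[:5]
            feats.append(
                FeatureInterval(fid, kind, trait, chrom, int(start) + 1, int(end))
            )
    return feats


def write_features_bed(feats: Sequence[FeatureInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in sorted(feats, key=lambda f: (f.chromosome, f.start, f.feature_id)):
            fh.write(
                f"{f.chromosome}\t{f.start - 1}\t{f.end}\t{f.feature_id}\t{f.trait}\n"
            )


# ---------------------------------------------------------------------------
# IBD segment BED I/O
# ---------------------------------------------------------------------------


def write_segments_bed(segments: Iterable, path: str | Path) -> None:
    """Write IBD segments as BED6: 0-based half-open, name = 'a|b',
    score = supporting marker count.  Deterministic (chrom, start, pair) sort.
    """
    rows = sorted(
        segments,
        key=lambda s: (s.chromosome, s.start_bp, s.sample_a, s.sample_b),
    )
    with open(path, "w") as fh:
        for s in rows:
            fh.write(
                f"{s.chromosome}\t{s.start_bp - 1}\t{s.end_bp}\t"
                f"{s.sample_a}|{s.sample_b}\t{s.n_markers}\t.\n"
            )


def read_segments_bed(path: str | Path) -> list:
    """Re-read a segment BED written by :func:`write_segments_bed`."""
    from .ibd import IBDSegment

    segments = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start, end, name, score, _ = line.split("\t")
            a, b = name.split("|")
            segments.append(
                IBDSegment(
                    sample_a=a,
                    sample_b=b,
                    chromosome=chrom,
                    start_bp=int(start) + 1,
                    end_bp=int(end),
                    n_markers=int(score),
                    n_mismatch=0,
                )
            )
    return segments
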