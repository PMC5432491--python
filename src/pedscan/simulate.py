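"""Forward simulation of a breeding pedigree of fully homozygous lines.

The generator walks the pedigree DAG in topological order.  Founders are
independent homozygous lines with per-marker allele frequencies drawn
from a configured distribution.  Each cross produces one recombinant
gamete per chromosome (crossover count Poisson with mean equal to the
chromosome's genetic length in Morgans, breakpoints uniform in genetic
distance, which under a uniform cM/Mb map is uniform in bp) and fixes it
to homozygosity — the doubled-haploid endpoint used in rapeseed
breeding programmes.  Every allele of every line carries an exact
ancestry track (which founder it came from and which parent transmitted
it), so true IBD segments, crossover breakpoints and realized genome
fractions are available as ground truth for the detector and the
selection scan.

Directional selection at designated trait loci is applied by gamete
rejection: whenever a parent carries the favored founder's allele at a
target locus, gametes are redrawn until the offspring carries it too,
mimicking deterministic breeder mass selection.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CHROMOSOMES, MISSING, GenotypeMatrix, MarkerMap, PedigreeGraph, subgenome
from .ibd import IBDSegment


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31, derived from a global seed and a
    stage label so adding a stage never perturbs earlier randomness."""
    digest = hashlib.blake2b(f"{seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class SimConfig:
    """Synthetic breeding-history parameters.

    Defaults are a scaled-down two-subgenome genome: 4 chromosomes of
    11 Mb with 500 evenly spaced markers each (~45 SNP/Mb, matching the
    marker density of a 60K array on the rapeseed genome), recombination
    at 2 cM/Mb, founder minor-allele frequencies uniform on [0.2, 0.8].
    """

    n_chromosomes: int = 4
    markers_per_chromosome: int = 500
    chromosome_length_bp: int = 11_000_000
    cm_per_mb: float = 2.0
    maf_distribution: tuple = ("uniform", 0.2, 0.8)
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    selection_targets: list = field(default_factory=list)  # (chrom, pos_bp, founder)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.genotyping_error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.chromosome_length_bp <= 0 or self.markers_per_chromosome <= 0:
            raise ValueError("lengths and marker counts must be positive")
        if self.n_chromosomes < 1 or self.n_chromosomes > 19:
            raise ValueError("n_chromosomes must be in 1..19")

    @property
    def chromosome_names(self) -> list[str]:
        """Half A, half C chromosomes (A gets the extra one when odd)."""
        n_a = (self.n_chromosomes + 1) // 2
        n_c = self.n_chromosomes - n_a
        return [f"A{i + 1:02d}" for i in range(n_a)] + [
            f"C{i + 1:02d}" for i in range(n_c)
        ]

    @property
    def morgans_per_chromosome(self) -> float:
        return self.cm_per_mb * (self.chromosome_length_bp / 1e6) / 100.0

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_chromosomes": self.n_chromosomes,
            "markers_per_chromosome": self.markers_per_chromosome,
            "chromosome_length_bp": self.chromosome_length_bp,
            "cm_per_mb": self.cm_per_mb,
            "maf_distribution": list(self.maf_distribution),
            "genotyping_error_rate": self.genotyping_error_rate,
            "missing_rate": self.missing_rate,
            "selection_targets": [list(t) for t in self.selection_targets],
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["maf_distribution"] = tuple(data.get("maf_distribution", ("uniform", 0.2, 0.8)))
        data["selection_targets"] = [tuple(t) for t in data.get("selection_targets", [])]
        return cls(**data)


@dataclass
class AncestryTrack:
    """Exact per-marker ancestry of one line.

    ``founder_origin[m]`` is the index (into the founder list) of the
    founder whose allele the line carries at marker m; ``parent_origin[m]``
    is the index (into the line list) of the parent that transmitted it,
    or -1 for founders.
    """

    founder_origin: np.ndarray
    parent_origin: np.ndarray


@dataclass
class SimResult:
    """Everything a downstream stage or a truth-based test needs."""

    config: SimConfig
    marker_map: MarkerMap
    genotypes: GenotypeMatrix          # observed calls (error + missingness)
    true_calls: np.ndarray             # error-free calls, lines x markers
    tracks: dict[str, AncestryTrack]
    founders: list[str]
    line_order: list[str]
    pedigree: PedigreeGraph

    def line_index(self, name: str) -> int:
        return self.line_order.index(name)


def build_marker_map(config: SimConfig) -> MarkerMap:
    """Evenly spaced markers on each simulated chromosome."""
    rows = []
    m = config.markers_per_chromosome
    for chrom in config.chromosome_names:
        spacing = config.chromosome_length_bp / (m + 1)
        for i in range(m):
            rows.append((f"{chrom}_m{i:05d}", chrom, int(round((i + 1) * spacing))))
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"]))


def simulate_founders(
    founder_names: list[str], config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, MarkerMap]:
    """Mutually independent homozygous founder haplotypes.

    Per-marker alternate-allele frequencies are drawn from the configured
    distribution; each founder's allele is then Bernoulli(q).
    """
    marker_map = build_marker_map(config)
    n_markers = len(marker_map)
    kind = config.maf_distribution[0]
    if kind == "uniform":
        _, low, high = config.maf_distribution
        q = rng.uniform(low, high, size=n_markers)
    elif kind == "fixed":
        q = np.full(n_markers, float(config.maf_distribution[1]))
    elif kind == "beta":
        _, a, b = config.maf_distribution
        q = rng.beta(a, b, size=n_markers)
    else:
        raise ValueError(f"unknown maf distribution {kind!r}")
    calls = (rng.random((len(founder_names), n_markers)) < q).astype(np.int8)
    return calls, marker_map


def _recombinant_gamete(
    chrom_slices: list[np.ndarray],
    positions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-marker parent choice (0 = mother, 1 = father) for one gamete."""
    choice = np.empty(positions.shape[0], dtype=np.int8)
    morgans = config.morgans_per_chromosome
    for idx in chrom_slices:
        n_xo = rng.poisson(morgans)
        start = rng.integers(0, 2)
        if n_xo == 0:
            choice[idx] = start
            continue
        breaks = np.sort(rng.uniform(0, config.chromosome_length_bp, size=n_xo))
        # phase at marker = start XOR (number of breakpoints to its left, mod 2)
        n_left = np.searchsorted(breaks, positions[idx])
        choice[idx] = (start + n_left) % 2
    return choice


def simulate_cross(
    mother: str,
    father: str,
    lines: dict[str, np.ndarray],
    tracks: dict[str, AncestryTrack],
    line_order: list[str],
    marker_map: MarkerMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, AncestryTrack]:
    """One doubled-haploid offspring of mother x father with its ancestry."""
    chrom_slices = [marker_map.chrom_indices(c) for c in marker_map.chromosomes]
    positions = marker_map.positions()
    choice = _recombinant_gamete(chrom_slices, positions, config, rng)
    calls = np.where(choice == 0, lines[mother], lines[father]).astype(np.int8)
    founder_origin = np.where(
        choice == 0, tracks[mother].founder_origin, tracks[father].founder_origin
    ).astype(np.int16)
    parent_origin = np.where(
        choice == 0, line_order.index(mother), line_order.index(father)
    ).astype(np.int16)
    return calls, AncestryTrack(founder_origin, parent_origin)


def _nearest_marker(marker_map: MarkerMap, chrom: str, pos_bp: int) -> int:
    idx = marker_map.chrom_indices(chrom)
    if idx.size == 0:
        raise ValueError(f"selection target on unmapped chromosome {chrom}")
    positions = marker_map.positions(chrom)
    if pos_bp < 1 or pos_bp > positions[-1] + (positions[-1] - positions[-2] if len(positions) > 1 else 0):
        raise ValueError(f"selection target {chrom}:{pos_bp} outside the map")
    return int(idx[np.argmin(np.abs(positions - pos_bp))])


def simulate_pedigree(ped: PedigreeGraph, config: SimConfig) -> SimResult:
    """Simulate every line of the pedigree with exact ancestry tracking.

    Selection targets are enforced by gamete rejection: if either parent
    carries the favored founder's allele at the target marker, offspring
    gametes are redrawn until the offspring carries it.
    """
    rng = np.random.default_rng(config.rng_seed)
    founders = ped.founders
    line_order = ped.topological_order()
    founder_calls, marker_map = simulate_founders(founders, config, rng)
    n_markers = len(marker_map)

    target_markers = [
        (_nearest_marker(marker_map, chrom, pos), founder)
        for chrom, pos, founder in config.selection_targets
    ]
    for _, founder in target_markers:
        if founder not in founders:
            raise ValueError(f"favored founder {founder!r} is not a pedigree founder")

    lines: dict[str, np.ndarray] = {}
    tracks: dict[str, AncestryTrack] = {}
    for i, name in enumerate(founders):
        lines[name] = founder_calls[i]
        tracks[name] = AncestryTrack(
            founder_origin=np.full(n_markers, i, dtype=np.int16),
            parent_origin=np.full(n_markers, -1, dtype=np.int16),
        )

    founder_index = {name: i for i, name in enumerate(founders)}
    for name in line_order:
        if name in lines:
            continue
        parents = ped.parents(name)
        if len(parents) == 1:  # partially documented cross: clone the parent
            lines[name] = lines[parents[0]].copy()
            tracks[name] = AncestryTrack(
                tracks[parents[0]].founder_origin.copy(),
                np.full(n_markers, line_order.index(parents[0]), dtype=np.int16),
            )
            continue
        mother, father = parents
        constraints = [
            (m, founder_index[f])
            for m, f in target_markers
            if tracks[mother].founder_origin[m] == founder_index[f]
            or tracks[father].founder_origin[m] == founder_index[f]
        ]
        for attempt in range(10_000):
            calls, track = simulate_cross(
                mother, father, lines, tracks, line_order, marker_map, config, rng
            )
            if all(track.founder_origin[m] == f for m, f in constraints):
                break
        else:  # pragma: no cover - astronomically unlikely under valid configs
            raise RuntimeError(f"selection constraint unsatisfiable for {name}")
        lines[name] = calls
        tracks[name] = track

    true_calls = np.stack([lines[name] for name in line_order]).astype(np.int8)
    observed = true_calls.copy()
    if config.genotyping_error_rate > 0:
        flips = rng.random(observed.shape) < config.genotyping_error_rate
        observed[flips] = 1 - observed[flips]
    if config.missing_rate > 0:
        observed[rng.random(observed.shape) < config.missing_rate] = MISSING
    # diploid-A lines (B. rapa) have no C subgenome: mask, don't exclude
    c_cols = np.array([subgenome(c) == "C" for c in marker_map.df["chromosome"]])
    for i, name in enumerate(line_order):
        if ped.species(name) == "A":
            observed[i, c_cols] = MISSING

    genotypes = GenotypeMatrix(line_order, marker_map, observed)
    return SimResult(
        config=config,
        marker_map=marker_map,
        genotypes=genotypes,
        true_calls=true_calls,
        tracks=tracks,
        founders=founders,
        line_order=line_order,
        pedigree=ped,
    )


# ---------------------------------------------------------------------------
# Ground truth extraction
# ---------------------------------------------------------------------------


def _passes_through(result: SimResult, ancestor: str, descendant: str) -> np.ndarray:
    """Boolean per-marker array: does the descendant's allele lineage pass
    through ``ancestor``?  Computed by walking the transmission chain."""
    n_markers = len(result.marker_map)
    if ancestor == descendant:
        return np.ones(n_markers, dtype=bool)
    cache: dict[str, np.ndarray] = {ancestor: np.ones(n_markers, dtype=bool)}

    def through(line: str) -> np.ndarray:
        if line in cache:
            return cache[line]
        track = result.tracks[line]
        if track.parent_origin[0] == -1 and np.all(track.parent_origin == -1):
            out = np.zeros(n_markers, dtype=bool)
        else:
            out = np.zeros(n_markers, dtype=bool)
            for pidx in np.unique(track.parent_origin):
                pname = result.line_order[pidx]
                mask = track.parent_origin == pidx
                out[mask] = through(pname)[mask]
        cache[line] = out
        return out

    return through(descendant)


def _runs_to_segments(
    mask: np.ndarray, result: SimResult, a: str, b: str
) -> list[IBDSegment]:
    segments = []
    mm = result.marker_map
    positions = mm.positions()
    for chrom in mm.chromosomes:
        idx = mm.chrom_indices(chrom)
        sub = mask[idx]
        if not sub.any():
            continue
        padded = np.concatenate([[False], sub, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
        for s, e in zip(starts, ends):
            segments.append(
                IBDSegment(
                    sample_a=a,
                    sample_b=b,
                    chromosome=chrom,
                    start_bp=int(positions[idx[s]]),
                    end_bp=int(positions[idx[e]]),
                    n_markers=int(e - s + 1),
                    n_mismatch=0,
                )
            )
    return segments


def true_ibd_segments(result: SimResult, ancestor: str, descendant: str) -> list[IBDSegment]:
    """Maximal marker runs of the descendant whose lineage passes through
    ``ancestor`` — the ground-truth IBD blocks for that ordered pair."""
    mask = _passes_through(result, ancestor, descendant)
    return _runs_to_segments(mask, result, ancestor, descendant)


def true_pairwise_ibd(result: SimResult, a: str, b: str) -> list[IBDSegment]:
    """Maximal runs where two lines carry the same founder's allele copy."""
    mask = result.tracks[a].founder_origin == result.tracks[b].founder_origin
    return _runs_to_segments(mask, result, a, b)


def genome_fraction(result: SimResult, ancestor: str, descendant: str) -> float:
    """Realized fraction of the descendant genome inherited via ``ancestor``."""
    return float(_passes_through(result, ancestor, descendant).mean())


def synthetic_features(result: SimResult, qtl_halfwidth_bp: int = 500_000,
                       gene_halfwidth_bp: int = 20_000):
    """Synthetic QTL and gene intervals planted around each selection target.

    Gives the overlap stage something real to intersect in simulate mode;
    trait labels cycle through the study's trait set.
    """
    from .io import TRAITS, FeatureInterval

    qtls, genes = [], []
    for i, (chrom, pos, founder) in enumerate(result.config.selection_targets):
        trait = TRAITS[i % len(TRAITS)]
        length = result.config.chromosome_length_bp
        qtls.append(
            FeatureInterval(
                f"qtl_{i}", "QTL", trait, chrom,
                max(1, pos - qtl_halfwidth_bp), min(length, pos + qtl_halfwidth_bp),
            )
        )
        genes.append(
            FeatureInterval(
                f"gene_{i}", "gene", trait, chrom,
                max(1, pos - gene_halfwidth_bp), min(length, pos + gene_halfwidth_bp),
            )
        )
    return qtls, genes
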