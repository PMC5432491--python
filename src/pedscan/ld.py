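"""Linkage disequilibrium, decay-distance estimation and gene clusters.

Inbred homozygous lines expose their haplotypes directly, so r^2 between
two markers is computed from observed haplotype frequencies over the
lines non-missing at both markers:

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B))

The decay curve r^2(d) = 1 / (1 + beta d) is anchored at r^2(0) = 1 by
construction and has a single rate parameter; the distance at which the
fitted curve crosses r^2 = 0.2 is d = 4 / beta.  The Hill-Weir drift
expectation is available as an alternative functional form.

Trait genes falling within one LD-decay distance of each other tend to
be transferred as one intact haplotype block, so genes are grouped into
clusters by single linkage with an inter-gene gap no larger than the
decay distance (0.7 Mb in the motivating study).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .io import MISSING, FeatureInterval, GenotypeMatrix


def pairwise_r2(
    gm: GenotypeMatrix,
    panel: list[str],
    max_distance_bp: int = 10_000_000,
    window_markers: int | None = None,
    step_markers: int | None = None,
) -> pd.DataFrame:
    """r^2 for same-chromosome marker pairs within ``max_distance_bp``.

    When ``window_markers`` is given, pairs are restricted to those
    co-occurring in a sliding marker window (step defaults to half the
    window), which bounds the pair count on dense maps.  Pairs where
    either marker is non-segregating among the shared non-missing lines,
    or with fewer than two shared calls, are skipped.

    Returns a frame with marker_i, marker_j, chromosome, distance_bp, r2.
    """
    calls = np.stack([gm.row(s) for s in panel]).astype(float)
    calls[calls == MISSING] = np.nan
    mm = gm.markers
    rows = []
    for chrom in mm.chromosomes:
        idx = mm.chrom_indices(chrom)
        positions = mm.positions(chrom)
        ids = np.asarray(mm.marker_ids)[idx]
        m = idx.size
        if window_markers:
            step = step_markers or max(1, window_markers // 2)
            pair_set: set[tuple[int, int]] = set()
            for lo in range(0, m, step):
                win = range(lo, min(lo + window_markers, m))
                pair_set.update((i, j) for i in win for j in win if i < j)
            pairs_iter = sorted(pair_set)
        else:
            pairs_iter = [(i, j) for i in range(m) for j in range(i + 1, m)]
        for i, j in pairs_iter:
            d = int(positions[j] - positions[i])
            if d > max_distance_bp:
                continue
            x, y = calls[:, idx[i]], calls[:, idx[j]]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 2:
                continue
            xi, yj = x[ok], y[ok]
            pa, pb = xi.mean(), yj.mean()
            denom = pa * (1 - pa) * pb * (1 - pb)
            if denom <= 0:
                continue
            pab = (xi * yj).mean()
            r2 = (pab - pa * pb) ** 2 / denom
            rows.append((ids[i], ids[j], chrom, d, float(r2)))
    return pd.DataFrame(
        rows, columns=["marker_i", "marker_j", "chromosome", "distance_bp", "r2"]
    )


@dataclass
class DecayFit:
    """Fitted LD decay: r^2(d) = 1/(1 + beta d) with beta in 1/bp."""

    beta: float
    decay_distance_mb: float  # distance where the fitted curve = 0.2; inf if never
    rss: float
    form: str = "rational"
    n_pairs: int = 0


def _hill_weir(d: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Hill-Weir drift expectation of r^2 at recombination-scaled distance."""
    C = rho * d
    term1 = (10 + C) / ((2 + C) * (11 + C))
    term2 = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    return term1 * term2


def fit_decay(
    pairs: pd.DataFrame,
    form: str = "rational",
    n: int | None = None,
    threshold: float = 0.2,
) -> DecayFit:
    """Least-squares fit of the decay curve to (distance, r^2) pairs.

    ``form='rational'`` fits r^2(d) = 1/(1 + beta d); ``'hill_weir'``
    fits the drift expectation (requires the panel size ``n``).  The
    decay distance is where the fitted curve crosses ``threshold``
    (infinite when it never does).
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs to fit a decay curve")
    d = pairs["distance_bp"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("all pair distances identical; decay not identifiable")

    if form == "rational":
        def resid(logb):
            return 1.0 / (1.0 + np.exp(logb[0]) * d) - r2

        # initialise from the distance scale of the data
        fit = least_squares(resid, x0=[np.log(1.0 / max(d.mean(), 1.0))])
        beta = float(np.exp(fit.x[0]))
        # LD that never decays (beta ~ 0): the threshold is never reached
        if beta < 1e-15 or (1.0 / threshold - 1.0) / beta > 1e12:
            decay_mb = float("inf")
        else:
            decay_mb = (1.0 / threshold - 1.0) / beta / 1e6  # 4/beta at 0.2
        return DecayFit(
            beta=beta,
            decay_distance_mb=decay_mb,
            rss=float((fit.fun**2).sum()),
            form=form,
            n_pairs=len(pairs),
        )
    if form == "hill_weir":
        if n is None:
            raise ValueError("hill_weir form needs the panel size n")

        def resid(logr):
            return _hill_weir(d, np.exp(logr[0]), n) - r2

        fit = least_squares(resid, x0=[np.log(1.0 / max(d.mean(), 1.0))])
        rho = float(np.exp(fit.x[0]))
        f0 = float(_hill_weir(np.array([0.0]), rho, n)[0])
        if f0 <= threshold:
            decay_mb = 0.0
        else:
            hi = 1.0
            while _hill_weir(np.array([hi]), rho, n)[0] > threshold and hi < 1e12:
                hi *= 10
            if hi >= 1e12:
                decay_mb = float("inf")
            else:
                decay_mb = brentq(
                    lambda x: _hill_weir(np.array([x]), rho, n)[0] - threshold, 0, hi
                ) / 1e6
        return DecayFit(
            beta=rho,
            decay_distance_mb=decay_mb,
            rss=float((fit.fun**2).sum()),
            form=form,
            n_pairs=len(pairs),
        )
    raise ValueError(f"unknown decay form {form!r}")


def mean_r2(pairs: pd.DataFrame) -> float:
    """Plain mean r^2 over all computed pairs."""
    if pairs.empty:
        raise ValueError("no pairs")
    return float(pairs["r2"].mean())


# ---------------------------------------------------------------------------
# Gene clusters
# ---------------------------------------------------------------------------


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[str]
    chromosome: str
    start_bp: int
    end_bp: int
    traits: tuple[str, ...]
    pedigrees: tuple[str, ...] = ()
    singleton: bool = False

    @property
    def multi_trait(self) -> bool:
        return len(self.traits) > 1


def call_clusters(
    genes: list[FeatureInterval],
    gap_mb: float,
    transfer_labels: dict[str, set] | None = None,
) -> list[GeneCluster]:
    """Single-linkage gene clusters within one LD-decay distance.

    Genes on the same chromosome join a cluster when the gap between
    consecutive intervals (next start minus previous end, floored at 0)
    is at most ``gap_mb``.  Clusters are annotated with the union of
    member traits and (optionally) the pedigrees through which members
    were transferred; single-gene groups are flagged ``singleton``.
    """
    if gap_mb <= 0:
        raise ValueError("gap_mb must be positive")
    gap_bp = gap_mb * 1e6
    transfer_labels = transfer_labels or {}
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[FeatureInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    counter = 0
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.feature_id))
        group: list[FeatureInterval] = []

        def flush():
            nonlocal counter
            if not group:
                return
            counter += 1
            traits = tuple(sorted({g.trait for g in group}))
            peds = set()
            for g in group:
                peds |= set(transfer_labels.get(g.feature_id, ()))
            clusters.append(
                GeneCluster(
                    cluster_id=f"cluster_{counter:03d}",
                    members=[g.feature_id for g in group],
                    chromosome=chrom,
                    start_bp=min(g.start for g in group),
                    end_bp=max(g.end for g in group),
                    traits=traits,
                    pedigrees=tuple(sorted(peds)),
                    singleton=len(group) == 1,
                )
            )

        prev_end = None
        for g in ordered:
            if prev_end is not None and max(0, g.start - prev_end) > gap_bp:
                flush()
                group = []
            group.append(g)
            prev_end = max(prev_end or g.end, g.end)
        flush()
    return clusters


def clusters_to_frame(clusters: list[GeneCluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "chromosome": c.chromosome,
            "start_bp": c.start_bp,
            "end_bp": c.end_bp,
            "n_genes": len(c.members),
            "members": ",".join(c.members),
            "traits": ",".join(c.traits),
            "pedigrees": ",".join(c.pedigrees),
            "multi_trait": c.multi_trait,
            "singleton": c.singleton,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "chromosome", "start_bp", "end_bp", "n_genes",
                 "members", "traits", "pedigrees", "multi_trait", "singleton"],
    )
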