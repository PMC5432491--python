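"""Sliding-window selection statistics for pedigree panels.

Each pedigree panel is a small set of inbred lines (five cultivars per
pedigree in the motivating study).  Homozygous lines contribute one
haplotype each, so the sample size n is the panel size.  Per window of
15 consecutive usable loci (advancing one locus per step, value assigned
to the midpoint, i.e. the 8th locus):

* S   — number of segregating sites,
* pi  — mean number of pairwise differences across all line pairs,
* D   — Tajima's D contrasting pi with S/a1,
* Hs  — Nei's gene diversity, mean over loci of 1 - q^2 - (1-q)^2,
* PIC — polymorphism information content (biallelic Botstein form),
        mean over loci of 1 - (p^2 + q^2) - 2 p^2 q^2.

A locus is *usable* when at least two panel lines have a call; loci are
not required to be segregating (the 15-locus unit is defined on array
loci, not on segregating sites).  D is undefined when S = 0, when the
variance term vanishes, or when n < 3.

Four-quadrant selection-timing classification (main-text convention,
default): negative D with low diversity (Hs < 0.3) points to selection
in earlier breeding cycles; negative D with high diversity to later
cycles; positive D with low diversity to selection predating the
documented pedigree; positive D with high diversity to no selection.
An alternative convention swapping the early/late assignment is kept
behind a switch because published descriptions of the scheme disagree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

QUADRANTS = ("early_breeding", "late_breeding", "pre_pedigree", "no_selection")
CONVENTIONS = ("main_text", "figure_legend")

#: Gene-diversity threshold separating the quadrants.
HS_THRESHOLD = 0.3


def tajima_constants(n: int) -> dict:
    """The usual normalising constants of Tajima's D for n sequences."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def site_stats(calls: np.ndarray) -> tuple[float, bool, bool]:
    """(alt-allele frequency, segregating?, usable?) for one panel column.

    Frequency is computed over non-missing calls; a site with fewer than
    two calls is flagged unusable (q = nan).
    """
    obs = calls[calls != MISSING]
    if obs.size < 2:
        return float("nan"), False, False
    q = float(obs.mean())
    return q, 0.0 < q < 1.0, True


def tajima_d(window_calls: np.ndarray) -> tuple[int, float, float]:
    """(S, pi, D) for one window of panel calls (lines x loci).

    pi is the mean over all line pairs of the number of sites at which
    the pair differs (sites missing in either member contribute
    nothing); S counts segregating sites.  D is nan when undefined.
    """
    n = window_calls.shape[0]
    if n < 3:
        raise ValueError("Tajima's D needs at least 3 lines")
    n_pairs = n * (n - 1) / 2.0
    S = 0
    diff_sum = 0.0
    for j in range(window_calls.shape[1]):
        q, seg, usable = site_stats(window_calls[:, j])
        if not usable:
            continue
        obs = window_calls[:, j][window_calls[:, j] != MISSING]
        n1 = int(obs.sum())
        n0 = obs.size - n1
        diff_sum += n0 * n1
        if seg:
            S += 1
    pi = diff_sum / n_pairs
    if S == 0:
        return 0, pi, float("nan")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return S, pi, float("nan")
    D = (pi - S / k["a1"]) / math.sqrt(var)
    return S, pi, D


def gene_diversity(q_values) -> tuple[float, np.ndarray]:
    """Nei's mean gene diversity: Hs = (1/k) sum(1 - q^2 - (1-q)^2).

    Returns the mean and the per-locus values.
    """
    q = np.asarray(q_values, dtype=float)
    if q.size == 0:
        raise ValueError("no loci supplied")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    per_locus = 1.0 - q**2 - (1.0 - q) ** 2
    return float(per_locus.mean()), per_locus


def pic(q_values) -> float:
    """Mean polymorphism information content of biallelic loci."""
    q = np.asarray(q_values, dtype=float)
    if q.size == 0:
        raise ValueError("no loci supplied")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    p = 1.0 - q
    per_locus = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(per_locus.mean())


def sliding_scan(
    gm: GenotypeMatrix,
    panel: list[str],
    window: int = 15,
    step: int = 1,
) -> pd.DataFrame:
    """Window statistics along every chromosome for one panel.

    Windows cover ``window`` consecutive usable loci and advance ``step``
    loci; chromosomes are scanned independently and those with fewer
    than ``window`` usable loci are skipped (logged).  One row per
    window: chromosome, window_index, midpoint marker/bp, n, S, pi, D,
    Hs, PIC.
    """
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    calls = np.stack([gm.row(s) for s in panel])
    mm = gm.markers
    rows = []
    mid_off = (window - 1) // 2  # 8th locus of a 15-locus window
    for chrom in mm.chromosomes:
        idx = mm.chrom_indices(chrom)
        usable = np.array([site_stats(calls[:, j])[2] for j in idx])
        use_idx = idx[usable]
        if use_idx.size < window:
            logger.info("chromosome %s: %d usable loci < window %d, skipped",
                        chrom, use_idx.size, window)
            continue
        positions = mm.positions()
        marker_ids = np.asarray(mm.marker_ids)
        q_all = np.array([site_stats(calls[:, j])[0] for j in use_idx])
        for w, lo in enumerate(range(0, use_idx.size - window + 1, step)):
            sel = use_idx[lo : lo + window]
            S, pi_val, D = tajima_d(calls[:, sel])
            qs = q_all[lo : lo + window]
            hs, _ = gene_diversity(qs)
            mid = sel[mid_off]
            rows.append(
                {
                    "chromosome": chrom,
                    "window_index": w,
                    "midpoint_marker": marker_ids[mid],
                    "midpoint_bp": int(positions[mid]),
                    "n": len(panel),
                    "S": S,
                    "pi": pi_val,
                    "D": D,
                    "Hs": hs,
                    "PIC": pic(qs),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "window_index", "midpoint_marker", "midpoint_bp",
                 "n", "S", "pi", "D", "Hs", "PIC"],
    )


def classify_selection(
    D: float, Hs: float, convention: str = "main_text"
) -> tuple[str, bool]:
    """Four-quadrant selection-timing call from (D, Hs).

    Returns (quadrant, boundary_flag); boundary values (D = 0 or
    Hs = 0.3 exactly) are called no_selection with the flag set.
    Undefined D raises.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    if D is None or (isinstance(D, float) and math.isnan(D)):
        raise ValueError("D is undefined; call suppressed")
    if not 0.0 <= Hs <= 1.0:
        raise ValueError("Hs must lie in [0, 1]")
    if D == 0.0 or Hs == HS_THRESHOLD:
        return "no_selection", True
    low_hs = Hs < HS_THRESHOLD
    if D < 0:
        quadrant = "early_breeding" if low_hs else "late_breeding"
        if convention == "figure_legend":
            quadrant = "late_breeding" if low_hs else "early_breeding"
    else:
        quadrant = "pre_pedigree" if low_hs else "no_selection"
    return quadrant, False


D_BINS = ((-2.0, -1.0), (-1.0, 0.0), (0.0, 1.0), (1.0, 2.0))


def d_histogram(d_values) -> dict:
    """Fractions of defined D values in the four unit-wide classes
    [-2,-1), [-1,0), [0,1), [1,2]; out-of-range values are excluded from
    the bins and reported under 'out_of_range'."""
    d = np.asarray([v for v in d_values if not (v is None or math.isnan(v))], dtype=float)
    if d.size == 0:
        raise ValueError("no defined D values")
    out = {}
    in_range = 0
    for lo, hi in D_BINS:
        if hi == 2.0:
            count = int(((d >= lo) & (d <= hi)).sum())
        else:
            count = int(((d >= lo) & (d < hi)).sum())
        out[f"[{lo:g},{hi:g})" if hi != 2.0 else f"[{lo:g},{hi:g}]"] = count / d.size
        in_range += count
    out["out_of_range"] = (d.size - in_range) / d.size
    return out


def genome_mean_d(scan: pd.DataFrame) -> float:
    """Genome-wide D: the mean over defined window values."""
    d = scan["D"].dropna()
    if d.empty:
        raise ValueError("no defined windows")
    return float(d.mean())
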