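"""Detection of IBD blocks between pairs of homozygous inbred lines.

Because every line is fully homozygous, its genotype vector *is* its
haplotype, and shared haplotype blocks are simply maximal runs of
concordant calls.  The detector scans each chromosome left to right and
grows a run greedily:

* a concordant marker extends the run;
* a missing call (in either line) neither extends nor breaks it, unless
  ``max_missing_gap_markers`` consecutive comparisons are missing;
* a discordant marker is absorbed only while the running mismatch
  fraction stays at or below ``max_mismatch_fraction`` (tie-break: the
  left run is extended greedily; an unabsorbable mismatch closes it);
* a run is reported only if it covers at least ``min_markers`` compared
  markers and spans at least ``min_length_mb``.

Segments are trimmed to their first and last concordant marker, so a
reported block always starts and ends on direct evidence of sharing.
Segment length in Mb is end_bp - start_bp (not +1), the convention under
which Mb totals are usually reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MarkerMap, subgenome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IBDSegment:
    """A maximal shared haplotype run between two lines.

    Coordinates are the 1-based bp positions of the first and last
    supporting (concordant, non-missing) marker.
    """

    sample_a: str
    sample_b: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int
    n_mismatch: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


@dataclass
class DetectorParams:
    min_markers: int = 20
    min_length_mb: float = 1.0
    max_mismatch_fraction: float = 0.02
    max_missing_gap_markers: int = 50

    def __post_init__(self) -> None:
        if min(self.min_markers, self.max_missing_gap_markers) < 0:
            raise ValueError("marker counts must be nonnegative")
        if self.min_length_mb < 0:
            raise ValueError("min_length_mb must be nonnegative")
        if not 0 <= self.max_mismatch_fraction < 0.5:
            raise ValueError("max_mismatch_fraction must lie in [0, 0.5)")


def _chromosome_runs(
    status: np.ndarray, params: DetectorParams
) -> list[tuple[int, int, int, int]]:
    """Greedy maximal concordance runs on one chromosome.

    ``status``: per-marker code 0 = concordant, 1 = discordant,
    -1 = missing in either line.  Returns (start_idx, end_idx,
    n_compared, n_mismatch) tuples with both endpoints concordant.
    """
    # prefix sums for exact recounts over the trimmed [start, end] range
    compared = np.cumsum(np.concatenate([[0], (status >= 0).astype(np.int64)]))
    mismatched = np.cumsum(np.concatenate([[0], (status == 1).astype(np.int64)]))

    runs: list[tuple[int, int, int, int]] = []

    def close(start: int, last_conc: int) -> None:
        if start is None or last_conc is None:
            return
        n_cmp = int(compared[last_conc + 1] - compared[start])
        n_mis = int(mismatched[last_conc + 1] - mismatched[start])
        runs.append((start, last_conc, n_cmp, n_mis))

    start = None  # first concordant marker of the open run
    last_conc = None
    n_cmp = 0  # compared markers since start (incl. absorbed mismatches)
    n_mis = 0
    gap = 0  # consecutive missing comparisons

    for i, code in enumerate(status):
        if code == -1:
            if start is not None:
                gap += 1
                if gap > params.max_missing_gap_markers:
                    close(start, last_conc)
                    start = last_conc = None
                    n_cmp = n_mis = 0
                    gap = 0
            continue
        if code == 0:
            if start is None:
                start, last_conc, n_cmp, n_mis = i, i, 1, 0
            else:
                n_cmp += 1
                last_conc = i
            gap = 0
            continue
        # discordant marker
        if start is None:
            continue
        if (n_mis + 1) <= params.max_mismatch_fraction * (n_cmp + 1):
            n_mis += 1
            n_cmp += 1
            gap = 0
        else:
            close(start, last_conc)
            start = last_conc = None
            n_cmp = n_mis = 0
            gap = 0
    close(start, last_conc)
    return runs


def pairwise_ibd(
    gm: GenotypeMatrix,
    a: str,
    b: str,
    params: DetectorParams | None = None,
) -> list[IBDSegment]:
    """All IBD segments between lines ``a`` and ``b``, sorted by
    (chromosome, start_bp).  Chromosomes with no usable comparison (e.g.
    the C subgenome of a diploid-A line) yield no segments."""
    params = params or DetectorParams()
    calls_a, calls_b = gm.row(a), gm.row(b)
    usable = (calls_a != MISSING) & (calls_b != MISSING)
    status_all = np.where(usable, (calls_a != calls_b).astype(np.int8), np.int8(-1))

    mm = gm.markers
    segments: list[IBDSegment] = []
    for chrom in mm.chromosomes:
        idx = mm.chrom_indices(chrom)
        status = status_all[idx]
        if not (status >= 0).any():
            logger.info("pair (%s, %s): chromosome %s all-missing, skipped", a, b, chrom)
            continue
        positions = mm.positions(chrom)
        for s, e, n_cmp, n_mis in _chromosome_runs(status, params):
            seg = IBDSegment(
                sample_a=a,
                sample_b=b,
                chromosome=chrom,
                start_bp=int(positions[s]),
                end_bp=int(positions[e]),
                n_markers=n_cmp,
                n_mismatch=n_mis,
            )
            if seg.n_markers >= params.min_markers and seg.length_mb >= params.min_length_mb:
                segments.append(seg)
    segments.sort(key=lambda s: (s.chromosome, s.start_bp))
    return segments


def all_pairs_ibd(
    gm: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
    params: DetectorParams | None = None,
) -> list[IBDSegment]:
    """Concatenated, pair-labelled segments for a list of line pairs,
    in deterministic (pair order, chromosome, start) order."""
    segments: list[IBDSegment] = []
    for a, b in pairs:
        segments.extend(pairwise_ibd(gm, a, b, params))
    return segments


def segments_to_frame(segments: Iterable[IBDSegment]) -> pd.DataFrame:
    rows = [
        {
            "sample_a": s.sample_a,
            "sample_b": s.sample_b,
            "chromosome": s.chromosome,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "n_markers": s.n_markers,
            "n_mismatch": s.n_mismatch,
            "length_mb": s.length_mb,
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_a", "sample_b", "chromosome", "start_bp", "end_bp",
            "n_markers", "n_mismatch", "length_mb",
        ],
    )


def ibd_summary(segments: Iterable[IBDSegment]) -> pd.DataFrame:
    """Per-pair counts and total Mb, split by subgenome, plus a pooled
    over-all-pairs row labelled ('(all)', '(all)')."""
    df = segments_to_frame(segments)
    cols = [
        "count_A", "length_A_mb", "count_C", "length_C_mb",
        "count_total", "length_total_mb",
    ]
    if df.empty:
        return pd.DataFrame(columns=["sample_a", "sample_b"] + cols)
    df["subgenome"] = [subgenome(c) for c in df["chromosome"]]

    def summarize(grp: pd.DataFrame) -> pd.Series:
        out = {}
        for sg in ("A", "C"):
            sub = grp[grp["subgenome"] == sg]
            out[f"count_{sg}"] = len(sub)
            out[f"length_{sg}_mb"] = float(sub["length_mb"].sum())
        out["count_total"] = len(grp)
        out["length_total_mb"] = float(grp["length_mb"].sum())
        return pd.Series(out)

    per_pair = (
        df.groupby(["sample_a", "sample_b"], sort=True)
        .apply(summarize, include_groups=False)
        .reset_index()
    )
    pooled = summarize(df).to_frame().T
    pooled.insert(0, "sample_a", "(all)")
    pooled.insert(1, "sample_b", "(all)")
    out = pd.concat([per_pair, pooled], ignore_index=True)
    for c in ("count_A", "count_C", "count_total"):
        out[c] = out[c].astype(int)
    return out


# ---------------------------------------------------------------------------
# Truth-based scoring
# ---------------------------------------------------------------------------


def _marker_mask(segments: Iterable[IBDSegment], mm: MarkerMap) -> np.ndarray:
    """Boolean mask over map markers covered by the segments."""
    mask = np.zeros(len(mm), dtype=bool)
    positions = mm.positions()
    chroms = mm.df["chromosome"].to_numpy()
    for s in segments:
        mask |= (chroms == s.chromosome) & (positions >= s.start_bp) & (positions <= s.end_bp)
    return mask


def detection_scores(
    detected: Sequence[IBDSegment],
    truth: Sequence[IBDSegment],
    mm: MarkerMap,
    params: DetectorParams | None = None,
) -> dict:
    """Markerwise precision/recall of detected segments against truth,
    plus the mean boundary error in inter-marker intervals.

    Truth segments failing the detector's own reporting thresholds are
    excluded from the recall denominator (the detector is not asked to
    find blocks it is configured to suppress).
    """
    params = params or DetectorParams()
    truth_kept = [
        t for t in truth
        if t.n_markers >= params.min_markers and t.length_mb >= params.min_length_mb
    ]
    det_mask = _marker_mask(detected, mm)
    tru_mask = _marker_mask(truth_kept, mm)
    tp = int((det_mask & tru_mask).sum())
    precision = tp / det_mask.sum() if det_mask.any() else float("nan")
    recall = tp / tru_mask.sum() if tru_mask.any() else float("nan")

    # boundary error: match each kept truth segment to the detected segment
    # with the largest overlap on its chromosome
    errors = []
    pos_index = {
        chrom: {int(p): i for i, p in enumerate(mm.positions(chrom))}
        for chrom in mm.chromosomes
    }
    for t in truth_kept:
        best, best_ov = None, 0
        for d in detected:
            if d.chromosome != t.chromosome:
                continue
            ov = min(d.end_bp, t.end_bp) - max(d.start_bp, t.start_bp)
            if ov > best_ov:
                best, best_ov = d, ov
        if best is None:
            continue
        idx = pos_index[t.chromosome]
        errors.append(abs(idx[best.start_bp] - idx[t.start_bp]))
        errors.append(abs(idx[best.end_bp] - idx[t.end_bp]))
    mean_boundary = float(np.mean(errors)) if errors else float("nan")
    median_boundary = float(np.median(errors)) if errors else float("nan")
    return {
        "precision": float(precision),
        "recall": float(recall),
        "mean_boundary_error_intervals": mean_boundary,
        "median_boundary_error_intervals": median_boundary,
        "n_truth_segments": len(truth_kept),
        "n_detected_segments": len(detected),
    }
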