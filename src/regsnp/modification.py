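"""Copy-number and methylation status calling, plus simplified segmentation.

Per-gene, per-patient calls are trichotomous at inclusive thresholds:
amplified when CN_dif >= 0.3, deleted when CN_dif <= -0.3, else neutral;
hypermethylated when the beta difference >= 0.25, hypomethylated when
<= -0.25, else unchanged.

Marker-level copy-number differences can first be reduced to segments by
recursive binary splitting: a candidate breakpoint is accepted only when both
flanks hold at least ``min_markers`` markers, the Welch two-sample t-test has
p <= ``break_p``, and the signal-to-noise ratio |mean difference| / pooled SD
is at least ``min_snr``. This is a deliberately simple stand-in for the
proprietary segmentation of commercial array suites; it honors the same
acceptance criteria (marker count, p-value, SNR) without reproducing their
exact boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegmentCriteria",
    "Segment",
    "segment_cn",
    "gene_cn_difference",
    "call_cnv_status",
    "call_methylation_status",
    "call_matrix",
]

AMPLIFIED, DELETED, NEUTRAL = "amplified", "deleted", "neutral"
HYPER, HYPO, UNCHANGED = "hyper", "hypo", "unchanged"


@dataclass(frozen=True)
class SegmentCriteria:
    """Acceptance rules for a copy-number segment boundary."""

    min_markers: int = 100
    break_p: float = 0.001
    min_snr: float = 0.3
    min_abs_cn_change: float = 0.3

    def __post_init__(self) -> None:
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")
        if self.break_p <= 0 or self.min_snr <= 0 or self.min_abs_cn_change <= 0:
            raise ValueError("break_p, min_snr and min_abs_cn_change must be positive")


@dataclass(frozen=True)
class Segment:
    """Half-open marker-index interval [start, end) with its mean value."""

    start: int
    end: int
    mean: float

    @property
    def n_markers(self) -> int:
        return self.end - self.start


def _welch(left: np.ndarray, right: np.ndarray) -> tuple[float, float]:
    """(p, snr) for a candidate split; degenerate variances handled."""
    n1, n2 = left.size, right.size
    m1, m2 = left.mean(), right.mean()
    v1 = left.var(ddof=1)
    v2 = right.var(ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled_var == 0:
        # flat flanks: any nonzero mean gap is infinitely sharp
        if m1 == m2:
            return 1.0, 0.0
        return 0.0, np.inf
    snr = abs(m1 - m2) / np.sqrt(pooled_var)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return (1.0, snr) if m1 == m2 else (0.0, snr)
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(p), float(snr)


def _best_split(values: np.ndarray, min_markers: int) -> tuple[int, float, float] | None:
    """Most significant admissible breakpoint, or None if no position allows one."""
    n = values.size
    if n < 2 * min_markers:
        return None
    csum = np.concatenate([[0.0], np.cumsum(values)])
    total = csum[-1]
    best = None
    for k in range(min_markers, n - min_markers + 1):
        m1 = csum[k] / k
        m2 = (total - csum[k]) / (n - k)
        gap = abs(m1 - m2)
        if best is None or gap > best[1]:
            best = (k, gap)
    # rank candidates by mean gap (cheap), confirm the winner with Welch
    k = best[0]
    p, snr = _welch(values[:k], values[k:])
    return k, p, snr


def segment_cn(marker_values, criteria: SegmentCriteria = SegmentCriteria()) -> list[Segment]:
    """Segment one chromosome's ordered marker-level CN differences.

    Recursive binary splitting: the largest-gap admissible breakpoint is
    accepted if it meets the p-value and SNR criteria, then both flanks are
    segmented recursively; otherwise the region stays one segment.
    """
    values = np.asarray(marker_values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("marker_values must be a non-empty 1-D array")
    if values.size < criteria.min_markers:
        warnings.warn(
            f"only {values.size} markers (< min_markers={criteria.min_markers}); "
            "returning a single segment",
            stacklevel=2,
        )
        return [Segment(0, values.size, float(values.mean()))]

    segments: list[Segment] = []

    def recurse(start: int, end: int) -> None:
        region = values[start:end]
        found = _best_split(region, criteria.min_markers)
        if found is not None:
            k, p, snr = found
            if p <= criteria.break_p and snr >= criteria.min_snr:
                recurse(start, start + k)
                recurse(start + k, end)
                return
        segments.append(Segment(start, end, float(region.mean())))

    recurse(0, values.size)
    return segments


def gene_cn_difference(
    segments_or_markers,
    gene_intervals: pd.DataFrame,
    marker_positions=None,
) -> pd.Series:
    """Per-gene CN difference for one patient.

    ``gene_intervals`` needs columns (gene_id, start, end) with 0-based
    half-open coordinates. Two input modes:

    * a list of :class:`Segment` plus ``marker_positions`` mapping marker
      index to genomic position — each gene gets the length-weighted mean of
      overlapping segment means (segment span = [pos[start], pos[end-1] + 1));
    * a pair ``(positions, values)`` of marker-level arrays — each gene gets
      the direct mean of markers inside its interval.

    Genes overlapping no segment/marker get NaN.
    """
    out = {}
    if segments_or_markers and isinstance(segments_or_markers[0], Segment):
        if marker_positions is None:
            raise ValueError("marker_positions required with segment input")
        pos = np.asarray(marker_positions)
        spans = [
            (int(pos[seg.start]), int(pos[seg.end - 1]) + 1, seg.mean)
            for seg in segments_or_markers
        ]
        for row in gene_intervals.itertuples(index=False):
            weight = value = 0.0
            for s, e, mean in spans:
                ov = min(e, row.end) - max(s, row.start)
                if ov > 0:
                    weight += ov
                    value += ov * mean
            out[row.gene_id] = value / weight if weight > 0 else np.nan
    else:
        positions, values = segments_or_markers
        positions = np.asarray(positions)
        values = np.asarray(values, dtype=float)
        for row in gene_intervals.itertuples(index=False):
            inside = (positions >= row.start) & (positions < row.end)
            out[row.gene_id] = float(values[inside].mean()) if inside.any() else np.nan
    return pd.Series(out, name="cn_dif")


def call_cnv_status(cn_dif: float, threshold: float = 0.3) -> str | float:
    """Trichotomous CNV status at an inclusive threshold; missing stays missing."""
    if cn_dif is None or (isinstance(cn_dif, float) and np.isnan(cn_dif)):
        return np.nan
    if cn_dif >= threshold:
        return AMPLIFIED
    if cn_dif <= -threshold:
        return DELETED
    return NEUTRAL


def call_methylation_status(beta_dif: float, threshold: float = 0.25) -> str | float:
    """Trichotomous methylation status; beta differences live in [-1, 1]."""
    if beta_dif is None or (isinstance(beta_dif, float) and np.isnan(beta_dif)):
        return np.nan
    if abs(beta_dif) > 1:
        raise ValueError(f"beta difference outside [-1, 1]: {beta_dif}")
    if beta_dif >= threshold:
        return HYPER
    if beta_dif <= -threshold:
        return HYPO
    return UNCHANGED


def call_matrix(values: pd.DataFrame, layer: str, threshold: float | None = None) -> pd.DataFrame:
    """Vectorized status calls for a gene x patient matrix.

    ``layer`` is 'cnv' (threshold 0.3, amplified/deleted/neutral) or
    'methylation' (threshold 0.25, hyper/hypo/unchanged).
    """
    arr = values.to_numpy(float)
    if layer == "cnv":
        thr = 0.3 if threshold is None else threshold
        labels = (AMPLIFIED, DELETED, NEUTRAL)
    elif layer == "methylation":
        thr = 0.25 if threshold is None else threshold
        labels = (HYPER, HYPO, UNCHANGED)
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(arr)) > 1:
                raise ValueError("beta differences outside [-1, 1]")
    else:
        raise ValueError(f"unknown layer: {layer!r}")
    out = np.where(arr >= thr, labels[0], np.where(arr <= -thr, labels[1], labels[2]))
    out = out.astype(object)
    out[np.isnan(arr)] = np.nan
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def read_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (chrom, start, end, gene_id); 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"BED file {path} has intervals with end <= start")
    return df
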