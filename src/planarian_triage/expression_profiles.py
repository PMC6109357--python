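"""RPKM with a restricted library-size denominator, summaries and percentile bins.

RPKM here follows the convention

    RPKM = reads / (length/1000 * total/1e6)

where ``total`` for a sample counts reads only over transcripts with >= 10
reads mapped in that sample.  A transcript is "expressed" in a sample iff it
has >= 10 reads there; per-transcript summary statistics are computed over
expressed samples only, and transcripts are binned by mean RPKM into
HIGH (top 20%), MEDIUM, and LOW (bottom 50%) under a descending-rank reading
of the percentile thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import CountTable

EXPRESSED_MIN_READS = 10


@dataclass
class RpkmMatrix:
    row_ids: list[str]
    col_ids: list[str]
    rpkm: np.ndarray
    expressed: np.ndarray
    lengths: dict[str, int]


@dataclass(frozen=True)
class ExpressionSummary:
    transcript_id: str
    n_expressed_samples: int
    mean: float
    sd: float
    median: float
    bin: str  # LOW | MEDIUM | HIGH | UNEXPRESSED


def rpkm(
    counts: CountTable,
    lengths: Mapping[str, int],
    min_reads: int = EXPRESSED_MIN_READS,
) -> RpkmMatrix:
    missing = [r for r in counts.row_ids if r not in lengths]
    if missing:
        raise ValueError(f"missing lengths for rows: {missing[:5]}")
    lens = np.array([lengths[r] for r in counts.row_ids], dtype=float)
    if np.any(lens <= 0):
        raise ValueError("non-positive transcript length")
    c = counts.counts.astype(float)
    expressed = counts.counts >= min_reads
    totals = np.where(expressed, c, 0.0).sum(axis=0)
    zero = [counts.col_ids[j] for j in np.flatnonzero(totals == 0)]
    if zero:
        raise ValueError(
            f"samples with no transcript reaching {min_reads} reads: {zero}"
        )
    # denominator applies to every row, including sub-threshold ones
    mat = c / (lens[:, None] / 1000.0 * totals[None, :] / 1e6)
    return RpkmMatrix(
        row_ids=list(counts.row_ids),
        col_ids=list(counts.col_ids),
        rpkm=mat,
        expressed=expressed,
        lengths={r: int(lengths[r]) for r in counts.row_ids},
    )


def summarize(m: RpkmMatrix) -> list[ExpressionSummary]:
    """Per-transcript mean/sd/median over expressed samples (population sd)."""
    out: list[ExpressionSummary] = []
    for i, tid in enumerate(m.row_ids):
        mask = m.expressed[i]
        n = int(mask.sum())
        if n == 0:
            out.append(ExpressionSummary(tid, 0, float("nan"), float("nan"),
                                         float("nan"), "UNEXPRESSED"))
            continue
        vals = m.rpkm[i, mask]
        out.append(
            ExpressionSummary(
                tid,
                n,
                float(vals.mean()),
                float(vals.std(ddof=0)),
                float(np.median(vals)),
                "MEDIUM",  # placeholder until percentile_bins assigns
            )
        )
    return out


def percentile_bins(
    summaries: Sequence[ExpressionSummary], convention: str = "descending"
) -> list[ExpressionSummary]:
    """Assign LOW/MEDIUM/HIGH by mean RPKM.

    ``descending`` (default): HIGH = top 20% (mean >= 80th value-percentile),
    LOW = bottom 50% (mean < 50th percentile), MEDIUM the remainder.
    ``literal``: the thresholds applied exactly as printed in the source
    convention (low < 50th percentile, high > 20th percentile), with LOW
    taking precedence; kept only for comparison.
    """
    expressed = [s for s in summaries if s.bin != "UNEXPRESSED"]
    if not expressed:
        raise ValueError("no expressed transcripts to bin")
    means = np.array([s.mean for s in expressed])
    p80 = np.percentile(means, 80)
    p50 = np.percentile(means, 50)
    p20 = np.percentile(means, 20)
    out: list[ExpressionSummary] = []
    for s in summaries:
        if s.bin == "UNEXPRESSED":
            out.append(s)
            continue
        if convention == "descending":
            if s.mean >= p80:
                b = "HIGH"
            elif s.mean < p50:
                b = "LOW"
            else:
                b = "MEDIUM"
        elif convention == "literal":
            if s.mean < p50:
                b = "LOW"
            elif s.mean > p20:
                b = "HIGH"
            else:
                b = "MEDIUM"
        else:
            raise ValueError(f"unknown percentile convention {convention!r}")
        out.append(ExpressionSummary(s.transcript_id, s.n_expressed_samples,
                                     s.mean, s.sd, s.median, b))
    return out


def expression_profile(
    counts: CountTable, lengths: Mapping[str, int]
) -> tuple[RpkmMatrix, list[ExpressionSummary]]:
    """Convenience: RPKM -> summaries -> bins in one call."""
    m = rpkm(counts, lengths)
    return m, percentile_bins(summarize(m))
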