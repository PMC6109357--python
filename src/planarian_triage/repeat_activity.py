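"""Repeat-element extraction, consensus divergence by global alignment, activity calls.

Each annotated repeat copy is extracted from the genome with 1000-bp flanks,
its core aligned to the family consensus with an affine-gap global aligner
(match +5, mismatch -4, gap open 10, gap extend 0.5), and the percent
divergence (100 - percent identity over the full alignment, gap columns in
the denominator) computed.  Copies diverging <= 5% from the consensus are
classified as likely transcriptionally/transpositionally active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coding_triage import revcomp
from .io_formats import FastaRecord, RepeatMaskerHit, to_internal

ACTIVE_MAX_DIVERGENCE = 5.0
DEFAULT_FLANK = 1000

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    #: when False, leading/trailing gaps are free (semi-global ends)
    end_gaps_penalized: bool = True

    def __post_init__(self) -> None:
        if not (self.gap_open > self.gap_extend >= 0):
            raise ValueError("require gap_open > gap_extend >= 0")


@dataclass(frozen=True)
class ElementInstance:
    element_id: str
    family: str
    seq_name: str
    core_start: int
    core_end: int
    ext_start: int
    ext_end: int
    strand: str
    sequence: str  # flank-extended, reverse-complemented on '-' strand

    def core_sequence(self) -> str:
        """The element proper, oriented with the extracted sequence."""
        if self.strand == "+":
            s = self.core_start - self.ext_start
            e = self.core_end - self.ext_start
        else:
            s = self.ext_end - self.core_end
            e = self.ext_end - self.core_start
        return self.sequence[s:e]


@dataclass(frozen=True)
class DivergenceRecord:
    element_id: str
    family: str
    identity_pct: float
    divergence_pct: float
    aln_len: int
    active: bool


# ---------------------------------------------------------------------------
# Extraction


def extract_elements(
    genome: Sequence[FastaRecord],
    hits: Sequence[RepeatMaskerHit],
    flank: int = DEFAULT_FLANK,
) -> list[ElementInstance]:
    """Extract each repeat copy with up to ``flank`` bp on either side, clipped
    at contig bounds; 'C'-strand hits are reverse-complemented."""
    contigs = {g.id: g.sequence for g in genome}
    out: list[ElementInstance] = []
    for i, h in enumerate(hits):
        if h.seq_name not in contigs:
            raise ValueError(f"hit {i} ({h.repeat_name}): unknown contig {h.seq_name!r}")
        seq = contigs[h.seq_name]
        core_start, core_end = to_internal(h.qstart, h.qend)
        if core_end > len(seq):
            raise ValueError(
                f"hit {i} ({h.repeat_name} on {h.seq_name}): coordinates beyond contig"
            )
        ext_start = max(0, core_start - flank)
        ext_end = min(len(seq), core_end + flank)
        strand = "+" if h.strand == "+" else "-"
        sub = seq[ext_start:ext_end]
        if strand == "-":
            sub = revcomp(sub)
        out.append(
            ElementInstance(
                element_id=f"{h.repeat_name}|{h.seq_name}:{core_start}-{core_end}",
                family=h.repeat_name,
                seq_name=h.seq_name,
                core_start=core_start,
                core_end=core_end,
                ext_start=ext_start,
                ext_end=ext_end,
                strand=strand,
                sequence=sub,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Global alignment (Gotoh, affine gaps)


def _gotoh_matrices(a: str, b: str, p: AlignmentParams):
    """Fill the three Gotoh state matrices.

    M: column aligning a[i-1] with b[j-1]; Ix: a[i-1] over a gap (vertical);
    Iy: gap over b[j-1] (horizontal).  A gap of length k costs open + k*extend.
    """
    m, n = len(a), len(b)
    open_, ext = p.gap_open, p.gap_extend
    end_open, end_ext = (open_, ext) if p.end_gaps_penalized else (0.0, 0.0)

    av = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bv = np.frombuffer(b.upper().encode(), dtype=np.uint8)

    M = np.full((m + 1, n + 1), NEG_INF)
    Ix = np.full((m + 1, n + 1), NEG_INF)
    Iy = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    # leading gaps
    for i in range(1, m + 1):
        Ix[i, 0] = -(end_open + i * end_ext)
    for j in range(1, n + 1):
        Iy[0, j] = -(end_open + j * end_ext)

    js = np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        prevH = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        sub = np.where(av[i - 1] == bv, p.match, p.mismatch)
        M[i, 1:] = prevH[:-1] + sub
        # vertical gap: trailing column (j == n) may be an end gap, priced below
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) - open_ - ext,
            Ix[i - 1, 1:] - ext,
        )
        # horizontal gap via running-max transform (sequential in j otherwise)
        V = np.maximum(M[i], Ix[i]) - open_
        W = V + ext * js
        U = np.empty(n + 1)
        U[0] = NEG_INF
        np.maximum.accumulate(W[:-1], out=U[1:])
        Iy[i, 1:] = U[1:] - ext * js[1:]
    return M, Ix, Iy


def _end_gap_cost(k: int, p: AlignmentParams) -> float:
    if k == 0:
        return 0.0
    if p.end_gaps_penalized:
        return p.gap_open + k * p.gap_extend
    return 0.0


def global_align(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[str, str, float, float]:
    """Optimal global alignment of two nucleotide strings under affine gaps.

    Returns ``(aligned_a, aligned_b, score, identity_pct)`` with identity
    computed over the full alignment length (gap columns count in the
    denominator).  Traceback is deterministic: diagonal, then up, then left.
    """
    p = params or AlignmentParams()
    if not a or not b:
        raise ValueError("empty sequence")
    m, n = len(a), len(b)
    M, Ix, Iy = _gotoh_matrices(a, b, p)

    # terminal cell: with penalized end gaps the optimum ends at (m, n); with
    # free end gaps any last-row/column cell may end the aligned region
    best_score = NEG_INF
    best = (m, n, "M")
    candidates: list[tuple[int, int]] = [(m, n)]
    if not p.end_gaps_penalized:
        candidates = [(i, n) for i in range(m, -1, -1)] + [
            (m, j) for j in range(n - 1, -1, -1)
        ]
    for (i, j) in candidates:
        tail = 0.0
        if p.end_gaps_penalized and (i < m or j < n):
            continue
        for state, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
            s = mat[i, j] + tail
            if s > best_score:
                best_score = s
                best = (i, j, state)
    i, j, state = best

    cols_a: list[str] = []
    cols_b: list[str] = []
    # trailing free end gaps
    for k in range(m - 1, i - 1, -1):
        cols_a.append(a[k])
        cols_b.append("-")
    for k in range(n - 1, j - 1, -1):
        cols_a.append("-")
        cols_b.append(b[k])

    open_, ext = p.gap_open, p.gap_extend

    def eq(x: float, y: float) -> bool:
        return x == y  # scores are exact multiples of 0.5

    while i > 0 or j > 0:
        if i == 0:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
            continue
        if j == 0:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            continue
        if state == "M":
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            s = p.match if a[i - 1].upper() == b[j - 1].upper() else p.mismatch
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if eq(mat[i, j], target):
                    state = st
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed in M state")
        elif state == "Ix":
            cols_a.append(a[i - 1])
            cols_b.append("-")
            target = Ix[i, j]
            i -= 1
            if j == 0:
                state = "Ix"
                continue
            if eq(M[i, j] - open_ - ext, target):
                state = "M"
            elif eq(Ix[i, j] - ext, target):
                state = "Ix"
            elif eq(Iy[i, j] - open_ - ext, target):
                state = "Iy"
            else:  # pragma: no cover
                raise AssertionError("traceback failed in Ix state")
        else:  # Iy
            cols_a.append("-")
            cols_b.append(b[j - 1])
            target = Iy[i, j]
            j -= 1
            if i == 0:
                state = "Iy"
                continue
            if eq(M[i, j] - open_ - ext, target):
                state = "M"
            elif eq(Ix[i, j] - open_ - ext, target):
                state = "Ix"
            elif eq(Iy[i, j] - ext, target):
                state = "Iy"
            else:  # pragma: no cover
                raise AssertionError("traceback failed in Iy state")

    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    ident = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x != "-" and y != "-" and x.upper() == y.upper()
    )
    identity_pct = 100.0 * ident / len(aligned_a)
    return aligned_a, aligned_b, float(best_score), identity_pct


def align_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Score only (no traceback); same model as :func:`global_align`."""
    p = params or AlignmentParams()
    if not a or not b:
        raise ValueError("empty sequence")
    m, n = len(a), len(b)
    M, Ix, Iy = _gotoh_matrices(a, b, p)
    if p.end_gaps_penalized:
        return float(max(M[m, n], Ix[m, n], Iy[m, n]))
    best = NEG_INF
    for i in range(m + 1):
        best = max(best, M[i, n], Ix[i, n], Iy[i, n])
    for j in range(n + 1):
        best = max(best, M[m, j], Ix[m, j], Iy[m, j])
    return float(best)


# ---------------------------------------------------------------------------
# Divergence profiles


def divergence_profile(
    elements: Sequence[ElementInstance],
    consensus_by_family: Mapping[str, str],
    params: AlignmentParams | None = None,
    region: str = "core",
) -> list[DivergenceRecord]:
    """Align each element (core by default, optionally flank-extended) to its
    family consensus; divergence = 100 - identity; active iff divergence <= 5%."""
    if region not in {"core", "extended"}:
        raise ValueError(f"unknown region {region!r}")
    p = params or AlignmentParams()
    out: list[DivergenceRecord] = []
    for el in elements:
        if el.family not in consensus_by_family:
            raise ValueError(f"family {el.family!r} has no consensus sequence")
        seq = el.core_sequence() if region == "core" else el.sequence
        aa, _bb, _score, identity = global_align(
            seq, consensus_by_family[el.family], p
        )
        div = 100.0 - identity
        out.append(
            DivergenceRecord(
                element_id=el.element_id,
                family=el.family,
                identity_pct=identity,
                divergence_pct=div,
                aln_len=len(aa),
                active=div <= ACTIVE_MAX_DIVERGENCE,
            )
        )
    return out


def divergence_histogram(
    records: Sequence[DivergenceRecord], bin_width: float = 1.0
) -> dict[str, dict]:
    """Per-family half-open divergence bins [0,1), [1,2), ... and fraction active."""
    if not records:
        raise ValueError("no divergence records")
    out: dict[str, dict] = {}
    for fam in sorted({r.family for r in records}):
        rs = [r for r in records if r.family == fam]
        divs = [r.divergence_pct for r in rs]
        n_bins = int(max(divs) // bin_width) + 1
        counts = [0] * n_bins
        for d in divs:
            counts[int(d // bin_width)] += 1
        out[fam] = {
            "bin_width": bin_width,
            "counts": counts,
            "n": len(rs),
            "fraction_active": sum(r.active for r in rs) / len(rs),
        }
    return out
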