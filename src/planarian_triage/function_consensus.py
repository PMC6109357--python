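"""Enzyme-annotation consensus, pathway conservation, TF consolidation, GO transfer.

Enzyme Commission (EC) calls from three predictors are filtered by
source-specific score cutoffs, then consolidated: a (transcript, EC) pair
enters the consensus iff it is supported by both the profile-based and the
homology-based predictor, or by the probabilistic density-estimation
predictor alone.  Percent pathway conservation is the fraction of a
pathway's EC set covered by distinct consensus ECs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import GafRecord

SOURCES = ("DETECT", "BLASTP", "PRIAM")


@dataclass(frozen=True)
class ECCall:
    transcript_id: str
    ec: str
    source: str
    ils: float | None = None            # DETECT integrated likelihood score
    positive_hits: int | None = None    # DETECT
    evalue: float | None = None         # BLASTP
    is_top_hit: bool = True             # BLASTP: query's top hit
    probability: float | None = None    # PRIAM
    profile_cov: float | None = None    # PRIAM, percent

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown EC source {self.source!r}")


@dataclass(frozen=True)
class PathwayMap:
    pathway_id: str
    name: str
    ec_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ec_set:
            raise ValueError(f"pathway {self.pathway_id!r} has empty EC set")


@dataclass(frozen=True)
class PathwayConservation:
    pathway_id: str
    n_predicted: int
    n_total: int
    pct: float


@dataclass(frozen=True)
class TFCall:
    transcript_id: str
    criteria: frozenset[str]  # subset of {DESCRIPTION, DBD_PFAM, DBD_SUPERFAMILY}
    families: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("TFCall with no firing criterion")


@dataclass(frozen=True)
class GOTransfer:
    transcript_id: str
    go_id: str
    aspect: str
    evidence_code: str
    source_object_id: str

    def __post_init__(self) -> None:
        if self.evidence_code == "IEA":
            raise ValueError("electronically inferred annotations are not transferable")


# ---------------------------------------------------------------------------
# Per-source filters and consensus

DETECT_ILS_MIN = 0.9
DETECT_POSITIVE_HITS_MIN = 5
BLASTP_EVALUE_MAX = 1e-10
PRIAM_PROBABILITY_MIN = 0.5   # strict >
PRIAM_PROFILE_COV_MIN = 70.0  # strict >


def _require(call: ECCall, attr: str) -> float:
    v = getattr(call, attr)
    if v is None:
        raise ValueError(
            f"{call.source} call for {call.transcript_id!r} missing {attr}"
        )
    return v


def filter_source(calls: Iterable[ECCall]) -> list[ECCall]:
    """Apply each predictor's published score cutoffs."""
    kept: list[ECCall] = []
    for c in calls:
        if c.source == "DETECT":
            if (_require(c, "ils") >= DETECT_ILS_MIN
                    and _require(c, "positive_hits") >= DETECT_POSITIVE_HITS_MIN):
                kept.append(c)
        elif c.source == "BLASTP":
            if _require(c, "evalue") <= BLASTP_EVALUE_MAX and c.is_top_hit:
                kept.append(c)
        elif c.source == "PRIAM":
            if (_require(c, "probability") > PRIAM_PROBABILITY_MIN
                    and _require(c, "profile_cov") > PRIAM_PROFILE_COV_MIN):
                kept.append(c)
    return kept


def consensus(filtered: Iterable[ECCall]) -> list[tuple[str, str, frozenset[str]]]:
    """(transcript, EC) pairs supported by PRIAM+BLASTP jointly or DETECT alone.

    EC strings are matched exactly; wildcard fields never match concrete ones.
    Returns (transcript_id, ec, supporting sources), sorted for determinism.
    """
    support: dict[tuple[str, str], set[str]] = {}
    for c in filtered:
        support.setdefault((c.transcript_id, c.ec), set()).add(c.source)
    out = []
    for (tid, ec), srcs in support.items():
        if {"PRIAM", "BLASTP"} <= srcs or "DETECT" in srcs:
            out.append((tid, ec, frozenset(srcs)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def _is_concrete(ec: str) -> bool:
    parts = ec.split(".")
    return len(parts) == 4 and all(p != "-" and p != "" for p in parts)


def pathway_conservation(
    consensus_pairs: Sequence[tuple[str, str, frozenset[str]]],
    pathways: Iterable[PathwayMap],
) -> list[PathwayConservation]:
    """Percent of each pathway's EC set covered by distinct consensus ECs."""
    predicted_ecs = {ec for _, ec, _ in consensus_pairs if _is_concrete(ec)}
    out: list[PathwayConservation] = []
    for p in pathways:
        n_total = len(p.ec_set)
        n_pred = len(p.ec_set & predicted_ecs)
        out.append(
            PathwayConservation(p.pathway_id, n_pred, n_total,
                                100.0 * n_pred / n_total)
        )
    return out


# ---------------------------------------------------------------------------
# Transcription factors


@dataclass(frozen=True)
class DomainScanRow:
    """One InterProScan-style row: which analysis produced it, the member-database
    family id, and the free-text signature description."""

    transcript_id: str
    analysis: str  # Pfam | SUPERFAMILY | other
    family_id: str
    description: str


def tf_consolidate(
    rows: Iterable[DomainScanRow],
    dbd_pfam: Iterable[str],
    dbd_superfamily: Iterable[str],
) -> list[TFCall]:
    """Union of three criteria per transcript: description contains
    "transcription factor" (case-insensitive); Pfam family in the curated
    DNA-binding-domain (DBD) Pfam list; Superfamily family in the DBD
    Superfamily list."""
    dbd_pfam = set(dbd_pfam)
    dbd_superfamily = set(dbd_superfamily)
    crit: dict[str, set[str]] = {}
    fams: dict[str, list[str]] = {}
    for r in rows:
        fired = False
        if "transcription factor" in r.description.lower():
            crit.setdefault(r.transcript_id, set()).add("DESCRIPTION")
            fired = True
        if r.analysis.lower() == "pfam" and r.family_id in dbd_pfam:
            crit.setdefault(r.transcript_id, set()).add("DBD_PFAM")
            fired = True
        if r.analysis.lower() == "superfamily" and r.family_id in dbd_superfamily:
            crit.setdefault(r.transcript_id, set()).add("DBD_SUPERFAMILY")
            fired = True
        if fired:
            fams.setdefault(r.transcript_id, [])
            if r.family_id not in fams[r.transcript_id]:
                fams[r.transcript_id].append(r.family_id)
    return [
        TFCall(tid, frozenset(crit[tid]), tuple(fams[tid]))
        for tid in sorted(crit)
    ]


# ---------------------------------------------------------------------------
# GO transfer


def go_transfer(
    ortholog_pairs: Sequence[tuple[str, str]],
    gaf: Iterable[GafRecord],
) -> list[GOTransfer]:
    """Transfer non-IEA GO annotations across 1:1 ortholog pairs.

    ``ortholog_pairs`` maps transcript id <-> model-organism object id and must
    be one-to-one; duplicated ids on either side are rejected.
    """
    left = [a for a, _ in ortholog_pairs]
    right = [b for _, b in ortholog_pairs]
    if len(set(left)) != len(left) or len(set(right)) != len(right):
        raise ValueError("ortholog table is not one-to-one")
    by_object: dict[str, list[GafRecord]] = {}
    for rec in gaf:
        by_object.setdefault(rec.object_id, []).append(rec)
    seen: set[tuple[str, str, str]] = set()
    out: list[GOTransfer] = []
    for tid, obj in ortholog_pairs:
        for rec in by_object.get(obj, ()):
            if rec.evidence_code == "IEA":
                continue
            key = (tid, rec.go_id, rec.aspect)
            if key in seen:
                continue
            seen.add(key)
            out.append(GOTransfer(tid, rec.go_id, rec.aspect,
                                  rec.evidence_code, obj))
    return out
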