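"""Tiered transcript triage: ORF calling, tier assignment, retention and flags.

Transcripts are classified by descending-stringency homology evidence
(ribosomal RNA > mitochondrial > nuclear protein), then by external coding
prediction, with a six-frame longest-ORF fallback.  Retention requires either
reference coverage (homology tiers) or a long ORF co-locating on the genome
(prediction tiers), with secondary evidence (conserved eukaryotic gene sets,
helminth ESTs, protein domains, genome co-location) rescuing failures.
Contaminant and mis-assembly flags veto retention unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import FastaRecord, TabularHit

STOP = "*"

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
#: standard genetic code (translation table 1)
CODON_TABLE: dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing a non-ACGT symbol yields 'X'."""
    codon = codon.upper()
    return CODON_TABLE.get(codon, "X")


@dataclass(frozen=True)
class OrfHit:
    """A maximal stop-free amino-acid segment in one reading frame.

    Coordinates are 0-based half-open on the forward strand of the input
    sequence, even for negative frames (which read the reverse complement).
    """

    transcript_id: str
    frame: str
    nt_start: int
    nt_end: int
    aa_len: int
    protein: str

    def __post_init__(self) -> None:
        if self.nt_end - self.nt_start != 3 * self.aa_len:
            raise ValueError("nt span inconsistent with aa_len")
        if STOP in self.protein:
            raise ValueError("protein contains a stop symbol")


@dataclass(frozen=True)
class TriageThresholds:
    rna_evalue: float = 1e-65
    mito_evalue: float = 1e-08
    nuclear_evalue: float = 1e-05
    ref_cov_retain: float = 2.0 / 3.0
    cegma_busco_evalue: float = 1e-08
    helminth_est_evalue: float = 1e-15
    interpro_evalue: float = 1e-03
    genome_f2_identity: float = 93.0
    genome_f2_cov: float = 93.0
    genome_f2_len: int = 200
    min_orf_aa: int = 100
    contam_nt_ident: float = 95.0
    contam_nt_cov: float = 95.0
    contam_nonmetazoan_ident: float = 80.0
    misassembly_unmapped: int = 25
    #: which side of the alignment the 2/3 coverage rule reads ("subject" or "query")
    ref_cov_side: str = "subject"


TIERS = ("RNA", "MITO", "NUCLEAR", "ESTSCAN", "LONGEST_ORF", "UNCLASSIFIED")

_TIER_TAG = {"RNA": "SILVA", "MITO": "MITO", "NUCLEAR": "UNIPROT"}


@dataclass(frozen=True)
class TriageDecision:
    transcript_id: str
    tier: str
    retained: bool
    contaminant: bool
    contaminant_rule: str  # NT95 | NONMETAZOAN80 | VECTOR | NONE
    misassembled: bool
    reasons: tuple[str, ...]


# ---------------------------------------------------------------------------
# ORF calling


def _frame_segments(transcript_id: str, seq: str, frame: str) -> list[OrfHit]:
    L = len(seq)
    neg = frame.startswith("-")
    offset = int(frame[1]) - 1
    read = revcomp(seq) if neg else seq
    n_codons = (L - offset) // 3
    hits: list[OrfHit] = []
    seg_start: int | None = None
    aas: list[str] = []

    def flush(end_codon: int) -> None:
        nonlocal seg_start, aas
        if seg_start is None:
            return
        s = offset + 3 * seg_start
        e = offset + 3 * end_codon
        if neg:
            s, e = L - e, L - s
        hits.append(
            OrfHit(transcript_id, frame, s, e, len(aas), "".join(aas))
        )
        seg_start, aas = None, []

    for i in range(n_codons):
        aa = translate_codon(read[offset + 3 * i : offset + 3 * i + 3])
        if aa == STOP:
            flush(i)
        else:
            if seg_start is None:
                seg_start = i
            aas.append(aa)
    flush(n_codons)
    return hits


def six_frame_orfs(seq: str, transcript_id: str = "") -> list[OrfHit]:
    """Every maximal stop-free amino-acid segment in all six reading frames."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out: list[OrfHit] = []
    for frame in FRAMES:
        out.extend(_frame_segments(transcript_id, seq, frame))
    return out


def longest_orf(seq: str, transcript_id: str = "") -> OrfHit:
    """The single longest stop-free segment; ties broken by frame order then
    smallest forward-strand start coordinate."""
    hits = six_frame_orfs(seq, transcript_id)
    hits = [h for h in hits if h.aa_len > 0]
    if not hits:
        raise ValueError(f"{transcript_id or 'sequence'}: no translatable codon")
    frame_rank = {f: i for i, f in enumerate(FRAMES)}
    return min(hits, key=lambda h: (-h.aa_len, frame_rank[h.frame], h.nt_start))


# ---------------------------------------------------------------------------
# Tier assignment


def assign_tier(
    transcript_id: str,
    hits: Sequence[TabularHit],
    has_estscan: bool,
    th: TriageThresholds | None = None,
) -> str:
    th = th or TriageThresholds()
    by_tag: dict[str, list[TabularHit]] = {}
    for h in hits:
        by_tag.setdefault(h.db_tag, []).append(h)
    for tier, (tag, cutoff) in (
        ("RNA", ("SILVA", th.rna_evalue)),
        ("MITO", ("MITO", th.mito_evalue)),
        ("NUCLEAR", ("UNIPROT", th.nuclear_evalue)),
    ):
        if any(h.evalue <= cutoff for h in by_tag.get(tag, ())):
            return tier
    return "ESTSCAN" if has_estscan else "LONGEST_ORF"


# ---------------------------------------------------------------------------
# Retention


def _best_hit(hits: Sequence[TabularHit]) -> TabularHit:
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.sid))


def _genome_support(hits: Sequence[TabularHit], overlaps_known_locus: bool,
                    th: TriageThresholds) -> bool:
    if not overlaps_known_locus:
        return False
    return any(
        h.db_tag == "GENOME"
        and h.pident >= th.genome_f2_identity
        and (h.qcov is not None and h.qcov >= th.genome_f2_cov)
        and h.aln_len > th.genome_f2_len
        for h in hits
    )


def retain(
    transcript_id: str,
    tier: str,
    hits: Sequence[TabularHit],
    aa_len: int,
    overlaps_known_locus: bool = False,
    interpro_min_evalue: float | None = None,
    th: TriageThresholds | None = None,
) -> tuple[bool, list[str]]:
    """Apply the tier-specific primary retention rule, then secondary rescues.

    Returns ``(retained, reasons)`` with one reason id per firing rule.
    """
    th = th or TriageThresholds()
    reasons: list[str] = []
    primary = False
    if tier in _TIER_TAG:
        tag = _TIER_TAG[tier]
        cutoff = {"RNA": th.rna_evalue, "MITO": th.mito_evalue,
                  "NUCLEAR": th.nuclear_evalue}[tier]
        tier_hits = [h for h in hits if h.db_tag == tag and h.evalue <= cutoff]
        if tier_hits:
            best = _best_hit(tier_hits)
            cov = best.scov if th.ref_cov_side == "subject" else best.qcov
            if cov is None:
                raise ValueError(
                    f"{transcript_id}: deciding {tag} hit lacks "
                    f"{th.ref_cov_side} coverage column"
                )
            if cov >= 100.0 * th.ref_cov_retain:
                primary = True
                reasons.append("REF_COV")
    elif tier in ("ESTSCAN", "LONGEST_ORF"):
        if aa_len > th.min_orf_aa and _genome_support(hits, overlaps_known_locus, th):
            primary = True
            reasons.append("ORF_COLOC")

    # secondary supports (always reported when they fire)
    secondary: list[str] = []
    if any(h.db_tag == "CEGMA_BUSCO" and h.evalue <= th.cegma_busco_evalue for h in hits):
        secondary.append("CEGMA_BUSCO")
    if any(h.db_tag == "HELMINTH_EST" and h.evalue <= th.helminth_est_evalue for h in hits):
        secondary.append("HELMINTH_EST")
    if interpro_min_evalue is not None and interpro_min_evalue <= th.interpro_evalue:
        secondary.append("INTERPRO")
    if tier in _TIER_TAG and _genome_support(hits, overlaps_known_locus, th):
        secondary.append("GENOME_COLOC")

    # a transcript failing its primary rule is retained if any secondary
    # support fires, regardless of tier
    retained = primary or bool(secondary)
    reasons.extend(secondary)
    return retained, reasons


# ---------------------------------------------------------------------------
# Flags


def flag_contaminants(
    transcript_id: str,
    nt_hits: Sequence[tuple[TabularHit, str]],
    uniprot_hits: Sequence[tuple[TabularHit, bool]],
    th: TriageThresholds | None = None,
) -> str:
    """First matching rule in order VECTOR, NT95, NONMETAZOAN80; else NONE.

    ``nt_hits`` carry caller-supplied labels in {"foreign", "self", "vector"};
    ``uniprot_hits`` carry a caller-supplied is-metazoan flag.
    """
    th = th or TriageThresholds()
    if any(label == "vector" for _, label in nt_hits):
        return "VECTOR"
    if any(
        label == "foreign"
        and h.pident >= th.contam_nt_ident
        and (h.qcov is not None and h.qcov >= th.contam_nt_cov)
        for h, label in nt_hits
    ):
        return "NT95"
    if uniprot_hits:
        best, is_metazoan = max(
            uniprot_hits, key=lambda t: (t[0].bitscore, -t[0].evalue)
        )
        if not is_metazoan and best.pident >= th.contam_nonmetazoan_ident:
            return "NONMETAZOAN80"
    return "NONE"


def flag_misassembled(
    transcript_id: str,
    per_base_read_coverage: Sequence[int] | np.ndarray,
    transcript_length: int | None = None,
    th: TriageThresholds | None = None,
) -> bool:
    """True iff the number of zero-coverage (unmapped) positions meets the cutoff."""
    th = th or TriageThresholds()
    cov = np.asarray(per_base_read_coverage)
    if transcript_length is not None and len(cov) != transcript_length:
        raise ValueError(
            f"{transcript_id}: coverage vector length {len(cov)} != "
            f"transcript length {transcript_length}"
        )
    return int((cov == 0).sum()) >= th.misassembly_unmapped


# ---------------------------------------------------------------------------
# Full triage


def triage(
    transcripts: Sequence[FastaRecord],
    evidence: Sequence[TabularHit],
    coverage: Mapping[str, Sequence[int]] | None = None,
    th: TriageThresholds | None = None,
    estscan_ids: Iterable[str] = (),
    genome_overlap_ids: Iterable[str] = (),
    nt_labels: Mapping[str, str] | None = None,
    metazoan_labels: Mapping[str, bool] | None = None,
    interpro_min_evalue: Mapping[str, float] | None = None,
) -> list[TriageDecision]:
    """Run misassembly -> contamination -> tier -> retention for every transcript.

    ``nt_labels`` maps NT subject ids to {"foreign","self","vector"};
    ``metazoan_labels`` maps UniProt subject ids to an is-metazoan flag;
    unlabeled subjects default to "self" / metazoan.
    """
    th = th or TriageThresholds()
    nt_labels = nt_labels or {}
    metazoan_labels = metazoan_labels or {}
    interpro_min_evalue = interpro_min_evalue or {}
    estscan_ids = set(estscan_ids)
    genome_overlap_ids = set(genome_overlap_ids)

    known = {t.id for t in transcripts}
    unknown = sorted({h.qid for h in evidence} - known)
    if unknown:
        raise ValueError(f"evidence references unknown transcript ids: {unknown}")

    by_qid: dict[str, list[TabularHit]] = {t.id: [] for t in transcripts}
    for h in evidence:
        by_qid[h.qid].append(h)
    # order invariance: sort each transcript's evidence canonically
    for lst in by_qid.values():
        lst.sort(key=lambda h: (h.db_tag, h.sid, h.evalue, -h.bitscore, h.qstart))

    decisions: list[TriageDecision] = []
    for t in transcripts:
        hits = by_qid[t.id]
        mis = False
        if coverage is not None and t.id in coverage:
            mis = flag_misassembled(t.id, coverage[t.id], len(t.sequence), th)
        nt_pairs = [
            (h, nt_labels.get(h.sid, "self")) for h in hits if h.db_tag == "NT"
        ]
        up_pairs = [
            (h, metazoan_labels.get(h.sid, True)) for h in hits if h.db_tag == "UNIPROT"
        ]
        rule = flag_contaminants(t.id, nt_pairs, up_pairs, th)
        contaminant = rule != "NONE"
        tier = assign_tier(t.id, hits, t.id in estscan_ids, th)
        try:
            aa_len = longest_orf(t.sequence, t.id).aa_len
        except ValueError:
            aa_len = 0
        retained, reasons = retain(
            t.id, tier, hits, aa_len,
            overlaps_known_locus=t.id in genome_overlap_ids,
            interpro_min_evalue=interpro_min_evalue.get(t.id),
            th=th,
        )
        if mis or contaminant:
            retained = False
        if contaminant:
            reasons = [f"CONTAMINANT_{rule}"] + reasons
        if mis:
            reasons = ["MISASSEMBLED"] + reasons
        decisions.append(
            TriageDecision(
                transcript_id=t.id,
                tier=tier,
                retained=retained,
                contaminant=contaminant,
                contaminant_rule=rule,
                misassembled=mis,
                reasons=tuple(reasons),
            )
        )
    return decisions


def triage_summary(decisions: Sequence[TriageDecision]) -> dict:
    """Per-tier / per-rule counts for reporting."""
    tiers = {t: 0 for t in TIERS}
    rules: dict[str, int] = {}
    retained = 0
    for d in decisions:
        tiers[d.tier] += 1
        retained += d.retained
        for r in d.reasons:
            rules[r] = rules.get(r, 0) + 1
    return {
        "n": len(decisions),
        "retained": retained,
        "contaminants": sum(d.contaminant for d in decisions),
        "misassembled": sum(d.misassembled for d in decisions),
        "tiers": tiers,
        "rules": dict(sorted(rules.items())),
    }
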