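"""Seeded generators for every input the pipeline consumes, with planted truth.

Each generator is a pure function of :class:`SimConfig` (the seed included);
sub-generators draw from independent child streams of the one seed so stages
do not couple.  Ground truth (planted tiers, retention verdicts, ORFs,
markers, divergences, consensus enzyme sets) is recorded alongside, enabling
exact recovery tests for the deterministic stages and calibrated tolerance
tests for the stochastic ones.

Transcript construction guarantees a unique longest open reading frame: the
planted ORF is framed by in-frame stops, non-ORF frames are interrupted by a
stop cassette at least every 15 codons, and the flanks are tiled with the
palindromic motif TTAA, which carries stop codons in all six frames within
every 12-nt window.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coding_triage import CODON_TABLE, revcomp
from .function_consensus import DomainScanRow, ECCall, PathwayMap
from .io_formats import CountTable, FastaRecord, GafRecord, RepeatMaskerHit, TabularHit

# codons per amino acid, for synonymous encoding of planted proteins
_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    if aa != "*":
        _AA_CODONS.setdefault(aa, []).append(codon)
_AMINO_ACIDS = sorted(_AA_CODONS)

#: 5 codons (peptide LIISY) planting stop codons in all five non-ORF frames
CASSETTE_NT = "CTAATCATTAGTTAC"
CASSETTE_AA = "LIISY"

TIER_NAMES = ("RNA", "MITO", "NUCLEAR", "ESTSCAN", "LONGEST_ORF")

REF_COV_BOUNDARY = 100.0 * 2.0 / 3.0


@dataclass
class SimConfig:
    seed: int = 0
    n_transcripts: int = 500
    length_range: tuple[int, int] = (500, 3000)
    tier_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "RNA": 0.10, "MITO": 0.10, "NUCLEAR": 0.40,
            "ESTSCAN": 0.20, "LONGEST_ORF": 0.20,
        }
    )
    contaminant_fraction: float = 0.05
    boundary_fraction: float = 0.20
    n_bulk_samples: int = 6
    sc_genes: int = 500
    sc_clusters: int = 6
    sc_cells_per_cluster: int = 30
    markers_per_cluster: int = 5
    marker_log2fc: float = 3.0
    nb_dispersion: float = 0.5
    dropout_rate: float = 0.2
    repeat_copies: int = 100
    repeat_length: int = 500
    repeat_divergence: float = 0.02
    pathway_sizes: list[int] = field(default_factory=lambda: [10, 8, 5])

    def __post_init__(self) -> None:
        for name in ("contaminant_fraction", "boundary_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.tier_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("tier_fractions must sum to 1")
        if set(self.tier_fractions) != set(TIER_NAMES):
            raise ValueError(f"tier_fractions keys must be {TIER_NAMES}")
        if not 0.0 <= self.repeat_divergence <= 0.3:
            raise ValueError("repeat_divergence must be in [0, 0.3]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("n_transcripts", "n_bulk_samples", "sc_genes", "sc_clusters",
                     "sc_cells_per_cluster", "markers_per_cluster", "repeat_copies",
                     "repeat_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.length_range[0] < 200 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")

    def stream(self, label: str) -> np.random.Generator:
        """An independent, deterministic child RNG for one generator stage."""
        key = zlib.crc32(label.encode()) % (2**31)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )


@dataclass
class GroundTruth:
    tier_of: dict[str, str] = field(default_factory=dict)
    contaminant_ids: set[str] = field(default_factory=set)
    contaminant_rule_of: dict[str, str] = field(default_factory=dict)
    planted_orf: dict[str, tuple[str, int]] = field(default_factory=dict)
    retained_of: dict[str, bool] = field(default_factory=dict)
    estscan_ids: set[str] = field(default_factory=set)
    genome_overlap_ids: set[str] = field(default_factory=set)
    nt_labels: dict[str, str] = field(default_factory=dict)
    metazoan_labels: dict[str, bool] = field(default_factory=dict)
    interpro_min_evalue: dict[str, float] = field(default_factory=dict)
    misassembled_ids: set[str] = field(default_factory=set)
    bulk_low_ids: set[str] = field(default_factory=set)
    marker_of: dict[str, str] = field(default_factory=dict)
    true_divergence: dict[str, float] = field(default_factory=dict)
    conserved_ecs: dict[str, set[str]] = field(default_factory=dict)
    consensus_pairs: set[tuple[str, str]] = field(default_factory=set)
    tf_criteria: dict[str, set[str]] = field(default_factory=dict)
    go_transfers: set[tuple[str, str]] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Transcripts with planted ORFs


def _flank(rng: np.random.Generator, length: int) -> str:
    return ("TTAA" * (length // 4 + 1))[:length]


def _orf_codons(rng: np.random.Generator, aa_len: int) -> tuple[str, str]:
    """Codon string and peptide of length ``aa_len`` with the stop cassette
    inserted every block of 10 random codons."""
    codons: list[str] = []
    peptide: list[str] = []
    while len(peptide) < aa_len:
        for c, a in zip(
            (CASSETTE_NT[k : k + 3] for k in range(0, 15, 3)), CASSETTE_AA
        ):
            if len(peptide) >= aa_len:
                break
            codons.append(c)
            peptide.append(a)
        for _ in range(10):
            if len(peptide) >= aa_len:
                break
            aa = _AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))]
            syn = _AA_CODONS[aa]
            codons.append(syn[rng.integers(len(syn))])
            peptide.append(aa)
    return "".join(codons), "".join(peptide)


def gen_transcripts(cfg: SimConfig) -> tuple[list[FastaRecord], GroundTruth]:
    """Transcripts each embedding exactly one maximal stop-free segment in a
    recorded frame; all other frames carry a stop at least every 60 nt."""
    rng = cfg.stream("transcripts")
    min_len, max_len = cfg.length_range
    truth = GroundTruth()
    records: list[FastaRecord] = []

    # tier assignment per transcript, proportional to tier_fractions
    n = cfg.n_transcripts
    tiers: list[str] = []
    for t in TIER_NAMES:
        tiers.extend([t] * int(round(cfg.tier_fractions[t] * n)))
    while len(tiers) < n:
        tiers.append("NUCLEAR")
    tiers = tiers[:n]
    rng.shuffle(tiers)

    for i in range(n):
        tid = f"tr{i:05d}"
        # aa lengths straddle the >100-aa retention boundary; keep >= 25 so the
        # planted segment dominates any other-frame run (bounded by 16 codons)
        aa_len = int(rng.integers(30, 181))
        if i % 25 == 0:
            aa_len = 101  # boundary: just retains under the strict > 100 rule
        elif i % 25 == 1:
            aa_len = 100  # boundary: just fails
        orf_nt, _pep = _orf_codons(rng, aa_len)
        need = len(orf_nt) + 6
        offset = int(rng.integers(3))
        pre_len = 16 + 4 * int(rng.integers(0, 12))
        pre_len += (offset - pre_len) % 3  # ORF starts at pre_len + 3
        total_target = int(rng.integers(max(min_len, pre_len + need + 16), max_len + 1)) \
            if pre_len + need + 16 <= max_len else 0
        if total_target == 0:
            raise ValueError("length_range too small to embed planted segment")
        post_len = total_target - pre_len - need
        oriented = _flank(rng, pre_len) + "TAA" + orf_nt + "TAA" + _flank(rng, post_len)
        orf_offset = (pre_len + 3) % 3
        frame_idx = orf_offset + 1
        negative = bool(rng.integers(2))
        if negative:
            seq = revcomp(oriented)
            frame = f"-{frame_idx}"
        else:
            seq = oriented
            frame = f"+{frame_idx}"
        records.append(FastaRecord(tid, f"planted tier={tiers[i]}", seq))
        truth.tier_of[tid] = tiers[i]
        truth.planted_orf[tid] = (frame, aa_len)
        if tiers[i] == "ESTSCAN":
            truth.estscan_ids.add(tid)

    # contaminants: an id subset flagged regardless of tier evidence
    n_contam = int(round(cfg.contaminant_fraction * n))
    contam = rng.choice(n, size=n_contam, replace=False)
    rules = ("NT95", "NONMETAZOAN80", "VECTOR")
    for j, idx in enumerate(sorted(contam)):
        tid = f"tr{idx:05d}"
        truth.contaminant_ids.add(tid)
        truth.contaminant_rule_of[tid] = rules[j % 3]
    return records, truth


# ---------------------------------------------------------------------------
# Evidence tables


def _hit(qid: str, sid: str, tag: str, evalue: float, *, pident: float = 90.0,
         qcov: float | None = 80.0, scov: float | None = 80.0,
         bitscore: float = 200.0, aln_len: int = 300) -> TabularHit:
    return TabularHit(
        qid=qid, sid=sid, pident=pident, aln_len=aln_len, mismatches=10,
        gapopen=1, qstart=1, qend=aln_len, sstart=1, send=aln_len,
        evalue=evalue, bitscore=bitscore, db_tag=tag, qcov=qcov, scov=scov,
    )


_TIER_THRESH = {"RNA": ("SILVA", 1e-65), "MITO": ("MITO", 1e-08),
                "NUCLEAR": ("UNIPROT", 1e-05)}


def gen_evidence(cfg: SimConfig, truth: GroundTruth) -> list[TabularHit]:
    """Evidence rows making each transcript's planted tier test pass, all
    stricter tiers fail, with a configurable fraction of exact-boundary hits;
    contaminants get foreign/vector/non-metazoan hits triggering their rule."""
    rng = cfg.stream("evidence")
    hits: list[TabularHit] = []
    ids = sorted(truth.tier_of)
    n_boundary = int(round(cfg.boundary_fraction * len(ids)))
    boundary_ids = set(
        np.array(ids)[rng.choice(len(ids), size=n_boundary, replace=False)]
    )

    def passing_evalue(cutoff: float, boundary: bool) -> float:
        if boundary:
            return cutoff
        return cutoff * 10 ** (-float(rng.uniform(1, 20)))

    def failing_evalue(cutoff: float) -> float:
        return cutoff * 10 ** (float(rng.uniform(2, 10)))

    for tid in ids:
        tier = truth.tier_of[tid]
        boundary = tid in boundary_ids
        aa_len = truth.planted_orf[tid][1]
        # stricter tiers than the planted one: emit a failing hit half the time
        for stricter in TIER_NAMES[: TIER_NAMES.index(tier)]:
            if stricter in _TIER_THRESH and rng.random() < 0.5:
                tag, cut = _TIER_THRESH[stricter]
                sid = f"metazoan_{tag.lower()}_{tid}"
                hits.append(_hit(tid, sid, tag, failing_evalue(cut), bitscore=90.0))
                truth.metazoan_labels[sid] = True
                truth.nt_labels.setdefault(sid, "self")

        mode = rng.random()
        if tier in _TIER_THRESH:
            tag, cut = _TIER_THRESH[tier]
            if mode < 0.6:       # primary retention: reference coverage
                scov = REF_COV_BOUNDARY if boundary else float(rng.uniform(70, 100))
                retained = True
            elif mode < 0.8:     # fails coverage, rescued by secondary support
                scov = float(rng.uniform(10, 60))
                retained = True
            else:                # fails coverage, no support
                scov = float(rng.uniform(10, 60))
                retained = False
            sid = f"metazoan_{tag.lower()}_ref_{tid}"
            hits.append(
                _hit(tid, sid, tag, passing_evalue(cut, boundary),
                     scov=scov, bitscore=300.0)
            )
            truth.metazoan_labels[sid] = True
            if mode >= 0.6 and retained:
                kind = rng.integers(3)
                if kind == 0:
                    hits.append(_hit(tid, f"cegma_{tid}", "CEGMA_BUSCO",
                                     passing_evalue(1e-08, boundary)))
                elif kind == 1:
                    hits.append(_hit(tid, f"est_{tid}", "HELMINTH_EST",
                                     passing_evalue(1e-15, boundary)))
                else:
                    truth.interpro_min_evalue[tid] = (
                        1e-03 if boundary else float(10 ** -rng.uniform(4, 10))
                    )
        else:
            # prediction tiers: retention = ORF > 100 aa AND genome co-location
            coloc = rng.random() < 0.7
            if coloc:
                truth.genome_overlap_ids.add(tid)
                pident = 93.0 if boundary else float(rng.uniform(93.5, 99.5))
                qcov = 93.0 if boundary else float(rng.uniform(93.5, 100))
                hits.append(
                    _hit(tid, f"genome_{tid}", "GENOME", 1e-30,
                         pident=pident, qcov=qcov, aln_len=201 if boundary else 400)
                )
            retained = coloc and aa_len > 100
            if not retained and rng.random() < 0.25:
                hits.append(_hit(tid, f"est_{tid}", "HELMINTH_EST", 1e-20))
                retained = True
        truth.retained_of[tid] = retained

    # contaminant evidence (flags veto retention regardless of the above)
    for tid in sorted(truth.contaminant_ids):
        rule = truth.contaminant_rule_of[tid]
        if rule == "NT95":
            sid = f"foreign_nt_{tid}"
            pid = 95.0 if tid in boundary_ids else float(rng.uniform(95.5, 100))
            cov = 95.0 if tid in boundary_ids else float(rng.uniform(95.5, 100))
            hits.append(_hit(tid, sid, "NT", 1e-50, pident=pid, qcov=cov))
            truth.nt_labels[sid] = "foreign"
        elif rule == "VECTOR":
            sid = f"vector_{tid}"
            hits.append(_hit(tid, sid, "NT", 1e-40, pident=99.0, qcov=90.0))
            truth.nt_labels[sid] = "vector"
        else:  # NONMETAZOAN80: must be the best-scoring protein hit; its evalue
            # is kept above the nuclear-tier cutoff so it cannot change the tier
            sid = f"nonmetazoan_{tid}"
            pid = 80.0 if tid in boundary_ids else float(rng.uniform(81, 99))
            hits.append(
                _hit(tid, sid, "UNIPROT", 1e-2, pident=pid, bitscore=900.0)
            )
            truth.metazoan_labels[sid] = False
        truth.retained_of[tid] = False
    return hits


def gen_coverage(cfg: SimConfig, truth: GroundTruth,
                 transcripts: Sequence[FastaRecord]) -> dict[str, np.ndarray]:
    """Per-base read coverage; ~3% of transcripts planted with >= 25 unmapped
    bases (plus one boundary case at exactly 24)."""
    rng = cfg.stream("coverage")
    cov: dict[str, np.ndarray] = {}
    for i, t in enumerate(transcripts):
        L = len(t.sequence)
        v = rng.integers(1, 50, size=L)
        if i % 33 == 5:
            n_zero = 24 if i % 66 == 5 else int(rng.integers(25, 80))
            pos = rng.choice(L, size=n_zero, replace=False)
            v[pos] = 0
            if n_zero >= 25:
                truth.misassembled_ids.add(t.id)
                truth.retained_of[t.id] = False
        cov[t.id] = v
    return cov


# ---------------------------------------------------------------------------
# Bulk counts


def gen_bulk_counts(cfg: SimConfig, truth: GroundTruth) -> CountTable:
    """Log-normal expression levels with Poisson noise; the first 5% of
    transcripts are forced below 10 reads in sample 1 to exercise the
    restricted-denominator rule."""
    rng = cfg.stream("bulk")
    ids = sorted(truth.tier_of) or [f"tr{i:05d}" for i in range(cfg.n_transcripts)]
    n, s = len(ids), cfg.n_bulk_samples
    mu = np.exp(rng.normal(3.0, 1.2, size=n))
    counts = rng.poisson(mu[:, None] * rng.uniform(0.5, 2.0, size=(1, s)))
    n_low = max(1, n // 20)
    counts[:n_low, 0] = rng.integers(0, 10, size=n_low)
    truth.bulk_low_ids = set(ids[:n_low])
    return CountTable(ids, [f"sample{j}" for j in range(s)], counts.astype(np.int64))


# ---------------------------------------------------------------------------
# Single-cell counts


def gen_single_cell(
    cfg: SimConfig,
) -> tuple[CountTable, dict[str, str], GroundTruth]:
    """Negative-binomial counts with cluster-specific marker shifts, per-cell
    library-size factors, and Bernoulli dropout."""
    rng = cfg.stream("single_cell")
    truth = GroundTruth()
    G, C = cfg.sc_genes, cfg.sc_clusters
    cells_per = cfg.sc_cells_per_cluster
    genes = [f"g{i:04d}" for i in range(G)]
    clusters = [f"c{k}" for k in range(C)]
    n_markers = cfg.markers_per_cluster * C
    if n_markers > G:
        raise ValueError("more planted markers than genes")
    marker_idx = rng.choice(G, size=n_markers, replace=False)
    for j, gi in enumerate(marker_idx):
        truth.marker_of[genes[gi]] = clusters[j // cfg.markers_per_cluster]

    base_mu = np.exp(rng.normal(0.5, 0.5, size=G))
    cell_ids: list[str] = []
    labels: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    r = 1.0 / cfg.nb_dispersion  # NB shape: var = mu + dispersion * mu^2
    for k, cl in enumerate(clusters):
        mu = base_mu.copy()
        for j, gi in enumerate(marker_idx):
            if j // cfg.markers_per_cluster == k:
                mu[gi] = mu[gi] * 2.0 ** cfg.marker_log2fc
        size_factors = np.exp(rng.normal(0.0, 0.3, size=cells_per))
        m = mu[:, None] * size_factors[None, :]
        p = r / (r + m)
        block = rng.negative_binomial(r, p)
        if cfg.dropout_rate > 0:
            keep = rng.random(block.shape) >= cfg.dropout_rate
            block = block * keep
        blocks.append(block)
        for c in range(cells_per):
            cid = f"{cl}_cell{c:03d}"
            cell_ids.append(cid)
            labels[cid] = cl
    counts = np.concatenate(blocks, axis=1).astype(np.int64)
    return CountTable(genes, cell_ids, counts), labels, truth


# ---------------------------------------------------------------------------
# Repeat families


def gen_repeat_family(
    cfg: SimConfig,
) -> tuple[FastaRecord, list[FastaRecord], FastaRecord, list[RepeatMaskerHit], GroundTruth]:
    """A repeat family: consensus, mutated copies (substitution-only), a genome
    embedding every copy with >= 1000 bp flanks (first copy flank-clipped at
    the contig edge), and the matching repeat-annotation rows."""
    rng = cfg.stream("repeats")
    truth = GroundTruth()
    L = cfg.repeat_length
    bases = np.array(list("ACGT"))
    consensus_arr = bases[rng.integers(4, size=L)]
    consensus = FastaRecord("repfam1", "family consensus", "".join(consensus_arr))

    copies: list[FastaRecord] = []
    genome_parts: list[str] = []
    hits: list[RepeatMaskerHit] = []
    pos = 0
    contig = "contig1"
    for i in range(cfg.repeat_copies):
        arr = consensus_arr.copy()
        sub = rng.random(L) < cfg.repeat_divergence
        for j in np.flatnonzero(sub):
            others = [b for b in "ACGT" if b != arr[j]]
            arr[j] = others[rng.integers(3)]
        realized = float(sub.sum()) / L
        copy_seq = "".join(arr)
        strand = "+" if rng.random() < 0.5 else "C"
        # first copy sits 100 bp from the contig edge (flank clipped)
        spacer = 100 if i == 0 else int(rng.integers(1000, 1400))
        genome_parts.append("".join(bases[rng.integers(4, size=spacer)]))
        pos += spacer
        start0 = pos
        genome_parts.append(copy_seq if strand == "+" else revcomp(copy_seq))
        pos += L
        copies.append(FastaRecord(f"copy{i:03d}", f"strand={strand}", copy_seq))
        hits.append(
            RepeatMaskerHit(
                score=1000, pct_div=realized * 100, pct_del=0.0, pct_ins=0.0,
                seq_name=contig, qstart=start0 + 1, qend=pos, strand=strand,
                repeat_name="repfam1", repeat_class_family="DNA/TcMar-Tigger",
            )
        )
        truth.true_divergence[f"repfam1|{contig}:{start0}-{pos}"] = realized
    genome_parts.append("".join(bases[rng.integers(4, size=1200)]))
    genome = FastaRecord(contig, "synthetic genome", "".join(genome_parts))
    return consensus, copies, genome, hits, truth


# ---------------------------------------------------------------------------
# Annotation fixtures (enzymes, pathways, TFs, GO)


@dataclass
class AnnotationFixtures:
    pathways: list[PathwayMap]
    detect_calls: list[ECCall]
    blastp_calls: list[ECCall]
    priam_calls: list[ECCall]
    domain_rows: list[DomainScanRow]
    dbd_pfam: set[str]
    dbd_superfamily: set[str]
    gaf_records: list[GafRecord]
    ortholog_pairs: list[tuple[str, str]]


def gen_annotation_fixtures(cfg: SimConfig) -> tuple[AnnotationFixtures, GroundTruth]:
    """Enzyme/TF/GO fixtures planting known consensus outcomes."""
    rng = cfg.stream("annotation")
    truth = GroundTruth()
    pathways: list[PathwayMap] = []
    detect: list[ECCall] = []
    blastp: list[ECCall] = []
    priam: list[ECCall] = []
    ec_counter = itertools.count(1)
    t_counter = itertools.count(0)

    def new_tid() -> str:
        return f"enz{next(t_counter):04d}"

    for p_idx, size in enumerate(cfg.pathway_sizes):
        ecs = [f"{p_idx + 1}.1.1.{next(ec_counter)}" for _ in range(size)]
        n_cons = int(rng.integers(1, size + 1))
        conserved = set(ecs[:n_cons])
        truth.conserved_ecs[f"path{p_idx:02d}"] = conserved
        pathways.append(PathwayMap(f"path{p_idx:02d}", f"pathway {p_idx}", frozenset(ecs)))
        for ec in ecs:
            tid = new_tid()
            if ec in conserved:
                # alternate the two consensus routes; one EC gets multiple
                # transcripts to exercise dedup in the conservation statistic
                route = rng.integers(2)
                if route == 0:
                    detect.append(ECCall(tid, ec, "DETECT", ils=0.95, positive_hits=7))
                else:
                    blastp.append(ECCall(tid, ec, "BLASTP", evalue=1e-20))
                    priam.append(ECCall(tid, ec, "PRIAM", probability=0.8, profile_cov=85.0))
                truth.consensus_pairs.add((tid, ec))
                if rng.random() < 0.3:
                    tid2 = new_tid()
                    blastp.append(ECCall(tid2, ec, "BLASTP", evalue=1e-30))
                    priam.append(ECCall(tid2, ec, "PRIAM", probability=0.9, profile_cov=90.0))
                    truth.consensus_pairs.add((tid2, ec))
            else:
                # planted non-consensus: single-source or sub-threshold calls
                foil = rng.integers(4)
                if foil == 0:
                    priam.append(ECCall(tid, ec, "PRIAM", probability=0.8, profile_cov=85.0))
                elif foil == 1:
                    blastp.append(ECCall(tid, ec, "BLASTP", evalue=1e-20))
                elif foil == 2:
                    detect.append(ECCall(tid, ec, "DETECT", ils=0.95, positive_hits=4))
                else:
                    priam.append(ECCall(tid, ec, "PRIAM", probability=0.5, profile_cov=85.0))
                    blastp.append(ECCall(tid, ec, "BLASTP", evalue=1e-9))

    # transcription factors: one transcript per criterion + one multi-criterion
    dbd_pfam = {"PF00001", "PF00002"}
    dbd_superfamily = {"SSF0001"}
    rows = [
        DomainScanRow("tf_desc", "Gene3D", "G3D:1", "Transcription Factor AP-2"),
        DomainScanRow("tf_pfam", "Pfam", "PF00001", "winged helix domain"),
        DomainScanRow("tf_sf", "SUPERFAMILY", "SSF0001", "lambda repressor-like"),
        DomainScanRow("tf_multi", "Pfam", "PF00002", "homeobox transcription factor"),
        DomainScanRow("not_tf", "Pfam", "PF09999", "kinase domain"),
    ]
    truth.tf_criteria = {
        "tf_desc": {"DESCRIPTION"},
        "tf_pfam": {"DBD_PFAM"},
        "tf_sf": {"DBD_SUPERFAMILY"},
        "tf_multi": {"DESCRIPTION", "DBD_PFAM"},
    }

    # GO transfer: non-IEA annotations transfer, IEA never does
    gaf = [
        GafRecord("UniProtKB", "H1", "h1", "", "GO:0008150", "EXP", "P"),
        GafRecord("UniProtKB", "H1", "h1", "", "GO:0003674", "IEA", "F"),
        GafRecord("UniProtKB", "H2", "h2", "", "GO:0005575", "IDA", "C"),
        GafRecord("UniProtKB", "H3", "h3", "", "GO:0008152", "ISS", "P"),
    ]
    pairs = [("tr00000", "H1"), ("tr00001", "H2")]
    truth.go_transfers = {("tr00000", "GO:0008150"), ("tr00001", "GO:0005575")}

    return (
        AnnotationFixtures(
            pathways=pathways,
            detect_calls=detect,
            blastp_calls=blastp,
            priam_calls=priam,
            domain_rows=rows,
            dbd_pfam=dbd_pfam,
            dbd_superfamily=dbd_superfamily,
            gaf_records=gaf,
            ortholog_pairs=pairs,
        ),
        truth,
    )
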