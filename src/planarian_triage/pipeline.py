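"""Pipeline orchestration: strict config, staged execution, run manifest.

Stages run in dependency order (simulate -> triage -> expression -> enzymes
-> tf -> go-transfer -> repeats -> markers -> enrich); every stage is a pure
function of its input files plus the config, so re-running with an unchanged
config and seed reproduces outputs byte for byte.  The manifest records the
config snapshot, the SHA-256 digest of every stage output, and wall-clock
times (the only non-deterministic field).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cell_markers as cm
from . import coding_triage as ct
from . import expression_profiles as ep
from . import function_consensus as fc
from . import io_formats as io
from . import repeat_activity as ra
from . import synthetic_data as sd

STAGES = ("simulate", "triage", "expression", "enzymes", "tf", "go-transfer",
          "repeats", "markers", "enrich")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    sim: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    markers: dict = field(default_factory=lambda: {"n_perm": 1000, "q_max": 0.05,
                                                   "k_required": None})
    repeats: dict = field(default_factory=lambda: {"flank": 1000, "region": "core"})
    enrich: dict = field(default_factory=lambda: {"mode": "go", "alpha": 0.05})

    def sim_config(self) -> sd.SimConfig:
        return sd.SimConfig(seed=self.seed, **self.sim)

    def triage_thresholds(self) -> ct.TriageThresholds:
        return ct.TriageThresholds(**self.thresholds)


_ALLOWED_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and strictly validate a YAML config (unknown keys are errors)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    # surface invalid nested parameters early
    cfg.sim_config()
    th = cfg.triage_thresholds()
    for name in ("genome_f2_identity", "genome_f2_cov", "contam_nt_ident",
                 "contam_nt_cov", "contam_nonmetazoan_ident"):
        v = getattr(th, name)
        if not 0 < v <= 100:
            raise ValueError(f"threshold {name}={v} out of range (0, 100]")
    if cfg.repeats.get("region", "core") not in {"core", "extended"}:
        raise ValueError("repeats.region must be 'core' or 'extended'")
    return cfg


@dataclass
class RunManifest:
    config: dict
    seed: int
    tool_version: str
    stage_outputs: dict[str, dict[str, str]]   # stage -> {path: sha256}
    stage_seconds: dict[str, float]

    def write(self, path: str | Path) -> None:
        tmp = Path(str(path) + ".partial")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        tmp.replace(path)  # atomic at run end


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Fixture serialization for the simulate stage


def write_simulation(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sim = cfg.sim_config()
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    transcripts, truth = sd.gen_transcripts(sim)
    evidence = sd.gen_evidence(sim, truth)
    coverage = sd.gen_coverage(sim, truth, transcripts)
    bulk = sd.gen_bulk_counts(sim, truth)
    sc_counts, labels, sc_truth = sd.gen_single_cell(sim)
    consensus, _copies, genome, rm_hits, rep_truth = sd.gen_repeat_family(sim)
    fixtures, ann_truth = sd.gen_annotation_fixtures(sim)

    def w(path: Path) -> Path:
        written.append(path)
        return path

    io.write_fasta(transcripts, w(outdir / "transcripts.fasta"))
    by_tag: dict[str, list[io.TabularHit]] = {}
    for h in evidence:
        by_tag.setdefault(h.db_tag, []).append(h)
    for tag, hits in sorted(by_tag.items()):
        io.write_blast_tab(hits, w(outdir / f"evidence_{tag}.tsv"))
    pd.DataFrame(
        sorted((tid, int((np.asarray(v) == 0).sum())) for tid, v in coverage.items()),
        columns=["transcript_id", "n_zero"],
    ).to_csv(w(outdir / "coverage_zero_counts.tsv"), sep="\t", index=False)
    io.write_counts(bulk, w(outdir / "bulk_counts.tsv"))
    pd.DataFrame(
        [(t.id, len(t.sequence)) for t in transcripts], columns=["transcript_id", "length"]
    ).to_csv(w(outdir / "lengths.tsv"), sep="\t", index=False)
    io.write_counts(sc_counts, w(outdir / "sc_counts.tsv"))
    pd.DataFrame(sorted(labels.items()), columns=["cell", "cluster"]).to_csv(
        w(outdir / "sc_labels.tsv"), sep="\t", index=False
    )
    io.write_fasta([genome], w(outdir / "genome.fasta"))
    io.write_fasta([consensus], w(outdir / "repeat_consensus.fasta"))
    io.write_repeatmasker_out(rm_hits, w(outdir / "repeats.out"))
    pd.DataFrame(
        [(p.pathway_id, p.name, ec) for p in fixtures.pathways for ec in sorted(p.ec_set)],
        columns=["pathway_id", "name", "ec"],
    ).to_csv(w(outdir / "pathways.tsv"), sep="\t", index=False)
    for name, calls in (("detect", fixtures.detect_calls),
                        ("blastp", fixtures.blastp_calls),
                        ("priam", fixtures.priam_calls)):
        pd.DataFrame(
            [dataclasses.asdict(c) for c in calls]
        ).to_csv(w(outdir / f"ec_{name}.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(r) for r in fixtures.domain_rows]
    ).to_csv(w(outdir / "domain_scan.tsv"), sep="\t", index=False)
    (w(outdir / "dbd_pfam.txt")).write_text("\n".join(sorted(fixtures.dbd_pfam)) + "\n")
    (w(outdir / "dbd_superfamily.txt")).write_text(
        "\n".join(sorted(fixtures.dbd_superfamily)) + "\n"
    )
    io.write_gaf(fixtures.gaf_records, w(outdir / "annotations.gaf"))
    pd.DataFrame(fixtures.ortholog_pairs, columns=["transcript_id", "object_id"]).to_csv(
        w(outdir / "orthologs.tsv"), sep="\t", index=False
    )
    # sidecar evidence labels (the caller-supplied taxonomy convention)
    meta = {
        "estscan_ids": sorted(truth.estscan_ids),
        "genome_overlap_ids": sorted(truth.genome_overlap_ids),
        "nt_labels": dict(sorted(truth.nt_labels.items())),
        "metazoan_labels": dict(sorted(truth.metazoan_labels.items())),
        "interpro_min_evalue": dict(sorted(truth.interpro_min_evalue.items())),
    }
    (w(outdir / "evidence_meta.json")).write_text(json.dumps(meta, indent=2, sort_keys=True))
    # planted truth for recovery checks
    gt = {
        "tier_of": truth.tier_of,
        "retained_of": truth.retained_of,
        "contaminant_ids": sorted(truth.contaminant_ids),
        "contaminant_rule_of": truth.contaminant_rule_of,
        "misassembled_ids": sorted(truth.misassembled_ids),
        "planted_orf": {k: list(v) for k, v in truth.planted_orf.items()},
        "marker_of": sc_truth.marker_of,
        "true_divergence": rep_truth.true_divergence,
        "conserved_ecs": {k: sorted(v) for k, v in ann_truth.conserved_ecs.items()},
    }
    (w(outdir / "ground_truth.json")).write_text(json.dumps(gt, indent=2, sort_keys=True))
    # enrichment term sets: random gene sets plus one set per planted cluster
    rng = sim.stream("terms")
    genes = sc_counts.row_ids
    rows = []
    for t in range(10):
        for g in rng.choice(len(genes), size=20, replace=False):
            rows.append((f"TERM:{t:04d}", genes[g]))
    by_cluster: dict[str, list[str]] = {}
    for g, c in sc_truth.marker_of.items():
        by_cluster.setdefault(c, []).append(g)
    for c, gs in sorted(by_cluster.items()):
        for g in sorted(gs):
            rows.append((f"TERM:{c}", g))
    pd.DataFrame(rows, columns=["term_id", "gene"]).to_csv(
        w(outdir / "terms.tsv"), sep="\t", index=False
    )
    return written


# ---------------------------------------------------------------------------
# Stage implementations (file-level)


def _load_sim_inputs(simdir: Path):
    transcripts = io.read_fasta(simdir / "transcripts.fasta")
    evidence: list[io.TabularHit] = []
    for f in sorted(simdir.glob("evidence_*.tsv")):
        if f.name == "evidence_meta.json":
            continue
        tag = f.stem.replace("evidence_", "")
        evidence.extend(io.read_blast_tab(f, tag))
    meta = json.loads((simdir / "evidence_meta.json").read_text())
    return transcripts, evidence, meta


def stage_triage(cfg: PipelineConfig, simdir: Path, outdir: Path) -> list[Path]:
    transcripts, evidence, meta = _load_sim_inputs(simdir)
    zeros = pd.read_csv(simdir / "coverage_zero_counts.tsv", sep="\t")
    th = cfg.triage_thresholds()
    # zero-count TSV: expand to a coverage vector with that many unmapped bases
    lengths = {t.id: len(t.sequence) for t in transcripts}
    coverage = {}
    for r in zeros.itertuples():
        tid = str(r.transcript_id)
        v = np.ones(lengths[tid], dtype=int)
        v[: int(r.n_zero)] = 0
        coverage[tid] = v
    decisions = ct.triage(
        transcripts, evidence,
        coverage=coverage,
        th=dataclasses.replace(th),
        estscan_ids=meta["estscan_ids"],
        genome_overlap_ids=meta["genome_overlap_ids"],
        nt_labels=meta["nt_labels"],
        metazoan_labels=meta["metazoan_labels"],
        interpro_min_evalue=meta["interpro_min_evalue"],
    )
    out = outdir / "triage_decisions.tsv"
    pd.DataFrame(
        [
            (d.transcript_id, d.tier, d.retained, d.contaminant,
             d.contaminant_rule, d.misassembled, ";".join(d.reasons))
            for d in decisions
        ],
        columns=["transcript_id", "tier", "retained", "contaminant",
                 "contaminant_rule", "misassembled", "reasons"],
    ).to_csv(out, sep="\t", index=False)
    summary = outdir / "triage_summary.json"
    summary.write_text(json.dumps(ct.triage_summary(decisions), indent=2, sort_keys=True))
    return [out, summary]


def stage_expression(cfg: PipelineConfig, simdir: Path, outdir: Path) -> list[Path]:
    counts = io.read_counts(simdir / "bulk_counts.tsv")
    lengths = pd.read_csv(simdir / "lengths.tsv", sep="\t")
    lengths_map = dict(zip(lengths.transcript_id.astype(str), lengths.length))
    mat, summaries = ep.expression_profile(counts, lengths_map)
    rpkm_out = outdir / "rpkm.tsv"
    pd.DataFrame(mat.rpkm, index=mat.row_ids, columns=mat.col_ids).to_csv(
        rpkm_out, sep="\t", index_label="id", float_format="%.6g"
    )
    summ_out = outdir / "expression_summary.tsv"
    pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries]
    ).to_csv(summ_out, sep="\t", index=False, float_format="%.6g")
    return [rpkm_out, summ_out]


def _read_ec_calls(path: Path, source: str) -> list[fc.ECCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for r in df.itertuples():
        kwargs = {}
        for opt in ("ils", "positive_hits", "evalue", "probability", "profile_cov"):
            v = getattr(r, opt, None)
            if v is not None and not pd.isna(v):
                kwargs[opt] = int(v) if opt == "positive_hits" else float(v)
        if hasattr(r, "is_top_hit") and not pd.isna(r.is_top_hit):
            kwargs["is_top_hit"] = bool(r.is_top_hit)
        calls.append(fc.ECCall(str(r.transcript_id), str(r.ec), source, **kwargs))
    return calls


def stage_enzymes(cfg: PipelineConfig, simdir: Path, outdir: Path) -> list[Path]:
    calls: list[fc.ECCall] = []
    for source in ("DETECT", "BLASTP", "PRIAM"):
        calls.extend(_read_ec_calls(simdir / f"ec_{source.lower()}.tsv", source))
    cons = fc.consensus(fc.filter_source(calls))
    pw = pd.read_csv(simdir / "pathways.tsv", sep="\t")
    pathways = [
        fc.PathwayMap(pid, grp.name.iloc[0], frozenset(grp.ec))
        for pid, grp in pw.groupby("pathway_id")
    ]
    conservation = fc.pathway_conservation(cons, pathways)
    cons_out = outdir / "ec_consensus.tsv"
    pd.DataFrame(
        [(t, e, ",".join(sorted(s))) for t, e, s in cons],
        columns=["transcript_id", "ec", "sources"],
    ).to_csv(cons_out, sep="\t", index=False)
    pc_out = outdir / "pathway_conservation.tsv"
    pd.DataFrame(
        [dataclasses.asdict(c) for c in conservation]
    ).to_csv(pc_out, sep="\t", index=False, float_format="%.6g")
    return [cons_out, pc_out]


def stage_tf(cfg: PipelineConfig, simdir: Path, outdir: Path) -> list[Path]:
    df = pd.read_csv(simdir / "domain_scan.tsv", sep="\t")
    rows = [
        fc.DomainScanRow(str(r.transcript_id), str(r.analysis), str(r.family_id),
                         str(r.description))
        for r in df.itertuples()
    ]
    dbd_pfam = (simdir / "dbd_pfam.txt").read_text().split()
    dbd_sf = (simdir / "dbd_superfamily.txt").read_text().split()
    calls = fc.tf_consolidate(rows, dbd_pfam, dbd_sf)
    out = outdir / "tf_calls.tsv"
    pd.DataFrame(
        [(c.transcript_id, ",".join(sorted(c.criteria)), ",".join(c.families))
         for c in calls],
        columns=["transcript_id", "criteria", "families"],
    ).to_csv(out, sep="\t", index=False)
    return [out]


def stage_go_transfer(cfg: PipelineConfig, simdir: Path, outdir: Path) -> list[Path]:
    gaf = io.read_gaf(simdir / "annotations.gaf")
    pairs_df = pd.read_csv(simdir / "orthologs.tsv", sep="\t")
    pairs = [(str(r.transcript_id), str(r.object_id)) for r in pairs_df.itertuples()]
    transfers = fc.go_transfer(pairs, gaf)
    out = outdir / "go_transfers.tsv"
    pd.DataFrame(
        [dataclasses.asdict(t) for t in transfers]
    ).to_csv(out, sep="\t", index=False)
    return [out]


def stage_repeats(cfg: PipelineConfig, simdir: Path, outdir: Path) -> list[Path]:
    genome = io.read_fasta(simdir / "genome.fasta")
    consensus = {r.id: r.sequence for r in io.read_fasta(simdir / "repeat_consensus.fasta")}
    hits = io.read_repeatmasker_out(simdir / "repeats.out")
    elements = ra.extract_elements(genome, hits, flank=int(cfg.repeats.get("flank", 1000)))
    records = ra.divergence_profile(
        elements, consensus, region=cfg.repeats.get("region", "core")
    )
    rec_out = outdir / "repeat_divergence.tsv"
    pd.DataFrame(
        [dataclasses.asdict(r) for r in records]
    ).to_csv(rec_out, sep="\t", index=False, float_format="%.6g")
    hist_out = outdir / "repeat_histogram.json"
    hist_out.write_text(json.dumps(ra.divergence_histogram(records), indent=2, sort_keys=True))
    return [rec_out, hist_out]


def stage_markers(cfg: PipelineConfig, simdir: Path, outdir: Path) -> list[Path]:
    counts = io.read_counts(simdir / "sc_counts.tsv")
    labels_df = pd.read_csv(simdir / "sc_labels.tsv", sep="\t")
    labels = dict(zip(labels_df.cell.astype(str), labels_df.cluster.astype(str)))
    filtered, labels = cm.qc_filter(counts, labels)
    de = cm.pairwise_de(
        filtered, labels,
        n_perm=int(cfg.markers.get("n_perm", 1000)),
        seed=cfg.seed,
    )
    de_out = outdir / "pairwise_de.tsv"
    cm.write_pairwise_de(de, de_out)
    calls = cm.consensus_markers(
        de, q_max=float(cfg.markers.get("q_max", 0.05)),
        k_required=cfg.markers.get("k_required"),
    )
    mk_out = outdir / "marker_calls.tsv"
    pd.DataFrame(
        [dataclasses.asdict(c) for c in calls if c.is_marker]
    ).to_csv(mk_out, sep="\t", index=False)
    return [de_out, mk_out]


def stage_enrich(cfg: PipelineConfig, simdir: Path, outdir: Path) -> list[Path]:
    de = cm.read_pairwise_de(outdir / "pairwise_de.tsv")
    terms_df = pd.read_csv(simdir / "terms.tsv", sep="\t")
    term_sets: dict[str, set[str]] = {}
    for r in terms_df.itertuples():
        term_sets.setdefault(str(r.term_id), set()).add(str(r.gene))
    pairs = sorted({(d.cluster_a, d.cluster_b) for d in de if d.cluster_a < d.cluster_b})
    rows = []
    for a, b in pairs:
        sub = [d for d in de if d.cluster_a == a and d.cluster_b == b]
        for res in cm.enrich(term_sets, sub, mode=cfg.enrich.get("mode", "go"),
                             alpha=float(cfg.enrich.get("alpha", 0.05))):
            rows.append((a, b) + tuple(dataclasses.asdict(res).values()))
    out = outdir / "enrichment.tsv"
    pd.DataFrame(
        rows,
        columns=["cluster_a", "cluster_b", "term_id", "N", "K", "n", "k", "p",
                 "enriched", "k_up", "k_down"],
    ).to_csv(out, sep="\t", index=False, float_format="%.6g")
    return [out]


# ---------------------------------------------------------------------------
# Runner


def run(cfg: PipelineConfig, stages: Sequence[str] | None = None) -> RunManifest:
    chosen = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    bad = set(stages or []) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}")
    out = Path(cfg.out_dir)
    simdir = out / "sim"
    out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, dict[str, str]] = {}
    seconds: dict[str, float] = {}
    table: dict[str, Callable[[], list[Path]]] = {
        "simulate": lambda: write_simulation(cfg, simdir),
        "triage": lambda: stage_triage(cfg, simdir, out),
        "expression": lambda: stage_expression(cfg, simdir, out),
        "enzymes": lambda: stage_enzymes(cfg, simdir, out),
        "tf": lambda: stage_tf(cfg, simdir, out),
        "go-transfer": lambda: stage_go_transfer(cfg, simdir, out),
        "repeats": lambda: stage_repeats(cfg, simdir, out),
        "markers": lambda: stage_markers(cfg, simdir, out),
        "enrich": lambda: stage_enrich(cfg, simdir, out),
    }
    for name in chosen:
        t0 = time.perf_counter()
        try:
            produced = table[name]()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        seconds[name] = time.perf_counter() - t0
        digests[name] = {str(p.relative_to(out)): _sha256(p) for p in produced}
    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        seed=cfg.seed,
        tool_version=_version(),
        stage_outputs=digests,
        stage_seconds=seconds,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("planarian-triage")
    except Exception:  # pragma: no cover
        return "unknown"
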