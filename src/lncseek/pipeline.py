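"""End-to-end pipeline driver: identify -> context -> scan -> DE -> enrich -> summarize.

The pipeline is configured by a strict key-checked mapping (usually a YAML
file): unknown keys abort before any stage runs, as do missing input files.
Every run logs its parameters and input checksums; reruns on identical
inputs are byte-identical (no timestamps enter the outputs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .context import (
    AMBIGUOUS,
    CodingAnnotation,
    LncRNARecord,
    assign_cis_targets,
    extract_promoter,
    gene_spans,
)
from .errors import ConfigurationError
from .formats_io import (
    SequenceStore,
    read_expression_table,
    read_gtf,
    spliced_sequence,
    write_fasta,
    write_gtf,
)
from .identify import FilterParams, find_longest_orf, run_filter_cascade
from .motifs import pwm_scan, read_mirnas, read_pwm, seed_scan
from .report import summarize
from .stats import de_test, enrich_targets

_INPUT_KEYS = {
    "genome", "annotation", "candidates", "expression", "smallrna",
    "pwm", "mirnas", "pathways", "qpcr",
}
_REQUIRED_INPUTS = {
    "genome", "annotation", "candidates", "expression", "smallrna", "pwm", "mirnas",
}
_PARAM_KEYS = {
    "min_experiments", "min_length_nt", "require_multi_exon", "min_coverage",
    "coding_orf_threshold_nt", "windows", "promoter_length", "pwm_threshold",
    "fpkm_threshold", "pseudocount", "lfc_threshold", "q_threshold",
    "case_samples", "control_samples",
}
_TOP_KEYS = {"inputs", "params", "outdir"}

_DEFAULT_PARAMS = {
    "min_experiments": 2,
    "min_length_nt": 200,
    "require_multi_exon": True,
    "min_coverage": 3.0,
    "coding_orf_threshold_nt": 300,
    "windows": [10_000, 100_000],
    "promoter_length": 2_000,
    "pwm_threshold": 0.85,
    "fpkm_threshold": 15.0,
    "pseudocount": 1.0,
    "lfc_threshold": 1.0,
    "q_threshold": 0.05,
}

__all__ = ["PipelineResult", "load_config", "validate_config", "run_pipeline"]


@dataclass
class PipelineResult:
    outdir: Path
    summary: dict
    records: List[LncRNARecord]
    report: "object"
    de_table: pd.DataFrame
    paths: Dict[str, Path]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: Mapping) -> dict:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    inputs = dict(cfg.get("inputs") or {})
    unknown = set(inputs) - _INPUT_KEYS
    if unknown:
        raise ConfigurationError(f"unknown input keys: {sorted(unknown)}")
    missing = _REQUIRED_INPUTS - set(inputs)
    if missing:
        raise ConfigurationError(f"missing required inputs: {sorted(missing)}")
    params = dict(_DEFAULT_PARAMS)
    user_params = dict(cfg.get("params") or {})
    unknown = set(user_params) - _PARAM_KEYS
    if unknown:
        raise ConfigurationError(f"unknown param keys: {sorted(unknown)}")
    params.update(user_params)
    if "outdir" not in cfg:
        raise ConfigurationError("config must name an outdir")
    for name, p in inputs.items():
        if not Path(p).is_file():
            raise ConfigurationError(f"input {name!r}: no such file {p}")
    return {"inputs": inputs, "params": params, "outdir": Path(cfg["outdir"])}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: Mapping) -> PipelineResult:
    """Run all stages in fixed order; write tables, summary and a run log."""
    resolved = validate_config(cfg)
    inputs, params = resolved["inputs"], resolved["params"]
    outdir = resolved["outdir"]
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def out(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    log_lines = ["lncseek pipeline run"]
    for name in sorted(inputs):
        log_lines.append(f"input {name} {inputs[name]} sha256={_sha256(inputs[name])}")
    for name in sorted(params):
        log_lines.append(f"param {name} = {params[name]!r}")

    genome = SequenceStore.from_fasta(inputs["genome"])
    coding = read_gtf(inputs["annotation"])
    candidates = read_gtf(inputs["candidates"])
    expr = read_expression_table(inputs["expression"])
    from .formats_io import read_bed

    smallrna = [iv for iv, _name, _score in read_bed(inputs["smallrna"])]

    # expression joins candidates; TSV wins over any GTF-borne FPKM
    candidates = [
        t.with_expression(expr.loc[t.transcript_id].to_dict())
        if t.transcript_id in expr.index
        else t
        for t in candidates
    ]

    # ---- stage 1: identify ------------------------------------------------
    fparams = FilterParams(
        min_experiments=int(params["min_experiments"]),
        min_length_nt=int(params["min_length_nt"]),
        require_multi_exon=bool(params["require_multi_exon"]),
        min_coverage=float(params["min_coverage"]),
        coding_orf_threshold_nt=int(params["coding_orf_threshold_nt"]),
    )
    survivors, report = run_filter_cascade(candidates, smallrna, fparams, genome=genome)
    write_gtf(survivors, out("survivors.gtf"))
    seqs = {t.transcript_id: spliced_sequence(t, genome) for t in survivors}
    write_fasta(seqs, out("survivors.fa"))
    report.write_tsv(out("filter_report.tsv"))
    log_lines.append(f"stage identify survivors={len(survivors)}")

    # ---- stage 2: genomic context ------------------------------------------
    annotation = CodingAnnotation(coding)
    spans = gene_spans(coding)
    windows = [int(w) for w in params["windows"]]
    records: List[LncRNARecord] = []
    n_ambiguous = 0
    for t in survivors:
        cls = annotation.classify(t)
        rec = LncRNARecord(transcript=t, positional_class=cls)
        if cls == AMBIGUOUS:
            n_ambiguous += 1
            records.append(rec)
            continue
        rec.longest_orf = find_longest_orf(seqs[t.transcript_id])
        rec.cis_targets = assign_cis_targets(t, spans, windows)
        rec.promoter, rec.promoter_seq = extract_promoter(
            t, genome, int(params["promoter_length"])
        )
        records.append(rec)
    classified = [r for r in records if r.positional_class != AMBIGUOUS]
    with open(out("classes.tsv"), "w") as fh:
        fh.write("transcript_id\tgene_id\tclass\n")
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.gene_id}\t{r.positional_class}\n")
    with open(out("targets.tsv"), "w") as fh:
        fh.write("lncrna_id\tgene_id\twindow\tdistance\n")
        for r in classified:
            for w in windows:
                for gid, dist in r.cis_targets.get(w, []):
                    fh.write(f"{r.transcript_id}\t{gid}\t{w}\t{dist}\n")
    write_fasta(
        {r.transcript_id: r.promoter_seq for r in classified}, out("promoters.fa")
    )
    log_lines.append(
        f"stage context classified={len(classified)} ambiguous={n_ambiguous}"
    )

    # ---- stage 3: regulatory scan ------------------------------------------
    pwm = read_pwm(inputs["pwm"])
    mirnas = read_mirnas(inputs["mirnas"])
    threshold = float(params["pwm_threshold"])
    with open(out("motif_hits.tsv"), "w") as fh:
        fh.write("promoter_id\toffset\tstrand\tscore\n")
        for r in classified:
            r.motif_hits = pwm_scan(
                r.promoter_seq, pwm, threshold, promoter_id=r.transcript_id
            )
            for h in r.motif_hits:
                fh.write(f"{h.promoter_id}\t{h.offset}\t{h.strand}\t{h.score:.6f}\n")
    with open(out("seed_hits.tsv"), "w") as fh:
        fh.write("transcript_id\tmirna\toffset\tsite_type\n")
        for r in classified:
            r.seed_hits = seed_scan(
                seqs[r.transcript_id], mirnas, transcript_id=r.transcript_id
            )
            for s in r.seed_hits:
                fh.write(f"{s.transcript_id}\t{s.mirna}\t{s.offset}\t{s.site_type}\n")
    log_lines.append(
        "stage scan motif_hits=%d seed_hits=%d"
        % (sum(len(r.motif_hits) for r in classified),
           sum(len(r.seed_hits) for r in classified))
    )

    # ---- stage 4: differential expression ----------------------------------
    case = params.get("case_samples") or [
        c for c in expr.columns if c.startswith("cas")
    ]
    ctrl = params.get("control_samples") or [
        c for c in expr.columns if c.startswith("int")
    ]
    de = de_test(
        expr,
        case,
        ctrl,
        pseudocount=float(params["pseudocount"]),
        lfc_threshold=float(params["lfc_threshold"]),
        q_threshold=float(params["q_threshold"]),
    )
    de.to_csv(out("de_table.tsv"), sep="\t", float_format="%.6g",
              index_label="transcript_id")
    survivor_ids = {t.transcript_id for t in survivors}
    de_lnc = de[(de.index.isin(survivor_ids)) & (de["call"] != "ns")]
    log_lines.append(
        f"stage de tested={len(de)} de_lncrna={len(de_lnc)}"
    )

    # ---- stage 5: enrichment ------------------------------------------------
    enrichment = None
    if "pathways" in inputs:
        pathway_sets: Dict[str, set] = {}
        with open(inputs["pathways"]) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    pathway_sets[parts[0]] = set(parts[2:])
        tx_gene = {t.transcript_id: t.gene_id for t in coding}
        universe = {tx_gene[tid] for tid in expr.index if tid in tx_gene}
        target_ids = set()
        for r in classified:
            if r.transcript_id in set(de_lnc.index):
                for w in windows:
                    target_ids.update(g for g, _d in r.cis_targets.get(w, []))
        target_ids &= universe
        enrichment = enrich_targets(target_ids, pathway_sets, universe)
        enrichment.to_csv(out("enrichment.tsv"), sep="\t", float_format="%.6g")
        log_lines.append(
            f"stage enrich targets={len(target_ids)} pathways={len(pathway_sets)}"
        )

    # ---- stage 6: summary ----------------------------------------------------
    stats = summarize(classified, fpkm_threshold=float(params["fpkm_threshold"]))
    summary = {
        "stats": stats.to_dict(),
        "display": stats.display(),
        "filter": {
            "input": report.n_input,
            "steps": report.steps,
            "survivors": report.n_survivors,
        },
        "ambiguous": n_ambiguous,
        "de_lncrna": {
            "up": int((de_lnc["call"] == "up").sum()),
            "down": int((de_lnc["call"] == "down").sum()),
        },
    }
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log_lines.append("stage summarize done")
    with open(out("run_log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return PipelineResult(
        outdir=outdir,
        summary=summary,
        records=records,
        report=report,
        de_table=de,
        paths=paths,
    )
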