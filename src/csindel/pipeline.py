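"""End-to-end orchestration: scan -> tree -> classify -> report.

Artifacts (calls.tsv, signatures/, tree.nwk, monophyly.tsv, table1.tsv,
summary.md) are deterministic for a fixed config and seed; timestamps
are confined to run.log so output directories diff cleanly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment import map_reference, strip_gap_columns
from .classifier import assign_isozyme, assignments_to_tsv, build_matrix
from .phylogeny import bootstrap_supports, monophyly
from .scanner import CsiCall, calls_to_tsv, check_atp_motif, render_signature, scan
from .seqio import parse_group_table, read_alignment, read_fasta
from .tree import midpoint_root

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pipeline inputs and parameters, serialisable to/from YAML."""

    alignment: str = ""
    groups: str = ""
    queries: str = ""                 # optional FASTA of classifier queries
    panel: str = ""                   # optional classifier panel FASTA
    reference: str = ""               # reference row id for coordinates
    outdir: str = "csindel_out"
    grouping: str = "by_class"
    flank_window: int = 30
    min_flank_conserved: int = 5
    consensus_threshold: float = 0.8
    exceptions: int = 0
    keep_unclassified: bool = False
    bootstrap: int = 100
    seed: int = 42
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name, log, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        log.error("stage %s failed: %s", name, exc)
        raise PipelineError(name, str(exc)) from exc
    log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns {artifact name: path}."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log = logging.getLogger("csindel.run")
    log.setLevel(cfg.log_level)
    log.addHandler(handler)
    artifacts: dict[str, Path] = {}
    try:
        aln = _stage("load", log, read_alignment, cfg.alignment)
        scheme = _stage("load", log, parse_group_table, cfg.groups)
        refmap = None
        if cfg.reference:
            refmap = map_reference(aln, cfg.reference)

        calls = _stage("scan", log, scan, aln, scheme, cfg.grouping,
                       cfg.flank_window, cfg.min_flank_conserved,
                       cfg.consensus_threshold, cfg.exceptions,
                       cfg.keep_unclassified, refmap)
        calls_to_tsv(calls, outdir / "calls.tsv")
        artifacts["calls"] = outdir / "calls.tsv"
        sigdir = outdir / "signatures"
        sigdir.mkdir(exist_ok=True)
        refmaps = [refmap] if refmap else []
        for i, call in enumerate(calls, start=1):
            text = render_signature(aln, call, refmaps=refmaps)
            (sigdir / f"signature_{i:02d}.txt").write_text(text, encoding="utf-8")
        motif = _stage("motif", log, check_atp_motif, aln, scheme)

        core, removed = _stage("strip", log, strip_gap_columns, aln)
        tree = _stage("tree", log, bootstrap_supports, core, cfg.bootstrap,
                      cfg.seed)
        rooted = midpoint_root(tree)
        (outdir / "tree.nwk").write_text(rooted.newick() + "\n", encoding="utf-8")
        artifacts["tree"] = outdir / "tree.nwk"
        reports = {}
        for grouping in ("by_class", "by_isozyme"):
            reports[grouping] = _stage("monophyly", log, monophyly, tree,
                                       scheme, grouping)
        reports["by_class"].to_tsv(outdir / "monophyly.tsv")
        artifacts["monophyly"] = outdir / "monophyly.tsv"

        matrix = None
        if cfg.queries:
            panel_path = cfg.panel or cfg.alignment
            panel = _stage("classify", log, _load_panel, panel_path, scheme)
            queries = _stage("classify", log, read_fasta, cfg.queries)
            assignments = [assign_isozyme(q, panel) for q in queries]
            for a, q in zip(assignments, queries):
                if a.taxon_group in ("", "other"):
                    a.taxon_group = scheme.taxon_group_of.get(q.id, a.taxon_group)
            assignments_to_tsv(assignments, outdir / "assignments.tsv")
            artifacts["assignments"] = outdir / "assignments.tsv"
            try:
                matrix = build_matrix(assignments)
                matrix.to_tsv(outdir / "table1.tsv")
                artifacts["table1"] = outdir / "table1.tsv"
            except Exception as exc:
                log.warning("presence/absence matrix skipped: %s", exc)

        summary = _render_summary(aln, removed, calls, motif, reports, matrix,
                                  refmap)
        (outdir / "summary.md").write_text(summary, encoding="utf-8")
        artifacts["summary"] = outdir / "summary.md"
        return artifacts
    finally:
        log.removeHandler(handler)
        handler.close()


def _load_panel(path, scheme):
    records = read_fasta(path)
    for rec in records:
        if rec.isozyme == "unknown":
            rec.isozyme = scheme.isozyme_of.get(rec.id, "unknown")
    return records


def _render_summary(aln, removed, calls, motif, reports, matrix, refmap) -> str:
    lines = [
        "# CSI pipeline summary",
        "",
        f"csindel {__version__}",
        "",
        f"Alignment: {aln.nrows} sequences x {aln.ncols} columns; "
        f"{aln.ncols - len(removed)} gap-free columns used for the tree.",
        "",
        f"## Conserved signature indels ({len(calls)})",
        "",
        f"Note: {CsiCall.POLARITY_CAVEAT}.",
        "",
        "| locus | reference | verdict | state | groups (length) | flanks L/R |",
        "|---|---|---|---|---|---|",
    ]
    for c in calls:
        groups = ", ".join(f"{g}:{a}" if a == b else f"{g}:{a}-{b}"
                           for g, (a, b) in sorted(c.groups.items()))
        anchor = c.ref_anchor or "-"
        fl = f"{c.flanks.left_conserved}/{c.flanks.right_conserved}" if c.flanks else "-"
        lines.append(f"| {c.locus.start}-{c.locus.end} | {anchor} | {c.verdict} "
                     f"| {c.state} | {groups} | {fl} |")
    lines += ["", "## Class monophyly", "",
              "| label | monophyletic | support | offending |", "|---|---|---|---|"]
    for grouping, rep in reports.items():
        for lab in sorted(rep.entries):
            e = rep.entries[lab]
            sup = "-" if e["support"] is None else e["support"]
            off = ",".join(sorted(e["offending"])) or "-"
            lines.append(f"| {lab} ({grouping}) | {e['monophyletic']} | {sup} | {off} |")
    lines += ["", "## ATP-binding motif (G-X-G-X-X-G)", ""]
    if motif.window_start is None:
        lines.append("Motif not found.")
    else:
        lines.append(f"Found at columns {motif.window_start}-{motif.window_start + 5} "
                     f"({motif.match_fraction:.0%} of rows).")
        dev = sorted(motif.deviant_isozymes)
        lines.append(f"Isozymes with substitutions at a G position: "
                     f"{', '.join(dev) if dev else 'none'}.")
    if matrix is not None:
        lines += ["", "## Isozyme presence/absence", ""]
        tab = matrix.table
        lines.append("| group | " + " | ".join(tab.columns) + " |")
        lines.append("|" + "---|" * (len(tab.columns) + 1))
        for grp, row in tab.iterrows():
            lines.append(f"| {grp} | " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"
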