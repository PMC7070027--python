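"""Stage orchestration: classify -> annotate -> polya -> concord.

Every stage recomputes from the primary inputs named in the configuration,
so running subcommands separately or via ``all`` yields byte-identical
artifacts.  Output tables carry a provenance header (tool version, config
hash, input checksums) and the log records read counts entering and
leaving each filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

from . import __version__
from .read_model import (AlignedRead, attach_polya, load_polya_table,
                         parse_alignments, read_stats, softclip_profile,
                         write_read_table)
from .site_clustering import greedy_cluster, tally_ends, write_site_table
from .grouping import (build_groups, splice_site_table, write_group_table)
from .orf_annotation import (GroupAnnotation, annotate_group,
                             dominant_transcripts, load_feature_table,
                             orf_usage_table, write_gff)
from .polya_stats import class_series, trend_report, write_trend_table
from .splice_concordance import (load_junctions, transcript_concordance,
                                 write_concordance)
from .synthetic_data import GENOME_ID

log = logging.getLogger("orfclass")


@dataclass
class PipelineConfig:
    genome: str = ""
    alignments: dict[str, str] = field(default_factory=dict)  # sample -> SAM/BAM
    features: str = ""
    polya_tables: dict[str, str] = field(default_factory=dict)
    junctions: str = ""
    junctions_format: str = "tsv"
    tss_window: int = 15
    tts_window: int = 15
    extension: int = 10
    min_aa: int = 10
    min_polya: float = 20.0
    min_mapq: int = 0
    require_polya_for_grouping: bool = False
    min_count: int = 1
    seed: int = 0
    outdir: str = "orfclass_out"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    samples: list[str] = field(default_factory=list)
    reads: list[AlignedRead] = field(default_factory=list)
    tss_clusters: dict = field(default_factory=dict)
    tts_clusters: dict = field(default_factory=dict)
    groups: list = field(default_factory=list)
    annotations: list[GroupAnnotation] = field(default_factory=list)
    usage: dict = field(default_factory=dict)
    dominant: dict = field(default_factory=dict)
    series: list = field(default_factory=list)
    trend: dict = field(default_factory=dict)
    concordance: Optional[object] = None
    skipped_groups: int = 0


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str, what: str) -> str:
    if not path:
        raise FileNotFoundError(f"no {what} configured")
    if not os.path.exists(path):
        raise FileNotFoundError(f"{what} not found: {path}")
    return path


def load_genome(path: str) -> str:
    from Bio import SeqIO
    recs = list(SeqIO.parse(path, "fasta"))
    if not recs:
        raise ValueError(f"{path}: no FASTA records")
    if len(recs) > 1:
        log.warning("%s: %d records; using the first (%s)", path, len(recs),
                    recs[0].id)
    return str(recs[0].seq).upper()


def _prepend_provenance(path: str, cfg: PipelineConfig,
                        inputs: dict[str, str]) -> None:
    lines = [f"# orfclass v{__version__} config_hash={cfg.config_hash()}"]
    for name, p in sorted(inputs.items()):
        lines.append(f"# input {name}={p} md5={_md5(p)}")
    with open(path) as fh:
        body = fh.read()
    if body.startswith("##gff-version"):
        first, rest = body.split("\n", 1)
        body = first + "\n" + "\n".join(lines) + "\n" + rest
    else:
        body = "\n".join(lines) + "\n" + body
    with open(path, "w") as fh:
        fh.write(body)


class _StageWriter:
    """Tracks files written by a stage so partial output can be removed on
    failure."""

    def __init__(self, cfg: PipelineConfig, inputs: dict[str, str]):
        self.cfg = cfg
        self.inputs = inputs
        self.written: list[str] = []

    def path(self, name: str) -> str:
        p = os.path.join(self.cfg.outdir, name)
        self.written.append(p)
        return p

    def finalize(self) -> None:
        for p in self.written:
            if os.path.exists(p):
                _prepend_provenance(p, self.cfg, self.inputs)

    def cleanup(self) -> None:
        for p in self.written:
            if os.path.exists(p):
                os.remove(p)


def _load_reads(cfg: PipelineConfig) -> tuple[list[AlignedRead], list[str]]:
    _require(cfg.genome, "genome FASTA")
    if not cfg.alignments:
        raise FileNotFoundError("no alignment files configured")
    samples = sorted(cfg.alignments)
    all_reads: list[AlignedRead] = []
    for sample in samples:
        path = _require(cfg.alignments[sample], f"alignment for {sample}")
        reads, stats = parse_alignments(path, sample,
                                        reference_name=GENOME_ID
                                        if cfg.genome else None,
                                        min_mapq=cfg.min_mapq)
        log.info("%s: %d primary reads kept, %d skipped "
                 "(unmapped=%d secondary=%d supplementary=%d no_ref_op=%d)",
                 sample, stats.primary, stats.skipped, stats.unmapped,
                 stats.secondary, stats.supplementary, stats.no_reference_op)
        if sample in cfg.polya_tables:
            recs = load_polya_table(_require(cfg.polya_tables[sample],
                                             f"polyA table for {sample}"))
            reads, usable = attach_polya(reads, recs, min_len=cfg.min_polya)
            log.info("%s: %d/%d reads polyA-usable (PASS and >= %g nt)",
                     sample, len(usable), len(reads), cfg.min_polya)
        all_reads.extend(reads)
    return all_reads, samples


def classify(cfg: PipelineConfig, result: Optional[PipelineResult] = None
             ) -> PipelineResult:
    """Parse alignments, cluster ends, build transcript groups."""
    res = result or PipelineResult(config=cfg)
    os.makedirs(cfg.outdir, exist_ok=True)
    reads, samples = _load_reads(cfg)
    res.reads, res.samples = reads, samples
    inputs = {f"alignment_{s}": cfg.alignments[s] for s in samples}
    inputs["genome"] = cfg.genome
    sw = _StageWriter(cfg, inputs)
    try:
        tss_tallies = tally_ends(reads, "TSS")
        tts_tallies = tally_ends(reads, "TTS")
        res.tss_clusters = {s: greedy_cluster(t, cfg.tss_window)
                            for s, t in tss_tallies.items()}
        res.tts_clusters = {s: greedy_cluster(t, cfg.tts_window)
                            for s, t in tts_tallies.items()}
        grouped = reads
        if cfg.require_polya_for_grouping:
            grouped = [r for r in reads if r.polya_usable]
            log.info("grouping restricted to %d/%d polyA-usable reads",
                     len(grouped), len(reads))
        res.groups = build_groups(grouped, res.tss_clusters, res.tts_clusters)
        log.info("%d reads -> %d transcript groups", len(grouped),
                 len(res.groups))
        write_read_table(reads, sw.path("reads.tsv"))
        write_site_table([c for v in res.tss_clusters.values() for c in v]
                         + [c for v in res.tts_clusters.values() for c in v],
                         sw.path("sites.tsv"))
        write_group_table(res.groups, samples, sw.path("groups.tsv"))
        genome = load_genome(cfg.genome)
        rows = splice_site_table(reads, genome)
        with open(sw.path("splice_sites.tsv"), "w") as fh:
            fh.write("site\tposition\tstrand\tcount\tdinucleotide\n")
            for r in rows:
                fh.write(f"{r['site']}\t{r['position']}\t{r['strand']}\t"
                         f"{r['count']}\t{r['dinucleotide']}\n")
        stats = read_stats(reads)
        clip5 = softclip_profile(reads, "5prime")
        clip3 = softclip_profile(reads, "3prime")
        with open(sw.path("read_stats.tsv"), "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in stats.items():
                fh.write(f"{k}\t{v}\n")
            fh.write(f"clip5_mean\t{clip5.mean:.3f}\nclip5_mode\t{clip5.mode}\n")
            fh.write(f"clip3_mean\t{clip3.mean:.3f}\nclip3_mode\t{clip3.mode}\n")
        sw.finalize()
    except Exception:
        sw.cleanup()
        raise
    return res


def annotate(cfg: PipelineConfig, result: Optional[PipelineResult] = None
             ) -> PipelineResult:
    """ORF-annotate every transcript group against the feature table."""
    res = result if result is not None and result.groups else classify(cfg, result)
    _require(cfg.features, "feature table")
    features = load_feature_table(cfg.features)
    genome = load_genome(cfg.genome)
    sw = _StageWriter(cfg, {"features": cfg.features, "genome": cfg.genome})
    try:
        anns: list[GroupAnnotation] = []
        skipped = 0
        for g in res.groups:
            try:
                anns.append(annotate_group(g, genome, features,
                                           extension=cfg.extension,
                                           min_aa=cfg.min_aa))
            except ValueError as exc:
                skipped += 1
                log.warning("group skipped during annotation: %s", exc)
        res.annotations = anns
        res.skipped_groups = skipped
        res.usage = orf_usage_table(anns, res.samples)
        res.dominant = dominant_transcripts(anns)
        with open(sw.path("annotations.tsv"), "w") as fh:
            fh.write("strand\ttss\tjunctions\ttts\ttotal\tmatched_feature\t"
                     "match_rank\tflags\n")
            for a in anns:
                k = a.group.key
                jtxt = ";".join(f"{j.donor}-{j.acceptor}"
                                for j in k.junctions) or "."
                fh.write(f"{k.strand}\t{k.tss_cluster}\t{jtxt}\t"
                         f"{k.tts_cluster}\t{a.group.total}\t"
                         f"{a.matched_feature or 'NA'}\t"
                         f"{a.match_rank or 'NA'}\t"
                         f"{','.join(sorted(a.flags)) or '.'}\n")
        with open(sw.path("orf_usage.tsv"), "w") as fh:
            fh.write("feature\t" + "\t".join(res.samples) + "\n")
            for feat, row in res.usage.items():
                fh.write(feat + "\t" +
                         "\t".join(f"{row[s]:.3f}" for s in res.samples) + "\n")
        write_gff(anns, sw.path("transcripts.gff3"), mode="all")
        write_gff(anns, sw.path("dominant.gff3"), mode="dominant")
        sw.finalize()
    except Exception:
        sw.cleanup()
        raise
    return res


def polya(cfg: PipelineConfig, result: Optional[PipelineResult] = None
          ) -> PipelineResult:
    """PolyA summaries per class and shift tests across the time course."""
    res = result if result is not None and result.annotations else annotate(cfg, result)
    sw = _StageWriter(cfg, {})
    try:
        res.series = class_series(res.annotations, class_by="group")
        res.trend = trend_report(res.series, res.samples)
        write_trend_table(res.trend, res.series, res.samples,
                          sw.path("polya_trend.tsv"))
        feat_series = class_series(res.annotations, class_by="feature")
        feat_trend = trend_report(feat_series, res.samples)
        write_trend_table(feat_trend, feat_series, res.samples,
                          sw.path("polya_trend_by_feature.tsv"))
        sw.finalize()
    except Exception:
        sw.cleanup()
        raise
    return res


def concord(cfg: PipelineConfig, result: Optional[PipelineResult] = None
            ) -> PipelineResult:
    """Validate long-read junctions against the short-read junction set."""
    res = result if result is not None and result.reads else PipelineResult(config=cfg)
    if not res.reads:
        res.reads, res.samples = _load_reads(cfg)
    _require(cfg.junctions, "junction set")
    jset = load_junctions(cfg.junctions, fmt=cfg.junctions_format)
    sw = _StageWriter(cfg, {"junctions": cfg.junctions})
    try:
        verdicts, summary = transcript_concordance(res.reads, jset)
        res.concordance = summary
        log.info("concordance: %d/%d spliced reads fully supported (%.1f%%); "
                 "%d unspliced excluded", summary.n_concordant,
                 summary.n_spliced, 100 * summary.fraction_spliced,
                 summary.n_unspliced)
        prefix = sw.path("concordance")
        write_concordance(verdicts, summary, prefix)
        for suffix in (".verdicts.tsv", ".summary.tsv", ".novel.tsv"):
            sw.written.append(prefix + suffix)
        sw.written.remove(prefix)
        sw.finalize()
    except Exception:
        sw.cleanup()
        raise
    return res


def run_all(cfg: PipelineConfig) -> PipelineResult:
    res = classify(cfg)
    res = annotate(cfg, res)
    res = polya(cfg, res)
    res = concord(cfg, res)
    return res


def report(cfg: PipelineConfig) -> str:
    """Aggregate existing stage outputs into a run summary; errors cleanly
    if a required artifact has not been produced yet."""
    needed = ["groups.tsv", "annotations.tsv"]
    lines = [f"orfclass v{__version__} run summary",
             f"output directory: {cfg.outdir}"]
    for name in needed:
        p = os.path.join(cfg.outdir, name)
        if not os.path.exists(p):
            raise FileNotFoundError(
                f"missing artifact {p}; run the producing stage first "
                f"(classify/annotate)")
    for name in ("read_stats.tsv", "groups.tsv", "annotations.tsv",
                 "orf_usage.tsv", "polya_trend.tsv", "concordance.summary.tsv"):
        p = os.path.join(cfg.outdir, name)
        if os.path.exists(p):
            with open(p) as fh:
                n = sum(1 for line in fh if not line.startswith("#"))
            lines.append(f"{name}: {n} rows")
        else:
            lines.append(f"{name}: not produced")
    text = "\n".join(lines) + "\n"
    out = os.path.join(cfg.outdir, "report.txt")
    with open(out, "w") as fh:
        fh.write(text)
    return text
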