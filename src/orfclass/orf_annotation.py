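"""ORF-centric annotation of transcript groups.

Each transcript group is turned into a *pseudo transcript*: the spliced
genome sequence of its consensus exon model, optionally extended a few nt
upstream of the 5' end.  The extension compensates for the systematic
5'-end under-read of nanopore direct RNA-seq (observed termini sit ~8-15 nt
downstream of mapped promoters), which otherwise hides start codons lying
immediately at the cap — the classic case being a 19K-type ORF whose AUG
sits a couple of nt from the transcription start.

Classification follows the 5'-most-ORF rule: the first AUG-opened ORF names
the transcript; if it matches no canonical feature, subsequent AUGs are
scanned in order and the first canonical hit is flagged "2nd Methionine".
Canonical identity is by start-codon genomic position + strand, so spliced
leader fusions sharing an N terminus match the same feature while their
full genomic footprints remain distinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .grouping import TranscriptGroup, revcomp

log = logging.getLogger("orfclass")

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


@dataclass(frozen=True)
class CanonicalFeature:
    """A known ORF, identified by the genomic position of the A of its AUG."""

    name: str
    strand: str
    start_codon_pos: int
    cds_end: int = 0
    expected_aa: Optional[int] = None


def load_feature_table(path: str) -> list[CanonicalFeature]:
    """Feature TSV: name, strand, start_codon_pos, cds_end[, expected_aa].

    Two features sharing a start codon position and strand are a fatal
    input error: the positional match rule could not tell them apart.
    """
    feats: list[CanonicalFeature] = []
    seen_start: dict[tuple[int, str], str] = {}
    seen_name: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for req in ("name", "strand", "start_codon_pos"):
            if req not in idx:
                raise ValueError(f"{path}: missing feature column {req!r}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[idx["name"]]
            strand = f[idx["strand"]]
            start = int(f[idx["start_codon_pos"]])
            cds_end = int(f[idx["cds_end"]]) if "cds_end" in idx and f[idx["cds_end"]] else 0
            exp = None
            if "expected_aa" in idx and len(f) > idx["expected_aa"] and f[idx["expected_aa"]] not in ("", "NA"):
                exp = int(f[idx["expected_aa"]])
            if name in seen_name:
                raise ValueError(f"{path}: duplicate feature name {name!r}")
            if (start, strand) in seen_start:
                raise ValueError(
                    f"{path}: features {seen_start[(start, strand)]!r} and "
                    f"{name!r} share start codon {start}{strand}")
            seen_name.add(name)
            seen_start[(start, strand)] = name
            feats.append(CanonicalFeature(name, strand, start, cds_end, exp))
    return feats


@dataclass
class PseudoTranscript:
    """Spliced consensus sequence of a group with a per-base genome map.

    ``sequence`` is written 5'->3' in transcript sense (DNA alphabet; AUG is
    scanned as ATG); ``coord_map[i]`` is the genomic coordinate of base
    ``i`` and is strictly decreasing for minus-strand groups.  ``extension``
    records how many upstream bases were actually prepended after clipping
    at the genome boundary.
    """

    group: TranscriptGroup
    sequence: str
    coord_map: list[int]
    extension: int


@dataclass
class ORFCall:
    """One AUG-opened reading frame on a pseudo transcript.

    Transcript coordinates are 1-based inclusive; ``tx_end`` includes the
    stop codon when ``complete``.  ``aa_len`` excludes the stop.
    """

    tx_start: int
    tx_end: int
    complete: bool
    aa_len: int
    start_genomic: int
    genomic_blocks: tuple[tuple[int, int], ...]
    rank: int = 0


@dataclass
class GroupAnnotation:
    group: TranscriptGroup
    orf_calls: list[ORFCall]
    matched_feature: Optional[str] = None
    match_rank: Optional[int] = None
    flags: set[str] = field(default_factory=set)


def build_pseudo_transcript(group: TranscriptGroup, genome: str,
                            extension: int = 10) -> PseudoTranscript:
    """Splice the group's consensus exon model out of the genome and extend
    its 5' end by ``extension`` genomic bases (clipped at genome ends)."""
    if extension < 0:
        raise ValueError("extension must be >= 0")
    L = len(genome)
    exons = group.exon_model()
    for s, e in exons:
        if s < 1 or e > L:
            raise ValueError(f"exon ({s},{e}) outside genome of length {L}")
    strand = group.key.strand
    coords: list[int] = []
    if strand == "+":
        first = exons[0][0]
        ext_lo = max(1, first - extension)
        actual_ext = first - ext_lo
        coords.extend(range(ext_lo, first))
        for s, e in exons:
            coords.extend(range(s, e + 1))
        seq = "".join(genome[c - 1] for c in coords)
    else:
        last = exons[-1][1]
        ext_hi = min(L, last + extension)
        actual_ext = ext_hi - last
        coords.extend(range(ext_hi, last, -1))
        for s, e in reversed(exons):
            coords.extend(range(e, s - 1, -1))
        # coords are already in transcript order, so complement base-by-base
        seq = "".join(revcomp(genome[c - 1]) for c in coords)
    return PseudoTranscript(group=group, sequence=seq.upper(),
                            coord_map=coords, extension=actual_ext)


def _genomic_blocks(coords: Sequence[int], start_idx: int, end_idx: int,
                    strand: str) -> tuple[tuple[int, int], ...]:
    """Collapse the genome coordinates of transcript bases [start, end]
    (0-based indices, inclusive) into maximal contiguous blocks, ascending."""
    step = 1 if strand == "+" else -1
    blocks: list[tuple[int, int]] = []
    run_start = prev = coords[start_idx]
    for i in range(start_idx + 1, end_idx + 1):
        c = coords[i]
        if c != prev + step:
            blocks.append((run_start, prev))
            run_start = c
        prev = c
    blocks.append((run_start, prev))
    norm = [(min(a, b), max(a, b)) for a, b in blocks]
    return tuple(sorted(norm))


def scan_orfs(pseudo: PseudoTranscript, min_aa: int = 10,
              canonical_starts: frozenset[int] | set[int] = frozenset()
              ) -> list[ORFCall]:
    """Find every AUG-opened ORF, 5'-most first.

    Reading proceeds from each AUG to the first in-frame stop (complete) or
    the transcript end (incomplete, flagged).  Candidates shorter than
    ``min_aa`` residues are dropped unless their start codon sits at a
    canonical feature position, which is always retained so that very short
    canonical peptides remain representable.
    """
    seq = pseudo.sequence
    n = len(seq)
    calls: list[ORFCall] = []
    for i in range(n - 2):
        if seq[i:i + 3] != START_CODON:
            continue
        j = i
        complete = False
        while j + 3 <= n:
            if seq[j:j + 3] in STOP_CODONS and j > i:
                complete = True
                break
            j += 3
        if complete:
            tx_end = j + 3          # last base of stop codon, 1-based
            aa_len = (j - i) // 3   # codons before the stop
            end_idx = tx_end - 1
        else:
            last_full = i + 3 * ((n - i) // 3)
            tx_end = last_full if last_full > i else n
            aa_len = (tx_end - i) // 3
            end_idx = tx_end - 1
        start_genomic = pseudo.coord_map[i]
        if aa_len < min_aa and start_genomic not in canonical_starts:
            continue
        calls.append(ORFCall(
            tx_start=i + 1, tx_end=tx_end, complete=complete, aa_len=aa_len,
            start_genomic=start_genomic,
            genomic_blocks=_genomic_blocks(pseudo.coord_map, i, end_idx,
                                           pseudo.group.key.strand)))
    for rank, call in enumerate(calls, start=1):
        call.rank = rank
    return calls


def match_canonical(orf: ORFCall, strand: str,
                    features: Sequence[CanonicalFeature]
                    ) -> tuple[Optional[str], bool]:
    """Match an ORF to a canonical feature by start-codon position + strand.

    Returns (name or None, truncated).  ``truncated`` is set when the
    feature declares an expected protein length and this ORF is shorter —
    e.g. an internal splice removed coding sequence downstream of the AUG.
    """
    for feat in features:
        if feat.strand == strand and feat.start_codon_pos == orf.start_genomic:
            truncated = feat.expected_aa is not None and orf.aa_len < feat.expected_aa
            return feat.name, truncated
    return None, False


def annotate_group(group: TranscriptGroup, genome: str,
                   features: Sequence[CanonicalFeature],
                   extension: int = 10, min_aa: int = 10) -> GroupAnnotation:
    """Classify one transcript group by the 5'-most-ORF rule."""
    strand = group.key.strand
    starts = frozenset(f.start_codon_pos for f in features if f.strand == strand)
    pseudo = build_pseudo_transcript(group, genome, extension)
    calls = scan_orfs(pseudo, min_aa=min_aa, canonical_starts=starts)
    ann = GroupAnnotation(group=group, orf_calls=calls)
    for call in calls:
        name, truncated = match_canonical(call, strand, features)
        if name is None:
            continue
        ann.matched_feature = name
        ann.match_rank = call.rank
        if call.rank >= 2:
            ann.flags.add("second_methionine")
        if truncated:
            ann.flags.add("truncated")
        if not call.complete:
            ann.flags.add("incomplete")
            ann.flags.add("truncated")
        break
    if ann.matched_feature is None:
        ann.flags.add("no_known_orf")
    return ann


def dominant_transcripts(annotations: Sequence[GroupAnnotation],
                         sample: Optional[str] = None
                         ) -> dict[str, TranscriptGroup]:
    """For each feature, the highest-count group whose rank-1 ORF is that
    feature (its 'dominant transcript').  Count ties break to the smaller
    TSS representative.  ``sample=None`` pools samples."""
    best: dict[str, tuple[int, int, TranscriptGroup]] = {}
    for ann in annotations:
        if ann.matched_feature is None or ann.match_rank != 1:
            continue
        g = ann.group
        n = g.total if sample is None else g.counts.get(sample, 0)
        if n == 0:
            continue
        cand = (-n, g.key.tss_cluster, g)
        cur = best.get(ann.matched_feature)
        if cur is None or cand[:2] < cur[:2]:
            best[ann.matched_feature] = cand
    return {name: t[2] for name, t in best.items()}


def orf_usage_table(annotations: Sequence[GroupAnnotation],
                    samples: Sequence[str]) -> dict[str, dict[str, float]]:
    """Per-sample percentage of classified reads whose rank-1 ORF is each
    feature, plus a ``no known ORF`` row.

    Reads whose canonical match required a downstream AUG (2nd Methionine)
    count in neither their feature's row nor the no-known-ORF row, so
    columns do not generally sum to 100.
    """
    totals = {s: 0 for s in samples}
    rank1: dict[str, dict[str, int]] = {}
    noorf = {s: 0 for s in samples}
    for ann in annotations:
        for s in samples:
            n = ann.group.counts.get(s, 0)
            if n == 0:
                continue
            totals[s] += n
            if "no_known_orf" in ann.flags:
                noorf[s] += n
            elif ann.match_rank == 1:
                rank1.setdefault(ann.matched_feature, dict.fromkeys(samples, 0))
                rank1[ann.matched_feature][s] += n
    table: dict[str, dict[str, float]] = {}
    for feat in sorted(rank1):
        table[feat] = {s: 100.0 * rank1[feat][s] / totals[s] if totals[s] else 0.0
                       for s in samples}
    table["no known ORF"] = {s: 100.0 * noorf[s] / totals[s] if totals[s] else 0.0
                             for s in samples}
    return table


def write_gff(annotations: Sequence[GroupAnnotation], path: str,
              mode: str = "all", feature: Optional[str] = None,
              source: str = "orfclass") -> None:
    """GFF3 export of transcript groups: one mRNA parent with exon children
    per group, 1-based inclusive coordinates, deterministic order.

    mode "all" writes every group, "dominant" only each feature's dominant
    transcript, "all_for_feature" every group matching ``feature``.
    """
    if mode not in ("all", "dominant", "all_for_feature"):
        raise ValueError(f"unknown GFF mode {mode!r}")
    if mode == "all_for_feature" and feature is None:
        raise ValueError("all_for_feature mode requires a feature name")
    chosen: list[GroupAnnotation]
    if mode == "all":
        chosen = list(annotations)
    elif mode == "all_for_feature":
        chosen = [a for a in annotations if a.matched_feature == feature]
    else:
        dom = dominant_transcripts(annotations)
        picked = {id(g) for g in dom.values()}
        chosen = [a for a in annotations if id(a.group) in picked]
    chosen.sort(key=lambda a: a.group.key.sort_key())
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ann in enumerate(chosen, start=1):
            g = ann.group
            exons = g.exon_model()
            start, end = exons[0][0], exons[-1][1]
            attrs = [f"ID=group{i}", f"reads={g.total}"]
            if ann.matched_feature:
                attrs.append(f"feature={ann.matched_feature}")
                attrs.append(f"match_rank={ann.match_rank}")
            if ann.flags:
                attrs.append("flags=" + ",".join(sorted(ann.flags)))
            fh.write("\t".join(["genome", source, "mRNA", str(start), str(end),
                                ".", g.key.strand, ".", ";".join(attrs)]) + "\n")
            for k, (s, e) in enumerate(exons, start=1):
                fh.write("\t".join([
                    "genome", source, "exon", str(s), str(e), ".",
                    g.key.strand, ".",
                    f"ID=group{i}.exon{k};Parent=group{i}"]) + "\n")


def parse_gff_exons(path: str) -> dict[str, tuple[str, tuple[tuple[int, int], ...]]]:
    """Minimal GFF3 reader for round-trip checks: mRNA ID -> (strand, exons)."""
    models: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if f[2] == "mRNA":
                models[attrs["ID"]] = (f[6], [])
            elif f[2] == "exon":
                models[attrs["Parent"]][1].append((int(f[3]), int(f[4])))
    return {k: (strand, tuple(sorted(ex))) for k, (strand, ex) in models.items()}
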