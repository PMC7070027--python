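"""Read-level model of spliced long-read alignments.

Direct RNA sequencing reads native mRNA, so every primary alignment is
treated as one full-length transcript observation: its exon chain gives the
splice pattern, its outermost aligned bases give the transcription start
site (TSS) and termination site (TTS), and its terminal soft clips measure
how imprecisely the ends mapped.  Coordinates are 1-based inclusive genome
positions throughout (GFF3 convention).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pysam

log = logging.getLogger("orfclass")

# CIGAR operator codes (pysam integer encoding)
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S = 0, 1, 2, 3, 4
_CIGAR_EQ, _CIGAR_X = 7, 8
_REF_CONSUMING = {_CIGAR_M, _CIGAR_D, _CIGAR_EQ, _CIGAR_X}


@dataclass(frozen=True)
class PolyARecord:
    """One per-read polyA tail estimate (nanopolish-polyA style)."""

    read_id: str
    qc_tag: str
    polya_length: float

    def __post_init__(self) -> None:
        if self.polya_length < 0:
            raise ValueError(f"negative polyA length for {self.read_id}")
        if not self.qc_tag:
            raise ValueError(f"empty qc_tag for {self.read_id}")


@dataclass(frozen=True)
class Junction:
    """A splice junction: last exonic base of the 5' exon (donor) and first
    exonic base of the 3' exon (acceptor), in genome coordinates."""

    donor: int
    acceptor: int
    strand: str

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("donor == acceptor")
        if self.strand == "+" and not self.donor < self.acceptor:
            raise ValueError("plus-strand junction must have donor < acceptor")
        if self.strand == "-" and not self.donor > self.acceptor:
            raise ValueError("minus-strand junction must have donor > acceptor")


@dataclass
class AlignedRead:
    """One primary spliced alignment in transcript orientation.

    ``exons`` are 1-based inclusive genomic intervals in ascending genomic
    order regardless of strand; ``clip5``/``clip3`` are soft-clip lengths at
    the transcript 5'/3' ends (so for minus-strand alignments the
    CIGAR-leading clip is ``clip3``).
    """

    read_id: str
    strand: str
    exons: list[tuple[int, int]]
    clip5: int = 0
    clip3: int = 0
    sample_id: str = ""
    polya: Optional[PolyARecord] = None
    polya_usable: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"read {self.read_id}: empty exon chain")
        if self.strand not in "+-":
            raise ValueError(f"read {self.read_id}: bad strand {self.strand!r}")
        if self.clip5 < 0 or self.clip3 < 0:
            raise ValueError(f"read {self.read_id}: negative clip")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"read {self.read_id}: exon start > end")
            if prev_end is not None and start <= prev_end + 1:
                raise ValueError(f"read {self.read_id}: exons overlap or abut")
            prev_end = end

    @property
    def tss(self) -> int:
        """Observed transcription start: 5'-most aligned genome position."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tts(self) -> int:
        """Observed termination (polyadenylation) site: 3'-most position."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class ClipProfile:
    end: str  # "5prime" or "3prime"
    mean: float
    mode: int
    histogram: dict[int, int] = field(default_factory=dict)


@dataclass
class ParseStats:
    primary: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    no_reference_op: int = 0

    @property
    def skipped(self) -> int:
        return (self.unmapped + self.secondary + self.supplementary
                + self.no_reference_op)


def _exons_from_cigar(pos: int, cigartuples) -> tuple[list[tuple[int, int]], int, int]:
    """Walk a CIGAR from 1-based ``pos``; M/=/X/D extend the current exon,
    each N closes it and opens the next.  Returns (exons, lead_clip, tail_clip)."""
    exons: list[tuple[int, int]] = []
    cur_start = pos
    cur = pos - 1  # last reference base consumed so far
    lead_clip = tail_clip = 0
    seen_ref_op = False
    for i, (op, n) in enumerate(cigartuples):
        if op in _REF_CONSUMING:
            cur += n
            seen_ref_op = True
        elif op == _CIGAR_N:
            exons.append((cur_start, cur))
            cur_start = cur + n + 1
            cur += n
        elif op == _CIGAR_S:
            if i == 0:
                lead_clip = n
            else:
                tail_clip = n
    if not seen_ref_op:
        return [], lead_clip, tail_clip
    exons.append((cur_start, cur))
    return exons, lead_clip, tail_clip


def parse_alignments(
    alignment_file: str,
    sample_id: str,
    reference_name: str | None = None,
    min_mapq: int = 0,
) -> tuple[list[AlignedRead], ParseStats]:
    """Parse primary, mapped records from a SAM/BAM file into AlignedReads.

    ``reference_name``, when given, must match the reference the records are
    aligned to (guards against pairing alignments with the wrong genome).
    Unmapped, secondary and supplementary records are skipped and tallied in
    the returned :class:`ParseStats`.
    """
    reads: list[AlignedRead] = []
    stats = ParseStats()
    with pysam.AlignmentFile(alignment_file, check_sq=False) as af:
        if reference_name is not None:
            names = list(af.references or [])
            if reference_name not in names:
                raise ValueError(
                    f"reference {reference_name!r} not in alignment header "
                    f"(found {names!r})")
        for rec in af:
            if rec.is_unmapped:
                stats.unmapped += 1
                continue
            if rec.is_secondary:
                stats.secondary += 1
                continue
            if rec.is_supplementary:
                stats.supplementary += 1
                continue
            if rec.mapping_quality < min_mapq:
                continue
            exons, lead, tail = _exons_from_cigar(
                rec.reference_start + 1, rec.cigartuples or [])
            if not exons:
                stats.no_reference_op += 1
                log.warning("read %s: CIGAR consumes no reference; skipped",
                            rec.query_name)
                continue
            strand = "-" if rec.is_reverse else "+"
            # transcript orientation: on '-' the CIGAR-leading clip is 3'
            clip5, clip3 = (tail, lead) if strand == "-" else (lead, tail)
            stats.primary += 1
            reads.append(AlignedRead(
                read_id=rec.query_name, strand=strand, exons=exons,
                clip5=clip5, clip3=clip3, sample_id=sample_id))
    return reads, stats


def junctions_of(read: AlignedRead) -> list[Junction]:
    """Splice junctions of a read, ordered 5'->3' along the transcript."""
    pairs = [
        (read.exons[i][1], read.exons[i + 1][0])
        for i in range(len(read.exons) - 1)
    ]
    if read.strand == "-":
        # transcript order runs from the genomically last exon downwards;
        # the donor of each intron is the higher-coordinate exon's first base
        pairs = [(acc, don) for don, acc in reversed(pairs)]
    return [Junction(d, a, read.strand) for d, a in pairs]


def exons_to_cigar(exons: Sequence[tuple[int, int]]) -> str:
    """Serialize an exon chain back to a clip-free CIGAR (gaps become N)."""
    parts = []
    for i, (s, e) in enumerate(exons):
        if i:
            parts.append(f"{s - exons[i - 1][1] - 1}N")
        parts.append(f"{e - s + 1}M")
    return "".join(parts)


def load_polya_table(path: str) -> list[PolyARecord]:
    """Read a nanopolish-polyA-style TSV.

    Requires a header row naming at least ``readname``, ``qc_tag`` and
    ``polya_length``; extra columns are ignored.
    """
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            icols = [header.index(c) for c in ("readname", "qc_tag", "polya_length")]
        except ValueError as exc:
            raise ValueError(f"{path}: missing required polyA column: {exc}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            records.append(PolyARecord(f[icols[0]], f[icols[1]], float(f[icols[2]])))
    return records


def attach_polya(
    reads: Iterable[AlignedRead],
    records: Iterable[PolyARecord],
    min_len: float = 20.0,
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Attach per-read polyA records and flag the polyA-usable subset.

    A read is usable for polyA/TTS analyses iff its record is QC ``PASS``
    and the estimated tail is at least ``min_len`` nt.  Reads without a
    record stay in the returned list (they still group) but are not usable.
    Returns (all reads, usable subset).
    """
    by_id: dict[str, PolyARecord] = {}
    for rec in records:
        if rec.read_id in by_id:
            log.warning("duplicate polyA record for %s; keeping first", rec.read_id)
            continue
        by_id[rec.read_id] = rec
    out, usable = [], []
    for read in reads:
        rec = by_id.get(read.read_id)
        ok = rec is not None and rec.qc_tag == "PASS" and rec.polya_length >= min_len
        annotated = replace(read, polya=rec, polya_usable=ok)
        out.append(annotated)
        if ok:
            usable.append(annotated)
    return out, usable


def softclip_profile(reads: Sequence[AlignedRead], end: str) -> ClipProfile:
    """Profile terminal soft-clip lengths at one transcript end.

    The modal clip length is the diagnostic the end-assignment rests on: a
    small mode means the aligner placed that end within a few nt of the true
    terminus.  Ties in the mode break toward the smaller length.
    """
    if end not in ("5prime", "3prime"):
        raise ValueError(f"end must be 5prime or 3prime, got {end!r}")
    if not reads:
        raise ValueError("softclip_profile requires at least one read")
    clips = [r.clip5 if end == "5prime" else r.clip3 for r in reads]
    hist = Counter(clips)
    best = max(hist.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return ClipProfile(end=end, mean=sum(clips) / len(clips), mode=best,
                       histogram=dict(sorted(hist.items())))


def read_stats(reads: Sequence[AlignedRead]) -> dict:
    """Summary statistics of aligned read lengths (sum of exon lengths)."""
    if not reads:
        raise ValueError("read_stats requires at least one read")
    lengths = [r.length for r in reads]
    hist = Counter(lengths)
    mode = max(hist.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return {
        "n": len(lengths),
        "longest": max(lengths),
        "mean_length": sum(lengths) / len(lengths),
        "modal_length": mode,
    }


def write_read_table(reads: Sequence[AlignedRead], path: str) -> None:
    """Read-level TSV export."""
    cols = ("read_id", "sample", "strand", "n_exons", "length",
            "clip5", "clip3", "polya_length", "polya_usable")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reads:
            pa = f"{r.polya.polya_length:.2f}" if r.polya else "NA"
            fh.write("\t".join(map(str, (
                r.read_id, r.sample_id, r.strand, len(r.exons), r.length,
                r.clip5, r.clip3, pa, int(r.polya_usable)))) + "\n")
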