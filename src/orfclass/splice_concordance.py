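"""Cross-validation of long-read splice junctions against short-read data.

A short-read RNA-seq junction set is, in effect, an untargeted survey of
splicing in the same RNA: a long-read transcript whose every junction also
appears there is independently supported end to end.  Matching is exact on
(donor, acceptor, strand) by default — splice sites are not windowed — with
an optional +/- fuzz for exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .read_model import AlignedRead, junctions_of


@dataclass
class JunctionSet:
    """(donor, acceptor, strand) -> supporting short-read count."""

    support: dict[tuple[int, int, str], int] = field(default_factory=dict)

    def __contains__(self, key: tuple[int, int, str]) -> bool:
        return key in self.support

    def __len__(self) -> int:
        return len(self.support)

    def add(self, donor: int, acceptor: int, strand: str, count: int = 1) -> None:
        key = (donor, acceptor, strand)
        self.support[key] = self.support.get(key, 0) + count

    def matches(self, donor: int, acceptor: int, strand: str, fuzz: int = 0) -> bool:
        if fuzz == 0:
            return (donor, acceptor, strand) in self.support
        return any(s == strand and abs(d - donor) <= fuzz
                   and abs(a - acceptor) <= fuzz
                   for d, a, s in self.support)


def load_junctions(path: str, fmt: str = "tsv",
                   min_support: int = 1) -> JunctionSet:
    """Load a junction table.

    TSV columns: donor, acceptor, strand, support (1-based inclusive, donor
    and acceptor as defined for spliced transcripts).  BED12 records are
    converted from 0-based half-open blocks; each pair of adjacent blocks
    yields one junction, with donor/acceptor assigned by strand.  Junctions
    supported by fewer than ``min_support`` reads are dropped.
    """
    if fmt not in ("tsv", "bed"):
        raise ValueError(f"format must be 'tsv' or 'bed', got {fmt!r}")
    jset = JunctionSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                if fmt == "tsv":
                    donor, acceptor = int(f[0]), int(f[1])
                    strand = f[2]
                    support = int(f[3]) if len(f) > 3 else 1
                    jset.add(donor, acceptor, strand, support)
                else:
                    chrom_start = int(f[1])
                    strand = f[5]
                    support = int(f[4]) if f[4] not in (".", "") else 1
                    sizes = [int(v) for v in f[10].rstrip(",").split(",")]
                    starts = [int(v) for v in f[11].rstrip(",").split(",")]
                    if len(sizes) < 2:
                        continue
                    for i in range(len(sizes) - 1):
                        # 1-based inclusive block bounds
                        up_last = chrom_start + starts[i] + sizes[i]
                        down_first = chrom_start + starts[i + 1] + 1
                        if strand == "-":
                            donor, acceptor = down_first, up_last
                        else:
                            donor, acceptor = up_last, down_first
                        jset.add(donor, acceptor, strand, support)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed junction line "
                                 f"({exc})") from exc
    jset.support = {k: v for k, v in jset.support.items() if v >= min_support}
    return jset


@dataclass
class ConcordanceSummary:
    n_spliced: int
    n_concordant: int
    n_unspliced: int
    known_junction_usage: int
    novel_junction_usage: int
    novel_junctions: dict[tuple[int, int, str], int]

    @property
    def fraction_spliced(self) -> float:
        """Concordant fraction among spliced reads (the headline figure)."""
        return self.n_concordant / self.n_spliced if self.n_spliced else 0.0

    @property
    def fraction_all(self) -> float:
        """Concordant fraction with unspliced reads in the denominator."""
        total = self.n_spliced + self.n_unspliced
        return self.n_concordant / total if total else 0.0


def transcript_concordance(reads: Iterable[AlignedRead], jset: JunctionSet,
                           fuzz: int = 0
                           ) -> tuple[list[tuple[str, str]], ConcordanceSummary]:
    """Per-read concordance verdicts plus a summary.

    A spliced read is concordant iff ALL of its junctions are in the
    short-read set.  Unspliced reads carry no testable junction; they are
    tallied separately and excluded from the primary denominator.
    """
    verdicts: list[tuple[str, str]] = []
    n_spliced = n_conc = n_unspliced = 0
    known_usage = novel_usage = 0
    novel: dict[tuple[int, int, str], int] = {}
    for read in reads:
        juncs = junctions_of(read)
        if not juncs:
            n_unspliced += 1
            verdicts.append((read.read_id, "unspliced"))
            continue
        n_spliced += 1
        ok = True
        for j in juncs:
            if jset.matches(j.donor, j.acceptor, j.strand, fuzz):
                known_usage += 1
            else:
                novel_usage += 1
                key = (j.donor, j.acceptor, j.strand)
                novel[key] = novel.get(key, 0) + 1
                ok = False
        if ok:
            n_conc += 1
        verdicts.append((read.read_id, "concordant" if ok else "discordant"))
    return verdicts, ConcordanceSummary(
        n_spliced=n_spliced, n_concordant=n_conc, n_unspliced=n_unspliced,
        known_junction_usage=known_usage, novel_junction_usage=novel_usage,
        novel_junctions=novel)


def write_concordance(verdicts: Sequence[tuple[str, str]],
                      summary: ConcordanceSummary, out_prefix: str) -> None:
    with open(out_prefix + ".verdicts.tsv", "w") as fh:
        fh.write("read_id\tverdict\n")
        for rid, v in verdicts:
            fh.write(f"{rid}\t{v}\n")
    with open(out_prefix + ".summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"spliced_reads\t{summary.n_spliced}\n")
        fh.write(f"concordant_reads\t{summary.n_concordant}\n")
        fh.write(f"unspliced_reads\t{summary.n_unspliced}\n")
        fh.write(f"fraction_concordant_spliced\t{summary.fraction_spliced:.4f}\n")
        fh.write(f"fraction_concordant_all\t{summary.fraction_all:.4f}\n")
        fh.write(f"known_junction_usage\t{summary.known_junction_usage}\n")
        fh.write(f"novel_junction_usage\t{summary.novel_junction_usage}\n")
    with open(out_prefix + ".novel.tsv", "w") as fh:
        fh.write("donor\tacceptor\tstrand\tread_count\n")
        for (d, a, s), n in sorted(summary.novel_junctions.items()):
            fh.write(f"{d}\t{a}\t{s}\t{n}\n")
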