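"""Transcript groups: equivalence classes of reads over end clusters and
exact splice chains.

Two reads belong to the same transcript group iff they share strand, TSS
cluster, the exact ordered splice-junction chain, and TTS cluster.  End
clusters absorb the few-nt scatter of mapped termini; junctions are matched
at exact coordinates because spliceosomal boundaries are, biologically,
exact.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .read_model import AlignedRead, Junction, junctions_of
from .site_clustering import SiteCluster, assign_site

log = logging.getLogger("orfclass")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GroupKey:
    strand: str
    tss_cluster: int  # representative genomic position
    junctions: tuple[Junction, ...]  # exact, ordered 5'->3'
    tts_cluster: int

    def sort_key(self):
        return (self.strand, self.tss_cluster,
                tuple((j.donor, j.acceptor) for j in self.junctions),
                self.tts_cluster)

    def splice_chain(self) -> tuple:
        """Key of the splice-chain-only rollup (TSS/TTS clusters ignored)."""
        return (self.strand, tuple((j.donor, j.acceptor) for j in self.junctions))


@dataclass
class TranscriptGroup:
    key: GroupKey
    counts: dict[str, int] = field(default_factory=dict)
    member_ids: dict[str, list[str]] = field(default_factory=dict)
    polya_lengths: dict[str, list[float]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def polya_summary(self, sample: str) -> tuple[float | None, float | None, int]:
        """(mean, sd, n) over polyA-usable members of one sample; sd uses the
        n-1 denominator and is None for n < 2."""
        vals = self.polya_lengths.get(sample, [])
        if not vals:
            return None, None, 0
        mean = sum(vals) / len(vals)
        sd = statistics.stdev(vals) if len(vals) >= 2 else None
        return mean, sd, len(vals)

    def exon_model(self) -> list[tuple[int, int]]:
        """Reconstruct the group's consensus exon chain (ascending genomic
        intervals) from its TSS/TTS representatives and junction chain."""
        k = self.key
        if k.strand == "+":
            bounds = [k.tss_cluster]
            for j in k.junctions:
                bounds += [j.donor, j.acceptor]
            bounds.append(k.tts_cluster)
            exons = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]
        else:
            # transcript runs high->low; junctions ordered 5'->3' descend
            bounds = [k.tss_cluster]
            for j in k.junctions:
                bounds += [j.donor, j.acceptor]
            bounds.append(k.tts_cluster)
            exons = [(bounds[i + 1], bounds[i]) for i in range(0, len(bounds), 2)]
            exons.reverse()
        for s, e in exons:
            if s > e:
                raise ValueError(
                    f"inconsistent group model (end-cluster representative "
                    f"crosses a junction): {k}")
        return exons


def group_key(read: AlignedRead,
              tss_clusters: dict[str, list[SiteCluster]],
              tts_clusters: dict[str, list[SiteCluster]]) -> GroupKey:
    """Key a read: windowed TSS/TTS cluster representatives, exact junctions."""
    tssc = assign_site(read.tss, tss_clusters[read.strand])
    ttsc = assign_site(read.tts, tts_clusters[read.strand])
    return GroupKey(strand=read.strand,
                    tss_cluster=tssc.representative,
                    junctions=tuple(junctions_of(read)),
                    tts_cluster=ttsc.representative)


def build_groups(reads: Iterable[AlignedRead],
                 tss_clusters: dict[str, list[SiteCluster]],
                 tts_clusters: dict[str, list[SiteCluster]],
                 require_polya: bool = False) -> list[TranscriptGroup]:
    """Group reads and count them per sample.

    ``require_polya`` restricts grouping to polyA-usable reads (the stricter
    reading of confining analysis to confirmed-polyA transcripts); by
    default all primary reads group and the polyA filter only gates the
    per-group tail-length summaries.  Groups are returned sorted by total
    count descending, then key.
    """
    by_key: dict[GroupKey, TranscriptGroup] = {}
    for read in reads:
        if require_polya and not read.polya_usable:
            continue
        key = group_key(read, tss_clusters, tts_clusters)
        grp = by_key.get(key)
        if grp is None:
            grp = by_key[key] = TranscriptGroup(key=key)
        grp.counts[read.sample_id] = grp.counts.get(read.sample_id, 0) + 1
        grp.member_ids.setdefault(read.sample_id, []).append(read.read_id)
        if read.polya_usable and read.polya is not None:
            grp.polya_lengths.setdefault(read.sample_id, []).append(
                read.polya.polya_length)
    return sorted(by_key.values(), key=lambda g: (-g.total, g.key.sort_key()))


def splice_chain_rollup(groups: Sequence[TranscriptGroup]) -> dict[tuple, int]:
    """Collapse groups that differ only in end clusters; count reads per
    distinct (strand, junction chain)."""
    rollup: dict[tuple, int] = {}
    for g in groups:
        ck = g.key.splice_chain()
        rollup[ck] = rollup.get(ck, 0) + g.total
    return rollup


def splice_site_table(reads: Iterable[AlignedRead], genome: str) -> list[dict]:
    """Every distinct donor/acceptor with usage counts and the flanking
    intronic dinucleotides on the coding strand (GT expected after donors,
    AG before acceptors; read from the reverse complement for '-' strands).
    """
    usage: dict[tuple[str, int, str], int] = {}
    for read in reads:
        for j in junctions_of(read):
            usage[("donor", j.donor, j.strand)] = \
                usage.get(("donor", j.donor, j.strand), 0) + 1
            usage[("acceptor", j.acceptor, j.strand)] = \
                usage.get(("acceptor", j.acceptor, j.strand), 0) + 1
    rows = []
    L = len(genome)

    def fetch(start: int, end: int) -> str:  # 1-based inclusive, clipped
        if start < 1 or end > L:
            log.warning("splice site dinucleotide at genome edge (%d-%d); "
                        "reported partial", start, end)
        return genome[max(start, 1) - 1:min(end, L)]

    for (kind, pos, strand), n in sorted(usage.items()):
        if kind == "donor":
            dinuc = fetch(pos + 1, pos + 2) if strand == "+" \
                else revcomp(fetch(pos - 2, pos - 1))
        else:
            dinuc = fetch(pos - 2, pos - 1) if strand == "+" \
                else revcomp(fetch(pos + 1, pos + 2))
        rows.append({"site": kind, "position": pos, "strand": strand,
                     "count": n, "dinucleotide": dinuc.upper()})
    return rows


def write_group_table(groups: Sequence[TranscriptGroup], samples: Sequence[str],
                      path: str) -> None:
    with open(path, "w") as fh:
        cols = ["strand", "tss", "junctions", "tts", "total"]
        for s in samples:
            cols += [f"count_{s}", f"polya_mean_{s}", f"polya_sd_{s}",
                     f"polya_n_{s}"]
        fh.write("\t".join(cols) + "\n")
        for g in groups:
            jtxt = ";".join(f"{j.donor}-{j.acceptor}" for j in g.key.junctions) or "."
            row = [g.key.strand, str(g.key.tss_cluster), jtxt,
                   str(g.key.tts_cluster), str(g.total)]
            for s in samples:
                mean, sd, n = g.polya_summary(s)
                row += [str(g.counts.get(s, 0)),
                        f"{mean:.2f}" if mean is not None else "NA",
                        f"{sd:.2f}" if sd is not None else "NA",
                        str(n)]
            fh.write("\t".join(row) + "\n")
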