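"""Synthetic spliced-transcriptome simulator with exact truth tables.

The generator builds a miniature "virus": a ~20 kb double-stranded genome
transcribed from multiple promoters on both strands, with alternative
splice chains sharing promoters, canonical GT/AG introns, and a feature
table of known ORFs.  Reads are emitted as spliced SAM alignments (the
pipeline's contract begins at mapped reads), together with a
nanopolish-style per-read polyA table, a matched short-read junction set,
and per-read provenance, so every downstream stage can be checked against
known truth.

The noise model mirrors what direct RNA-seq of an infected cell actually
shows: observed 5' ends sit a uniform 8-15 nt downstream of the promoter
(nanopore under-reads the cap end), a small fraction of reads start at
internal positions (RNA breakage before sequencing), 3' ends jitter a few
nt around the polyadenylation site, terminal soft clips have small modes
(5' mode ~1, 3' mode ~2), ~60% of reads get a PASS polyA call, and
per-sample polyA means decline as the time course progresses.

Sequence design guarantees each isoform's classification: every base
upstream of the designed rank-1 ORF (including 15 nt of genomic context
beyond the TSS, covering any 5' extension up to that length) is scrubbed
of AUGs, ORF bodies avoid internal stops and AUGs, and introns are flanked
GT..AG on the coding strand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .grouping import GroupKey, revcomp
from .orf_annotation import CanonicalFeature
from .read_model import Junction

log = logging.getLogger("orfclass")

GENOME_ID = "genome"

_SAFE_CODONS = [
    "GCA", "GCC", "GCT", "AAA", "AAC", "GAA", "GAC", "TTC", "CTG", "CCA",
    "GGA", "GGC", "TCA", "ACC", "CAT", "CAG", "AGA", "GTG", "TGG", "TAC",
]  # no start, no stop codons


@dataclass
class IsoformDef:
    """One designed isoform: exon chain, intended classification, weights."""

    iso_id: str
    strand: str
    exons: list[tuple[int, int]]
    feature: Optional[str]          # intended matched canonical feature
    expected_flags: frozenset[str]  # e.g. {"second_methionine"}, {"no_known_orf"}
    weights: tuple[float, ...]      # relative abundance per sample

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tts(self) -> int:
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    def junctions(self) -> tuple[Junction, ...]:
        pairs = [(self.exons[i][1], self.exons[i + 1][0])
                 for i in range(len(self.exons) - 1)]
        if self.strand == "-":
            pairs = [(a, d) for d, a in reversed(pairs)]
        return tuple(Junction(d, a, self.strand) for d, a in pairs)

    def group_key(self) -> GroupKey:
        """The transcript-group key a perfectly mapped read would get."""
        return GroupKey(strand=self.strand, tss_cluster=self.tss,
                        junctions=self.junctions(), tts_cluster=self.tts)

    def transcript_coords(self) -> list[int]:
        coords: list[int] = []
        if self.strand == "+":
            for s, e in self.exons:
                coords.extend(range(s, e + 1))
        else:
            for s, e in reversed(self.exons):
                coords.extend(range(e, s - 1, -1))
        return coords


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults encode the observed data characteristics: 3 time-point
    samples, 5000 reads each, 5' under-read uniform on 8-15 nt, +/-5 nt
    3'-end jitter, 5% internal (breakage) 5' ends, ~60% PASS polyA calls
    with per-sample means declining 20% per time point, and 10% short-read
    junction dropout.
    """

    seed: int = 0
    genome_length: int = 20000
    samples: tuple[str, ...] = ("16h", "24h", "48h")
    reads_per_sample: int = 5000
    truncation5: tuple[int, int] = (8, 15)  # uniform inclusive; (0, 0) = off
    tts_jitter: int = 5
    fragmentation_rate: float = 0.05
    polya_pass_rate: float = 0.6
    polya_decline: float = 0.2   # fractional mean decrease per successive sample
    polya_sigma: float = 0.47    # lognormal shape; CV ~ 0.5 (sd ~50 at mean ~100)
    illumina_dropout: float = 0.1
    isoforms: Optional[list[IsoformDef]] = None  # None -> default layout


@dataclass
class SimTruth:
    genome: str
    features: list[CanonicalFeature]
    isoforms: list[IsoformDef]
    junctions: set[tuple[int, int, str]]
    polya_base_mean: dict[str, float] = field(default_factory=dict)


# --- default genome layout -------------------------------------------------
# (feature name, strand, genomic position of the A of AUG, protein length)
_FEATURES = [
    ("P1", "+", 1003, 40), ("P2", "+", 3510, 50), ("P3", "+", 5212, 45),
    ("P4", "+", 7004, 60), ("P5", "+", 10560, 40), ("P6", "-", 16097, 40),
    ("P7", "-", 18190, 55), ("P8", "-", 17490, 45), ("P9", "+", 203, 30),
    ("P10", "-", 15597, 30),
]
# decoy (non-canonical) ORFs: (strand, AUG position, protein length)
_DECOYS = [("+", 10503, 12), ("+", 12520, 20)]


def default_isoforms() -> list[IsoformDef]:
    """Fifteen isoforms over eight transcription units on both strands:
    shared promoters with alternative splice chains and alternative TTS,
    an unspliced unit, minus-strand units, one designed second-Methionine
    transcript and two designed no-known-ORF transcripts."""
    F = frozenset
    return [
        IsoformDef("U1",  "+", [(1000, 2200)], "P1", F(), (10, 6, 3)),
        IsoformDef("U1b", "+", [(1000, 2600)], "P1", F(), (4, 3, 2)),
        IsoformDef("U2a", "+", [(3000, 3060), (3501, 4800)], "P2", F(), (8, 6, 4)),
        IsoformDef("U2b", "+", [(3000, 3060), (5201, 6500)], "P3", F(), (6, 5, 3)),
        IsoformDef("U2c", "+", [(3000, 3060), (3501, 4680)], "P2", F(), (3, 2, 2)),
        IsoformDef("U3a", "+", [(7000, 7300), (7801, 9000)], "P4", F(), (3, 6, 10)),
        IsoformDef("U3b", "+", [(7000, 7300), (7801, 8200), (8701, 10000)],
                   "P4", F(), (2, 4, 8)),
        IsoformDef("U4",  "+", [(10500, 11900)], "P5",
                   F({"second_methionine"}), (3, 3, 3)),
        IsoformDef("U5",  "+", [(12500, 13100), (13601, 14500)], None,
                   F({"no_known_orf"}), (2, 3, 4)),
        IsoformDef("U5b", "+", [(12500, 13100)], None,
                   F({"no_known_orf"}), (1, 2, 2)),
        IsoformDef("U6",  "-", [(14800, 16100)], "P6", F(), (5, 5, 5)),
        IsoformDef("U6b", "-", [(14800, 15600)], "P10", F(), (2, 2, 3)),
        IsoformDef("U7a", "-", [(17000, 18200), (19440, 19500)], "P7",
                   F(), (3, 5, 9)),
        IsoformDef("U7b", "-", [(16400, 17500), (19440, 19500)], "P8",
                   F(), (2, 4, 7)),
        IsoformDef("U8",  "+", [(200, 760)], "P9", F(), (4, 3, 2)),
    ]


def _write_sense(genome: list[str], pos: int, strand: str, text: str) -> None:
    """Write ``text`` in transcript sense starting at genomic ``pos``:
    ascending plus-strand bases for '+', descending complemented for '-'."""
    if strand == "+":
        for i, ch in enumerate(text):
            genome[pos - 1 + i] = ch
    else:
        for i, ch in enumerate(text):
            genome[pos - 1 - i] = revcomp(ch)


def _read_sense(genome: list[str], positions: Sequence[int], strand: str) -> str:
    if strand == "+":
        return "".join(genome[p - 1] for p in positions)
    return "".join(revcomp(genome[p - 1]) for p in positions)


def _scrub_atg(genome: list[str], positions: Sequence[int], strand: str,
               protected: set[int]) -> None:
    """Remove every transcript-sense ATG whose bases all lie in ``positions``
    by mutating its G to C (cannot create a new ATG)."""
    for _ in range(4):  # re-scan; one pass suffices but be safe
        seq = _read_sense(genome, positions, strand)
        hit = False
        for i in range(len(seq) - 2):
            if seq[i:i + 3] == "ATG":
                gpos = positions[i + 2]
                if gpos in protected:
                    raise ValueError(
                        f"infeasible geometry: scrub region overlaps protected "
                        f"content at genome position {gpos}")
                _write_sense(genome, gpos, strand, "C")
                hit = True
        if not hit:
            return
    raise ValueError("infeasible geometry: ATG scrub did not converge")


def _orf_positions(start: int, n_nt: int, strand: str) -> list[int]:
    step = 1 if strand == "+" else -1
    return [start + step * i for i in range(n_nt)]


def make_genome(config: SimConfig) -> SimTruth:
    """Construct the genome, feature table and isoform truth.

    Deterministic under ``config.seed``.  Raises on infeasible geometry
    (e.g. a designed ORF colliding with another isoform's scrubbed 5' UTR).
    """
    rng = np.random.default_rng([config.seed, 7])
    isoforms = config.isoforms or default_isoforms()
    n_samples = len(config.samples)
    for iso in isoforms:
        if len(iso.weights) != n_samples:
            raise ValueError(f"{iso.iso_id}: {len(iso.weights)} weights for "
                             f"{n_samples} samples")
        if not any(w > 0 for w in iso.weights):
            raise ValueError(f"{iso.iso_id}: all-zero weights")
        for s, e in iso.exons:
            if s < 1 or e > config.genome_length:
                raise ValueError(f"infeasible geometry: {iso.iso_id} exon "
                                 f"({s},{e}) outside genome")
    genome = list("".join(rng.choice(list("ACGT"), size=config.genome_length)))

    features = [CanonicalFeature(name, strand, pos, expected_aa=aa,
                                 cds_end=pos + (3 * aa + 2) * (1 if strand == "+" else -1))
                for name, strand, pos, aa in _FEATURES]
    protected: set[int] = set()

    # 1. write ORF bodies (canonical + decoys): ATG, safe codons, stop
    orf_specs = [(strand, pos, aa) for _, strand, pos, aa in _FEATURES]
    orf_specs += _DECOYS
    for strand, pos, aa in orf_specs:
        body = "".join(rng.choice(_SAFE_CODONS) for _ in range(aa - 1))
        text = "ATG" + body + "TAA"
        _write_sense(genome, pos, strand, text)
        protected.update(_orf_positions(pos, len(text), strand))

    # 2. canonical GT/AG intron boundaries (transcript sense)
    for iso in isoforms:
        for j in iso.junctions():
            step = 1 if iso.strand == "+" else -1
            gt = [j.donor + step, j.donor + 2 * step]
            ag = [j.acceptor - 2 * step, j.acceptor - step]
            for positions, text in ((gt, "GT"), (ag, "AG")):
                current = _read_sense(genome, positions, iso.strand)
                if any(p in protected for p in positions) and current != text:
                    # shared donors/acceptors rewrite identical bases; any
                    # other collision means the layout is inconsistent
                    raise ValueError(
                        f"infeasible geometry: splice dinucleotide of "
                        f"{iso.iso_id} at {positions} hits protected content")
                _write_sense(genome, positions[0], iso.strand, text)
                protected.update(positions)

    # 3. scrub AUGs upstream of each designed rank-1 ORF
    decoy_by_pos = {(s, p): aa for s, p, aa in _DECOYS}
    feat_by_name = {f.name: f for f in features}
    for iso in isoforms:
        coords = iso.transcript_coords()
        step = 1 if iso.strand == "+" else -1
        upstream = [iso.tss - step * k for k in range(15, 0, -1)]
        # the designed rank-1 start: a decoy if the transcript carries one
        # upstream of (or instead of) its canonical feature, else the feature
        cand_positions = []
        if iso.feature is not None:
            cand_positions.append(feat_by_name[iso.feature].start_codon_pos)
        for (s, p) in decoy_by_pos:
            if s == iso.strand and p in set(coords):
                cand_positions.append(p)
        if not cand_positions:
            raise ValueError(f"infeasible geometry: {iso.iso_id} carries no "
                             f"designed ORF")
        by_tx = {coords.index(p): p for p in cand_positions if p in set(coords)}
        if not by_tx:
            raise ValueError(f"infeasible geometry: {iso.iso_id}: designed ORF "
                             f"start not on the transcript")
        first_idx = min(by_tx)
        scrub = upstream + coords[:first_idx]
        _scrub_atg(genome, scrub, iso.strand, protected)
        # second-Methionine designs: also scrub between decoy stop and feature
        if "second_methionine" in iso.expected_flags and iso.feature is not None:
            decoy_pos = by_tx[first_idx]
            decoy_aa = decoy_by_pos[(iso.strand, decoy_pos)]
            gap_start = first_idx + 3 * decoy_aa + 3
            feat_idx = coords.index(feat_by_name[iso.feature].start_codon_pos)
            _scrub_atg(genome, coords[gap_start:feat_idx], iso.strand, protected)

    junctions = {(j.donor, j.acceptor, j.strand)
                 for iso in isoforms for j in iso.junctions()}
    base_means = {iso.iso_id: 85.0 + 3.0 * i for i, iso in enumerate(isoforms)}
    return SimTruth(genome="".join(genome), features=features,
                    isoforms=isoforms, junctions=junctions,
                    polya_base_mean=base_means)


# --- read simulation -------------------------------------------------------

# terminal soft-clip length distributions (nt -> probability); 5' mode 1,
# 3' mode 2, echoing observed end-mapping imprecision
_CLIP5_P = {0: 0.25, 1: 0.35, 2: 0.20, 3: 0.10, 4: 0.06, 5: 0.04}
_CLIP3_P = {0: 0.05, 1: 0.10, 2: 0.30, 3: 0.25, 4: 0.15, 5: 0.07,
            6: 0.04, 7: 0.03, 8: 0.01}


@dataclass
class SimRead:
    read_id: str
    sample_id: str
    iso_id: str
    exons: list[tuple[int, int]]
    strand: str
    clip5: int
    clip3: int
    truncation: int
    fragmented: bool
    jitter: int
    qc_tag: str
    polya_length: float
    true_polya: float


def _coords_to_exons(coords: Sequence[int], strand: str) -> list[tuple[int, int]]:
    ordered = coords if strand == "+" else list(reversed(coords))
    exons: list[tuple[int, int]] = []
    run = prev = ordered[0]
    for c in ordered[1:]:
        if c != prev + 1:
            exons.append((run, prev))
            run = c
        prev = c
    exons.append((run, prev))
    return exons


def simulate_sample(truth: SimTruth, sample_index: int,
                    config: SimConfig) -> list[SimRead]:
    """Simulate one sample's reads from the truth isoform set."""
    rng = np.random.default_rng([config.seed, 1000 + sample_index])
    sample_id = config.samples[sample_index]
    isoforms = truth.isoforms
    weights = np.array([iso.weights[sample_index] for iso in isoforms],
                       dtype=float)
    weights = weights / weights.sum()
    lo, hi = config.truncation5
    qc_fail_tags = ["SUFFCLIP", "ADAPTER", "NOREGION"]
    c5_vals, c5_p = zip(*sorted(_CLIP5_P.items()))
    c3_vals, c3_p = zip(*sorted(_CLIP3_P.items()))
    decline = (1.0 - config.polya_decline) ** sample_index
    reads: list[SimRead] = []
    choices = rng.choice(len(isoforms), size=config.reads_per_sample, p=weights)
    for i, iso_idx in enumerate(choices):
        iso = isoforms[iso_idx]
        coords = iso.transcript_coords()
        # 5' end: systematic under-read, or internal breakage
        fragmented = bool(rng.random() < config.fragmentation_rate)
        if fragmented:
            cut = int(rng.integers(0, max(1, len(coords) - 50)))
        elif hi > 0:
            cut = int(rng.integers(lo, hi + 1))
        else:
            cut = 0
        # 3' end jitter within/just beyond the final exon
        jit = int(rng.integers(-config.tts_jitter, config.tts_jitter + 1)) \
            if config.tts_jitter > 0 else 0
        kept = coords[cut:]
        if jit < 0:
            kept = kept[:jit] if len(kept) + jit > 30 else kept
            jit_used = jit if len(coords[cut:]) + jit > 30 else 0
        else:
            jit_used = jit
            step = 1 if iso.strand == "+" else -1
            tail = [kept[-1] + step * k for k in range(1, jit + 1)]
            tail = [p for p in tail if 1 <= p <= len(truth.genome)]
            kept = kept + tail
        exons = _coords_to_exons(kept, iso.strand)
        clip5 = int(rng.choice(c5_vals, p=c5_p))
        clip3 = int(rng.choice(c3_vals, p=c3_p))
        # polyA call
        mean = truth.polya_base_mean[iso.iso_id] * decline
        sigma = config.polya_sigma
        mu = np.log(mean) - sigma * sigma / 2.0
        true_polya = float(rng.lognormal(mu, sigma))
        qc = "PASS" if rng.random() < config.polya_pass_rate \
            else qc_fail_tags[int(rng.integers(0, 3))]
        reads.append(SimRead(
            read_id=f"{sample_id}_read{i:06d}", sample_id=sample_id,
            iso_id=iso.iso_id, exons=exons, strand=iso.strand,
            clip5=clip5, clip3=clip3, truncation=0 if fragmented else cut,
            fragmented=fragmented, jitter=jit_used, qc_tag=qc,
            polya_length=true_polya, true_polya=true_polya))
    return reads


def write_sam(reads: Sequence[SimRead], truth: SimTruth, path: str) -> None:
    """Emit simulated reads as spliced SAM alignments.

    SEQ is the plus-strand spliced genome sequence with random clipped
    bases appended at the soft-clipped ends; CIGAR is S (M N)* S with the
    leading clip being the transcript 3' clip for minus-strand reads.
    """
    rng = np.random.default_rng(len(reads) + 13)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": GENOME_ID, "LN": len(truth.genome)}]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.reference_id = 0
            a.reference_start = r.exons[0][0] - 1
            a.mapping_quality = 60
            a.flag = 16 if r.strand == "-" else 0
            lead, tail = (r.clip3, r.clip5) if r.strand == "-" \
                else (r.clip5, r.clip3)
            cig = []
            if lead:
                cig.append(f"{lead}S")
            for k, (s, e) in enumerate(r.exons):
                if k:
                    cig.append(f"{s - r.exons[k - 1][1] - 1}N")
                cig.append(f"{e - s + 1}M")
            if tail:
                cig.append(f"{tail}S")
            a.cigarstring = "".join(cig)
            body = "".join(truth.genome[s - 1:e] for s, e in r.exons)
            pre = "".join(rng.choice(list("ACGT"), size=lead)) if lead else ""
            post = "".join(rng.choice(list("ACGT"), size=tail)) if tail else ""
            a.query_sequence = pre + body + post
            out.write(a)


def write_polya_tsv(reads: Sequence[SimRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("readname\tcontig\tqc_tag\tpolya_length\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{GENOME_ID}\t{r.qc_tag}\t"
                     f"{r.polya_length:.2f}\n")


def write_provenance(reads: Sequence[SimRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample\tisoform\ttruncation\tfragmented\t"
                 "jitter\ttrue_polya\tqc_tag\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.sample_id}\t{r.iso_id}\t"
                     f"{r.truncation}\t{int(r.fragmented)}\t{r.jitter}\t"
                     f"{r.true_polya:.2f}\t{r.qc_tag}\n")


def simulate_illumina_junctions(truth: SimTruth, dropout: float,
                                seed: int, path: str) -> set[tuple[int, int, str]]:
    """Matched short-read junction table: every true junction kept
    independently with probability 1 - dropout, support counts >= 1."""
    rng = np.random.default_rng([seed, 99])
    kept = set()
    with open(path, "w") as fh:
        fh.write("#donor\tacceptor\tstrand\tsupport\n")
        for d, a, s in sorted(truth.junctions):
            if rng.random() < dropout:
                continue
            support = 1 + int(rng.poisson(50))
            fh.write(f"{d}\t{a}\t{s}\t{support}\n")
            kept.add((d, a, s))
    return kept


def write_genome_fasta(truth: SimTruth, path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    rec = SeqRecord(Seq(truth.genome), id=GENOME_ID,
                    description="synthetic multi-promoter spliced genome")
    SeqIO.write([rec], path, "fasta")


def write_feature_tsv(truth: SimTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstrand\tstart_codon_pos\tcds_end\texpected_aa\n")
        for f in truth.features:
            fh.write(f"{f.name}\t{f.strand}\t{f.start_codon_pos}\t"
                     f"{f.cds_end}\t{f.expected_aa}\n")


def write_truth_json(truth: SimTruth, config: SimConfig,
                     realized: dict[str, dict[str, int]], path: str) -> None:
    payload = {
        "genome_length": len(truth.genome),
        "samples": list(config.samples),
        "isoforms": [{
            "iso_id": iso.iso_id, "strand": iso.strand, "exons": iso.exons,
            "feature": iso.feature, "flags": sorted(iso.expected_flags),
            "tss": iso.tss, "tts": iso.tts,
            "junctions": [(j.donor, j.acceptor) for j in iso.junctions()],
            "weights": list(iso.weights),
            "realized_counts": realized.get(iso.iso_id, {}),
        } for iso in truth.isoforms],
        "junctions": sorted(truth.junctions),
        "polya_base_mean": truth.polya_base_mean,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_dataset(config: SimConfig, outdir: str) -> dict:
    """Generate the full dataset on disk; returns a manifest of paths plus
    the in-memory truth and simulated reads."""
    import os
    os.makedirs(outdir, exist_ok=True)
    truth = make_genome(config)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "features": os.path.join(outdir, "features.tsv"),
        "junctions": os.path.join(outdir, "illumina_junctions.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_genome_fasta(truth, paths["genome"])
    write_feature_tsv(truth, paths["features"])
    all_reads: dict[str, list[SimRead]] = {}
    realized: dict[str, dict[str, int]] = {}
    for si, sample in enumerate(config.samples):
        reads = simulate_sample(truth, si, config)
        all_reads[sample] = reads
        for r in reads:
            realized.setdefault(r.iso_id, {}).setdefault(sample, 0)
            realized[r.iso_id][sample] += 1
        sam = os.path.join(outdir, f"{sample}.sam")
        polya = os.path.join(outdir, f"{sample}.polya.tsv")
        prov = os.path.join(outdir, f"{sample}.provenance.tsv")
        write_sam(reads, truth, sam)
        write_polya_tsv(reads, polya)
        write_provenance(reads, prov)
        paths[f"sam_{sample}"] = sam
        paths[f"polya_{sample}"] = polya
        paths[f"provenance_{sample}"] = prov
    simulate_illumina_junctions(truth, config.illumina_dropout, config.seed,
                                paths["junctions"])
    write_truth_json(truth, config, realized, paths["truth"])
    return {"paths": paths, "truth": truth, "reads": all_reads,
            "realized": realized}
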