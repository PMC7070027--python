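import pytest

from orfclass import PipelineConfig, SimConfig, simulate_dataset
from orfclass.pipeline import run_all

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:genome\tLN:100000\n"


def sam_line(name, flag, pos, cigar, mapq=60):
    qlen = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                qlen += int(num)
            num = ""
    seq = "A" * qlen
    return (f"{name}\t{flag}\tgenome\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
            f"{seq}\t*\n")


@pytest.fixture()
def sam_file(tmp_path):
    def make(lines, name="reads.sam"):
        path = tmp_path / name
        path.write_text(SAM_HEADER + "".join(lines))
        return str(path)
    return make


@pytest.fixture(scope="session")
def noise_free_sim(tmp_path_factory):
    """Small noise-free simulated dataset: observed ends equal truth."""
    outdir = tmp_path_factory.mktemp("sim_clean")
    cfg = SimConfig(seed=11, reads_per_sample=800, truncation5=(0, 0),
                    tts_jitter=0, fragmentation_rate=0.0)
    sim = simulate_dataset(cfg, str(outdir))
    sim["config"] = cfg
    return sim


@pytest.fixture(scope="session")
def noise_free_run(noise_free_sim, tmp_path_factory):
    """Full pipeline result over the noise-free dataset."""
    sim = noise_free_sim
    cfg = sim["config"]
    outdir = tmp_path_factory.mktemp("run_clean")
    pc = PipelineConfig(
        genome=sim["paths"]["genome"],
        alignments={s: sim["paths"][f"sam_{s}"] for s in cfg.samples},
        polya_tables={s: sim["paths"][f"polya_{s}"] for s in cfg.samples},
        features=sim["paths"]["features"],
        junctions=sim["paths"]["junctions"],
        outdir=str(outdir))
    return run_all(pc)
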