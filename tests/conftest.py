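import numpy as np
import pandas as pd
import pytest

from rescursor.genome_io import (
    Gene,
    GenomeAnnotation,
    SignalTrack,
    Transcript,
    derive_introns,
)
from rescursor.synthetic_data import SimulationConfig, simulate_experiment


def toy_annotation(exons, strand="+", gid="g1", chrom="chr1"):
    """Single-gene, single-transcript annotation from exon intervals."""
    ann = GenomeAnnotation()
    ann.genes[gid] = Gene(gid, chrom, strand, exons[0][0], exons[-1][1])
    ann.transcripts[f"{gid}.t1"] = Transcript(f"{gid}.t1", gid, chrom, strand, list(exons))
    return derive_introns(ann)


def constant_track(chrom, start, end, value, kind="coverage"):
    t = SignalTrack(kind)
    t.add_intervals(chrom, [start], [end], [value])
    return t


def dense_track(chrom, start, values, kind="coverage"):
    """Per-base track from a dense array anchored at ``start``."""
    values = np.asarray(values, dtype=float)
    t = SignalTrack(kind)
    starts = start + np.arange(len(values))
    t.add_intervals(chrom, starts, starts + 1, values)
    return t


@pytest.fixture(scope="session")
def default_experiment(tmp_path_factory):
    """The default synthetic study: 20 genes, 3+3 replicates + 1 poly(A),
    40 true RSSs and 20 single-criterion decoys, seed fixed."""
    outdir = tmp_path_factory.mktemp("default_sim")
    cfg = SimulationConfig(seed=1)
    paths = simulate_experiment(cfg, str(outdir))
    truth = pd.read_csv(paths["truth"], sep="\t")
    return cfg, paths, truth
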