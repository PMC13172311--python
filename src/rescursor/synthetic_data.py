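"""Ground-truthed synthetic inputs for the recursive-splicing pipeline.

The generator emits every format the pipeline reads — genome FASTA, GFF3
annotation (with RS-exon isoforms), per-base conservation and per-sample
coverage bedGraphs, STAR-dialect junction tables, and a sample manifest —
together with a truth table of every planted site.

The generative model:

* genes with long introns on both strands; random background sequence with a
  YAG|NN motif written at each planted RS point (transcription orientation);
* intronic coverage follows co-transcriptional decay,
  ``base_coverage * exp(-decay_rate * d)``, with a multiplicative step drop of
  ``step_fold ** min(1, u / usage_saturation)`` at each upstream RS point —
  recursion on nascent RNA saturates quickly, so even moderately used sites
  show the full sawtooth step while unused sites show none;
* per-base coverage is Poisson around its expectation; conservation is a
  clipped Normal, high over planted motifs and low elsewhere;
* junction reads: the donor total is Poisson(read_depth) per intron and each
  RS junction draws Binomial(donor_total, usage) with per-replicate Normal
  noise on usage, the remainder going to the canonical junction;
* decoys fail exactly one criterion each (non-YAG motif, low conservation,
  overhang <= 5, missing coverage step, or presence in the poly(A) library).

All randomness stems from one seed; per-sample substreams are derived by a
stable CRC32 hash of the sample id so samples are reproducible independently.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    GenomeAnnotation,
    Gene,
    Transcript,
    derive_introns,
    reverse_complement,
    write_bedgraph,
    write_gff3,
)

DECOY_TYPES = ("motif", "conservation", "overhang", "sawtooth", "polyA")

DEFAULT_DONOR_MIX = {
    "GT": 0.35, "AT": 0.20, "GA": 0.10, "GC": 0.10,
    "AA": 0.10, "AC": 0.05, "CA": 0.05, "TA": 0.05,
}


@dataclass
class SimulationConfig:
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_length: int = 150
    intron_length: tuple[int, int] = (2800, 4000)
    spacer: int = 500
    donor_class_mix: dict = field(default_factory=lambda: dict(DEFAULT_DONOR_MIX))
    rs_exon_fraction: float = 0.9
    rs_exon_length: int = 90
    cryptic_fraction: float = 0.25
    cryptic_cov_fold: float = 3.0
    usage_by_condition: dict = field(
        default_factory=lambda: {"ctrl": 0.25, "ko": 0.05}
    )
    usage_sd: float = 0.03
    n_null_rss: int = 20
    step_fold: float = 4.0
    #: usage at which the coverage step saturates to the full step_fold
    usage_saturation: float = 0.2
    base_coverage: float = 30.0
    exon_coverage: float = 150.0
    decay_rate: float = 1e-4
    read_depth: int = 200
    replicates: int = 2 + 1  # per condition
    decoys_per_type: int = 4
    polyA_leak_fraction: float = 0.0
    cons_high_mean: float = 0.85
    cons_low_mean: float = 0.65
    cons_high_fraction: float = 0.5
    cons_background: float = 0.08
    cons_sd: float = 0.05
    decoy_cons_mean: float = 0.2
    total_mapped_reads: int = 50_000_000
    seed: int = 0

    def __post_init__(self):
        probs = np.array(list(self.donor_class_mix.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("donor_class_mix probabilities must sum to 1")
        for u in self.usage_by_condition.values():
            if not 0 < u < 1:
                raise ValueError("usage means must lie in (0,1)")
        if self.step_fold < 1:
            raise ValueError("step_fold must be >= 1")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")

    @property
    def conditions(self) -> list[str]:
        return list(self.usage_by_condition)

    @property
    def ctrl_condition(self) -> str:
        return self.conditions[0]


TRUTH_COLUMNS = [
    "rss_id", "gene_id", "chrom", "strand", "intron_start", "intron_end",
    "rs_point", "motif3", "donor2", "kind", "stratum", "rs_exon_start",
    "rs_exon_end", "cryptic", "diff_status",
]


def _sample_rng(cfg: SimulationConfig, sample_id: str) -> np.random.Generator:
    return np.random.default_rng(
        [cfg.seed, zlib.crc32(sample_id.encode()) & 0x7FFFFFFF]
    )


def _plant_motif(seq: np.ndarray, rs_point: int, strand: str, motif3: str, donor2: str):
    """Write the acceptor/donor bases around rs_point in genomic orientation."""
    if strand == "+":
        seq[rs_point - 3 : rs_point] = list(motif3)
        seq[rs_point : rs_point + 2] = list(donor2)
    else:
        seq[rs_point : rs_point + 3] = list(reverse_complement(motif3))
        seq[rs_point - 2 : rs_point] = list(reverse_complement(donor2))


def simulate_genome(cfg: SimulationConfig):
    """Build (sequences, annotation, truth table).

    Returns ``(seqs: dict chrom->str, ann: GenomeAnnotation, truth:
    pd.DataFrame)``.  One true RSS is planted per intron; decoys (one extra
    RSS each) go into the first introns in genomic order, cycling over the
    five decoy types.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    n_introns_per_gene = cfg.exons_per_gene - 1
    if n_introns_per_gene < 1:
        raise ValueError("need >= 2 exons per gene")
    lo, hi = cfg.intron_length
    if lo < 2400:
        raise ValueError("intron_length range too small for planted-site margins")

    ann = GenomeAnnotation()
    cursors: dict[str, int] = {}
    gene_layouts = []  # (gene_id, chrom, strand, exons, introns[(start,end)])
    for gi in range(cfg.n_genes):
        chrom = "chrS1" if gi < (cfg.n_genes + 1) // 2 else "chrS2"
        strand = "+" if gi % 2 == 0 else "-"
        gid = f"G{gi:03d}"
        pos = cursors.get(chrom, cfg.spacer)
        exons = []
        introns = []
        for e in range(cfg.exons_per_gene):
            exons.append((pos, pos + cfg.exon_length))
            pos += cfg.exon_length
            if e < n_introns_per_gene:
                ilen = int(rng.integers(lo, hi + 1))
                introns.append((pos, pos + ilen))
                pos += ilen
        cursors[chrom] = pos + cfg.spacer
        ann.genes[gid] = Gene(gid, chrom, strand, exons[0][0], exons[-1][1])
        ann.transcripts[f"{gid}.t1"] = Transcript(
            f"{gid}.t1", gid, chrom, strand, list(exons)
        )
        gene_layouts.append((gid, chrom, strand, exons, introns))

    seqs = {
        chrom: rng.choice(list("ACGT"), size=end).astype("U1")
        for chrom, end in cursors.items()
    }

    # --- plant sites -------------------------------------------------------
    donors = list(cfg.donor_class_mix)
    donor_p = np.array(list(cfg.donor_class_mix.values()), dtype=float)
    truth_rows = []
    intron_counter = 0
    n_decoys = cfg.decoys_per_type * len(DECOY_TYPES)
    true_sites = []

    for gid, chrom, strand, exons, introns in gene_layouts:
        for (istart, iend) in introns:
            ilen = iend - istart
            # primary (true) site ~40% into the intron and decoy ~70%, both
            # measured along transcription (strand-symmetric) and respecting
            # sawtooth-window margins

            def _genomic(offset: int) -> int:
                return istart + offset if strand == "+" else iend - offset

            rs1 = _genomic(int(rng.integers(int(0.32 * ilen), int(0.42 * ilen))))
            planted = [("true", rs1)]
            if intron_counter < n_decoys:
                decoy_kind = DECOY_TYPES[intron_counter % len(DECOY_TYPES)]
                rs2 = _genomic(int(rng.integers(int(0.62 * ilen), int(0.72 * ilen))))
                planted.append((f"decoy_{decoy_kind}", rs2))
            intron_counter += 1
            for kind, rs in planted:
                donor2 = donors[int(rng.choice(len(donors), p=donor_p))]
                y = str(rng.choice(["C", "T"]))
                motif3 = ("A" + "AG") if kind == "decoy_motif" else (y + "AG")
                _plant_motif(seqs[chrom], rs, strand, motif3, donor2)
                if kind == "decoy_conservation":
                    stratum = "decoy"
                elif kind.startswith("decoy"):
                    stratum = "high"
                else:
                    stratum = (
                        "high" if rng.random() < cfg.cons_high_fraction else "low"
                    )
                truth_rows.append(
                    {
                        "rss_id": f"{gid}:{rs}",
                        "gene_id": gid, "chrom": chrom, "strand": strand,
                        "intron_start": istart, "intron_end": iend,
                        "rs_point": rs, "motif3": motif3, "donor2": donor2,
                        "kind": kind, "stratum": stratum,
                        "rs_exon_start": -1, "rs_exon_end": -1,
                        "cryptic": False, "diff_status": "stable",
                    }
                )
                if kind == "true":
                    true_sites.append(len(truth_rows) - 1)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    # --- differential status, RS-exons, cryptic flags ----------------------
    order = rng.permutation(len(true_sites))
    null_idx = {true_sites[i] for i in order[: cfg.n_null_rss]}
    for i in true_sites:
        if i not in null_idx:
            truth.loc[i, "diff_status"] = "lost"

    rs_exon_rows = [
        i for i in true_sites if rng.random() < cfg.rs_exon_fraction
    ]
    for i in rs_exon_rows:
        row = truth.loc[i]
        if row["strand"] == "+":
            ex = (int(row["rs_point"]), int(row["rs_point"]) + cfg.rs_exon_length)
        else:
            ex = (int(row["rs_point"]) - cfg.rs_exon_length, int(row["rs_point"]))
        truth.loc[i, ["rs_exon_start", "rs_exon_end"]] = ex
        truth.loc[i, "cryptic"] = bool(rng.random() < cfg.cryptic_fraction)

    # RS-exon isoforms: one extra transcript per gene carrying all RS-exons
    for gid in truth.loc[truth["rs_exon_start"] >= 0, "gene_id"].unique():
        base = ann.transcripts[f"{gid}.t1"]
        extra = [
            (int(a), int(b))
            for a, b in truth.loc[
                (truth["gene_id"] == gid) & (truth["rs_exon_start"] >= 0),
                ["rs_exon_start", "rs_exon_end"],
            ].itertuples(index=False)
        ]
        ann.transcripts[f"{gid}.t2"] = Transcript(
            f"{gid}.t2", gid, base.chrom, base.strand,
            sorted(base.exons + extra),
        )

    # polyA leakage of true sites (over and above the polyA decoys)
    if cfg.polyA_leak_fraction > 0:
        k = int(round(cfg.polyA_leak_fraction * len(true_sites)))
        for i in true_sites[:k]:
            truth.loc[i, "kind"] = "true_polyA_leak"

    derive_introns(ann)
    seq_strings = {chrom: "".join(arr) for chrom, arr in seqs.items()}
    return seq_strings, ann, truth


# ---------------------------------------------------------------------------
# Tracks


def _intron_expectation(cfg, ilen, site_offsets_usages, strand_agnostic=True):
    """Expected intronic coverage along transcription offsets 0..ilen-1."""
    d = np.arange(ilen)
    expect = cfg.base_coverage * np.exp(-cfg.decay_rate * d)
    for off, u in site_offsets_usages:
        if u <= 0:
            continue
        factor = cfg.step_fold ** -min(1.0, u / cfg.usage_saturation)
        expect[off:] *= factor
    return expect


def simulate_tracks(truth: pd.DataFrame, ann: GenomeAnnotation, cfg: SimulationConfig,
                    sample_id: str, condition: str, library: str = "total"):
    """Per-sample coverage blocks {chrom: {start: values}} (Poisson draws)."""
    rng = _sample_rng(cfg, f"{sample_id}/coverage")
    blocks: dict[str, dict[int, np.ndarray]] = {}
    for gid, gene in ann.genes.items():
        tx = ann.transcripts[f"{gid}.t1"]
        chrom = tx.chrom
        blocks.setdefault(chrom, {})
        for (a, b) in tx.exons:
            lam = np.full(b - a, cfg.exon_coverage)
            blocks[chrom][a] = rng.poisson(lam).astype(float)
        if library == "polyA":
            # mature transcripts only: cryptic RS-exons are included in a
            # fraction of mRNAs and show signal; the rest of the intron is dark
            for row in truth[(truth["gene_id"] == gid) & truth["cryptic"]].itertuples(index=False):
                lam = np.full(
                    int(row.rs_exon_end - row.rs_exon_start),
                    cfg.cryptic_cov_fold * cfg.base_coverage,
                )
                blocks[chrom][int(row.rs_exon_start)] = rng.poisson(lam).astype(float)
            continue
        for intr in ann.introns_by_transcript[f"{gid}.t1"]:
            ilen = intr.end - intr.start
            sites = truth[
                (truth["gene_id"] == gid)
                & (truth["intron_start"] == intr.start)
            ]
            offs = []
            for row in sites.itertuples(index=False):
                if row.kind == "decoy_sawtooth":
                    continue  # planted without a coverage step
                if row.kind.startswith("true") and row.diff_status == "lost":
                    u = cfg.usage_by_condition.get(
                        condition, cfg.usage_by_condition[cfg.ctrl_condition]
                    )
                else:
                    u = cfg.usage_by_condition[cfg.ctrl_condition]
                off = (
                    row.rs_point - intr.start
                    if intr.strand == "+"
                    else intr.end - row.rs_point
                )
                offs.append((off, u, row))
            expect = _intron_expectation(cfg, ilen, [(o, u) for o, u, _ in offs])
            if intr.strand == "-":
                expect = expect[::-1]
            blocks[chrom][intr.start] = rng.poisson(expect).astype(float)
    return blocks


def simulate_conservation(truth: pd.DataFrame, ann: GenomeAnnotation,
                          cfg: SimulationConfig):
    """Conservation blocks: low clipped-Normal background over gene spans,
    stratum-specific means over the 5-nt planted motifs."""
    rng = np.random.default_rng([cfg.seed, 202])
    blocks: dict[str, dict[int, np.ndarray]] = {}
    span_arrays = {}
    for gid, gene in ann.genes.items():
        vals = rng.normal(cfg.cons_background, cfg.cons_sd, gene.end - gene.start)
        span_arrays[gid] = np.clip(vals, 0.0, 1.0)
    means = {"high": cfg.cons_high_mean, "low": cfg.cons_low_mean,
             "decoy": cfg.decoy_cons_mean}
    for row in truth.itertuples(index=False):
        gene = ann.genes[row.gene_id]
        rs = row.rs_point
        a = rs - 3 if row.strand == "+" else rs - 2
        vals = np.clip(rng.normal(means[row.stratum], cfg.cons_sd, 5), 0.0, 1.0)
        span_arrays[row.gene_id][a - gene.start : a - gene.start + 5] = vals
    for gid, gene in ann.genes.items():
        blocks.setdefault(gene.chrom, {})[gene.start] = np.round(
            span_arrays[gid], 4
        )
    return blocks


# ---------------------------------------------------------------------------
# Junctions


def simulate_junctions(truth: pd.DataFrame, ann: GenomeAnnotation,
                       cfg: SimulationConfig, sample_id: str, condition: str,
                       library: str = "total") -> list[tuple]:
    """Rows of the SJ-dialect table for one sample.

    Returns tuples (chrom, start0, end0, strand, unique, overhang) in 0-based
    half-open coordinates (conversion happens in the writer).
    """
    rng = _sample_rng(cfg, f"{sample_id}/junctions")
    rows = []
    for gid in ann.genes:
        for intr in ann.introns_by_transcript[f"{gid}.t1"]:
            donor_total = int(rng.poisson(cfg.read_depth))
            if donor_total == 0:
                continue
            remaining = donor_total
            sites = truth[
                (truth["gene_id"] == gid) & (truth["intron_start"] == intr.start)
            ]
            for row in sites.itertuples(index=False):
                in_polyA_file = row.kind in ("decoy_polyA", "true_polyA_leak")
                if library == "polyA" and not in_polyA_file:
                    continue
                if row.kind.startswith("true") and row.diff_status == "lost":
                    mean_u = cfg.usage_by_condition.get(
                        condition, cfg.usage_by_condition[cfg.ctrl_condition]
                    )
                else:
                    mean_u = cfg.usage_by_condition[cfg.ctrl_condition]
                u = float(np.clip(rng.normal(mean_u, cfg.usage_sd), 0.0, 1.0))
                reads = int(rng.binomial(donor_total, u))
                if reads == 0:
                    continue
                remaining = max(remaining - reads, 0)
                if row.kind == "decoy_overhang":
                    overhang = int(rng.integers(1, 6))
                else:
                    overhang = int(rng.integers(10, 41))
                if intr.strand == "+":
                    j = (row.chrom, intr.start, row.rs_point, "+", reads, overhang)
                else:
                    j = (row.chrom, row.rs_point, intr.end, "-", reads, overhang)
                rows.append(j)
            if remaining > 0:
                rows.append(
                    (
                        intr.chrom, intr.start, intr.end, intr.strand,
                        remaining, int(rng.integers(20, 51)),
                    )
                )
    rows.sort()
    return rows


def _write_sj(rows: list[tuple], path: str) -> None:
    strand_code = {"+": 1, "-": 2}
    with open(path, "w") as fh:
        for chrom, s, e, strand, reads, over in rows:
            fh.write(
                f"{chrom}\t{s + 1}\t{e}\t{strand_code[strand]}\t0\t0\t"
                f"{reads}\t0\t{over}\n"
            )


def _write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = seqs[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Full experiment


def simulate_experiment(cfg: SimulationConfig, outdir: str) -> dict:
    """Emit the complete synthetic experiment into ``outdir``.

    Files: genome.fa, annotation.gff3, conservation.bedgraph, truth.tsv,
    manifest.tsv and per-sample ``<sample>.sj.tsv`` / ``<sample>.cov.bedgraph``
    for ``replicates`` samples per condition plus one poly(A) replicate.
    Deterministic for a given config and seed.
    """
    os.makedirs(outdir, exist_ok=True)
    seqs, ann, truth = simulate_genome(cfg)

    _write_fasta(seqs, os.path.join(outdir, "genome.fa"))
    write_gff3(ann, os.path.join(outdir, "annotation.gff3"))
    write_bedgraph(
        simulate_conservation(truth, ann, cfg),
        os.path.join(outdir, "conservation.bedgraph"),
    )
    truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)

    samples = []
    for cond in cfg.conditions:
        for r in range(1, cfg.replicates + 1):
            samples.append((f"{cond}_rep{r}", cond, "total"))
    samples.append((f"polyA_rep1", cfg.ctrl_condition, "polyA"))

    manifest_rows = []
    for sample_id, cond, library in samples:
        sj = os.path.join(outdir, f"{sample_id}.sj.tsv")
        cov = os.path.join(outdir, f"{sample_id}.cov.bedgraph")
        _write_sj(
            simulate_junctions(truth, ann, cfg, sample_id, cond, library), sj
        )
        write_bedgraph(
            simulate_tracks(truth, ann, cfg, sample_id, cond, library), cov
        )
        manifest_rows.append(
            (
                sample_id, cond, cfg.total_mapped_reads, library,
                os.path.basename(sj), os.path.basename(cov),
            )
        )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "sample_id", "condition", "total_mapped_reads", "library",
            "junction_path", "coverage_path",
        ],
    )
    manifest.to_csv(os.path.join(outdir, "manifest.tsv"), sep="\t", index=False)
    return {
        "outdir": outdir,
        "fasta": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "conservation": os.path.join(outdir, "conservation.bedgraph"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
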