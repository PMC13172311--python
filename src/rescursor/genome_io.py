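"""Annotation, junction, track and sequence I/O.

All internal coordinates are 0-based half-open; conversion to and from the
1-based conventions of GFF3 and the STAR ``SJ.out.tab`` dialect happens only
at file boundaries.  "Upstream"/"downstream", exon 3' ends and intron
transcription indices always follow transcription orientation: for minus-strand
genes the first intron is the genomically *last* gap and motif logic runs on
the reverse complement.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed or internally inconsistent annotation input."""


# ---------------------------------------------------------------------------
# Annotation model


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class Transcript:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    #: exon intervals, 0-based half-open, sorted by genomic start
    exons: list[tuple[int, int]]


@dataclass(frozen=True)
class Intron:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    #: 0-based index in transcription order (reversed on the minus strand)
    tx_index: int
    #: genomic coordinate of the upstream (donor) exon's 3' end boundary;
    #: equals ``start`` on '+' and ``end`` on '-'
    donor: int

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def acceptor(self) -> int:
        """Genomic boundary coordinate of the canonical 3' splice site."""
        return self.end if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    #: filled by :func:`derive_introns`
    introns_by_transcript: dict[str, list[Intron]] = field(default_factory=dict)
    #: per gene, introns deduplicated by (interval, donor)
    gene_introns: dict[str, list[Intron]] = field(default_factory=dict)

    def transcripts_of_gene(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def exons_of_gene(self, gene_id: str) -> list[tuple[int, int]]:
        out = set()
        for t in self.transcripts_of_gene(gene_id):
            out.update(t.exons)
        return sorted(out)

    def validate(self) -> None:
        for tx in self.transcripts.values():
            if tx.strand not in "+-":
                raise AnnotationError(f"transcript {tx.tx_id}: bad strand {tx.strand!r}")
            if not tx.exons:
                raise AnnotationError(f"transcript {tx.tx_id}: no exons")
            exons = sorted(tx.exons)
            if exons != tx.exons:
                tx.exons = exons
            prev_end = None
            for (a, b) in exons:
                if a >= b:
                    raise AnnotationError(f"transcript {tx.tx_id}: empty exon [{a},{b})")
                if prev_end is not None:
                    if a < prev_end:
                        raise AnnotationError(
                            f"transcript {tx.tx_id}: overlapping exons at {a}"
                        )
                    if a == prev_end:
                        raise AnnotationError(
                            f"transcript {tx.tx_id}: abutting exons give a "
                            f"zero-length intron at {a}"
                        )
                prev_end = b


def derive_introns(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Populate per-transcript introns and the per-gene deduplicated set.

    For consecutive exons ``[a,b)`` and ``[c,d)`` in genomic order the intron
    is ``[b,c)``; its transcription index counts from the 5' end of the
    transcript, so on the minus strand the genomically last gap is index 0.
    """
    ann.validate()
    for tx in ann.transcripts.values():
        introns: list[Intron] = []
        n = len(tx.exons) - 1
        for i in range(n):
            b = tx.exons[i][1]
            c = tx.exons[i + 1][0]
            tx_index = i if tx.strand == "+" else n - 1 - i
            donor = b if tx.strand == "+" else c
            introns.append(
                Intron(tx.chrom, b, c, tx.strand, tx.gene_id, tx_index, donor)
            )
        ann.introns_by_transcript[tx.tx_id] = introns
    ann.gene_introns = {}
    for gid in ann.genes:
        seen: dict[tuple[int, int, int], Intron] = {}
        for tx in ann.transcripts_of_gene(gid):
            for intr in ann.introns_by_transcript.get(tx.tx_id, []):
                seen.setdefault((intr.start, intr.end, intr.donor), intr)
        ann.gene_introns[gid] = sorted(seen.values(), key=lambda i: (i.start, i.end))
    return ann


# ---------------------------------------------------------------------------
# Annotation readers / writer


def read_annotation(path: str, fmt: str = "gff3") -> GenomeAnnotation:
    """Read a GFF3 or BED12 file into a validated :class:`GenomeAnnotation`."""
    if fmt == "gff3":
        ann = _read_gff3(path)
    elif fmt == "bed12":
        ann = _read_bed12(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    ann.validate()
    return ann


def _read_gff3(path: str) -> GenomeAnnotation:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"cannot parse GFF3 {path}: {exc}") from exc

    ann = GenomeAnnotation()
    for g in db.features_of_type("gene"):
        gid = g.id
        ann.genes[gid] = Gene(gid, g.seqid, g.strand, g.start - 1, g.end)
    for ftype in ("mRNA", "transcript"):
        for t in db.features_of_type(ftype):
            parents = [p.id for p in db.parents(t, featuretype="gene")]
            gid = parents[0] if parents else t.attributes.get("Parent", [t.id])[0]
            if gid not in ann.genes:
                ann.genes[gid] = Gene(gid, t.seqid, t.strand, t.start - 1, t.end)
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(t, featuretype="exon")
            )
            if not exons:
                raise AnnotationError(f"transcript {t.id}: no exon children")
            ann.transcripts[t.id] = Transcript(t.id, gid, t.seqid, t.strand, exons)
    n_orphans = sum(
        1
        for e in db.features_of_type("exon")
        if not list(db.parents(e, featuretype=("mRNA", "transcript")))
    )
    if n_orphans:
        raise AnnotationError(f"{n_orphans} exon feature(s) with no transcript parent")
    return ann


def _read_bed12(path: str) -> GenomeAnnotation:
    ann = GenomeAnnotation()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}:{lineno}: BED12 needs 12 columns")
            try:
                chrom, start = f[0], int(f[1])
                name, strand = f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
            tx_id = name
            gid = f[3].split(".")[0]
            if gid not in ann.genes:
                ann.genes[gid] = Gene(gid, chrom, strand, exons[0][0], exons[-1][1])
            ann.transcripts[tx_id] = Transcript(tx_id, gid, chrom, strand, exons)
    return ann


def write_gff3(ann: GenomeAnnotation, path: str) -> None:
    """Write the annotation back to GFF3 (exon intervals round-trip exactly)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(ann.genes):
            g = ann.genes[gid]
            fh.write(
                f"{g.chrom}\trescursor\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}\n"
            )
            for tx in sorted(ann.transcripts_of_gene(gid), key=lambda t: t.tx_id):
                fh.write(
                    f"{tx.chrom}\trescursor\tmRNA\t{tx.exons[0][0] + 1}\t"
                    f"{tx.exons[-1][1]}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.tx_id};Parent={gid}\n"
                )
                for k, (a, b) in enumerate(tx.exons, 1):
                    fh.write(
                        f"{tx.chrom}\trescursor\texon\t{a + 1}\t{b}\t.\t"
                        f"{tx.strand}\t.\tID={tx.tx_id}.e{k};Parent={tx.tx_id}\n"
                    )


# ---------------------------------------------------------------------------
# Junctions


@dataclass(frozen=True)
class JunctionRecord:
    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    unique_reads: int
    max_overhang: int

    def __post_init__(self):
        if self.intron_start >= self.intron_end:
            raise ValueError(f"junction start {self.intron_start} >= end {self.intron_end}")
        if self.unique_reads < 0 or self.max_overhang < 0:
            raise ValueError("negative read count or overhang")


_SJ_STRAND = {1: "+", 2: "-"}


def read_junctions(
    path: str, dialect: str = "star_sj", keep_undetermined: bool = False
) -> list[JunctionRecord]:
    """Read a STAR ``SJ.out.tab``-style table.

    Columns: chrom, first and last intronic base (1-based inclusive), strand
    code (0 undetermined / 1 + / 2 -), motif code, annotated flag, unique
    reads, multimapping reads (ignored), max overhang.  Junctions with strand
    code 0 are dropped (counted) unless ``keep_undetermined``.
    """
    if dialect != "star_sj":
        raise ValueError(f"unknown junction dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=[
                "chrom", "first", "last", "strand_code", "motif",
                "annotated", "unique", "multi", "overhang",
            ],
            dtype={
                "chrom": str, "first": np.int64, "last": np.int64,
                "strand_code": np.int64, "motif": np.int64,
                "annotated": np.int64, "unique": np.int64,
                "multi": np.int64, "overhang": np.int64,
            },
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"cannot parse junction table {path}: {exc}") from exc
    if (df["unique"] < 0).any() or (df["overhang"] < 0).any():
        raise ValueError(f"{path}: negative unique-read or overhang value")
    if (df["first"] > df["last"]).any():
        raise ValueError(f"{path}: junction with start > end")
    records: list[JunctionRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        if row.strand_code == 0 and not keep_undetermined:
            n_dropped += 1
            continue
        strand = _SJ_STRAND.get(row.strand_code, ".")
        records.append(
            JunctionRecord(
                row.chrom, int(row.first) - 1, int(row.last), strand,
                int(row.unique), int(row.overhang),
            )
        )
    if n_dropped:
        log.info("%s: dropped %d undetermined-strand junction(s)", path, n_dropped)
    return records


def write_junctions(records: list[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            code = 1 if r.strand == "+" else 2 if r.strand == "-" else 0
            fh.write(
                f"{r.chrom}\t{r.intron_start + 1}\t{r.intron_end}\t{code}\t0\t0\t"
                f"{r.unique_reads}\t0\t{r.max_overhang}\n"
            )


# ---------------------------------------------------------------------------
# Per-base signal tracks


class SignalTrack:
    """Sparse per-base numeric track (RNA-seq coverage or conservation).

    Positions absent from the underlying bedGraph read as 0.  Coverage values
    must be non-negative; conservation values must additionally be <= 1.
    """

    def __init__(self, kind: str = "coverage"):
        if kind not in ("coverage", "conservation"):
            raise ValueError(f"unknown track kind {kind!r}")
        self.kind = kind
        # chrom -> (starts, ends, values), sorted, non-overlapping
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def add_intervals(self, chrom, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(ends <= starts):
            raise ValueError(f"{chrom}: empty or inverted bedGraph interval")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping bedGraph intervals")
        if np.any(values < 0):
            raise ValueError(f"{chrom}: negative {self.kind} value")
        if self.kind == "conservation" and np.any(values > 1):
            raise ValueError(f"{chrom}: conservation value > 1")
        if chrom in self._data:
            s0, e0, v0 = self._data[chrom]
            starts = np.concatenate([s0, starts])
            ends = np.concatenate([e0, ends])
            values = np.concatenate([v0, values])
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping bedGraph intervals")
        self._data[chrom] = (starts, ends, values)

    def _slice(self, chrom, start, end):
        if chrom not in self._data or end <= start:
            return None
        starts, ends, values = self._data[chrom]
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i0 >= i1:
            return None
        return starts[i0:i1], ends[i0:i1], values[i0:i1]

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over [start, end); absent positions are 0."""
        n = end - start
        out = np.zeros(max(n, 0))
        sl = self._slice(chrom, start, end)
        if sl is None:
            return out
        s, e, v = sl
        s = np.clip(s - start, 0, n)
        e = np.clip(e - start, 0, n)
        d = np.zeros(n + 1)
        np.add.at(d, s, v)
        np.add.at(d, e, -v)
        return np.cumsum(d[:-1])

    def covered_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean per-base mask of positions stored in the track."""
        n = end - start
        out = np.zeros(n + 1)
        sl = self._slice(chrom, start, end)
        if sl is not None:
            s, e, _ = sl
            np.add.at(out, np.clip(s - start, 0, n), 1.0)
            np.add.at(out, np.clip(e - start, 0, n), -1.0)
        return np.cumsum(out[:-1]) > 0

    def point(self, chrom: str, pos: int) -> float:
        return float(self.window(chrom, pos, pos + 1)[0])

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty window")
        return float(self.window(chrom, start, end).mean())


def read_track(path: str, kind: str = "coverage") -> SignalTrack:
    """Read a bedGraph (chrom start end value; 0-based half-open)."""
    track = SignalTrack(kind)
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        track.add_intervals(
            str(chrom), sub["start"].values, sub["end"].values, sub["value"].values
        )
    return track


def write_bedgraph(chrom_values: dict[str, dict[int, np.ndarray]], path: str) -> None:
    """Write dense blocks to bedGraph, merging runs of equal adjacent values.

    ``chrom_values`` maps chrom -> {block_start: dense value array}.
    Zero-valued runs are omitted (absent positions read back as 0).
    """
    buf = io.StringIO()
    for chrom in sorted(chrom_values):
        for bstart in sorted(chrom_values[chrom]):
            vals = np.asarray(chrom_values[chrom][bstart])
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            run_starts = np.concatenate([[0], change])
            run_ends = np.concatenate([change, [vals.size]])
            for rs, re_ in zip(run_starts, run_ends):
                v = vals[rs]
                if v == 0:
                    continue
                if float(v).is_integer():
                    vtxt = str(int(v))
                else:
                    vtxt = f"{v:.4f}"
                buf.write(f"{chrom}\t{bstart + rs}\t{bstart + re_}\t{vtxt}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Sequence access


def fetch_sequence(fasta, chrom: str, start: int, end: int, strand: str = "+") -> str:
    """Fetch an uppercase slice; minus strand returns the reverse complement.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> sequence
    supporting ``len`` and slicing).
    """
    n = len(fasta[chrom])
    if start < 0 or end > n or start > end:
        raise ValueError(f"interval [{start},{end}) out of bounds for {chrom} (len {n})")
    seq = str(fasta[chrom][start:end]).upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        log.warning("%s:[%d,%d): non-ACGTN characters %s", chrom, start, end, bad)
    return reverse_complement(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# Sample manifest


MANIFEST_COLUMNS = [
    "sample_id", "condition", "total_mapped_reads", "library",
    "junction_path", "coverage_path",
]


def read_manifest(path: str) -> pd.DataFrame:
    """Read and validate the sample manifest TSV; paths resolved relative to it."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"manifest {path}: duplicate sample_id")
    if (df["total_mapped_reads"] <= 0).any():
        raise ValueError(f"manifest {path}: total_mapped_reads must be positive")
    bad = set(df["library"]) - {"total", "polyA"}
    if bad:
        raise ValueError(f"manifest {path}: unknown library type(s) {bad}")
    base = os.path.dirname(os.path.abspath(path))
    for col in ("junction_path", "coverage_path"):
        df[col] = [
            p if os.path.isabs(p) else os.path.join(base, p) for p in df[col]
        ]
    return df
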