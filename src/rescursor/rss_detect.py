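"""Detection of candidate recursive splice sites (RSSs).

A recursive splice site leaves a hybrid junction: the donor side coincides
exactly with an annotated exon 3' end while the acceptor side lands inside the
following intron at a YAG|NN motif — a pyrimidine-A-G acceptor immediately
followed by the two nucleotides that become the regenerated donor.  The
``rs_point`` of a candidate is the genomic boundary between the YAG and the
NN, expressed in 0-based coordinates: on the plus strand it is the junction's
acceptor coordinate (first retained base), on the minus strand likewise the
acceptor-side boundary (``intron_start``), with motif strings reported in
transcription orientation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import (
    GenomeAnnotation,
    Intron,
    JunctionRecord,
    fetch_sequence,
)

log = logging.getLogger(__name__)

YAG_RE = re.compile(r"^[CT]AG$")

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "N": {"A", "C", "G", "T"},
    "V": {"A", "C", "G"},
    "Y": {"C", "T"},
    "R": {"A", "G"},
}

#: mutually exclusive donor-dinucleotide partition plus the composite
#: classes used in reporting
DEFAULT_DONOR_PATTERNS = ["GT", "GV", "AT", "AV", "CN", "TN", "GN", "AN"]


@dataclass
class RssCandidate:
    gene_id: str
    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    intron_tx_index: int
    rs_point: int
    upstream_exon_3p: int
    motif3: str = ""
    donor2: str = ""
    unique_reads: int = 0
    overhang: int = 0
    conservation_mean: float = float("nan")
    sawtooth_fold: float = float("nan")
    sawtooth_p: float = float("nan")
    in_polyA: bool = False
    #: per-criterion outcomes: motif, conservation, overhang, sawtooth, polyA
    filter_flags: dict = field(default_factory=dict)
    status: str = "candidate"
    fail_reason: str = ""

    @property
    def rss_id(self) -> str:
        return f"{self.gene_id}:{self.rs_point}"

    @property
    def intron(self) -> tuple[int, int]:
        return (self.intron_start, self.intron_end)


CATALOG_COLUMNS = [
    "sample_id", "rss_id", "gene_id", "chrom", "strand", "intron_start",
    "intron_end", "intron_tx_index", "rs_point", "upstream_exon_3p", "motif3",
    "donor2", "unique_reads", "overhang", "conservation_mean",
    "sawtooth_fold", "sawtooth_p", "flags", "status", "fail_reason",
]


@dataclass
class RssCatalog:
    sample_id: str
    candidates: list[RssCandidate] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.candidates)

    def passing(self) -> list[RssCandidate]:
        return [c for c in self.candidates if c.status == "pass"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            flags = ";".join(
                f"{k}={'1' if v else '0'}" for k, v in sorted(c.filter_flags.items())
            )
            rows.append(
                (
                    self.sample_id, c.rss_id, c.gene_id, c.chrom, c.strand,
                    c.intron_start, c.intron_end, c.intron_tx_index, c.rs_point,
                    c.upstream_exon_3p, c.motif3, c.donor2, c.unique_reads,
                    c.overhang, c.conservation_mean, c.sawtooth_fold,
                    c.sawtooth_p, flags, c.status, c.fail_reason,
                )
            )
        return pd.DataFrame(rows, columns=CATALOG_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RssCatalog":
        sample_ids = df["sample_id"].unique().tolist() if len(df) else ["NA"]
        cat = cls(sample_id=sample_ids[0])
        for row in df.itertuples(index=False):
            flags = {}
            if isinstance(row.flags, str) and row.flags:
                for item in row.flags.split(";"):
                    k, v = item.split("=")
                    flags[k] = v == "1"
            cat.candidates.append(
                RssCandidate(
                    gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
                    intron_start=int(row.intron_start),
                    intron_end=int(row.intron_end),
                    intron_tx_index=int(row.intron_tx_index),
                    rs_point=int(row.rs_point),
                    upstream_exon_3p=int(row.upstream_exon_3p),
                    motif3=str(row.motif3), donor2=str(row.donor2),
                    unique_reads=int(row.unique_reads),
                    overhang=int(row.overhang),
                    conservation_mean=float(row.conservation_mean),
                    sawtooth_fold=float(row.sawtooth_fold),
                    sawtooth_p=float(row.sawtooth_p),
                    filter_flags=flags, status=str(row.status),
                    fail_reason="" if pd.isna(row.fail_reason) else str(row.fail_reason),
                )
            )
        return cat


# ---------------------------------------------------------------------------


def _excluded_acceptors(ann: GenomeAnnotation, gene_id: str, intron: Intron) -> set:
    """Acceptor coordinates vetoed as ordinary alternative 3' splice sites.

    An acceptor coinciding with the 5' start of a host-gene exon marks
    ordinary alternative splicing rather than recursion — unless that exon is
    fully contained within the host intron, in which case it is a putative
    RS-/cryptic exon and does not veto the candidate.
    """
    out = set()
    for (a, b) in ann.exons_of_gene(gene_id):
        contained = intron.start < a and b < intron.end
        if contained:
            continue
        out.add(a if intron.strand == "+" else b)
    return out


def find_hybrid_junctions(
    junctions: list[JunctionRecord],
    ann: GenomeAnnotation,
    min_margin: int = 20,
) -> list[tuple[JunctionRecord, str, Intron]]:
    """Match junctions whose donor is an annotated exon 3' end and whose
    acceptor lies strictly inside the following intron.

    Returns (junction, gene_id, host_intron) triples.  A junction matching
    donors in more than one gene is skipped with a log message; if several
    deduplicated introns of one gene host the acceptor, the longest is kept.
    ``min_margin`` keeps the rs_point at least that many nt from both intron
    boundaries (boundary-artifact guard).
    """
    donor_index: dict[tuple[str, str, int], list[tuple[str, Intron]]] = {}
    for gid, introns in ann.gene_introns.items():
        for intr in introns:
            donor_index.setdefault((intr.chrom, intr.strand, intr.donor), []).append(
                (gid, intr)
            )

    out: list[tuple[JunctionRecord, str, Intron]] = []
    n_unmatched = 0
    for j in junctions:
        donor = j.intron_start if j.strand == "+" else j.intron_end
        acceptor = j.intron_end if j.strand == "+" else j.intron_start
        hits = donor_index.get((j.chrom, j.strand, donor))
        if not hits:
            n_unmatched += 1
            continue
        genes = {gid for gid, _ in hits}
        if len(genes) > 1:
            log.info(
                "junction %s:%d-%d matches donors in %d genes; skipped",
                j.chrom, j.intron_start, j.intron_end, len(genes),
            )
            continue
        gid = genes.pop()
        hosts = [
            intr
            for _, intr in hits
            if intr.start + min_margin <= acceptor <= intr.end - min_margin
        ]
        if not hosts:
            n_unmatched += 1
            continue
        host = max(hosts, key=len)
        if acceptor in _excluded_acceptors(ann, gid, host):
            continue
        out.append((j, gid, host))
    if n_unmatched:
        log.debug("%d junction(s) without a hybrid donor/acceptor match", n_unmatched)
    return out


def call_motif(fasta, chrom: str, strand: str, rs_point: int) -> tuple[str, str, bool]:
    """Return (motif3, donor2, motif_pass) at ``rs_point``.

    ``motif3`` is the 3-nt acceptor ending at the boundary and ``donor2`` the
    2-nt regenerated donor following it, both in transcription orientation.
    The motif passes iff the acceptor matches ``[CT]AG``; any N in the 5-nt
    window fails with the flag kept for auditing.
    """
    if strand == "+":
        motif3 = fetch_sequence(fasta, chrom, rs_point - 3, rs_point, "+")
        donor2 = fetch_sequence(fasta, chrom, rs_point, rs_point + 2, "+")
    else:
        motif3 = fetch_sequence(fasta, chrom, rs_point, rs_point + 3, "-")
        donor2 = fetch_sequence(fasta, chrom, rs_point - 2, rs_point, "-")
    if "N" in motif3 + donor2:
        return motif3, donor2, False
    return motif3, donor2, bool(YAG_RE.match(motif3))


def classify_donor(donor2: str, pattern: str) -> bool:
    """True iff each base of ``donor2`` falls in the pattern letter's set.

    Patterns are 2-character IUPAC-like strings over {A,C,G,T,N,V,Y,R};
    N = any base, V = A/C/G.
    """
    if len(donor2) != 2 or any(b not in "ACGT" for b in donor2):
        raise ValueError(f"invalid donor dinucleotide {donor2!r}")
    if len(pattern) != 2:
        raise ValueError(f"invalid donor pattern {pattern!r}")
    for base, letter in zip(donor2, pattern):
        if letter not in IUPAC_SETS:
            raise ValueError(f"invalid pattern letter {letter!r}")
        if base not in IUPAC_SETS[letter]:
            return False
    return True


def build_catalog(
    sample_id: str,
    hybrid_junctions: list[tuple[JunctionRecord, str, Intron]],
    fasta,
) -> RssCatalog:
    """One candidate per unique (gene, rs_point): reads summed over junction
    records, overhang maximised, motif fields populated, deterministic
    (chrom, rs_point) ordering.  Motif-failing candidates are retained with
    status ``motif_fail`` for QC but can never pass filtering.
    """
    grouped: dict[tuple[str, int], RssCandidate] = {}
    for j, gid, intron in hybrid_junctions:
        rs_point = j.intron_end if j.strand == "+" else j.intron_start
        key = (gid, rs_point)
        if key in grouped:
            c = grouped[key]
            c.unique_reads += j.unique_reads
            c.overhang = max(c.overhang, j.max_overhang)
            continue
        motif3, donor2, ok = call_motif(fasta, j.chrom, j.strand, rs_point)
        grouped[key] = RssCandidate(
            gene_id=gid, chrom=j.chrom, strand=j.strand,
            intron_start=intron.start, intron_end=intron.end,
            intron_tx_index=intron.tx_index, rs_point=rs_point,
            upstream_exon_3p=intron.donor, motif3=motif3, donor2=donor2,
            unique_reads=j.unique_reads, overhang=j.max_overhang,
            filter_flags={"motif": ok},
            status="candidate" if ok else "motif_fail",
            fail_reason="" if ok else "motif",
        )
    cat = RssCatalog(sample_id=sample_id)
    cat.candidates = sorted(
        grouped.values(), key=lambda c: (c.chrom, c.rs_point, c.gene_id)
    )
    cat.stage_counts = {
        "hybrid": len(cat.candidates),
        "motif": sum(1 for c in cat.candidates if c.filter_flags.get("motif")),
    }
    return cat
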