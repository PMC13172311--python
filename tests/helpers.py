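"""Shared fixture builders and independent oracles for the test suite."""

import numpy as np

from rescursor.genome_io import (
    Gene,
    GenomeAnnotation,
    JunctionRecord,
    Transcript,
    derive_introns,
    reverse_complement,
)


def make_candidate(rs_point=1000, intron=(200, 2200), strand="+", overhang=20, **kw):
    from rescursor.rss_detect import RssCandidate

    return RssCandidate(
        gene_id="g1", chrom="chr1", strand=strand,
        intron_start=intron[0], intron_end=intron[1], intron_tx_index=0,
        rs_point=rs_point, upstream_exon_3p=intron[0] if strand == "+" else intron[1],
        motif3="CAG", donor2="GT", unique_reads=10, overhang=overhang,
        filter_flags={"motif": True}, **kw,
    )


def make_scan_fixture(n_genes=10, intron_len=300, exon_len=60, seed=11):
    """Random genome with alternating-strand two-exon genes plus a junction
    from the donor to *every* intronic position (saturating detection)."""
    rng = np.random.default_rng(seed)
    ann = GenomeAnnotation()
    pos = 50
    for gi in range(n_genes):
        gid = f"g{gi}"
        strand = "+" if gi % 2 == 0 else "-"
        exons = [
            (pos, pos + exon_len),
            (pos + exon_len + intron_len, pos + 2 * exon_len + intron_len),
        ]
        ann.genes[gid] = Gene(gid, "chrT", strand, exons[0][0], exons[-1][1])
        ann.transcripts[f"{gid}.t"] = Transcript(f"{gid}.t", gid, "chrT", strand, exons)
        pos = exons[-1][1] + 50
    derive_introns(ann)
    seqs = {"chrT": "".join(rng.choice(list("ACGT"), size=pos + 50))}

    junctions = []
    margin = 3
    for gid, introns in ann.gene_introns.items():
        for intr in introns:
            for p in range(intr.start + margin, intr.end - margin + 1):
                if intr.strand == "+":
                    junctions.append(
                        JunctionRecord("chrT", intr.start, p, "+", 5, 20)
                    )
                else:
                    junctions.append(
                        JunctionRecord("chrT", p, intr.end, "-", 5, 20)
                    )
    return seqs, ann, junctions


def brute_force_yag_scan(seqs, ann, margin=3):
    """Independent oracle: scan every intron for [CT]AG acceptors in
    transcription orientation and return the (gene_id, rs_point) set."""
    hits = set()
    for gid, introns in ann.gene_introns.items():
        for intr in introns:
            seq = seqs[intr.chrom]
            for p in range(intr.start + margin, intr.end - margin + 1):
                if intr.strand == "+":
                    motif = seq[p - 3 : p].upper()
                else:
                    motif = reverse_complement(seq[p : p + 3].upper())
                if motif[0] in "CT" and motif[1:] == "AG":
                    hits.add((gid, p))
    return hits


def revcomp_fixture(seqs, ann, junctions):
    """Mirror the whole fixture: reverse-complement every chromosome and flip
    all coordinates and strands.  Detection must be invariant under this map."""
    lengths = {c: len(s) for c, s in seqs.items()}
    seqs2 = {c: reverse_complement(s) for c, s in seqs.items()}
    flip = {"+": "-", "-": "+"}

    ann2 = GenomeAnnotation()
    for gid, g in ann.genes.items():
        L = lengths[g.chrom]
        ann2.genes[gid] = Gene(gid, g.chrom, flip[g.strand], L - g.end, L - g.start)
    for tid, tx in ann.transcripts.items():
        L = lengths[tx.chrom]
        exons = sorted((L - b, L - a) for a, b in tx.exons)
        ann2.transcripts[tid] = Transcript(tid, tx.gene_id, tx.chrom, flip[tx.strand], exons)
    derive_introns(ann2)

    junctions2 = [
        JunctionRecord(
            j.chrom,
            lengths[j.chrom] - j.intron_end,
            lengths[j.chrom] - j.intron_start,
            flip[j.strand],
            j.unique_reads,
            j.max_overhang,
        )
        for j in junctions
    ]
    return seqs2, ann2, junctions2


def pooled_t_closed_form(x, y):
    """Independent closed-form Student's t (pooled variance) and its
    two-tailed P from the t CDF via the regularized incomplete beta."""
    from scipy.special import betainc

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = betainc(df / 2, 0.5, df / (df + t * t))
    return float(t), float(p)


def fisher_two_sided_exact(a, b, c, d):
    """Exhaustive hypergeometric summation for the two-sided Fisher P,
    in exact integer arithmetic (gate matches the conventional 1+1e-7
    relative tolerance on the observed table probability)."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    num_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        num_k = comb(r1, k) * comb(r2, c1 - k)
        if num_k * 10**7 <= num_obs * (10**7 + 1):
            total += num_k
    return total / denom
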