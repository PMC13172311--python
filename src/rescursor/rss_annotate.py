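"""Downstream annotation of recursive splice sites.

Covers RS-exon association (does an annotated exon begin at the RS point?),
cryptic-exon evidence (coverage enrichment over the RS-exon), conservation
stratification and per-position profiles, position probability matrices for
sequence logos, donor-dinucleotide enrichment among gained/lost sites
(two-tailed Fisher), and over-representation of RS genes among alternative
splicing event classes (one-tailed hypergeometric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeAnnotation, SignalTrack, fetch_sequence
from .rss_detect import RssCandidate, classify_donor

log = logging.getLogger(__name__)

#: AS event classes (tandem ends/starts, cassette exon, intron retention,
#: alternative acceptor/donor, alternative first/last exon)
AS_TYPES = ["TE", "TS", "CE", "IR", "AA", "AD", "AF", "AL"]


@dataclass
class RsExonLink:
    rss_id: str
    exon: tuple[int, int] | None
    associated: bool
    coverage_fold: float = float("nan")
    cryptic: bool = False


@dataclass
class EnrichmentResult:
    label: str
    direction: str  # gained | lost | n/a
    table: tuple  # ((a, b), (c, d))
    odds_ratio: float
    p_value: float
    flagged: bool = False

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value))


# ---------------------------------------------------------------------------
# RS-exon association and cryptic-exon evidence


def associate_rs_exon(
    rss: RssCandidate, ann: GenomeAnnotation, tolerance_nt: int = 0
) -> RsExonLink:
    """Link an RSS to an annotated exon starting at its RS point.

    The RS acceptor AG is the RS-exon's 3' splice site, so the exon's 5'
    start (transcription orientation) must equal ``rs_point`` within
    ``tolerance_nt``, and the exon must end before the host intron's
    downstream exon.  Sites with no such exon are "zero-length" RS sites.
    """
    best: tuple[int, int] | None = None
    for (a, b) in ann.exons_of_gene(rss.gene_id):
        if not (rss.intron_start < a and b < rss.intron_end):
            continue
        start5 = a if rss.strand == "+" else b
        if abs(start5 - rss.rs_point) <= tolerance_nt:
            if best is None or (b - a) < (best[1] - best[0]):
                best = (a, b)
    return RsExonLink(rss.rss_id, best, best is not None)


def cryptic_exon_flag(
    link: RsExonLink,
    rss: RssCandidate,
    coverage: SignalTrack,
    fold_threshold: float = 2.0,
    epsilon: float = 0.5,
) -> RsExonLink:
    """Flag RS-exons with coverage enrichment over their intronic flanks.

    fold = (mean exon coverage + eps) / (mean flank coverage + eps), with
    flanks of the same width as the exon on each side, truncated to the host
    intron.  A fold above ``fold_threshold`` marks a likely cryptic exon.
    """
    if not link.associated or link.exon is None:
        raise ValueError(f"{link.rss_id}: cannot test cryptic evidence without an RS-exon")
    a, b = link.exon
    width = b - a
    exon_mean = coverage.mean(rss.chrom, a, b)
    flanks = []
    la, lb = max(rss.intron_start, a - width), a
    ra, rb = b, min(rss.intron_end, b + width)
    for (fa, fb) in ((la, lb), (ra, rb)):
        if fb > fa:
            flanks.append(coverage.window(rss.chrom, fa, fb))
    flank_mean = float(np.concatenate(flanks).mean()) if flanks else 0.0
    fold = (exon_mean + epsilon) / (flank_mean + epsilon)
    link.coverage_fold = fold
    link.cryptic = fold > fold_threshold
    return link


# ---------------------------------------------------------------------------
# Conservation stratification and profiles


def stratify_conservation(
    candidates: list[RssCandidate], threshold: float = 0.45
) -> dict[str, list[RssCandidate]]:
    """Partition into conserved (mean > threshold) and non-conserved sites.

    Sites exactly at the threshold go to "low" (logged), since the strata are
    defined by strict inequalities on both sides.
    """
    out = {"high": [], "low": []}
    n_boundary = 0
    for c in candidates:
        if c.conservation_mean > threshold:
            out["high"].append(c)
        else:
            if c.conservation_mean == threshold:
                n_boundary += 1
            out["low"].append(c)
    if n_boundary:
        log.info(
            "%d site(s) exactly at conservation %.2f assigned to 'low'",
            n_boundary, threshold,
        )
    return out


def conservation_profile(
    sites: list[tuple[str, int, str]],
    cons: SignalTrack,
    half_window: int = 15,
) -> np.ndarray:
    """Mean conservation per position in a window around aligned sites.

    ``sites`` are (chrom, position, strand); offset 0 is the site itself and
    offsets run in transcription orientation (reversed window on the minus
    strand).  Returns a vector of length ``2 * half_window + 1``.
    """
    if not sites:
        raise ValueError("empty site list")
    acc = np.zeros(2 * half_window + 1)
    for chrom, pos, strand in sites:
        w = cons.window(chrom, pos - half_window, pos + half_window + 1)
        acc += w[::-1] if strand == "-" else w
    return acc / len(sites)


def random_intronic_sites(
    candidates: list[RssCandidate],
    rng: np.random.Generator,
    margin: int = 20,
) -> list[tuple[str, int, str]]:
    """One random interior position per candidate, drawn from its own host
    intron — the matched background for conservation profiles."""
    out = []
    for c in candidates:
        lo, hi = c.intron_start + margin, c.intron_end - margin
        if hi <= lo:
            continue
        out.append((c.chrom, int(rng.integers(lo, hi)), c.strand))
    return out


def sequence_probability_matrix(
    sites: list[tuple[str, int, str]],
    fasta,
    half_window: int = 10,
) -> np.ndarray:
    """4 x (2*half_window + 1) base-probability matrix around aligned sites.

    Rows are A, C, G, T; columns sum to 1.  Ns are excluded from the column
    denominator.  Column ``half_window`` corresponds to offset 0 (the first
    base after the site boundary in transcription orientation).
    """
    if not sites:
        raise ValueError("empty site list")
    width = 2 * half_window + 1
    counts = np.zeros((4, width))
    row = {"A": 0, "C": 1, "G": 2, "T": 3}
    for chrom, pos, strand in sites:
        if strand == "+":
            seq = fetch_sequence(fasta, chrom, pos - half_window, pos + half_window + 1, "+")
        else:
            seq = fetch_sequence(fasta, chrom, pos - half_window, pos + half_window + 1, "-")
        for col, base in enumerate(seq):
            if base in row:
                counts[row[base], col] += 1
    denom = counts.sum(axis=0)
    if np.any(denom == 0):
        raise ValueError("a column has no unambiguous bases")
    return counts / denom


# ---------------------------------------------------------------------------
# Enrichment statistics


def donor_class_enrichment(
    diff_status: dict[str, str],
    donor_by_rss: dict[str, str],
    patterns: list[str],
    directions: tuple[str, ...] = ("gained", "lost"),
) -> list[EnrichmentResult]:
    """Two-tailed Fisher test of donor-pattern membership among
    gained (or lost) RSSs versus unchanged ones.

    For each pattern x direction the 2x2 table is
    [[direction & match, direction & no-match],
     [unchanged & match, unchanged & no-match]].
    """
    results = []
    for pattern in patterns:
        match = {
            rss_id: classify_donor(d2, pattern) for rss_id, d2 in donor_by_rss.items()
        }
        n_match_total = sum(match.values())
        for direction in directions:
            a = b = c = d = 0
            for rss_id, status in diff_status.items():
                if rss_id not in match:
                    continue
                m = match[rss_id]
                if status == direction:
                    a, b = a + m, b + (not m)
                elif status == "unchanged":
                    c, d = c + m, d + (not m)
            flagged = n_match_total == 0
            if flagged or (a + b == 0) or (c + d == 0):
                odds, p = float("nan"), 1.0
            else:
                odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            results.append(
                EnrichmentResult(
                    pattern, direction, ((a, b), (c, d)), float(odds), float(p),
                    flagged=flagged,
                )
            )
    return results


def read_as_events(path: str) -> tuple[pd.DataFrame, set]:
    """Read a gene -> AS-event-type TSV (columns gene_id, as_type).

    Returns the event table and the universe (every gene in the table,
    i.e. all genes tested for alternative splicing).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_id", "as_type"} - set(df.columns)
    if missing:
        raise ValueError(f"AS-event table {path}: missing columns {sorted(missing)}")
    unknown = set(df["as_type"]) - set(AS_TYPES)
    if unknown:
        log.warning("AS-event table %s: unknown type codes %s", path, sorted(unknown))
    return df, set(df["gene_id"])


def as_overlap_enrichment(
    rs_genes: set,
    as_events: pd.DataFrame,
    universe: set,
    types: list[str] | None = None,
) -> list[EnrichmentResult]:
    """One-tailed hypergeometric over-representation of RS genes per AS type.

    ``as_events`` has columns (gene_id, as_type); ``universe`` is the set of
    genes tested for alternative splicing.  P = P[X >= overlap] for X
    hypergeometric(|universe|, |type genes|, |rs_genes|).
    """
    offenders = sorted(rs_genes - universe)
    if offenders:
        raise ValueError(f"RS genes outside the AS universe: {offenders}")
    types = types if types is not None else AS_TYPES
    M, N = len(universe), len(rs_genes)
    results = []
    for as_type in types:
        type_genes = set(as_events.loc[as_events["as_type"] == as_type, "gene_id"])
        type_genes &= universe
        k = len(rs_genes & type_genes)
        n = len(type_genes)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        table = ((k, N - k), (n - k, M - N - (n - k)))
        results.append(
            EnrichmentResult(as_type, "n/a", table, float("nan"), min(p, 1.0))
        )
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.label, r.direction, r.table[0][0], r.table[0][1], r.table[1][0],
                r.table[1][1], r.odds_ratio, r.p_value, r.neg_log10_p, r.flagged,
            )
            for r in results
        ],
        columns=[
            "label", "direction", "n11", "n12", "n21", "n22",
            "odds_ratio", "p_value", "neg_log10_p", "flagged",
        ],
    )
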