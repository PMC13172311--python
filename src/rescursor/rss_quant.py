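"""Per-sample RS usage, differential usage between conditions, and
catalog-level metrics.

RS usage is the fraction of junction reads sharing the RSS's upstream-exon
donor that support the recursive junction.  The alternative ``flanking_exons``
mode normalizes to the canonical junction joining the two exons flanking the
host intron instead; the default ``upstream_exon`` mode bounds usage in
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import JunctionRecord
from .rss_detect import RssCandidate


@dataclass
class RssUsage:
    rss_id: str
    sample_id: str
    rs_reads: int
    donor_total_reads: int
    usage: float  # NaN when undefined
    testable: bool


@dataclass
class DifferentialRss:
    rss_id: str
    usage_ctrl: list
    usage_ko: list
    mean_ctrl: float
    mean_ko: float
    t_stat: float
    p_value: float
    status: str  # gained | lost | unchanged | untestable


def compute_usage(
    rss: RssCandidate,
    junctions: list[JunctionRecord],
    sample_id: str,
    mode: str = "upstream_exon",
    min_donor_reads: int = 10,
) -> RssUsage:
    """Usage of one RSS in one sample's junction table.

    ``upstream_exon``: denominator = all junction reads whose donor equals
    the RSS's upstream-exon 3' end (the RS junction included).
    ``flanking_exons``: denominator = reads of the canonical junction that
    joins the exons flanking the host intron.

    When the RS junction has zero reads, usage is 0 only if the donor still
    carries at least ``min_donor_reads`` (evidence of power); otherwise the
    sample is untestable for this site.
    """
    if mode not in ("upstream_exon", "flanking_exons"):
        raise ValueError(f"unknown usage mode {mode!r}")
    donor = rss.upstream_exon_3p
    rs_reads = 0
    donor_total = 0
    canonical = 0
    for j in junctions:
        if j.chrom != rss.chrom or j.strand != rss.strand:
            continue
        j_donor = j.intron_start if j.strand == "+" else j.intron_end
        j_acceptor = j.intron_end if j.strand == "+" else j.intron_start
        if j_donor != donor:
            continue
        donor_total += j.unique_reads
        if j_acceptor == rss.rs_point:
            rs_reads += j.unique_reads
        if (j.intron_start, j.intron_end) == (rss.intron_start, rss.intron_end):
            canonical += j.unique_reads
    denom = donor_total if mode == "upstream_exon" else canonical
    if denom <= 0:
        return RssUsage(rss.rss_id, sample_id, rs_reads, denom, float("nan"), False)
    if rs_reads == 0 and donor_total < min_donor_reads:
        return RssUsage(rss.rss_id, sample_id, 0, denom, float("nan"), False)
    return RssUsage(rss.rss_id, sample_id, rs_reads, denom, rs_reads / denom, True)


def usage_matrix(usages: list[RssUsage]) -> pd.DataFrame:
    """rss_id x sample_id matrix of usage values (NaN = untestable)."""
    df = pd.DataFrame(
        [(u.rss_id, u.sample_id, u.usage) for u in usages],
        columns=["rss_id", "sample_id", "usage"],
    )
    return df.pivot_table(
        index="rss_id", columns="sample_id", values="usage", dropna=False
    )


def student_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample two-tailed Student's t (pooled variance)."""
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def differential_usage(
    usage: pd.DataFrame,
    manifest: pd.DataFrame,
    ctrl: str,
    ko: str,
    alpha: float = 0.05,
) -> list[DifferentialRss]:
    """Student's t-test of per-replicate usage between two conditions.

    ``usage`` is the rss_id x sample_id matrix.  An RSS needs >= 2 defined
    replicates per condition; otherwise it is untestable.  Gained means
    higher usage in ``ko`` than in ``ctrl`` at P < alpha; lost the converse.
    No multiple-testing correction is applied (per-site P cutoff).
    """
    cond = dict(zip(manifest["sample_id"], manifest["condition"]))
    for c in (ctrl, ko):
        if c not in set(cond.values()):
            raise ValueError(f"condition {c!r} absent from manifest")
    ctrl_samples = [s for s in usage.columns if cond.get(s) == ctrl]
    ko_samples = [s for s in usage.columns if cond.get(s) == ko]
    out: list[DifferentialRss] = []
    for rss_id, row in usage.iterrows():
        x = row[ctrl_samples].dropna().to_numpy(dtype=float)
        y = row[ko_samples].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            out.append(
                DifferentialRss(
                    rss_id, list(x), list(y),
                    float(np.mean(x)) if len(x) else float("nan"),
                    float(np.mean(y)) if len(y) else float("nan"),
                    float("nan"), float("nan"), "untestable",
                )
            )
            continue
        mx, my = float(np.mean(x)), float(np.mean(y))
        if np.allclose(x, x[0]) and np.allclose(y, y[0]) and np.isclose(mx, my):
            t, p = 0.0, 1.0
        else:
            t, p = student_t(x, y)
        if p < alpha and my > mx:
            status = "gained"
        elif p < alpha and my < mx:
            status = "lost"
        else:
            status = "unchanged"
        out.append(DifferentialRss(rss_id, list(x), list(y), mx, my, t, p, status))
    return out


def differential_frame(diff: list[DifferentialRss]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (d.rss_id, d.mean_ctrl, d.mean_ko, d.t_stat, d.p_value, d.status)
            for d in diff
        ],
        columns=["rss_id", "mean_ctrl", "mean_ko", "t_stat", "p_value", "status"],
    )


def rss_per_million(n_pass: int, total_mapped_reads: int) -> float:
    """Final RSS count normalized per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return n_pass / (total_mapped_reads / 1e6)


def intron_length_correlation(
    counts: list[int], median_lengths: list[float]
) -> tuple[float, int]:
    """Pearson correlation of per-catalog RSS totals against the median
    length of introns hosting >= 1 passing RSS.  Returns (rho, n); rho is NaN
    when either variable has zero variance.
    """
    x = np.asarray(counts, dtype=float)
    y = np.asarray(median_lengths, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired catalogs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), len(x)
    rho = stats.pearsonr(x, y).statistic
    return float(rho), len(x)


def catalog_length_stats(catalog) -> tuple[int, float]:
    """(number of passing RSSs, median host-intron length) for one catalog."""
    passing = catalog.passing()
    if not passing:
        return 0, float("nan")
    lengths = {
        (c.gene_id, c.intron_start, c.intron_end): c.intron_end - c.intron_start
        for c in passing
    }
    return len(passing), float(np.median(sorted(lengths.values())))


def gain_loss_summary(
    diff: list[DifferentialRss], rs_exon_links: dict[str, bool]
) -> dict[str, int]:
    """Counts of gained/lost RSSs and their subsets lacking an RS-exon.

    ``rs_exon_links`` maps rss_id -> associated flag (from rss_annotate).
    """
    out = {"gained": 0, "lost": 0, "gained_no_rs_exon": 0, "lost_no_rs_exon": 0}
    for d in diff:
        if d.status not in ("gained", "lost"):
            continue
        out[d.status] += 1
        if not rs_exon_links.get(d.rss_id, False):
            out[f"{d.status}_no_rs_exon"] += 1
    return out
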