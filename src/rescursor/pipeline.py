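"""End-to-end orchestration: detect -> filter -> quantify -> diff -> annotate.

Each stage consumes and produces plain TSV tables so any stage can be rerun
from its predecessor's output alone.  Every written table carries a header
comment with the package version, the run seed and a hash of the filter
parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyfaidx

from . import __version__
from .genome_io import (
    GenomeAnnotation,
    derive_introns,
    read_annotation,
    read_junctions,
    read_manifest,
    read_track,
)
from .rss_annotate import (
    RsExonLink,
    as_overlap_enrichment,
    associate_rs_exon,
    cryptic_exon_flag,
    donor_class_enrichment,
    enrichment_frame,
    read_as_events,
    stratify_conservation,
)
from .rss_detect import (
    DEFAULT_DONOR_PATTERNS,
    RssCandidate,
    RssCatalog,
    build_catalog,
    find_hybrid_junctions,
)
from .rss_filter import FilterConfig, apply_filters, polyA_site_set
from .rss_quant import (
    catalog_length_stats,
    compute_usage,
    differential_frame,
    differential_usage,
    gain_loss_summary,
    intron_length_correlation,
    rss_per_million,
    usage_matrix,
)

log = logging.getLogger(__name__)


def param_hash(cfg: FilterConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str, seed: int, cfg: FilterConfig | None = None) -> None:
    """Write a TSV with a self-describing comment header, atomically."""
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(f"# rescursor {__version__}\tseed={seed}")
        if cfg is not None:
            fh.write(f"\tparams={param_hash(cfg)}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False)
    os.replace(tmp, path)


@dataclass
class PipelineResult:
    catalogs: dict[str, RssCatalog] = field(default_factory=dict)
    final_rss: dict[str, RssCandidate] = field(default_factory=dict)
    usage: pd.DataFrame | None = None
    diff: list = field(default_factory=list)
    rs_exon_links: dict[str, RsExonLink] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def detect_sample(
    sample_id: str,
    junction_path: str,
    ann: GenomeAnnotation,
    fasta,
    min_margin: int = 20,
) -> RssCatalog:
    """Hybrid-junction detection + motif calling for one sample."""
    junctions = read_junctions(junction_path)
    hybrids = find_hybrid_junctions(junctions, ann, min_margin=min_margin)
    return build_catalog(sample_id, hybrids, fasta)


def run_pipeline(
    manifest_path: str,
    annotation_path: str,
    fasta_path: str,
    conservation_path: str,
    cfg: FilterConfig | None = None,
    ctrl: str | None = None,
    ko: str | None = None,
    usage_mode: str = "upstream_exon",
    diff_alpha: float = 0.05,
    min_margin: int = 20,
    annotation_format: str = "gff3",
    as_events_path: str | None = None,
    outdir: str | None = None,
) -> PipelineResult:
    """Run the full analysis on a manifest of samples.

    Detection and filtering run per total-RNA sample (poly(A) samples
    contribute only the subtraction set).  The final RSS set is the union of
    per-sample passing sites; each is quantified in every total sample and
    tested between ``ctrl`` and ``ko`` conditions (defaults: first and second
    condition of the manifest).  Cryptic-exon evidence is scored on poly(A)
    coverage when a poly(A) sample is present (cryptic exons are retained in
    mature transcripts), falling back to the first control replicate.
    """
    cfg = cfg or FilterConfig()
    manifest = read_manifest(manifest_path)
    ann = derive_introns(read_annotation(annotation_path, annotation_format))
    fasta = pyfaidx.Fasta(fasta_path)
    conservation = read_track(conservation_path, kind="conservation")

    conditions = list(dict.fromkeys(manifest["condition"]))
    ctrl = ctrl or conditions[0]
    ko = ko or (conditions[1] if len(conditions) > 1 else conditions[0])

    total = manifest[manifest["library"] == "total"]
    polya = manifest[manifest["library"] == "polyA"]

    res = PipelineResult()

    # --- detect ------------------------------------------------------------
    for row in manifest.itertuples(index=False):
        res.catalogs[row.sample_id] = detect_sample(
            row.sample_id, row.junction_path, ann, fasta, min_margin
        )

    # --- filter ------------------------------------------------------------
    polyA_keys = polyA_site_set(
        [res.catalogs[s] for s in polya["sample_id"]], cfg.min_polyA_reads
    )
    junctions_by_sample = {}
    cryptic_cov = None
    for row in total.itertuples(index=False):
        coverage = read_track(row.coverage_path, kind="coverage")
        apply_filters(
            res.catalogs[row.sample_id], coverage, conservation, cfg, polyA_keys
        )
        junctions_by_sample[row.sample_id] = read_junctions(row.junction_path)
        if cryptic_cov is None or (row.condition == ctrl and cryptic_cov[0] != ctrl):
            cryptic_cov = (row.condition, coverage)
    if len(polya):
        cryptic_cov = ("polyA", read_track(polya.iloc[0]["coverage_path"], "coverage"))

    # --- final set and quantification --------------------------------------
    for sid in total["sample_id"]:
        for c in res.catalogs[sid].passing():
            res.final_rss.setdefault(c.rss_id, c)

    usages = []
    for sid in total["sample_id"]:
        for rss in res.final_rss.values():
            usages.append(
                compute_usage(rss, junctions_by_sample[sid], sid, usage_mode)
            )
    res.usage = (
        usage_matrix(usages)
        if usages
        else pd.DataFrame(columns=list(total["sample_id"]))
    )

    res.diff = differential_usage(res.usage, manifest, ctrl, ko, diff_alpha)

    # --- annotate -----------------------------------------------------------
    for rss_id, rss in res.final_rss.items():
        link = associate_rs_exon(rss, ann)
        if link.associated and cryptic_cov is not None:
            cryptic_exon_flag(link, rss, cryptic_cov[1])
        res.rs_exon_links[rss_id] = link

    diff_status = {d.rss_id: d.status for d in res.diff}
    donor_by_rss = {r: c.donor2 for r, c in res.final_rss.items()}
    enrich = donor_class_enrichment(
        diff_status, donor_by_rss, DEFAULT_DONOR_PATTERNS
    )
    as_enrich = None
    if as_events_path:
        as_events, universe = read_as_events(as_events_path)
        rs_genes = {c.gene_id for c in res.final_rss.values()} & universe
        as_enrich = as_overlap_enrichment(rs_genes, as_events, universe)

    # --- summary metrics ----------------------------------------------------
    per_sample = {}
    counts, medians = [], []
    for row in total.itertuples(index=False):
        cat = res.catalogs[row.sample_id]
        n_pass, med = catalog_length_stats(cat)
        counts.append(n_pass)
        medians.append(med)
        per_sample[row.sample_id] = {
            "n_pass": n_pass,
            "rss_per_million": rss_per_million(n_pass, row.total_mapped_reads),
            "median_intron_length": med,
            "stage_counts": cat.stage_counts,
        }
    if len(counts) >= 3 and not any(np.isnan(medians)):
        rho, n_rho = intron_length_correlation(counts, medians)
    else:
        rho, n_rho = float("nan"), len(counts)

    strata = stratify_conservation(list(res.final_rss.values()))
    gl = gain_loss_summary(
        res.diff, {r: l.associated for r, l in res.rs_exon_links.items()}
    )
    n_assoc = sum(1 for l in res.rs_exon_links.values() if l.associated)
    res.summary = {
        "conditions": {"ctrl": ctrl, "ko": ko},
        "per_sample": per_sample,
        "n_final_rss": len(res.final_rss),
        "rs_exon_associated": n_assoc,
        "rs_exon_fraction": n_assoc / len(res.final_rss) if res.final_rss else float("nan"),
        "n_cryptic": sum(1 for l in res.rs_exon_links.values() if l.cryptic),
        "conservation_strata": {k: len(v) for k, v in strata.items()},
        "intron_length_correlation": {"rho": rho, "n": n_rho},
        "gain_loss": gl,
        "donor_enrichment": enrichment_frame(enrich).to_dict(orient="records"),
        "seed": cfg.seed,
    }
    if as_enrich is not None:
        res.summary["as_overlap"] = enrichment_frame(as_enrich).to_dict(
            orient="records"
        )

    if outdir:
        write_outputs(res, outdir, cfg)
    return res


def write_outputs(res: PipelineResult, outdir: str, cfg: FilterConfig) -> None:
    os.makedirs(outdir, exist_ok=True)
    cats = pd.concat(
        [c.to_frame() for c in res.catalogs.values()], ignore_index=True
    )
    write_table(cats, os.path.join(outdir, "catalogs.tsv"), cfg.seed, cfg)
    if res.usage is not None:
        write_table(
            res.usage.reset_index(), os.path.join(outdir, "usage.tsv"), cfg.seed, cfg
        )
    write_table(
        differential_frame(res.diff),
        os.path.join(outdir, "differential.tsv"), cfg.seed, cfg,
    )
    links = pd.DataFrame(
        [
            (
                l.rss_id,
                l.exon[0] if l.exon else -1,
                l.exon[1] if l.exon else -1,
                l.associated, l.coverage_fold, l.cryptic,
            )
            for l in res.rs_exon_links.values()
        ],
        columns=["rss_id", "exon_start", "exon_end", "associated",
                 "coverage_fold", "cryptic"],
    )
    write_table(links, os.path.join(outdir, "rs_exons.tsv"), cfg.seed, cfg)
    tmp = os.path.join(outdir, "summary.json.tmp")
    with open(tmp, "w") as fh:
        json.dump(res.summary, fh, indent=2, default=float)
    os.replace(tmp, os.path.join(outdir, "summary.json"))
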