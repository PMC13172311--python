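"""Three-criterion RSS filtering plus poly(A) subtraction.

A detected candidate becomes a final RSS only if (i) the 5-nt YAG|NN motif is
evolutionarily conserved (mean PhastCons > 0.5), (ii) its junction is anchored
by an alignment overhang > 5 nt, (iii) intronic coverage shows a sawtooth step
— a > two-fold drop from the upstream to the downstream window at the RS
point, with a breakpoint-randomization permutation P < 0.01 — and (iv) the
event is absent from poly(A)-enriched libraries, where recursive
intermediates should not survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import SignalTrack
from .rss_detect import RssCandidate, RssCatalog

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    cons_threshold: float = 0.5
    min_overhang_exclusive: int = 5
    fold_threshold: float = 2.0
    perm_alpha: float = 0.01
    n_perm: int = 1000
    window_nt: int = 500
    #: smallest usable window after truncation to the intron
    min_window_nt: int = 50
    epsilon: float = 0.5
    min_polyA_reads: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.fold_threshold, self.window_nt, self.min_window_nt) <= 0:
            raise ValueError("thresholds and windows must be positive")
        if not 0 < self.perm_alpha < 1:
            raise ValueError("perm_alpha must lie in (0,1)")


@dataclass(frozen=True)
class SawtoothResult:
    up_mean: float
    down_mean: float
    fold: float
    p_perm: float
    n_perm: int
    window_up: int
    window_down: int
    testable: bool = True


def conservation_filter(
    candidate: RssCandidate, cons: SignalTrack, cfg: FilterConfig
) -> tuple[float, bool]:
    """Mean PhastCons over the 5 motif bases (YAG + NN); strict > threshold.

    Positions absent from the track contribute 0 and set a per-candidate
    warning flag.
    """
    if candidate.strand == "+":
        a, b = candidate.rs_point - 3, candidate.rs_point + 2
    else:
        a, b = candidate.rs_point - 2, candidate.rs_point + 3
    vals = cons.window(candidate.chrom, a, b)
    mask = cons.covered_mask(candidate.chrom, a, b)
    if not mask.all():
        candidate.filter_flags["conservation_gap"] = True
    mean_score = float(vals.mean())
    return mean_score, mean_score > cfg.cons_threshold


def overhang_filter(candidate: RssCandidate, cfg: FilterConfig) -> bool:
    """Junction support must exceed ``min_overhang_exclusive`` nt (strict)."""
    return candidate.overhang > cfg.min_overhang_exclusive


def _window_means(cum: np.ndarray, brk: np.ndarray, w_left, w_right):
    """Window means at intron-relative breakpoints via prefix sums."""
    left = (cum[brk] - cum[brk - w_left]) / w_left
    right = (cum[brk + w_right] - cum[brk]) / w_right
    return left, right


def sawtooth_test(
    candidate: RssCandidate,
    coverage: SignalTrack,
    cfg: FilterConfig,
    rng: np.random.Generator,
) -> SawtoothResult:
    """Permutation test of the coverage step at the RS point.

    Windows of ``cfg.window_nt`` on each side of the rs_point (transcription
    orientation, truncated to the intron) give the observed statistic
    ``S = (up_mean + eps) / (down_mean + eps)``.  The null redraws the
    breakpoint uniformly inside the intron (respecting the minimum truncated
    window) and recomputes the same statistic on the same coverage, which
    preserves the positional autocorrelation of the signal.  The add-one
    estimator ``p = (1 + #{S_null >= S_obs}) / (n_perm + 1)`` never returns 0.
    """
    istart, iend = candidate.intron_start, candidate.intron_end
    ilen = iend - istart
    W, minw, eps = cfg.window_nt, cfg.min_window_nt, cfg.epsilon
    rs_rel = candidate.rs_point - istart
    w_left = min(W, rs_rel)
    w_right = min(W, ilen - rs_rel)
    if w_left < minw or w_right < minw or ilen < 2 * minw:
        return SawtoothResult(
            float("nan"), float("nan"), float("nan"), float("nan"),
            cfg.n_perm, w_left, w_right, testable=False,
        )

    cov = coverage.window(candidate.chrom, istart, iend)
    cum = np.concatenate([[0.0], np.cumsum(cov)])

    left, right = _window_means(
        cum, np.array([rs_rel]), np.array([w_left]), np.array([w_right])
    )
    if candidate.strand == "+":
        up_mean, down_mean = float(left[0]), float(right[0])
    else:
        up_mean, down_mean = float(right[0]), float(left[0])
    s_obs = (up_mean + eps) / (down_mean + eps)

    brk = rng.integers(minw, ilen - minw, size=cfg.n_perm, endpoint=True)
    wl = np.minimum(W, brk)
    wr = np.minimum(W, ilen - brk)
    nl, nr = _window_means(cum, brk, wl, wr)
    if candidate.strand == "+":
        s_null = (nl + eps) / (nr + eps)
    else:
        s_null = (nr + eps) / (nl + eps)
    p_perm = (1.0 + int(np.sum(s_null >= s_obs))) / (cfg.n_perm + 1.0)

    return SawtoothResult(
        up_mean, down_mean, float(s_obs), float(p_perm),
        cfg.n_perm, int(w_left), int(w_right),
    )


def sawtooth_pass(res: SawtoothResult, cfg: FilterConfig) -> bool:
    if not res.testable:
        return False
    return res.fold > cfg.fold_threshold and res.p_perm < cfg.perm_alpha


def polyA_site_set(
    polyA_catalogs: list[RssCatalog], min_reads: int = 1
) -> set[tuple[str, int]]:
    """(gene_id, rs_point) keys detected in any poly(A) library."""
    out = set()
    for cat in polyA_catalogs:
        for c in cat.candidates:
            if c.unique_reads >= min_reads:
                out.add((c.gene_id, c.rs_point))
    return out


def polyA_subtraction(catalog: RssCatalog, polyA_keys: set) -> RssCatalog:
    """Flag candidates seen in poly(A) libraries; they can never pass."""
    n_removed = 0
    for c in catalog.candidates:
        if (c.gene_id, c.rs_point) in polyA_keys:
            c.in_polyA = True
            n_removed += 1
    if n_removed:
        log.info(
            "%s: %d candidate(s) subtracted as poly(A)-detected",
            catalog.sample_id, n_removed,
        )
    return catalog


def apply_filters(
    catalog: RssCatalog,
    coverage: SignalTrack,
    conservation: SignalTrack,
    cfg: FilterConfig,
    polyA_keys: set | None = None,
) -> RssCatalog:
    """Run the full filter chain; final ``pass`` requires motif AND
    conservation AND overhang AND sawtooth AND not-poly(A).

    Candidates are evaluated in catalog order with one seeded generator per
    run, so results are reproducible for a given (catalog, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    if polyA_keys:
        polyA_subtraction(catalog, polyA_keys)

    counts = dict(catalog.stage_counts)
    counts.setdefault("hybrid", len(catalog.candidates))
    n_motif = n_cons = n_over = n_saw = n_final = 0
    for c in catalog.candidates:
        motif_ok = bool(c.filter_flags.get("motif"))
        cons_mean, cons_ok = conservation_filter(c, conservation, cfg)
        c.conservation_mean = cons_mean
        over_ok = overhang_filter(c, cfg)
        saw = sawtooth_test(c, coverage, cfg, rng)
        c.sawtooth_fold = saw.fold
        c.sawtooth_p = saw.p_perm
        saw_ok = sawtooth_pass(saw, cfg)
        c.filter_flags.update(
            {
                "motif": motif_ok,
                "conservation": cons_ok,
                "overhang": over_ok,
                "sawtooth": saw_ok,
                "polyA": not c.in_polyA,
            }
        )
        # first failing criterion, in chain order
        if not motif_ok:
            c.status, c.fail_reason = "fail", "motif"
        elif not cons_ok:
            c.status, c.fail_reason = "fail", "conservation"
            n_motif += 1
        elif not over_ok:
            c.status, c.fail_reason = "fail", "overhang"
            n_motif += 1
            n_cons += 1
        elif not saw_ok:
            c.status, c.fail_reason = (
                "fail",
                "sawtooth" if saw.testable else "untestable",
            )
            n_motif += 1
            n_cons += 1
            n_over += 1
        elif c.in_polyA:
            c.status, c.fail_reason = "fail", "polyA"
            n_motif += 1
            n_cons += 1
            n_over += 1
            n_saw += 1
        else:
            c.status, c.fail_reason = "pass", ""
            n_motif += 1
            n_cons += 1
            n_over += 1
            n_saw += 1
            n_final += 1
    counts.update(
        motif=n_motif, conservation=n_cons, overhang=n_over,
        sawtooth=n_saw, final=n_final, seed=cfg.seed,
    )
    catalog.stage_counts = counts
    return catalog
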