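"""m6A peak calling from IP/INPUT fragment coverage.

Candidate peaks are local maxima of the smoothed IP fragment-coverage track
(the expected peak footprint is roughly twice the sequenced fragment length);
partially overlapping peaks separated by a coverage valley are split at the
summit midpoint.  Each peak region is then tested for IP enrichment over the
matched INPUT library with a one-sided Fisher's exact test on raw fragment
counts, p-values are FDR-adjusted across all tested regions, and
enrichment-fold / minimum-coverage / reproducibility filters flag
low-confidence calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .alignment_io import (
    AlignedFragment,
    CoverageTrack,
    ReadFilterConfig,
    compute_coverage,
    count_fragments,
    filter_alignments,
    infer_fragments,
    open_sorted_indexed,
)

logger = logging.getLogger(__name__)

FDR_METHODS = ("bh", "by", "bonferroni", "none")


@dataclass
class PeakCall:
    """One called peak: summit, region, counts, test results and filter flags."""

    chrom: str
    summit: int
    region_start: int
    region_end: int
    ip_count: int
    input_count: int
    ip_total: int
    input_total: int
    enrichment: float
    p_value: float = 1.0
    q_value: float = 1.0
    flags: set[str] = field(default_factory=set)
    sample_id: str = ""
    gene: str = ""
    consensus_distance: float = float("nan")
    fp_score: float = float("nan")
    sites: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.region_start <= self.summit < self.region_end):
            raise ValueError("summit must lie inside the region")
        if min(self.ip_count, self.input_count, self.ip_total, self.input_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.enrichment < 0:
            raise ValueError("enrichment must be non-negative")

    @property
    def retained(self) -> bool:
        return not self.flags

    @property
    def site(self) -> int:
        """Best site estimate: top-weight deconvolved site, else the summit."""
        return self.sites[0][0] if self.sites else self.summit


@dataclass
class PeakCallConfig:
    """Peak-calling thresholds (defaults favour high-confidence peaks)."""

    fragment_size: int = 100
    p_cutoff: float = 0.05
    min_enrichment: float = 2.0
    min_coverage: int = 20
    fdr_method: str = "bh"
    smoothing_window: int = 0  # 0 -> fragment_size/4 rounded to odd
    min_peak_separation: int = 0  # 0 disables; valley rule governs splitting
    min_valley_fraction: float = 0.75
    reproducibility: bool = False
    mode: str = "paired"
    read_filter: ReadFilterConfig = field(default_factory=ReadFilterConfig)

    def __post_init__(self) -> None:
        for name in ("fragment_size", "p_cutoff", "min_enrichment", "min_coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fdr_method not in FDR_METHODS:
            raise ValueError(f"fdr_method must be one of {FDR_METHODS}")
        if not self.smoothing_window:
            w = max(1, self.fragment_size // 4)
            self.smoothing_window = w if w % 2 == 1 else w + 1


def smooth(track: CoverageTrack, window: int) -> CoverageTrack:
    """Centred moving average with edge shrinkage (window truncated at ends).

    A window of 1 is the identity; even windows are incremented with a
    warning so the average stays centred.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        logger.warning("even smoothing window %d incremented to %d", window, window + 1)
        window += 1
    if window == 1 or len(track.values) == 0:
        return CoverageTrack(track.chrom, track.start, track.values.copy(), track.scale)
    v = track.values
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(len(v))
    lo = np.maximum(0, idx - half)
    hi = np.minimum(len(v), idx + half + 1)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return CoverageTrack(track.chrom, track.start, out, track.scale)


def find_local_maxima(
    track: CoverageTrack,
    expected_width: int,
    min_height: float = 0.0,
    min_valley_fraction: float = 0.75,
) -> list[int]:
    """Summits of a (smoothed) coverage track, as genomic positions.

    A position — or the centre of a run of equal coverage — is a summit when
    coverage trends upward over the preceding ``expected_width/4`` flank and
    downward over the following one.  Summits below ``min_height`` are
    suppressed.  Adjacent maxima are reported separately only when the valley
    between them drops below ``min_valley_fraction`` of the lower summit;
    otherwise they are merged into the higher one.
    """
    v = track.values
    n = len(v)
    if n == 0:
        return []
    flank = max(1, expected_width // 4)

    # plateau-aware local maxima: runs of equal value higher than both sides
    candidates: list[tuple[int, float]] = []  # (index, height)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[j]
        spans_track = i == 0 and j == n - 1  # no gradient change anywhere
        if left_ok and right_ok and v[i] > 0 and not spans_track:
            center = (i + j) // 2
            lo = max(0, i - flank)
            hi = min(n, j + 1 + flank)
            rising = i == 0 or np.mean(v[lo:i]) < v[i]
            falling = j == n - 1 or np.mean(v[j + 1 : hi]) < v[j]
            if rising and falling and v[i] >= min_height:
                candidates.append((center, float(v[i])))
        i = j + 1

    # valley rule: merge neighbours whose separating dip is too shallow
    merged = candidates
    changed = True
    while changed and len(merged) > 1:
        changed = False
        out: list[tuple[int, float]] = [merged[0]]
        for pos, height in merged[1:]:
            prev_pos, prev_height = out[-1]
            valley = float(np.min(v[prev_pos : pos + 1]))
            lower = min(height, prev_height)
            if valley > min_valley_fraction * lower:
                if height > prev_height:
                    out[-1] = (pos, height)
                changed = True
            else:
                out.append((pos, height))
        merged = out
    return [track.start + pos for pos, _ in merged]


def enforce_min_separation(summits: list[int], heights: list[float],
                           min_separation: int) -> list[int]:
    """Optionally thin summits closer than ``min_separation``, keeping the higher."""
    if min_separation <= 0 or len(summits) < 2:
        return summits
    kept: list[tuple[int, float]] = []
    for s, h in zip(summits, heights):
        if kept and s - kept[-1][0] < min_separation:
            if h > kept[-1][1]:
                kept[-1] = (s, h)
        else:
            kept.append((s, h))
    return [s for s, _ in kept]


def define_regions(
    summits: list[int],
    fragment_size: int,
    bounds: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    """Peak regions: fragment_size to each side of the summit, split at the
    midpoint between overlapping neighbours; regions are pairwise disjoint."""
    if sorted(summits) != list(summits):
        raise ValueError("summits must be sorted")
    regions: list[list[int]] = [[s - fragment_size, s + fragment_size] for s in summits]
    for i in range(len(regions) - 1):
        if regions[i][1] > regions[i + 1][0]:
            mid = (summits[i] + summits[i + 1] + 1) // 2  # ceil keeps left summit inside
            regions[i][1] = mid
            regions[i + 1][0] = mid
    if bounds is not None:
        for r in regions:
            r[0] = max(r[0], bounds[0])
            r[1] = min(r[1], bounds[1])
    return [(lo, hi) for lo, hi in regions]


def test_enrichment(ip_count: int, input_count: int, ip_total: int, input_total: int) -> float:
    """One-sided Fisher's exact p-value that the IP fraction exceeds INPUT's.

    The 2x2 table is (ip_count, ip_total - ip_count) vs (input_count,
    input_total - input_count); the p-value is the upper hypergeometric tail
    P(X >= ip_count) with X ~ Hypergeom(N=ip_total+input_total,
    K=ip_count+input_count, n=ip_total).
    """
    for v in (ip_count, input_count, ip_total, input_total):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    if ip_count > ip_total or input_count > input_total:
        raise ValueError("region count exceeds library total")
    if ip_total == 0 or input_total == 0:
        logger.warning("empty library total; p-value set to 1")
        return 1.0
    if ip_count == 0:
        return 1.0
    n_pop = ip_total + input_total
    n_success = ip_count + input_count
    return float(hypergeom.sf(ip_count - 1, n_pop, n_success, ip_total))


def adjust_fdr(p_values, method: str = "bh"):
    """Multiple-testing adjustment; output order matches input order.

    ``bh`` Benjamini–Hochberg step-up, ``by`` Benjamini–Yekutieli,
    ``bonferroni`` min(1, m*p), ``none`` identity.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    try:
        sm_method = {"bh": "fdr_bh", "by": "fdr_by", "bonferroni": "bonferroni"}[method]
    except KeyError:
        raise ValueError(f"unknown FDR method {method!r}; choose from {FDR_METHODS}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=sm_method)[1]


def apply_filters(peaks: list[PeakCall], cfg: PeakCallConfig) -> list[PeakCall]:
    """Flag peaks failing the q-value, enrichment-fold or coverage filters.

    Peaks are flagged in place (order preserved) and all are returned; the
    default text output excludes flagged peaks but they stay available.
    """
    for peak in peaks:
        if peak.q_value > cfg.p_cutoff:
            peak.flags.add("not_significant")
        if peak.enrichment < cfg.min_enrichment:
            peak.flags.add("low_enrichment")
        if peak.ip_count < cfg.min_coverage:
            peak.flags.add("low_coverage")
    return peaks


def reproducibility_filter(
    replicate_peak_sets: list[list[PeakCall]], match_window: int = 50
) -> list[list[PeakCall]]:
    """Flag peaks lacking a summit match in every replicate of the group."""
    if len(replicate_peak_sets) < 2:
        logger.warning("reproducibility filter needs >= 2 replicates; no-op")
        return replicate_peak_sets
    summits = [
        {c: sorted(p.summit for p in peaks if p.chrom == c) for c in {p.chrom for p in peaks}}
        for peaks in replicate_peak_sets
    ]
    for i, peaks in enumerate(replicate_peak_sets):
        for peak in peaks:
            for j, other in enumerate(summits):
                if j == i:
                    continue
                cand = other.get(peak.chrom, [])
                if not cand or min(abs(s - peak.summit) for s in cand) > match_window:
                    peak.flags.add("not_reproducible")
                    break
    return replicate_peak_sets


def _count_in_region(starts: np.ndarray, ends: np.ndarray, lo: int, hi: int) -> int:
    """Fragments whose span overlaps [lo, hi) (integer count for the exact test)."""
    return int(np.count_nonzero((starts < hi) & (ends > lo)))


def call_peaks_from_fragments(
    ip_fragments: list[AlignedFragment],
    input_fragments: list[AlignedFragment],
    chrom: str,
    length: int,
    cfg: PeakCallConfig,
    ip_total: int | None = None,
    input_total: int | None = None,
    sample_id: str = "",
    adjust: bool = True,
) -> list[PeakCall]:
    """Peak calling on in-memory fragments of one chromosome/contig.

    The BAM front end :func:`call_peaks` delegates here; the simulator's
    tests drive it directly.  ``adjust=False`` defers FDR adjustment to a
    caller pooling several chromosomes.
    """
    ip_total = ip_total if ip_total is not None else len(ip_fragments)
    input_total = input_total if input_total is not None else len(input_fragments)
    scale = ip_total / input_total if input_total else 1.0

    ip_cov = compute_coverage(ip_fragments, chrom, 0, length)
    smoothed = smooth(ip_cov, cfg.smoothing_window)
    summits = find_local_maxima(
        smoothed,
        expected_width=2 * cfg.fragment_size,
        min_height=cfg.min_coverage,
        min_valley_fraction=cfg.min_valley_fraction,
    )
    summits = enforce_min_separation(
        summits, [float(smoothed.values[s]) for s in summits], cfg.min_peak_separation
    )
    regions = define_regions(summits, cfg.fragment_size, bounds=(0, length))

    ip_starts = np.array([f.start for f in ip_fragments], dtype=int)
    ip_ends = np.array([f.end for f in ip_fragments], dtype=int)
    in_starts = np.array([f.start for f in input_fragments], dtype=int)
    in_ends = np.array([f.end for f in input_fragments], dtype=int)

    peaks: list[PeakCall] = []
    for summit, (lo, hi) in zip(summits, regions):
        ip_n = _count_in_region(ip_starts, ip_ends, lo, hi)
        in_n = _count_in_region(in_starts, in_ends, lo, hi)
        # scaled-coverage fold with +1 pseudocount to avoid infinities
        enrichment = (ip_n + 1.0) / (in_n * scale + 1.0)
        p = test_enrichment(ip_n, in_n, ip_total, input_total)
        peaks.append(
            PeakCall(
                chrom=chrom,
                summit=summit,
                region_start=lo,
                region_end=hi,
                ip_count=ip_n,
                input_count=in_n,
                ip_total=ip_total,
                input_total=input_total,
                enrichment=enrichment,
                p_value=p,
                sample_id=sample_id,
            )
        )
    if adjust:
        finalize_peaks(peaks, cfg)
    return peaks


def finalize_peaks(peaks: list[PeakCall], cfg: PeakCallConfig) -> list[PeakCall]:
    """FDR-adjust pooled p-values and apply the confidence filters."""
    q = adjust_fdr([p.p_value for p in peaks], cfg.fdr_method)
    for peak, qv in zip(peaks, q):
        peak.q_value = float(qv)
    return apply_filters(peaks, cfg)


def call_peaks(
    ip_bam: str,
    input_bam: str,
    cfg: PeakCallConfig | None = None,
    annotation=None,
    sample_id: str = "",
) -> list[PeakCall]:
    """Call m6A peaks from sorted, indexed IP and INPUT BAM files.

    INPUT coverage is scaled to the IP library by the ratio of total filtered
    fragment counts.  Deterministic given inputs and configuration.
    """
    cfg = cfg or PeakCallConfig()
    ip = open_sorted_indexed(ip_bam)
    ctrl = open_sorted_indexed(input_bam)
    try:
        ip_refs = dict(zip(ip.references, ip.lengths))
        in_refs = dict(zip(ctrl.references, ctrl.lengths))
        shared = [c for c in ip.references if c in in_refs]
        if not shared:
            raise ValueError(
                f"no shared chromosomes between {ip_bam} ({list(ip.references)[:5]}...) "
                f"and {input_bam} ({list(ctrl.references)[:5]}...)"
            )

        def fragments_for(fh, chrom):
            recs = filter_alignments(fh.fetch(chrom), cfg.read_filter)
            return list(
                infer_fragments(
                    recs,
                    mode=cfg.mode,
                    fragment_size=cfg.fragment_size,
                    exons=annotation,
                    chrom_names=fh.references,
                )
            )

        ip_total = count_fragments(ip, cfg.read_filter, cfg.mode)
        input_total = count_fragments(ctrl, cfg.read_filter, cfg.mode)
        logger.info("library totals: IP=%d INPUT=%d fragments", ip_total, input_total)

        peaks: list[PeakCall] = []
        for chrom in shared:
            ip_frags = fragments_for(ip, chrom)
            if not ip_frags:
                continue
            in_frags = fragments_for(ctrl, chrom)
            chrom_peaks = call_peaks_from_fragments(
                ip_frags,
                in_frags,
                chrom,
                ip_refs[chrom],
                cfg,
                ip_total=ip_total,
                input_total=input_total,
                sample_id=sample_id,
                adjust=False,
            )
            logger.info("%s: %d candidate peaks", chrom, len(chrom_peaks))
            peaks.extend(chrom_peaks)
        finalize_peaks(peaks, cfg)
        logger.info(
            "called %d peaks, %d retained after filters",
            len(peaks),
            sum(p.retained for p in peaks),
        )
        return peaks
    finally:
        ip.close()
        ctrl.close()
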