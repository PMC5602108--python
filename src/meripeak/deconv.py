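"""EM deconvolution of enriched regions into candidate m6A sites.

The fragment pile-up in an enriched region is modelled as a mixture: each
component is the coverage distribution produced by antibody binding at one
methylated adenosine, plus a uniform "noise" component for fragments that
carry no positional signal (non-specific binding, contamination, alignment
error).  Because methylation can only occur at an adenosine, candidate site
positions are restricted to the A's of the region (optionally only those
inside an RRACH consensus).  EM alternates between soft-assigning fragments
to sites and re-estimating mixture weights and site positions; the number of
sites is chosen by the Bayesian information criterion.

Placement kernel: a fragment of covered length L whose span contains a site
is given density 1/L — a uniform choice among the L start positions that
make the fragment cover the site; fragments not covering the site have
density 0.  Inside EM the zero is floored at a small constant so the
monotone-likelihood guarantee survives the hard indicator (see
``LIKELIHOOD_FLOOR``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import AlignedFragment
from .annotation import DEFAULT_MOTIF, iupac_regex, motif_a_offset

logger = logging.getLogger(__name__)

#: Density assigned inside EM to a (fragment, site) pair the kernel scores 0.
LIKELIHOOD_FLOOR = 1e-12

#: Components whose weight collapses below this are frozen and flagged.
WEIGHT_COLLAPSE = 1e-6


@dataclass
class DeconvConfig:
    max_sites: int = 5
    tol: float = 1e-4
    max_iter: int = 200
    restrict_to_consensus: bool = False
    motif: str = DEFAULT_MOTIF
    init_noise_weight: float = 0.05


@dataclass
class SiteMixture:
    """A fitted mixture: site positions, weights, noise weight, fit statistics."""

    sites: list[int]
    weights: np.ndarray
    noise_weight: float
    log_likelihood: float
    bic: float
    n_fragments: int
    converged: bool = False
    n_iterations: int = 0
    collapsed: list[int] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12) or self.noise_weight < -1e-12:
            raise ValueError("mixture weights must be non-negative")
        total = float(self.weights.sum() + self.noise_weight)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total})")

    @property
    def k(self) -> int:
        """Free parameters for BIC: site positions + free mixture weights."""
        return 2 * len(self.sites)

    def ranked_sites(self) -> list[tuple[int, float]]:
        order = np.argsort(-self.weights)
        return [(self.sites[i], float(self.weights[i])) for i in order]


def candidate_sites(
    region_start: int,
    seq: str,
    restrict_to_consensus: bool = False,
    motif: str = DEFAULT_MOTIF,
) -> list[int]:
    """Genomic positions of candidate adenosines within a region.

    ``seq`` is the region's sequence (U normalised to T).  With
    ``restrict_to_consensus`` only A's at the methylated position of a motif
    occurrence are returned.
    """
    if not seq:
        raise ValueError(
            "no sequence available for region; run in summit-only mode "
            "or provide a FASTA reference"
        )
    s = seq.upper().replace("U", "T")
    if restrict_to_consensus:
        off = motif_a_offset(motif)
        return [region_start + m.start() + off for m in iupac_regex(motif).finditer(s)]
    return [region_start + i for i, base in enumerate(s) if base == "A"]


def fragment_site_likelihood(fragment: AlignedFragment, site: int, fragment_len: int) -> float:
    """P(fragment | site): uniform over admissible placements covering the site.

    A fragment of covered length L has L start positions that place the site
    within its span, hence density 1/L when it covers the site and 0
    otherwise.  ``fragment_len`` is used for fragments whose own length is
    degenerate (kept for API symmetry; the fragment's covered length wins).
    """
    if fragment_len <= 0:
        raise ValueError("fragment_len must be positive")
    length = fragment.length or fragment_len
    return 1.0 / length if fragment.covers(site) else 0.0


def _coverage_matrix(fragments: list[AlignedFragment], candidates: list[int]) -> np.ndarray:
    """Boolean (n_fragments, n_candidates): does fragment f cover candidate c."""
    cand = np.asarray(candidates, dtype=int)
    cov = np.zeros((len(fragments), len(cand)), dtype=bool)
    for i, frag in enumerate(fragments):
        for s, e in frag.blocks:
            cov[i] |= (cand >= s) & (cand < e)
    return cov


def _density_matrix(
    fragments: list[AlignedFragment],
    candidates: list[int],
    region_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Floored per-site densities (n_frag, n_cand) and the noise density column."""
    cov = _coverage_matrix(fragments, candidates)
    lengths = np.array([f.length for f in fragments], dtype=float)
    dens = np.where(cov, 1.0 / lengths[:, None], LIKELIHOOD_FLOOR)
    noise = np.full(len(fragments), 1.0 / max(region_len, 1))
    return dens, noise


def init_em(
    fragments: list[AlignedFragment],
    candidates: list[int],
    n_sites: int,
    region_len: int,
    init_noise_weight: float = 0.05,
) -> SiteMixture:
    """Greedy set-cover initialization.

    Repeatedly pick the candidate adenosine covering the most not-yet-assigned
    fragments; initial weights are the normalised fragment shares of the
    chosen sites, with a small initial noise weight.
    """
    if not fragments:
        raise ValueError("cannot initialize EM with no fragments")
    if n_sites > len(candidates):
        logger.warning(
            "n_sites=%d exceeds %d candidate adenosines; reduced", n_sites, len(candidates)
        )
        n_sites = len(candidates)
    cov = _coverage_matrix(fragments, candidates)
    unassigned = np.ones(len(fragments), dtype=bool)
    chosen: list[int] = []
    chosen_idx: list[int] = []
    for _ in range(n_sites):
        gain = (cov & unassigned[:, None]).sum(axis=0)
        gain[chosen_idx] = -1
        best = int(np.argmax(gain))
        chosen_idx.append(best)
        chosen.append(candidates[best])
        unassigned &= ~cov[:, best]
    counts = cov[:, chosen_idx].sum(axis=0).astype(float)
    if counts.sum() == 0:
        counts[:] = 1.0
    weights = counts / counts.sum() * (1.0 - init_noise_weight)
    order = np.argsort(chosen)
    sites = [chosen[i] for i in order]
    weights = weights[order]
    dens, noise = _density_matrix(fragments, sites, region_len)
    ll = _loglik(dens, noise, weights, init_noise_weight)
    return SiteMixture(
        sites=sites,
        weights=weights,
        noise_weight=init_noise_weight,
        log_likelihood=ll,
        bic=_bic(len(sites), len(fragments), ll),
        n_fragments=len(fragments),
    )


def _loglik(dens: np.ndarray, noise: np.ndarray, weights: np.ndarray, noise_w: float) -> float:
    mix = dens @ weights + noise_w * noise
    return float(np.log(np.maximum(mix, 1e-300)).sum())


def _bic(n_sites: int, n_fragments: int, loglik: float) -> float:
    k = 2 * n_sites
    return k * np.log(max(n_fragments, 1)) - 2.0 * loglik


def em_fit(
    fragments: list[AlignedFragment],
    candidates: list[int],
    n_sites: int,
    region_start: int,
    region_len: int,
    cfg: DeconvConfig | None = None,
    init: SiteMixture | None = None,
) -> SiteMixture:
    """Fit an ``n_sites``-component mixture (plus noise) by EM.

    E-step: responsibilities of fragments over sites and noise.  M-step:
    weights become responsibility means; each site relocates to the candidate
    adenosine maximising its component's expected log-likelihood.  The
    (floored-model) log-likelihood is non-decreasing every iteration; the fit
    stops when the gain drops below ``cfg.tol`` or after ``cfg.max_iter``.
    """
    cfg = cfg or DeconvConfig()
    if not fragments:
        raise ValueError("cannot fit a mixture with no fragments")
    mix = init or init_em(
        fragments, candidates, n_sites, region_len, init_noise_weight=cfg.init_noise_weight
    )
    cand_dens, noise = _density_matrix(fragments, candidates, region_len)
    log_cand_dens = np.log(cand_dens)
    cand_index = {c: i for i, c in enumerate(candidates)}

    sites = list(mix.sites)
    weights = mix.weights.copy()
    noise_w = mix.noise_weight
    collapsed: set[int] = set()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        site_idx = [cand_index[s] for s in sites]
        dens = cand_dens[:, site_idx]
        # E-step
        joint = np.column_stack([dens * weights, noise_w * noise])
        joint_sum = joint.sum(axis=1, keepdims=True)
        ll = float(np.log(np.maximum(joint_sum, 1e-300)).sum())
        trace.append(ll)
        resp = joint / np.maximum(joint_sum, 1e-300)
        # M-step: weights
        new_weights = resp[:, :-1].mean(axis=0)
        new_noise_w = float(resp[:, -1].mean())
        for j in range(len(sites)):
            if new_weights[j] < WEIGHT_COLLAPSE:
                collapsed.add(j)
        # M-step: site relocation among candidate adenosines
        scores = resp[:, :-1].T @ log_cand_dens  # (n_sites, n_candidates)
        for j in range(len(sites)):
            if j in collapsed:
                continue
            sites[j] = candidates[int(np.argmax(scores[j]))]
        weights, noise_w = new_weights, new_noise_w
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < cfg.tol:
            converged = True
            break

    order = np.argsort(sites)
    sites = [sites[i] for i in order]
    weights = np.maximum(weights[order], 0.0)
    total = weights.sum() + noise_w
    weights, noise_w = weights / total, noise_w / total
    site_idx = [cand_index[s] for s in sites]
    ll = _loglik(cand_dens[:, site_idx], noise, weights, noise_w)
    trace.append(ll)
    return SiteMixture(
        sites=sites,
        weights=weights,
        noise_weight=noise_w,
        log_likelihood=ll,
        bic=_bic(len(sites), len(fragments), ll),
        n_fragments=len(fragments),
        converged=converged,
        n_iterations=it,
        collapsed=sorted(collapsed),
        loglik_trace=trace,
    )


def select_model(
    fragments: list[AlignedFragment],
    candidates: list[int],
    region_start: int,
    region_len: int,
    cfg: DeconvConfig | None = None,
) -> SiteMixture:
    """Fit mixtures with 1..max_sites components and return the minimum-BIC fit.

    Ties favour fewer sites (BIC compared with a small tolerance).
    """
    cfg = cfg or DeconvConfig()
    best: SiteMixture | None = None
    for n in range(1, min(cfg.max_sites, len(candidates)) + 1):
        fit = em_fit(fragments, candidates, n, region_start, region_len, cfg)
        if best is None or fit.bic < best.bic - 1e-9:
            best = fit
    assert best is not None
    return best


def deconvolute_peaks(
    peaks: list,
    fragments_by_chrom: dict[str, list[AlignedFragment]],
    fasta,
    cfg: DeconvConfig | None = None,
) -> list:
    """Attach deconvolved (site, weight) lists to called peaks.

    ``fasta`` is any mapping-like object supporting ``fasta[chrom][start:end]``
    returning sequence (e.g. ``pyfaidx.Fasta`` with as_raw or a dict of
    strings).  Peaks whose region holds no candidate adenosine keep the
    summit-only call and are flagged ``no_adenosine``.
    """
    cfg = cfg or DeconvConfig()
    for peak in peaks:
        seq = str(fasta[peak.chrom][peak.region_start : peak.region_end])
        cands = candidate_sites(
            peak.region_start, seq, cfg.restrict_to_consensus, cfg.motif
        )
        region_len = peak.region_end - peak.region_start
        frags = [
            f
            for f in fragments_by_chrom.get(peak.chrom, [])
            if f.start < peak.region_end and f.end > peak.region_start
        ]
        if not cands or not frags:
            peak.flags.add("no_adenosine" if not cands else "no_fragments")
            continue
        fit = select_model(frags, cands, peak.region_start, region_len, cfg)
        peak.sites = fit.ranked_sites()
    return peaks
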