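"""Synthetic MeRIP-seq experiments with known ground truth.

The generator emulates the m6A-seq design: transcripts (optionally
multi-exon) expressed at varying levels, methylated adenosines planted inside
RRACH consensus contexts, an INPUT library of fragments placed uniformly
along transcripts in proportion to expression, and an IP library in which a
fraction of fragments is drawn to cover a methylation site (start uniform
among the placements covering it — the same admissible-placement kernel the
deconvolution model assumes, so parameter-recovery tests are exact).  A
configurable noise fraction of IP fragments ignores the sites entirely;
``noise_fraction=1`` yields a null experiment statistically identical to
INPUT.

Everything is deterministic under the configured seed.  Output formats are
standard (FASTA + .fai, GTF, coordinate-sorted indexed BAM, truth TSV), so
every other module can be exercised end-to-end without external downloads.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .alignment_io import AlignedFragment
from .annotation import ExonModel, Transcript

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
#: Margin (nt) kept free of planted sites at transcript ends.
SITE_MARGIN = 150
#: Minimum spacing (nt) between planted sites on one transcript.
SITE_SPACING = 250


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe the standard evaluation fixture: 50 moderately
    expressed transcripts of 1.5-3 kb with one or two sites each, eightfold
    IP enrichment at sites, 100 +- 20 nt fragments sequenced as 50-nt
    paired-end reads at 2x10^5 fragments per library with 10% non-specific
    IP background.
    """

    n_transcripts: int = 50
    exons_per_transcript: tuple[int, int] = (1, 3)
    transcript_length: tuple[int, int] = (1500, 3000)
    n_sites: tuple[int, int] = (1, 2)
    expression_sigma: float = 0.5  # log-normal spread of expression levels
    ip_enrichment_fold: float = 8.0
    fragment_length_mean: float = 100.0
    fragment_length_sd: float = 20.0
    read_length: int = 50
    paired: bool = True
    noise_fraction: float = 0.1
    depth: int = 200_000
    seed: int = 0
    plant_in_motif: bool = True  # False plants sites at arbitrary adenosines

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for name in ("n_transcripts", "ip_enrichment_fold", "fragment_length_mean", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass(frozen=True)
class SiteRecord:
    chrom: str
    position: int  # genomic (contig) coordinate of the methylated A
    tx_position: int  # transcript coordinate
    transcript_id: str
    enrichment: float


@dataclass
class GroundTruth:
    sites: list[SiteRecord]
    expression: dict[str, float]  # transcript_id -> relative expression


@dataclass
class Reference:
    """In-memory synthetic reference: contig sequences + gene model + truth."""

    sequences: dict[str, str]
    transcripts: list[Transcript]
    truth: GroundTruth

    @property
    def exon_model(self) -> ExonModel:
        return ExonModel(self.transcripts)

    def transcript_sequence(self, tx: Transcript) -> str:
        contig = self.sequences[tx.chrom]
        return "".join(contig[s:e] for s, e in tx.exons)


def _random_motif(rng: np.random.Generator) -> str:
    r1, r2 = rng.choice(list("AG")), rng.choice(list("AG"))
    h = rng.choice(list("ACT"))
    return f"{r1}{r2}AC{h}"


def simulate_reference(cfg: SimConfig) -> Reference:
    """Build transcripts, genomic contigs and planted sites.

    One contig per transcript (padding plus intron sequence around the
    exons); site positions are at least ``SITE_MARGIN`` from transcript ends
    and ``SITE_SPACING`` apart, each with an RRACH motif written around the
    methylated A (unless ``plant_in_motif`` is off).
    """
    rng = np.random.default_rng(cfg.seed)
    sequences: dict[str, str] = {}
    transcripts: list[Transcript] = []
    sites: list[SiteRecord] = []
    expr_raw = rng.lognormal(mean=0.0, sigma=cfg.expression_sigma, size=cfg.n_transcripts)
    expression: dict[str, float] = {}

    for i in range(cfg.n_transcripts):
        tid = f"tx{i + 1:03d}"
        contig = f"contig{i + 1:03d}"
        tx_len = int(rng.integers(cfg.transcript_length[0], cfg.transcript_length[1] + 1))
        tx_seq = list(rng.choice(BASES, size=tx_len))

        lo, hi = cfg.n_sites
        n_sites = int(rng.integers(lo, hi + 1))
        usable = tx_len - 2 * SITE_MARGIN
        n_sites = max(0, min(n_sites, usable // SITE_SPACING + 1)) if usable > 0 else 0
        site_pos: list[int] = []
        for _ in range(200):
            if len(site_pos) >= n_sites:
                break
            cand = int(rng.integers(SITE_MARGIN, tx_len - SITE_MARGIN))
            if all(abs(cand - s) >= SITE_SPACING for s in site_pos):
                site_pos.append(cand)
        if len(site_pos) < n_sites:
            raise ValueError(
                f"{tid}: could not place {n_sites} sites (transcript too short)"
            )
        site_pos.sort()
        for sp in site_pos:
            if cfg.plant_in_motif:
                motif = _random_motif(rng)
                tx_seq[sp - 2 : sp + 3] = list(motif)
            else:
                tx_seq[sp] = "A"

        # exon/intron layout on the contig
        lo_e, hi_e = cfg.exons_per_transcript
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        n_exons = min(n_exons, max(1, tx_len // 300))
        if n_exons > 1:
            cuts = sorted(rng.choice(np.arange(200, tx_len - 200), size=n_exons - 1, replace=False))
        else:
            cuts = []
        bounds = [0, *cuts, tx_len]
        pad = 200
        exons: list[tuple[int, int]] = []
        contig_seq: list[str] = list(rng.choice(BASES, size=pad))
        gpos = pad
        for a, b in zip(bounds, bounds[1:]):
            exons.append((gpos, gpos + (b - a)))
            contig_seq.extend(tx_seq[a:b])
            gpos += b - a
            if b != tx_len:
                intron_len = int(rng.integers(200, 1001))
                contig_seq.extend(rng.choice(BASES, size=intron_len))
                gpos += intron_len
        contig_seq.extend(rng.choice(BASES, size=pad))

        tx = Transcript(
            transcript_id=tid,
            gene_id=f"gene{i + 1:03d}",
            gene_name=f"gene{i + 1:03d}",
            chrom=contig,
            strand="+",
            exons=exons,
        )
        sequences[contig] = "".join(contig_seq)
        transcripts.append(tx)
        expression[tid] = float(expr_raw[i])
        for sp in site_pos:
            sites.append(
                SiteRecord(
                    chrom=contig,
                    position=tx.tx_to_genome(sp),
                    tx_position=sp,
                    transcript_id=tid,
                    enrichment=cfg.ip_enrichment_fold,
                )
            )
    total = sum(expression.values())
    expression = {k: v / total for k, v in expression.items()}
    logger.info(
        "simulated %d transcripts with %d planted sites", len(transcripts), len(sites)
    )
    return Reference(sequences=sequences, transcripts=transcripts, truth=GroundTruth(sites, expression))


def write_reference(ref: Reference, out_dir: str, prefix: str = "sim") -> dict[str, str]:
    """Write FASTA (+.fai), GTF and truth TSV; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, f"{prefix}.fa")
    with open(fasta, "w") as fh:
        for contig, seq in ref.sequences.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(fasta)
    gtf = os.path.join(out_dir, f"{prefix}.gtf")
    with open(gtf, "w") as fh:
        for tx in ref.transcripts:
            for n, (s, e) in enumerate(tx.exons, 1):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'exon_number "{n}";'
                )
                fh.write(
                    f"{tx.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
    truth = os.path.join(out_dir, f"{prefix}.truth.tsv")
    with open(truth, "w") as fh:
        fh.write("chrom\tposition\ttranscript_id\ttx_position\tenrichment\n")
        for s in ref.truth.sites:
            fh.write(
                f"{s.chrom}\t{s.position + 1}\t{s.transcript_id}\t{s.tx_position + 1}\t"
                f"{s.enrichment}\n"
            )
    return {"fasta": fasta, "gtf": gtf, "truth": truth}


def _signal_probability(cfg: SimConfig, tx_len: int, n_sites: int) -> float:
    """IP mixture weight of the site-covering component.

    Chosen so the expected IP/INPUT coverage ratio at a site approaches the
    configured enrichment fold: with background coverage density N*L/len and
    signal N*p/n_sites concentrated on the site, the ratio is
    (1-p) + p*len/(n_sites*L).
    """
    if n_sites == 0:
        return 0.0
    ratio = tx_len / (n_sites * cfg.fragment_length_mean)
    if ratio <= 1.0:
        return 0.95
    p = (cfg.ip_enrichment_fold - 1.0) / (ratio - 1.0)
    return float(np.clip(p, 0.0, 0.95))


def _sample_fragment_lengths(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    fl = rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, size=n)
    return np.clip(np.round(fl), cfg.read_length, 2.5 * cfg.fragment_length_mean).astype(int)


def simulate_library_fragments(
    ref: Reference, cfg: SimConfig, ip: bool, rng: np.random.Generator
) -> dict[str, list[tuple[int, int]]]:
    """Transcript-coordinate fragments [start, end) per transcript id.

    INPUT libraries (``ip=False``) place fragments uniformly; IP libraries
    mix uniform background with site-covering placements.
    """
    tx_by_id = {t.transcript_id: t for t in ref.transcripts}
    sites_by_tx: dict[str, list[int]] = {}
    for s in ref.truth.sites:
        sites_by_tx.setdefault(s.transcript_id, []).append(s.tx_position)
    tids = list(tx_by_id)
    probs = np.array([ref.truth.expression[t] for t in tids])
    counts = rng.multinomial(cfg.depth, probs / probs.sum())

    out: dict[str, list[tuple[int, int]]] = {}
    for tid, n in zip(tids, counts):
        tx = tx_by_id[tid]
        tx_len = tx.tx_length
        sites = sites_by_tx.get(tid, [])
        flens = _sample_fragment_lengths(rng, cfg, n)
        flens = np.minimum(flens, tx_len)
        starts = np.empty(n, dtype=int)
        p_signal = 0.0
        if ip and sites:
            p_signal = (1.0 - cfg.noise_fraction) * _signal_probability(cfg, tx_len, len(sites))
        is_signal = rng.random(n) < p_signal
        # background: uniform over admissible starts
        n_bg = int((~is_signal).sum())
        starts[~is_signal] = np.floor(
            rng.random(n_bg) * (tx_len - flens[~is_signal] + 1)
        ).astype(int)
        if is_signal.any():
            which = rng.integers(0, len(sites), size=int(is_signal.sum()))
            site_arr = np.array(sites)[which]
            fl = flens[is_signal]
            lo = np.maximum(site_arr - fl + 1, 0)
            hi = np.minimum(site_arr, tx_len - fl)
            hi = np.maximum(hi, lo)
            starts[is_signal] = lo + np.floor(rng.random(len(fl)) * (hi - lo + 1)).astype(int)
        out[tid] = list(zip(starts.tolist(), (starts + flens).tolist()))
    return out


def fragments_to_genomic(
    ref: Reference, frags: dict[str, list[tuple[int, int]]]
) -> dict[str, list[AlignedFragment]]:
    """Map transcript-space fragments to genomic splice-aware fragments."""
    tx_by_id = {t.transcript_id: t for t in ref.transcripts}
    out: dict[str, list[AlignedFragment]] = {}
    for tid, pairs in frags.items():
        tx = tx_by_id[tid]
        for k, (ts, te) in enumerate(pairs):
            blocks = _tx_interval_to_blocks(tx, ts, te)
            out.setdefault(tx.chrom, []).append(
                AlignedFragment(
                    chrom=tx.chrom,
                    blocks=tuple(blocks),
                    strand="+",
                    source_read_id=f"{tid}.f{k}",
                )
            )
    return out


def _tx_interval_to_blocks(tx: Transcript, ts: int, te: int) -> list[tuple[int, int]]:
    blocks: list[tuple[int, int]] = []
    off = 0
    for s, e in tx.exons:
        ex_len = e - s
        lo = max(ts, off)
        hi = min(te, off + ex_len)
        if lo < hi:
            blocks.append((s + (lo - off), s + (hi - off)))
        off += ex_len
    return blocks


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig: list[tuple[int, int]] = []
    for (s1, e1), (s2, _e2) in zip(blocks, blocks[1:]):
        cig.append((0, e1 - s1))
        cig.append((3, s2 - e1))
    cig.append((0, blocks[-1][1] - blocks[-1][0]))
    return cig


def write_experiment_bam(
    ref: Reference,
    frags: dict[str, list[tuple[int, int]]],
    cfg: SimConfig,
    path: str,
    rng: np.random.Generator,
) -> str:
    """Emit fragments as a coordinate-sorted, indexed BAM of reads.

    Paired mode sequences ``read_length`` nt from both fragment ends (FR
    orientation); single-end mode sequences one end on a random strand.
    Splice-aware CIGARs carry N operations across introns.
    """
    tx_by_id = {t.transcript_id: t for t in ref.transcripts}
    contigs = list(ref.sequences)
    lengths = [len(ref.sequences[c]) for c in contigs]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in zip(contigs, lengths)],
    }
    tid_of = {c: i for i, c in enumerate(contigs)}
    unsorted = path + ".unsorted.bam"
    rl = cfg.read_length
    with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
        for txid, pairs in frags.items():
            tx = tx_by_id[txid]
            for k, (ts, te) in enumerate(pairs):
                name = f"{txid}.f{k}"
                if cfg.paired:
                    r1b = _tx_interval_to_blocks(tx, ts, min(ts + rl, te))
                    r2b = _tx_interval_to_blocks(tx, max(te - rl, ts), te)
                    span_lo = r1b[0][0]
                    span_hi = r2b[-1][1]
                    a1 = _make_read(name, tid_of[tx.chrom], r1b, rl, flag_read1=True)
                    a2 = _make_read(name, tid_of[tx.chrom], r2b, rl, flag_read1=False)
                    a1.next_reference_id = a2.reference_id = a1.reference_id
                    a1.next_reference_start = a2.reference_start
                    a2.next_reference_id = a1.reference_id
                    a2.next_reference_start = a1.reference_start
                    a1.template_length = span_hi - span_lo
                    a2.template_length = -(span_hi - span_lo)
                    out.write(a1)
                    out.write(a2)
                else:
                    minus = bool(rng.random() < 0.5)
                    if minus:
                        blocks = _tx_interval_to_blocks(tx, max(te - rl, ts), te)
                    else:
                        blocks = _tx_interval_to_blocks(tx, ts, min(ts + rl, te))
                    a = pysam.AlignedSegment()
                    a.query_name = name
                    a.reference_id = tid_of[tx.chrom]
                    a.reference_start = blocks[0][0]
                    a.cigartuples = _blocks_to_cigar(blocks)
                    a.flag = 16 if minus else 0
                    n_bases = sum(e - s for s, e in blocks)
                    a.query_sequence = "A" * n_bases
                    a.mapping_quality = 60
                    out.write(a)
    pysam.sort("-o", path, unsorted)
    os.remove(unsorted)
    pysam.index(path)
    return path


def _make_read(name, ref_id, blocks, read_len, flag_read1):
    a = pysam.AlignedSegment()
    a.query_name = name
    a.reference_id = ref_id
    a.reference_start = blocks[0][0]
    a.cigartuples = _blocks_to_cigar(blocks)
    flag = 0x1 | 0x2  # paired, proper pair
    if flag_read1:
        flag |= 0x40 | 0x20  # read1, mate reverse
    else:
        flag |= 0x80 | 0x10  # read2, reverse
    a.flag = flag
    n_bases = sum(e - s for s, e in blocks)
    a.query_sequence = "A" * n_bases
    a.mapping_quality = 60
    return a


def simulate_experiment(
    ref: Reference, cfg: SimConfig, out_dir: str, prefix: str = "sim"
) -> dict[str, str]:
    """Simulate IP + INPUT libraries and write sorted indexed BAMs."""
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    paths = {}
    for label, is_ip in (("ip", True), ("input", False)):
        frags = simulate_library_fragments(ref, cfg, ip=is_ip, rng=rng)
        path = os.path.join(out_dir, f"{prefix}.{label}.bam")
        write_experiment_bam(ref, frags, cfg, path, rng)
        paths[label] = path
    return paths


def simulate_region_fragments(
    region_len: int,
    sites: list[int],
    n_fragments: int,
    fragment_len: int = 50,
    noise_fraction: float = 0.1,
    seed: int = 0,
    chrom: str = "region",
) -> list[AlignedFragment]:
    """Fragments for one enriched region with known site positions.

    Signal fragments pick a site uniformly and a start uniform among the
    placements covering it; noise fragments start uniformly in the region.
    Used for deconvolution parameter-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    frags: list[AlignedFragment] = []
    for i in range(n_fragments):
        if sites and rng.random() >= noise_fraction:
            site = int(rng.choice(sites))
            lo = max(site - fragment_len + 1, 0)
            hi = min(site, region_len - fragment_len)
            start = int(rng.integers(lo, max(hi, lo) + 1))
        else:
            start = int(rng.integers(0, max(region_len - fragment_len, 0) + 1))
        frags.append(
            AlignedFragment(
                chrom=chrom,
                blocks=((start, start + fragment_len),),
                source_read_id=f"frag{i}",
            )
        )
    return frags


def truth_eval(peaks: list, truth: GroundTruth, tolerance: int = 100) -> dict:
    """Recall/precision/distance metrics of called peaks vs planted sites.

    A retained peak matches a site when the site falls inside the peak region
    or within ``tolerance`` of the summit; distances use the peak's best site
    estimate (top deconvolved site, else summit).
    """
    retained = [p for p in peaks if p.retained]
    matched_sites: set[int] = set()
    matched_peaks = 0
    distances: list[int] = []
    for p in retained:
        best = None
        for i, s in enumerate(truth.sites):
            if s.chrom != p.chrom:
                continue
            in_region = p.region_start <= s.position < p.region_end
            near = abs(p.summit - s.position) <= tolerance
            if in_region or near:
                d = abs(p.site - s.position)
                if best is None or d < best[1]:
                    best = (i, d)
        if best is not None:
            matched_peaks += 1
            matched_sites.add(best[0])
            distances.append(p.site - truth.sites[best[0]].position)
    n_sites = len(truth.sites)
    recall = len(matched_sites) / n_sites if n_sites else float("nan")
    precision = matched_peaks / len(retained) if retained else 0.0
    return {
        "n_sites": n_sites,
        "n_peaks": len(retained),
        "recall": recall,
        "precision": precision,
        "distances": distances,
        "median_abs_distance": float(np.median(np.abs(distances))) if distances else float("nan"),
    }
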