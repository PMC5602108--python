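"""Gene models, consensus-motif search and matched random controls.

The m6A consensus motif RRACH (R = A/G, H = A/C/U) marks the sequence context
in which methylation overwhelmingly occurs; the distance from a called peak to
the nearest consensus adenosine is the standard annotation-free precision
metric for m6A peak callers.  This module parses GTF gene annotation into an
exon model (used for splice-aware read extension and for classifying peaks
into 5'UTR/CDS/3'UTR/intronic), scans sequence windows for IUPAC motifs, and
draws feature-class-matched random control positions for background
distributions.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_MOTIF = "RRACH"

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> re.Pattern[str]:
    """Compile an IUPAC motif into a lookahead regex (overlaps allowed)."""
    try:
        body = "".join(f"[{IUPAC[c]}]" for c in motif.upper())
    except KeyError as exc:  # pragma: no cover - config error
        raise ValueError(f"invalid IUPAC symbol {exc} in motif {motif!r}") from exc
    return re.compile(f"(?=({body}))")


def motif_a_offset(motif: str) -> int:
    """Offset of the putative methylated A within the motif (first literal A)."""
    idx = motif.upper().find("A")
    if idx < 0:
        raise ValueError(f"motif {motif!r} contains no literal A")
    return idx


@dataclass(frozen=True)
class ConsensusHit:
    """One motif occurrence: position of its A and signed distance to a query."""

    motif: str
    a_position: int
    distance: int


@dataclass
class Transcript:
    """One transcript: ordered exons plus optional CDS span for UTR classes."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None  # genomic min of CDS
    cds_end: int | None = None  # genomic max of CDS (half-open)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev = -1
        for s, e in self.exons:
            if s >= e or s < prev:
                raise ValueError(f"{self.transcript_id}: bad exon chain")
            prev = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def contains(self, start: int, end: int) -> bool:
        """True if [start, end) lies within the transcript's genomic span."""
        return self.start <= start and end <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def intersect_exons(self, start: int, end: int) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out.append((lo, hi))
        return out

    def genome_to_tx(self, pos: int) -> int | None:
        """Transcript coordinate (5'->3' in genome + orientation) of a genomic base."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
        return None

    def tx_to_genome(self, tpos: int) -> int:
        off = 0
        for s, e in self.exons:
            if tpos < off + (e - s):
                return s + (tpos - off)
            off += e - s
        raise IndexError(f"transcript position {tpos} out of range")

    def walk_downstream(self, tip: int, extra: int, direction: str) -> list[tuple[int, int]]:
        """Exon-chain walk from genomic position ``tip``, collecting ``extra``
        covered bases toward higher (+) or lower (-) genome coordinates.

        ``tip`` is the first position *not yet* covered for '+', the position
        just past the last covered base for '-'.  Truncated silently at the
        transcript boundary.
        """
        pieces: list[tuple[int, int]] = []
        remaining = extra
        if direction == "+":
            for s, e in self.exons:
                if remaining <= 0:
                    break
                lo = max(s, tip)
                if lo >= e:
                    continue
                take = min(remaining, e - lo)
                pieces.append((lo, lo + take))
                remaining -= take
        else:
            for s, e in reversed(self.exons):
                if remaining <= 0:
                    break
                hi = min(e, tip)
                if hi <= s:
                    continue
                take = min(remaining, hi - s)
                pieces.append((hi - take, hi))
                remaining -= take
        return pieces

    def classify(self, pos: int) -> str:
        """Feature class of a genomic position within this transcript."""
        if not self.in_exon(pos):
            return "intronic"
        if self.cds_start is None or self.cds_end is None:
            return "exonic"
        if self.cds_start <= pos < self.cds_end:
            return "CDS"
        before_cds = pos < self.cds_start
        if self.strand == "+":
            return "5UTR" if before_cds else "3UTR"
        return "3UTR" if before_cds else "5UTR"


class ExonModel:
    """All transcripts of an annotation, indexed by chromosome."""

    def __init__(self, transcripts: list[Transcript]):
        self.transcripts = transcripts
        self._by_chrom: dict[str, list[Transcript]] = {}
        for tx in transcripts:
            self._by_chrom.setdefault(tx.chrom, []).append(tx)
        for txs in self._by_chrom.values():
            txs.sort(key=lambda t: (t.start, t.end))
        self._starts = {c: [t.start for t in txs] for c, txs in self._by_chrom.items()}

    def __len__(self) -> int:
        return len(self.transcripts)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Transcript]:
        txs = self._by_chrom.get(chrom, [])
        idx = bisect_right(self._starts.get(chrom, []), end)
        return [t for t in txs[:idx] if t.end > start]

    def containing_transcript(self, chrom: str, start: int, end: int) -> Transcript | None:
        """The longest transcript whose genomic span contains [start, end)."""
        hits = [t for t in self.overlapping(chrom, start, end) if t.contains(start, end)]
        if not hits:
            return None
        return max(hits, key=lambda t: t.tx_length)

    def classify_position(self, chrom: str, pos: int) -> str:
        """Feature class of a genomic position: CDS/5UTR/3UTR/exonic/intronic/intergenic.

        When several transcripts overlap the position, coding classes win over
        UTRs, which win over plain exonic, which wins over intronic.
        """
        rank = {"CDS": 0, "5UTR": 1, "3UTR": 2, "exonic": 3, "intronic": 4}
        best = "intergenic"
        best_rank = 5
        for tx in self.overlapping(chrom, pos, pos + 1):
            cls = tx.classify(pos)
            if rank[cls] < best_rank:
                best, best_rank = cls, rank[cls]
        return best

    def class_regions(self, cls: str) -> list[tuple[str, int, int]]:
        """All genomic intervals of one feature class across the annotation."""
        out: list[tuple[str, int, int]] = []
        for tx in self.transcripts:
            if cls == "intronic":
                for (s1, e1), (s2, _e2) in zip(tx.exons, tx.exons[1:]):
                    out.append((tx.chrom, e1, s2))
            else:
                for s, e in tx.exons:
                    if cls in ("exonic",):
                        out.append((tx.chrom, s, e))
                    elif tx.cds_start is not None and tx.cds_end is not None:
                        for lo, hi in _class_pieces(tx, s, e, cls):
                            out.append((tx.chrom, lo, hi))
        return [r for r in out if r[2] > r[1]]


def _class_pieces(tx: Transcript, s: int, e: int, cls: str) -> list[tuple[int, int]]:
    cs, ce = tx.cds_start, tx.cds_end
    if cls == "CDS":
        return [(max(s, cs), min(e, ce))]
    left = (max(s, 0), min(e, cs))  # genomic left of CDS
    right = (max(s, ce), e)
    if (cls == "5UTR") == (tx.strand == "+"):
        return [left]
    return [right]


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf(path: str) -> ExonModel:
    """Parse GTF exon (and CDS) features into an :class:`ExonModel`.

    Handles Ensembl/UCSC attribute dialects; exon lines without a
    transcript_id are skipped with a warning.  Transcripts with identical
    coordinates are deduplicated.  GTF is 1-based inclusive; the model is
    0-based half-open.
    """
    exons: dict[str, dict] = {}
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                n_skipped += 1
                continue
            rec = exons.setdefault(
                tid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "gene_id": attr.get("gene_id", ""),
                    "gene_name": attr.get("gene_name", attr.get("gene_id", "")),
                    "exons": [],
                    "cds": [],
                },
            )
            iv = (int(start) - 1, int(end))
            if feature == "exon":
                rec["exons"].append(iv)
            else:
                rec["cds"].append(iv)
    if n_skipped:
        logger.warning("skipped %d GTF records without transcript_id", n_skipped)

    transcripts: list[Transcript] = []
    seen: set[tuple] = set()
    for tid, rec in exons.items():
        if not rec["exons"]:
            continue
        key = (rec["chrom"], rec["strand"], tuple(sorted(rec["exons"])))
        if key in seen:
            continue
        seen.add(key)
        cds_start = min(s for s, _ in rec["cds"]) if rec["cds"] else None
        cds_end = max(e for _, e in rec["cds"]) if rec["cds"] else None
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                gene_name=rec["gene_name"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=sorted(rec["exons"]),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    model = ExonModel(transcripts)
    logger.info(
        "parsed %d transcripts (%d exons) from %s",
        len(model),
        sum(len(t.exons) for t in model.transcripts),
        path,
    )
    return model


def nearest_consensus(
    pos: int,
    seq_window: str,
    window_origin: int,
    motif: str = DEFAULT_MOTIF,
    both_strands: bool = False,
) -> int | None:
    """Signed distance (nt) from ``pos`` to the A of the nearest motif occurrence.

    ``seq_window`` is genomic sequence starting at ``window_origin``
    (U normalised to T).  Negative distances point upstream in genome
    coordinates; ``None`` when the window holds no occurrence.  With
    ``both_strands`` the reverse-complement strand is scanned too and the
    minimum-magnitude distance returned.
    """
    seq = seq_window.upper().replace("U", "T")
    if not (window_origin <= pos < window_origin + len(seq)):
        raise ValueError("query position outside the sequence window")
    a_off = motif_a_offset(motif)
    pattern = iupac_regex(motif)

    distances: list[int] = []
    for m in pattern.finditer(seq):
        a_pos = window_origin + m.start() + a_off
        distances.append(a_pos - pos)
    if both_strands:
        rc = reverse_complement(seq)
        n = len(seq)
        for m in pattern.finditer(rc):
            # A sits at rc index m.start()+a_off; map back to forward coords
            a_pos = window_origin + (n - 1 - (m.start() + a_off))
            distances.append(a_pos - pos)
    if not distances:
        return None
    return min(distances, key=lambda d: (abs(d), d))


def random_control_positions(
    peaks: list,
    exons: ExonModel,
    seed: int,
) -> list[tuple[str, int]]:
    """One feature-class-matched random position per peak.

    Each control is drawn uniformly from the genomic intervals of the same
    feature class (CDS, 5'UTR, 3'UTR, intronic, exonic) as the peak summit;
    peaks whose class has no annotated intervals fall back to a
    whole-transcript draw (logged).
    """
    rng = np.random.default_rng(seed)
    region_cache: dict[str, list[tuple[str, int, int]]] = {}
    all_exonic = exons.class_regions("exonic")
    controls: list[tuple[str, int]] = []
    n_fallback = 0
    for peak in peaks:
        cls = exons.classify_position(peak.chrom, peak.summit)
        if cls in ("intergenic", "exonic"):
            regions = all_exonic
            if cls == "intergenic":
                n_fallback += 1
        else:
            if cls not in region_cache:
                region_cache[cls] = exons.class_regions(cls)
            regions = region_cache[cls] or all_exonic
            if not region_cache[cls]:
                n_fallback += 1
        lengths = np.array([e - s for _, s, e in regions], dtype=float)
        idx = int(rng.choice(len(regions), p=lengths / lengths.sum()))
        chrom, s, e = regions[idx]
        controls.append((chrom, int(rng.integers(s, e))))
    if n_fallback:
        logger.info("%d control draws fell back to whole-transcript regions", n_fallback)
    return controls
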