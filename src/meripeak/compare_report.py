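"""Cross-sample peak matching, log fold changes and tab-delimited output.

One TSV per sample lists every detected peak (positions 1-based inclusive in
text output) with significance, enrichment, filter flags and optional
annotation columns.  With multiple samples, peaks are matched by summit
proximity and collated into a comparison table carrying a log2 enrichment
fold change for every sample pair, to surface the peaks with the largest
methylation changes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .peakcall import PeakCall

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = [
    "chrom",
    "summit",
    "region_start",
    "region_end",
    "ip_count",
    "input_count",
    "enrichment",
    "p_value",
    "q_value",
    "flags",
    "gene",
    "consensus_distance",
    "fp_score",
    "deconvolved_sites",
]

_FLOAT_FMT = "%.6g"


@dataclass
class ComparisonRecord:
    """One matched peak key with per-sample stats and pairwise log2 changes."""

    chrom: str
    summit: int  # representative (first-sample) summit
    per_sample: dict[str, PeakCall] = field(default_factory=dict)

    def log2_change(self, sample_a: str, sample_b: str) -> float | None:
        a = self.per_sample.get(sample_a)
        b = self.per_sample.get(sample_b)
        if a is None or b is None:
            return None
        return log_fold_change(a.enrichment, b.enrichment)


def log_fold_change(enr_a: float, enr_b: float) -> float | None:
    """log2(enr_a / enr_b); None (blank in output) for nonpositive input."""
    if enr_a <= 0 or enr_b <= 0:
        logger.warning("nonpositive enrichment in fold change; left blank")
        return None
    return math.log2(enr_a / enr_b)


def match_peaks(
    peak_sets: dict[str, list[PeakCall]], window: int = 50
) -> list[ComparisonRecord]:
    """Greedy nearest-summit matching of peaks across samples.

    All peaks are pooled and sorted by position; a peak joins the current
    cluster when its summit is within ``window`` of the cluster's anchor
    (first) summit and its sample is not yet represented, making the result
    independent of sample order.  Unmatched peaks become singleton records.
    """
    if len(peak_sets) < 2:
        raise ValueError("need >= 2 samples to compare")
    pooled = [
        (p.chrom, p.summit, sample, p)
        for sample, peaks in peak_sets.items()
        for p in peaks
    ]
    pooled.sort(key=lambda t: (t[0], t[1], t[2]))
    records: list[ComparisonRecord] = []
    current: ComparisonRecord | None = None
    for chrom, summit, sample, peak in pooled:
        if (
            current is not None
            and chrom == current.chrom
            and summit - current.summit <= window
            and sample not in current.per_sample
        ):
            current.per_sample[sample] = peak
        else:
            current = ComparisonRecord(chrom=chrom, summit=summit, per_sample={sample: peak})
            records.append(current)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return _FLOAT_FMT % value
    return str(value)


def write_sample_tsv(peaks: list[PeakCall], path: str, include_flagged: bool = True) -> None:
    """Write one sample's peaks as TSV (header always written).

    Summit and region coordinates are 1-based inclusive in the file.
    Deconvolved sites are ``pos:weight`` pairs, semicolon-delimited.
    """
    rows = []
    for p in peaks:
        if not include_flagged and not p.retained:
            continue
        rows.append(
            {
                "chrom": p.chrom,
                "summit": p.summit + 1,
                "region_start": p.region_start + 1,
                "region_end": p.region_end,
                "ip_count": p.ip_count,
                "input_count": p.input_count,
                "enrichment": _fmt(p.enrichment),
                "p_value": _fmt(p.p_value),
                "q_value": _fmt(p.q_value),
                "flags": ";".join(sorted(p.flags)) or ".",
                "gene": p.gene or ".",
                "consensus_distance": _fmt(p.consensus_distance),
                "fp_score": _fmt(p.fp_score),
                "deconvolved_sites": ";".join(f"{s + 1}:{_fmt(w)}" for s, w in p.sites) or ".",
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)
    logger.info("wrote %d peaks to %s", len(rows), path)


def read_sample_tsv(path: str, sample_id: str = "") -> list[PeakCall]:
    """Read a sample TSV back into PeakCall objects (lossless round trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    peaks: list[PeakCall] = []
    for _, row in df.iterrows():
        sites = []
        if row["deconvolved_sites"] not in (".", ""):
            for item in row["deconvolved_sites"].split(";"):
                pos, w = item.split(":")
                sites.append((int(pos) - 1, float(w)))
        flags = set() if row["flags"] in (".", "") else set(row["flags"].split(";"))
        peaks.append(
            PeakCall(
                chrom=row["chrom"],
                summit=int(row["summit"]) - 1,
                region_start=int(row["region_start"]) - 1,
                region_end=int(row["region_end"]),
                ip_count=int(row["ip_count"]),
                input_count=int(row["input_count"]),
                ip_total=max(int(row["ip_count"]), 1),
                input_total=max(int(row["input_count"]), 1),
                enrichment=float(row["enrichment"]) if row["enrichment"] else 0.0,
                p_value=float(row["p_value"]) if row["p_value"] else 1.0,
                q_value=float(row["q_value"]) if row["q_value"] else 1.0,
                flags=flags,
                sample_id=sample_id,
                gene="" if row["gene"] == "." else row["gene"],
                consensus_distance=(
                    float(row["consensus_distance"]) if row["consensus_distance"] else float("nan")
                ),
                fp_score=float(row["fp_score"]) if row["fp_score"] else float("nan"),
                sites=sites,
            )
        )
    return peaks


def write_comparison_tsv(
    records: list[ComparisonRecord], samples: list[str], path: str
) -> None:
    """Write the cross-sample comparison table.

    One row per matched peak key; per-sample presence/enrichment/p/q columns
    plus one ``<A>_vs_<B>`` log2 enrichment-change column per sample pair.
    Blank cells mean the peak was absent in a sample (change undefined).
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 samples to compare")
    pairs = list(itertools.combinations(samples, 2))
    rows = []
    for rec in records:
        row: dict[str, object] = {"chrom": rec.chrom, "summit": rec.summit + 1}
        for s in samples:
            p = rec.per_sample.get(s)
            row[f"{s}_present"] = int(p is not None)
            row[f"{s}_enrichment"] = _fmt(p.enrichment) if p else ""
            row[f"{s}_p_value"] = _fmt(p.p_value) if p else ""
            row[f"{s}_q_value"] = _fmt(p.q_value) if p else ""
        for a, b in pairs:
            row[f"{a}_vs_{b}"] = _fmt(rec.log2_change(a, b))
        rows.append(row)
    columns = ["chrom", "summit"]
    for s in samples:
        columns += [f"{s}_present", f"{s}_enrichment", f"{s}_p_value", f"{s}_q_value"]
    columns += [f"{a}_vs_{b}" for a, b in pairs]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    logger.info("wrote %d comparison records to %s", len(rows), path)


def write_bed(peaks: list[PeakCall], path: str, name_prefix: str = "peak") -> None:
    """BED6 export of peak regions; the summit is stored as thickStart."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            strand = "."
            fh.write(
                f"{p.chrom}\t{p.region_start}\t{p.region_end}\t{name_prefix}{i + 1}\t"
                f"{min(1000, int(round(p.enrichment * 100)))}\t{strand}\t{p.summit}\n"
            )
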