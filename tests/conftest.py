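"""Shared fixtures: crafted BAM/GTF builders and the standard simulation."""

from __future__ import annotations

import os

import pysam
import pytest

from meripeak.simdata import SimConfig, simulate_experiment, simulate_reference, write_reference


def make_bam(path: str, references: list[tuple[str, int]], records: list[dict]) -> str:
    """Write a coordinate-sorted, indexed BAM from record dicts.

    Record keys: name, ref, start, cigar (e.g. '30M'), and optionally
    flag, mapq, tlen, mate_start, mate_ref.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in references],
    }
    ref_index = {n: i for i, (n, _) in enumerate(references)}
    unsorted = path + ".unsorted"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec["name"]
            a.reference_id = ref_index[rec["ref"]]
            a.reference_start = rec["start"]
            a.cigarstring = rec["cigar"]
            a.flag = rec.get("flag", 0)
            a.mapping_quality = rec.get("mapq", 60)
            a.template_length = rec.get("tlen", 0)
            if "mate_start" in rec:
                a.next_reference_id = ref_index[rec.get("mate_ref", rec["ref"])]
                a.next_reference_start = rec["mate_start"]
            a.query_sequence = "A" * a.infer_query_length() if a.infer_query_length() else None
            out.write(a)
    pysam.sort("-o", path, unsorted)
    os.remove(unsorted)
    pysam.index(path)
    return path


@pytest.fixture
def bam_factory(tmp_path):
    def _factory(records, references=(("chr1", 100_000),), name="test.bam"):
        return make_bam(str(tmp_path / name), list(references), records)

    return _factory


@pytest.fixture(scope="session")
def standard_sim(tmp_path_factory):
    """The standard evaluation fixture: 50 transcripts, fold 8, 2e5 fragments, seed 7."""
    out = tmp_path_factory.mktemp("standard_sim")
    cfg = SimConfig(seed=7)
    ref = simulate_reference(cfg)
    paths = write_reference(ref, str(out))
    paths |= simulate_experiment(ref, cfg, str(out))
    return {"cfg": cfg, "ref": ref, **paths}


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A fast low-depth simulation for pipeline-level unit tests."""
    out = tmp_path_factory.mktemp("small_sim")
    cfg = SimConfig(n_transcripts=8, depth=30_000, seed=11)
    ref = simulate_reference(cfg)
    paths = write_reference(ref, str(out))
    paths |= simulate_experiment(ref, cfg, str(out))
    return {"cfg": cfg, "ref": ref, **paths}
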