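"""Shared fixtures: small simulated studies and hand-built read batches."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hybridmeth import SimConfig, simulate_study, study_counts, validate_study
from hybridmeth.config import default_samples
from hybridmeth.context import ValidatedSites
from hybridmeth.reads import OB, OT, ReadBatch

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


def build_batch(
    frags: list[dict],
    chrom: str = "c",
    chrom_len: int = 200,
    read_length: int = 10,
    sample_id: str = "test",
    chroms: list[str] | None = None,
    chrom_lengths: list[int] | None = None,
) -> ReadBatch:
    """Construct a ReadBatch from terse per-fragment specs.

    Each spec: strand (OT/OB), r1_pos, r2_pos, frag_start, frag_len,
    optional hap, and per-read dicts mapping column -> XM char or base
    char (r1_xm, r2_xm, r1_seq, r2_seq). Unspecified XM cells are '.',
    unspecified bases are 'A'.
    """
    from hybridmeth.genome import _CODE

    chroms = chroms or [chrom]
    chrom_lengths = chrom_lengths or [chrom_len]
    n = len(frags)
    rl = read_length
    arr = dict(
        chrom_idx=np.zeros(n, dtype=np.int32),
        frag_start=np.zeros(n, dtype=np.int64),
        frag_len=np.zeros(n, dtype=np.int32),
        strand=np.zeros(n, dtype=np.uint8),
        hap=np.zeros(n, dtype=np.uint8),
        r1_pos=np.zeros(n, dtype=np.int64),
        r2_pos=np.zeros(n, dtype=np.int64),
        r1_seq=np.full((n, rl), _CODE[ord("A")], dtype=np.uint8),
        r2_seq=np.full((n, rl), _CODE[ord("A")], dtype=np.uint8),
        r1_xm=np.full((n, rl), ord("."), dtype=np.uint8),
        r2_xm=np.full((n, rl), ord("."), dtype=np.uint8),
    )
    for i, f in enumerate(frags):
        arr["chrom_idx"][i] = f.get("chrom_idx", 0)
        arr["strand"][i] = f.get("strand", OT)
        arr["hap"][i] = f.get("hap", 0)
        arr["r1_pos"][i] = f["r1_pos"]
        arr["r2_pos"][i] = f.get("r2_pos", f["r1_pos"])
        arr["frag_start"][i] = f.get(
            "frag_start", min(arr["r1_pos"][i], arr["r2_pos"][i])
        )
        arr["frag_len"][i] = f.get(
            "frag_len",
            int(max(arr["r1_pos"][i], arr["r2_pos"][i]) + rl - arr["frag_start"][i]),
        )
        for key, mat in (("r1_xm", "r1_xm"), ("r2_xm", "r2_xm")):
            for col, ch in f.get(key, {}).items():
                arr[mat][i, col] = ord(ch)
        for key, mat in (("r1_seq", "r1_seq"), ("r2_seq", "r2_seq")):
            for col, ch in f.get(key, {}).items():
                arr[mat][i, col] = _CODE[ord(ch)]
    return ReadBatch(
        sample_id=sample_id,
        chroms=chroms,
        chrom_lengths=chrom_lengths,
        read_length=rl,
        **arr,
    )


def clipping_fixture():
    """Three hand-built fragments exercising read2 clipping and
    mate-overlap deduplication; returns (batch, validated, expected).

    expected maps site -> (meth, depth) after extraction.
    """
    frags = [
        # OT fragment: r1 10..19, r2 stored 20..29 (reverse-mapped; stored
        # cols 6..9 are the physical first four, col 0 the physical last).
        dict(
            strand=OT, r1_pos=10, r2_pos=20, frag_start=10, frag_len=20,
            r1_xm={2: "Z", 8: "Z"},
            r2_xm={0: "Z", 1: "z", 6: "Z"},
        ),
        # OT fragment with overlapping mates: r1 30..39, r2 36..45;
        # read1 says Z at site 38, read2 says z -> counted once, meth.
        dict(
            strand=OT, r1_pos=30, r2_pos=36, frag_start=30, frag_len=16,
            r1_xm={0: "Z", 8: "Z"},
            r2_xm={2: "z", 4: "z"},
        ),
        # OB fragment: observations at the plus-strand G map to site pos-1.
        dict(
            strand=OB, r1_pos=54, r2_pos=50, frag_start=50, frag_len=14,
            r1_xm={2: "z"},
        ),
    ]
    batch = build_batch(frags, chrom_len=100)
    validated = ValidatedSites(
        chroms=["c"],
        cpg={"c": np.array([12, 18, 20, 21, 26, 30, 38, 40, 55])},
    )
    expected = {
        12: (1, 1),  # read1 Z
        18: (1, 1),  # read1 Z (read2 does not reach)
        20: (0, 0),  # only read2 stored col 0 = physical last base, clipped
        21: (0, 1),  # read2 retained cell, z
        26: (0, 0),  # only read2 physical-first-four, clipped
        30: (1, 1),
        38: (1, 1),  # overlap: read1 Z beats read2 z
        40: (0, 1),  # read2 cell outside read1 span
        55: (0, 1),  # OB read1 z at plus pos 56 -> site 55
    }
    return batch, validated, expected


@pytest.fixture(scope="session")
def study_small():
    """Default-condition study at desk scale: 1 chromosome x 250 kb,
    all 24 animals, fragment depth 20."""
    cfg = SimConfig(seed=7, n_chroms=1, chrom_length=250_000, depth=20)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def counts_small(study_small):
    validated = validate_study(study_small)
    counts = study_counts(study_small, validated)
    return validated, counts


@pytest.fixture(scope="session")
def study_clean():
    """Error-free study (sequencing error 0) for oracle-exact checks."""
    cfg = SimConfig(
        seed=11, n_chroms=1, chrom_length=200_000, depth=15, error_rate=0.0
    )
    return simulate_study(cfg)
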