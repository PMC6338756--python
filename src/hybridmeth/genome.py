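"""Sequence primitives and synthetic genome-pair generation.

Bases are encoded as uint8: A=0, C=1, G=2, T=3 (N=4, only possible on
imported sequences). Coordinates are 0-based half-open throughout the
library; the VCF writer converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

A, C, G, T, N = 0, 1, 2, 3, 4
BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, N, dtype=np.uint8)
for i, b in enumerate(b"ACGTN"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

# context codes
CTX_NONE, CTX_CPG, CTX_CHG, CTX_CHH = 0, 1, 2, 3

LAMBDA_CHROM = "lambda"


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return BASES[arr].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    return COMPLEMENT[arr[::-1]]


def context_codes(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position cytosine context on each strand.

    Returns ``(plus, minus)`` uint8 arrays of ``len(seq)``. ``plus[p]`` is
    nonzero iff ``seq[p]`` is C, classified by the plus-strand trinucleotide
    starting at ``p``; ``minus[p]`` is nonzero iff ``seq[p]`` is G (a
    minus-strand C), classified by the minus-strand 5'->3' trinucleotide
    (plus positions p, p-1, p-2, complemented). Positions whose trinucleotide
    would run off the chromosome are left unclassified (0), as context there
    is undefined.
    """
    n = len(seq)
    plus = np.zeros(n, dtype=np.uint8)
    minus = np.zeros(n, dtype=np.uint8)
    if n < 3:
        return plus, minus

    is_c = seq == C
    is_g = seq == G

    # plus strand: trinucleotide seq[p], seq[p+1], seq[p+2]
    p_c = is_c[:-2]
    nxt1 = seq[1:-1]
    nxt2 = seq[2:]
    plus[:-2][p_c & (nxt1 == G)] = CTX_CPG
    plus[:-2][p_c & (nxt1 != G) & (nxt2 == G)] = CTX_CHG
    plus[:-2][p_c & (nxt1 != G) & (nxt2 != G)] = CTX_CHH

    # minus strand: complemented trinucleotide at plus positions p, p-1, p-2
    m_c = is_g[2:]
    prv1 = seq[1:-1]
    prv2 = seq[:-2]
    minus[2:][m_c & (prv1 == C)] = CTX_CPG
    minus[2:][m_c & (prv1 != C) & (prv2 == C)] = CTX_CHG
    minus[2:][m_c & (prv1 != C) & (prv2 != C)] = CTX_CHH
    return plus, minus


def cpg_positions(seq: np.ndarray) -> np.ndarray:
    """Plus-strand C positions of CpG dinucleotides."""
    return np.flatnonzero((seq[:-1] == C) & (seq[1:] == G))


@dataclass
class GenomePair:
    """Two equal-length strain assemblies plus the shared lambda spike-in.

    ``p1``/``p2`` map chromosome name -> uint8 sequence; the two assemblies
    differ only at SNV positions. ``snvs`` has columns
    (chrom, pos, ref, alt) with 0-based pos, ref = P1 allele, alt = P2
    allele (single characters).
    """

    p1: dict[str, np.ndarray]
    p2: dict[str, np.ndarray]
    lambda_seq: np.ndarray
    snvs: pd.DataFrame
    islands: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    @property
    def chroms(self) -> list[str]:
        return list(self.p1)

    def chrom_length(self, chrom: str) -> int:
        return self.lambda_seq.size if chrom == LAMBDA_CHROM else self.p1[chrom].size

    def haplotype(self, which: str) -> dict[str, np.ndarray]:
        if which == "P1":
            return self.p1
        if which == "P2":
            return self.p2
        raise KeyError(which)

    def shared_cpg_sites(self, chrom: str) -> np.ndarray:
        """CpG plus-C positions present in *both* assemblies."""
        a = cpg_positions(self.p1[chrom])
        b = cpg_positions(self.p2[chrom])
        return np.intersect1d(a, b)

    def union_cpg_sites(self, chrom: str) -> np.ndarray:
        """CpG plus-C positions present in at least one assembly."""
        a = cpg_positions(self.p1[chrom])
        b = cpg_positions(self.p2[chrom])
        return np.union1d(a, b)


def _random_sequence(rng: np.random.Generator, length: int, gc_rich: bool = False) -> np.ndarray:
    if gc_rich:
        p = [0.15, 0.35, 0.35, 0.15]  # CpG-island-like composition
    else:
        p = [0.30, 0.20, 0.20, 0.30]
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _place_islands(
    rng: np.random.Generator, chrom_len: int, count: int, length: int
) -> list[tuple[int, int]]:
    """Non-overlapping island intervals, uniformly placed, sorted."""
    spans: list[tuple[int, int]] = []
    attempts = 0
    while len(spans) < count and attempts < count * 200:
        attempts += 1
        s = int(rng.integers(0, chrom_len - length))
        e = s + length
        if all(e <= a or s >= b for a, b in spans):
            spans.append((s, e))
    return sorted(spans)


def generate_genomes(config) -> GenomePair:
    """Generate the two strain assemblies and their SNV table.

    The P1 assembly doubles as the alignment reference. A configurable
    fraction of SNVs is placed so as to create or destroy CpG dinucleotides
    in P2, exercising context validation downstream. CpG islands are
    embedded as G+C/CpG-rich stretches shared by both assemblies.
    """
    rng = np.random.default_rng([int(config.seed), 101])
    p1: dict[str, np.ndarray] = {}
    p2: dict[str, np.ndarray] = {}
    snv_rows: list[tuple[str, int, int, int]] = []
    island_rows: list[tuple[str, int, int]] = []

    for chrom in config.chrom_names:
        seq = _random_sequence(rng, config.chrom_length)
        for s, e in _place_islands(
            rng, config.chrom_length, config.cpg_island_count, config.cpg_island_length
        ):
            seq[s:e] = _random_sequence(rng, e - s, gc_rich=True)
            island_rows.append((chrom, s, e))
        alt = seq.copy()

        n_snv = rng.binomial(config.chrom_length, config.snv_rate)
        if n_snv > 0:
            n_cpg_snv = int(round(n_snv * config.cpg_snv_fraction))
            pos_list: list[int] = []
            taken = np.zeros(config.chrom_length, dtype=bool)

            # CpG-disrupting/creating SNVs: half destroy a P1 CpG in P2,
            # half create a P2-only CpG.
            cpgs = cpg_positions(seq)
            n_destroy = n_cpg_snv // 2
            n_create = n_cpg_snv - n_destroy
            if cpgs.size and n_destroy:
                chosen = rng.choice(cpgs, size=min(n_destroy, cpgs.size), replace=False)
                for p in chosen:
                    p = int(p)
                    if taken[p]:
                        continue
                    alt[p] = rng.choice([A, G, T])  # C -> non-C destroys the CpG
                    taken[p] = True
                    pos_list.append(p)
            # create: position q with seq[q] != C and seq[q+1] == G, alt C
            candidates = np.flatnonzero((seq[:-1] != C) & (seq[1:] == G))
            # avoid making a CHG->CpG right after an existing C (harmless either way)
            if candidates.size and n_create:
                chosen = rng.choice(
                    candidates, size=min(n_create, candidates.size), replace=False
                )
                for q in chosen:
                    q = int(q)
                    if taken[q]:
                        continue
                    alt[q] = C
                    taken[q] = True
                    pos_list.append(q)

            n_rest = n_snv - len(pos_list)
            if n_rest > 0:
                free = np.flatnonzero(~taken)
                chosen = rng.choice(free, size=n_rest, replace=False)
                shift = rng.integers(1, 4, size=n_rest)
                for q, sh in zip(chosen, shift):
                    q = int(q)
                    alt[q] = (seq[q] + sh) % 4
                    taken[q] = True
                    pos_list.append(q)

            for p in sorted(pos_list):
                snv_rows.append((chrom, p, int(seq[p]), int(alt[p])))

        p1[chrom] = seq
        p2[chrom] = alt

    lam = _random_sequence(rng, config.lambda_length)
    snvs = pd.DataFrame(snv_rows, columns=["chrom", "pos", "ref_code", "alt_code"])
    snvs["ref"] = [chr(BASES[c]) for c in snvs["ref_code"]]
    snvs["alt"] = [chr(BASES[c]) for c in snvs["alt_code"]]
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return GenomePair(p1=p1, p2=p2, lambda_seq=lam, snvs=snvs, islands=islands)
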