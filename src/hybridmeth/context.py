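"""Validation of genomic cytosine context.

A cytosine's context (CpG / CHG / CHH) is accepted for downstream
analysis only when (a) the context class agrees between the alignment
reference and both strain assemblies, and (b)/(c) at least ``threshold``
(default 75%) of mapped bases at each of the three offsets N, N+1, N+2
are consistent with the expected context in the reads of *each* parental
group separately.

Consistency is conversion-aware: on reads from the original top strand a
T is consistent with an expected C (bisulfite conversion), and on
original-bottom reads an A is consistent with an expected G. At offsets
where the context pattern allows any H (= A/C/T) or any base, every
observation compatible with the pattern counts as consistent. For CpG
context, validation on either strand suffices; CHG and CHH are validated
per strand independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import A, C, CTX_CHG, CTX_CHH, CTX_CPG, G, T, context_codes
from .reads import ReadBatch

_CTX_NAMES = {CTX_CPG: "CpG", CTX_CHG: "CHG", CTX_CHH: "CHH"}


def expected_context(assembly: dict[str, np.ndarray], chrom: str, pos: int, strand: str) -> str:
    """Trinucleotide context of the cytosine at (chrom, pos, strand).

    ``pos`` is the 0-based plus-strand coordinate of the base; for
    ``strand == '-'`` the base must be a plus-strand G (a minus-strand C)
    and the trinucleotide runs in the minus 5'->3' direction. Returns
    ``"undefined"`` where the trinucleotide runs off the chromosome.
    """
    seq = assembly[chrom]
    base = seq[pos]
    if strand == "+":
        if base != C:
            raise ValueError(f"{chrom}:{pos}(+) is not a cytosine")
    elif strand == "-":
        if base != G:
            raise ValueError(f"{chrom}:{pos}(-) is not a cytosine")
    else:
        raise ValueError("strand must be '+' or '-'")
    plus, minus = context_codes(seq)
    code = plus[pos] if strand == "+" else minus[pos]
    return _CTX_NAMES.get(int(code), "undefined")


@dataclass
class ValidatedSites:
    """Validated cytosine sites per context.

    ``cpg[chrom]`` holds plus-strand C positions of validated CpG
    dinucleotides (the site key; both strands' observations merge onto
    it downstream). ``cpg_insufficient`` are CpG sites that failed only
    for lack of coverage at a required offset, kept distinct from
    threshold failures. CHG/CHH sets are per strand.
    """

    chroms: list[str]
    cpg: dict[str, np.ndarray]
    cpg_insufficient: dict[str, np.ndarray] = field(default_factory=dict)
    chg_plus: dict[str, np.ndarray] = field(default_factory=dict)
    chg_minus: dict[str, np.ndarray] = field(default_factory=dict)
    chh_plus: dict[str, np.ndarray] = field(default_factory=dict)
    chh_minus: dict[str, np.ndarray] = field(default_factory=dict)
    report: pd.DataFrame | None = None

    def n_cpg(self) -> int:
        return int(sum(v.size for v in self.cpg.values()))


def _group_pileup(batches: list[ReadBatch], chrom: str, L: int) -> np.ndarray:
    out = np.zeros((2, 4, L), dtype=np.int64)
    for b in batches:
        if chrom in b.chroms:
            out += b.base_pileup(chrom)
    return out


def _consistency_arrays(counts: np.ndarray):
    """Per-position consistent-fraction arrays for the five expected symbols.

    ``counts`` has shape (2 read strands, 4 bases, L). Returns a dict of
    float arrays (NaN where coverage is zero) plus the coverage array:

    * ``C+``: expected plus-strand C  (OT C or T; OB C)
    * ``C-``: expected minus-strand C, i.e. plus-strand G (OB G or A; OT G)
    * ``H+``: expected plus-strand H  (anything but G)
    * ``H-``: expected minus-strand H (anything but plus-strand C)
    * ``any``: always consistent
    """
    ot, ob = counts[0], counts[1]
    cov = counts.sum(axis=(0, 1)).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = {
            "C+": (ot[C] + ot[T] + ob[C]) / cov,
            "C-": (ob[G] + ob[A] + ot[G]) / cov,
            "H+": (cov - ot[G] - ob[G]) / cov,
            "H-": (cov - ot[C] - ob[C]) / cov,
            "any": np.where(cov > 0, 1.0, np.nan),
        }
    for k in fr:
        fr[k] = np.where(cov > 0, fr[k], np.nan)
    return fr, cov


# context pattern -> expected symbols at offsets N, N+1, N+2, per strand.
# Offsets for a minus-strand cytosine run in the minus 5'->3' direction
# (N+1 = pos-1 in plus coordinates).
_PATTERNS = {
    (CTX_CPG, "+"): ("C+", "C-", "any"),
    (CTX_CPG, "-"): ("C-", "C+", "any"),
    (CTX_CHG, "+"): ("C+", "H+", "C-"),
    (CTX_CHG, "-"): ("C-", "H-", "C+"),
    (CTX_CHH, "+"): ("C+", "H+", "H+"),
    (CTX_CHH, "-"): ("C-", "H-", "H-"),
}


def _offsets(pos: np.ndarray, strand: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if strand == "+":
        return pos, pos + 1, pos + 2
    return pos, pos - 1, pos - 2


def validate_contexts(
    group1: list[ReadBatch],
    group2: list[ReadBatch],
    asm1: dict[str, np.ndarray],
    asm2: dict[str, np.ndarray],
    reference: dict[str, np.ndarray] | None = None,
    threshold: float = 0.75,
    contexts: tuple[str, ...] = ("CpG", "CHG", "CHH"),
    report: bool = False,
) -> ValidatedSites:
    """Validate cytosine contexts against assemblies and both read groups.

    ``reference`` defaults to the P1 assembly (the simulator's alignment
    reference), in which case the three-way agreement check degenerates
    to two-way. A site with zero coverage at any required offset in
    either group is not validated and is flagged as insufficient rather
    than as a threshold failure.
    """
    if reference is None:
        reference = asm1
    chroms = list(asm1)
    out = ValidatedSites(chroms=chroms, cpg={}, cpg_insufficient={})
    report_rows: list[pd.DataFrame] = []

    for chrom in chroms:
        L = asm1[chrom].size
        ctx_ref = context_codes(reference[chrom])
        ctx_a1 = context_codes(asm1[chrom])
        ctx_a2 = context_codes(asm2[chrom])
        counts1 = _group_pileup(group1, chrom, L)
        counts2 = _group_pileup(group2, chrom, L)
        fr1, cov1 = _consistency_arrays(counts1)
        fr2, cov2 = _consistency_arrays(counts2)

        def strand_pass(code: int, strand: str, candidates: np.ndarray):
            """(passes, insufficient) boolean arrays over candidate positions."""
            o0, o1, o2 = _offsets(candidates, strand)
            in_bounds = (o2 >= 0) & (o2 < L) & (o1 >= 0) & (o1 < L)
            sym = _PATTERNS[(code, strand)]
            passes = np.zeros(candidates.size, dtype=bool)
            insufficient = np.zeros(candidates.size, dtype=bool)
            ib = np.flatnonzero(in_bounds)
            if ib.size == 0:
                return passes, insufficient
            offs = (o0[ib], o1[ib], o2[ib])
            ok = np.ones(ib.size, dtype=bool)
            insuf = np.zeros(ib.size, dtype=bool)
            for fr in (fr1, fr2):
                for sym_k, off in zip(sym, offs):
                    f = fr[sym_k][off]
                    insuf |= np.isnan(f)
                    ok &= f >= threshold
            ok &= ~insuf
            passes[ib] = ok
            insufficient[ib] = insuf
            return passes, insufficient

        if "CpG" in contexts:
            # site key: plus-strand C position of a CpG present in all
            # three sequences (plus and minus context agree by symmetry)
            cand = np.flatnonzero(
                (ctx_ref[0] == CTX_CPG) & (ctx_a1[0] == CTX_CPG) & (ctx_a2[0] == CTX_CPG)
            )
            plus_pass, plus_insuf = strand_pass(CTX_CPG, "+", cand)
            minus_pass, minus_insuf = strand_pass(CTX_CPG, "-", cand + 1)
            validated = plus_pass | minus_pass
            insufficient = ~validated & (plus_insuf | minus_insuf)
            out.cpg[chrom] = cand[validated]
            out.cpg_insufficient[chrom] = cand[insufficient]
            if report:
                rep = pd.DataFrame({"chrom": chrom, "pos": cand, "validated": validated})
                for label, fr, cov in (("g1", fr1, cov1), ("g2", fr2, cov2)):
                    rep[f"{label}_frac_N"] = fr["C+"][cand]
                    rep[f"{label}_frac_N1"] = fr["C-"][cand + 1]
                    with np.errstate(invalid="ignore"):
                        rep[f"{label}_frac_N2"] = fr["any"][np.minimum(cand + 2, L - 1)]
                report_rows.append(rep)
        if "CHG" in contexts or "CHH" in contexts:
            for code, name in ((CTX_CHG, "CHG"), (CTX_CHH, "CHH")):
                if name not in contexts:
                    continue
                for strand, store in (
                    ("+", getattr(out, f"{name.lower()}_plus")),
                    ("-", getattr(out, f"{name.lower()}_minus")),
                ):
                    k = 0 if strand == "+" else 1
                    cand = np.flatnonzero(
                        (ctx_ref[k] == code) & (ctx_a1[k] == code) & (ctx_a2[k] == code)
                    )
                    passes, _ = strand_pass(code, strand, cand)
                    store[chrom] = cand[passes]

    if report and report_rows:
        out.report = pd.concat(report_rows, ignore_index=True)
    return out


def cpg_scan_oracle(
    reference: dict[str, np.ndarray],
    asm1: dict[str, np.ndarray],
    asm2: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Direct sequence-scan CpG set: positions whose CpG is present in all
    three sequences (trinucleotide in bounds). The expected validated set
    under error-free, fully covered reads."""
    out = {}
    for chrom in asm1:
        sets = []
        for seq in (reference[chrom], asm1[chrom], asm2[chrom]):
            p = np.flatnonzero((seq[:-2] == C) & (seq[1:-1] == G))
            sets.append(p)
        common = sets[0]
        for s in sets[1:]:
            common = np.intersect1d(common, s)
        out[chrom] = common
    return out
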