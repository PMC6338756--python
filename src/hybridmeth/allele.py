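"""Parental-origin assignment of F1 bisulfite fragments via diagnostic SNVs.

Bisulfite conversion collapses base identities in a strand-dependent
way: on original-top (OT) reads a genomic C may appear as C or T, and on
original-bottom (OB) reads a genomic G may appear as G or A. An
inter-strain SNV is therefore *diagnostic* on a given read strand only
through bases unique to one allele's bisulfite image. A C/T SNV read on
the OT strand is the canonical partial case: an observed C proves the
C allele, while an observed T proves nothing.

Fragments are assigned to a parent when they carry allele-unique
evidence for exactly one parent; conflicting fragments are reported
separately, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import MethylationCounts, weighted_score
from .reads import OB, OT, ReadBatch

# bisulfite image sets, indexed [strand][base] -> frozenset of observed codes
from .genome import A, C, G, T

IMAGES = {
    OT: {A: frozenset({A}), C: frozenset({C, T}), G: frozenset({G}), T: frozenset({T})},
    OB: {A: frozenset({A}), C: frozenset({C}), G: frozenset({G, A}), T: frozenset({T})},
}

PARENT_UNINFORMATIVE, PARENT_P1, PARENT_P2, PARENT_CONFLICT = 0, 1, 2, 3
PARENT_LABELS = {0: "uninformative", 1: "P1", 2: "P2", 3: "conflict"}


@dataclass(frozen=True)
class StrandDiagnosability:
    unique_p1: frozenset[int]  # observed bases proving the P1 allele
    unique_p2: frozenset[int]
    level: str  # "full" | "partial" | "none"


def classify_snv(ref: int | str, alt: int | str) -> dict[int, StrandDiagnosability]:
    """Per-read-strand diagnosability of a biallelic SNV.

    ``ref``/``alt`` are the P1/P2 alleles (plus-strand, base code or
    letter). A strand is fully diagnostic when the two alleles' bisulfite
    images are disjoint, partially diagnostic when only one allele has a
    unique observable base.
    """
    code = {"A": A, "C": C, "G": G, "T": T}
    if isinstance(ref, str):
        ref = code.get(ref.upper(), -1)
    if isinstance(alt, str):
        alt = code.get(alt.upper(), -1)
    if ref not in (A, C, G, T) or alt not in (A, C, G, T):
        raise ValueError("SNV alleles must be A/C/G/T")
    if ref == alt:
        raise ValueError("SNV alleles must differ")
    out = {}
    for strand in (OT, OB):
        img1 = IMAGES[strand][ref]
        img2 = IMAGES[strand][alt]
        u1 = img1 - img2
        u2 = img2 - img1
        if not (img1 & img2):
            level = "full"
        elif u1 or u2:
            level = "partial"
        else:
            level = "none"
        out[strand] = StrandDiagnosability(frozenset(u1), frozenset(u2), level)
    return out


def _support_lookup(snvs: pd.DataFrame) -> np.ndarray:
    """(n_snv, 2 strands, 4 bases) -> 0 none / 1 supports P1 / 2 supports P2."""
    lut = np.zeros((len(snvs), 2, 4), dtype=np.int8)
    for i, (ref, alt) in enumerate(zip(snvs["ref"], snvs["alt"])):
        diag = classify_snv(ref, alt)
        for strand in (OT, OB):
            for b in diag[strand].unique_p1:
                lut[i, strand, b] = 1
            for b in diag[strand].unique_p2:
                lut[i, strand, b] = 2
    return lut


@dataclass
class FragmentAssignments:
    """Per-fragment parental-origin calls for one sample's batch.

    ``support_obs`` records every allele-unique base observation
    (fragment, chrom, SNV position, read strand, observed base, supported
    parent) for auditing. ``cpg_calls`` carries the fragment-resolved
    CpG methylation calls (site key = plus-strand C position) used by
    allelic profiling.
    """

    sample_id: str
    batch: ReadBatch
    parent: np.ndarray  # (n_fragments,) int8 codes
    n_support_p1: np.ndarray
    n_support_p2: np.ndarray
    support_obs: pd.DataFrame
    cpg_calls: pd.DataFrame  # frag, chrom, site, meth
    min_support: int = 1

    def counts(self) -> dict[str, int]:
        return {
            label: int((self.parent == code).sum())
            for code, label in PARENT_LABELS.items()
        }


def assign_fragments(
    batch: ReadBatch,
    snvs: pd.DataFrame,
    validated_sites: dict[str, np.ndarray] | None = None,
    min_support: int = 1,
) -> FragmentAssignments:
    """Assign each fragment to its parental allele via diagnostic SNVs.

    Base observations at SNV positions are collected after the standard
    read2 clipping and mate-overlap deduplication, translated to allele
    support through per-strand bisulfite images, and aggregated per
    fragment: a fragment is assigned to a parent when it has at least
    ``min_support`` allele-unique observations for that parent and none
    for the other; both kinds of evidence yield ``conflict``, neither
    yields ``uninformative``. The fragment's CpG calls are recorded from
    the methylation-call string (restricted to ``validated_sites`` when
    given). The simulator's truth haplotype tag is never consulted.
    """
    n = batch.n_fragments
    sup1 = np.zeros(n, dtype=np.int32)
    sup2 = np.zeros(n, dtype=np.int32)
    obs_rows = []
    call_rows = []
    _Z, _z = ord("Z"), ord("z")

    for ci, chrom in enumerate(batch.chroms):
        in_chrom = batch.chrom_idx == ci
        if not in_chrom.any():
            continue
        chrom_snvs = snvs[snvs["chrom"] == chrom]
        snv_pos = chrom_snvs["pos"].to_numpy()
        order = np.argsort(snv_pos)
        snv_pos = snv_pos[order]
        lut = _support_lookup(chrom_snvs.iloc[order]) if len(chrom_snvs) else None
        val = validated_sites.get(chrom) if validated_sites else None

        for read in (1, 2):
            rows, cols, pos = batch.read_cells(read)
            keep = in_chrom[rows]
            rows, cols, pos = rows[keep], cols[keep], pos[keep]
            if rows.size == 0:
                continue
            seqmat = batch.r1_seq if read == 1 else batch.r2_seq
            xmat = batch.r1_xm if read == 1 else batch.r2_xm
            strand = batch.strand[rows]

            # --- SNV support ---
            if lut is not None and snv_pos.size:
                si = np.searchsorted(snv_pos, pos)
                hit = (si < snv_pos.size) & (snv_pos[np.minimum(si, snv_pos.size - 1)] == pos)
                if hit.any():
                    hrows = rows[hit]
                    hbase = seqmat[hrows, cols[hit]]
                    hstrand = strand[hit].astype(np.int64)
                    hsnv = si[hit]
                    ok = hbase < 4
                    code = np.zeros(hsnv.size, dtype=np.int8)
                    code[ok] = lut[hsnv[ok], hstrand[ok], hbase[ok]]
                    sup1 += np.bincount(hrows[code == 1], minlength=n)
                    sup2 += np.bincount(hrows[code == 2], minlength=n)
                    informative = code > 0
                    if informative.any():
                        obs_rows.append(
                            pd.DataFrame(
                                {
                                    "frag": hrows[informative],
                                    "chrom": chrom,
                                    "snv_pos": snv_pos[hsnv[informative]],
                                    "strand": np.where(
                                        hstrand[informative] == OT, "OT", "OB"
                                    ),
                                    "base": hbase[informative],
                                    "parent": code[informative],
                                }
                            )
                        )

            # --- CpG calls ---
            xm = xmat[rows, cols]
            zm = (xm == _Z) | (xm == _z)
            if zm.any():
                zrows = rows[zm]
                site = pos[zm] - (strand[zm] == OB)
                methv = xm[zm] == _Z
                if val is not None:
                    vi = np.searchsorted(val, site)
                    okv = (vi < val.size) & (val[np.minimum(vi, val.size - 1)] == site)
                    zrows, site, methv = zrows[okv], site[okv], methv[okv]
                call_rows.append(
                    pd.DataFrame(
                        {"frag": zrows, "chrom": chrom, "site": site, "meth": methv}
                    )
                )

    parent = np.full(n, PARENT_UNINFORMATIVE, dtype=np.int8)
    parent[(sup1 >= min_support) & (sup2 == 0)] = PARENT_P1
    parent[(sup2 >= min_support) & (sup1 == 0)] = PARENT_P2
    parent[(sup1 >= 1) & (sup2 >= 1)] = PARENT_CONFLICT
    support_obs = (
        pd.concat(obs_rows, ignore_index=True)
        if obs_rows
        else pd.DataFrame(columns=["frag", "chrom", "snv_pos", "strand", "base", "parent"])
    )
    cpg_calls = (
        pd.concat(call_rows, ignore_index=True)
        if call_rows
        else pd.DataFrame(columns=["frag", "chrom", "site", "meth"])
    )
    return FragmentAssignments(
        sample_id=batch.sample_id,
        batch=batch,
        parent=parent,
        n_support_p1=sup1,
        n_support_p2=sup2,
        support_obs=support_obs,
        cpg_calls=cpg_calls,
        min_support=min_support,
    )


def allelic_methylation(
    assignments: list[FragmentAssignments],
    dmrs,
    parental_counts: MethylationCounts | None = None,
    p1_sample_ids: list[str] | None = None,
    p2_sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-DMR pooled methylation on P1- and P2-assigned F1 fragments,
    paired (when parental counts are given) with the parental strains'
    weighted scores over the same region. Undefined fractions (no
    assigned CpG observations) are NaN."""
    rows = []
    for r in dmrs:
        chrom, start, end = r.chrom, r.start, r.end
        tot = {PARENT_P1: [0, 0], PARENT_P2: [0, 0]}  # parent -> [meth, n]
        for asn in assignments:
            calls = asn.cpg_calls
            sel = calls[
                (calls["chrom"] == chrom)
                & (calls["site"] >= start)
                & (calls["site"] < end)
            ]
            if not len(sel):
                continue
            par = asn.parent[sel["frag"].to_numpy()]
            for code in (PARENT_P1, PARENT_P2):
                m = par == code
                tot[code][0] += int(sel["meth"].to_numpy()[m].sum())
                tot[code][1] += int(m.sum())
        row = {
            "chrom": chrom,
            "start": start,
            "end": end,
            "p1_frac": tot[PARENT_P1][0] / tot[PARENT_P1][1] if tot[PARENT_P1][1] else float("nan"),
            "p1_n_obs": tot[PARENT_P1][1],
            "p2_frac": tot[PARENT_P2][0] / tot[PARENT_P2][1] if tot[PARENT_P2][1] else float("nan"),
            "p2_n_obs": tot[PARENT_P2][1],
        }
        if parental_counts is not None and p1_sample_ids and p2_sample_ids:
            row["parent_p1_score"] = weighted_score(
                parental_counts, chrom, start, end, p1_sample_ids
            ).score
            row["parent_p2_score"] = weighted_score(
                parental_counts, chrom, start, end, p2_sample_ids
            ).score
        rows.append(row)
    return pd.DataFrame(rows)


def read_matrix(dmr, assignments: FragmentAssignments, sites: np.ndarray) -> pd.DataFrame:
    """Fragment x CpG-site call matrix for one DMR.

    Rows are assigned fragments grouped by parent (P1 block first), in
    deterministic order (leftmost position, then fragment index); columns
    are the region's CpG site positions. Cells: ``M`` methylated, ``u``
    unmethylated, ``x`` covered without a CpG call on that allele (e.g.
    the SNV destroyed the cytosine), ``.`` no mapped base.
    """
    batch = assignments.batch
    chrom = dmr.chrom
    ci = batch.chroms.index(chrom)
    sites = sites[(sites >= dmr.start) & (sites < dmr.end)]
    frag_mask = (
        (batch.chrom_idx == ci)
        & (batch.frag_start < dmr.end)
        & (batch.frag_start + batch.frag_len > dmr.start)
        & np.isin(assignments.parent, [PARENT_P1, PARENT_P2])
    )
    frags = np.flatnonzero(frag_mask)
    order = np.lexsort(
        (frags, batch.frag_start[frags], (assignments.parent[frags] != PARENT_P1).astype(int))
    )
    frags = frags[order]
    mat = pd.DataFrame(".", index=[f"frag{f}" for f in frags], columns=sites)
    row_of = {f: i for i, f in enumerate(frags)}
    parent_col = [PARENT_LABELS[int(assignments.parent[f])] for f in frags]

    for read in (1, 2):
        rows, cols, pos = batch.read_cells(read)
        keep = frag_mask[rows]
        rows, cols, pos = rows[keep], cols[keep], pos[keep]
        xmat = batch.r1_xm if read == 1 else batch.r2_xm
        xm = xmat[rows, cols]
        strand = batch.strand[rows]
        site = pos - (strand == OB)
        in_region = np.isin(site, sites)
        for rrow, s, x in zip(rows[in_region], site[in_region], xm[in_region]):
            cur = mat.iat[row_of[rrow], int(np.searchsorted(sites, s))]
            if x == ord("Z"):
                mat.iat[row_of[rrow], int(np.searchsorted(sites, s))] = "M"
            elif x == ord("z"):
                mat.iat[row_of[rrow], int(np.searchsorted(sites, s))] = "u"
            elif cur == ".":
                mat.iat[row_of[rrow], int(np.searchsorted(sites, s))] = "x"
    mat.insert(0, "parent", parent_col)
    return mat
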