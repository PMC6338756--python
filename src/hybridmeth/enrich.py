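"""Permutation-based genomic-context statistics for region sets.

The null model preserves the query set's length multiset: every
iteration places one random region of identical length per query region,
uniformly over the allowed autosomal space (optionally excluding an
assembly-gap mask, optionally chromosome-matched). Empirical p-values
carry an add-one correction and can never be zero.

All interval arithmetic is 0-based half-open; an overlap requires at
least one shared base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import empirical_p, rank_sum_test


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge possibly-overlapping intervals (chrom, start, end)."""
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        g = grp.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(g["start"], g["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _allowed_spans(
    chrom_lengths: dict[str, int], gap_mask: pd.DataFrame | None
) -> pd.DataFrame:
    """Placeable intervals: chromosomes minus the (merged) gap mask."""
    rows = []
    gaps = merge_intervals(gap_mask) if gap_mask is not None and len(gap_mask) else None
    for chrom, L in chrom_lengths.items():
        cur = 0
        if gaps is not None:
            for s, e in gaps[gaps["chrom"] == chrom][["start", "end"]].itertuples(index=False):
                if s > cur:
                    rows.append((chrom, cur, s))
                cur = max(cur, e)
        if cur < L:
            rows.append((chrom, cur, L))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class RandomRegionSets:
    """``n_iter`` length-matched random placements of a query region set.

    ``chrom_idx[i, j]`` / ``start[i, j]`` locate the random counterpart
    of query region ``j`` in iteration ``i``; ``lengths[j]`` is shared by
    construction with the query.
    """

    chrom_names: list[str]
    chrom_idx: np.ndarray  # (n_iter, n_regions) int32
    start: np.ndarray  # (n_iter, n_regions) int64
    lengths: np.ndarray  # (n_regions,) int64
    seed: int

    @property
    def n_iter(self) -> int:
        return self.chrom_idx.shape[0]

    def iteration(self, i: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [self.chrom_names[c] for c in self.chrom_idx[i]],
                "start": self.start[i],
                "end": self.start[i] + self.lengths,
            }
        )


def random_regions(
    query: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_iter: int = 1000,
    seed: int = 0,
    gap_mask: pd.DataFrame | None = None,
    chrom_matched: bool = False,
) -> RandomRegionSets:
    """Generate size-matched random region sets.

    Each query region is matched, per iteration, by one random region of
    identical length placed uniformly over the allowed space (placement
    probability of a span is proportional to its number of valid start
    positions). Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    spans = _allowed_spans(chrom_lengths, gap_mask)
    chrom_names = list(chrom_lengths)
    name_to_idx = {c: i for i, c in enumerate(chrom_names)}
    span_chrom = spans["chrom"].map(name_to_idx).to_numpy()
    span_start = spans["start"].to_numpy()
    span_len = (spans["end"] - spans["start"]).to_numpy()

    lengths = (query["end"] - query["start"]).to_numpy().astype(np.int64)
    if (lengths <= 0).any():
        raise ValueError("query regions must have positive length")
    n_regions = lengths.size
    chrom_idx = np.zeros((n_iter, n_regions), dtype=np.int32)
    start = np.zeros((n_iter, n_regions), dtype=np.int64)

    for j in range(n_regions):
        L = int(lengths[j])
        if chrom_matched:
            qc = name_to_idx[query["chrom"].iloc[j]]
            ok = span_chrom == qc
        else:
            ok = np.ones(span_chrom.size, dtype=bool)
        w = np.maximum(span_len - L + 1, 0) * ok
        total = w.sum()
        if total == 0:
            raise ValueError(
                f"region of length {L} does not fit in any allowed span"
            )
        cw = np.cumsum(w)
        pick = np.searchsorted(cw, rng.random(n_iter) * total, side="right")
        off = np.floor(rng.random(n_iter) * (span_len[pick] - L + 1)).astype(np.int64)
        chrom_idx[:, j] = span_chrom[pick]
        start[:, j] = span_start[pick] + off
    return RandomRegionSets(
        chrom_names=chrom_names,
        chrom_idx=chrom_idx,
        start=start,
        lengths=lengths,
        seed=seed,
    )


def _track_arrays(track: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(track)
    return {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in merged.groupby("chrom")
    }


def _hits(
    chrom: np.ndarray, start: np.ndarray, end: np.ndarray, track_arr
) -> np.ndarray:
    """Boolean: region intersects >= 1 merged track interval by >= 1 bp."""
    out = np.zeros(start.size, dtype=bool)
    for c in np.unique(chrom):
        if c not in track_arr:
            continue
        ts, te = track_arr[c]
        m = chrom == c
        # for merged sorted intervals: overlap iff some interval has
        # start < region_end and end > region_start
        n_start_before = np.searchsorted(ts, end[m], side="left")
        n_end_before = np.searchsorted(te, start[m], side="right")
        out[m] = n_start_before > n_end_before
    return out


@dataclass
class EnrichmentResult:
    track_name: str
    observed: float  # fraction of query regions overlapping the track
    null_mean: float
    null_sd: float
    p_value: float  # empirical, add-one corrected
    fold: float
    n_iter: int
    n_regions: int


def overlap_enrichment(
    query: pd.DataFrame,
    track: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_iter: int = 1000,
    seed: int = 0,
    gap_mask: pd.DataFrame | None = None,
    chrom_matched: bool = False,
    track_name: str = "track",
) -> EnrichmentResult:
    """Region-level overlap fraction of the query vs the size-matched null.

    A region counts once no matter how many track intervals it hits,
    matching a single per-set overlap-fraction readout.
    """
    track_arr = _track_arrays(track) if len(track) else {}
    qc = query["chrom"].to_numpy()
    qs = query["start"].to_numpy()
    qe = query["end"].to_numpy()
    if not track_arr:
        return EnrichmentResult(track_name, 0.0, 0.0, 0.0, 1.0, 0.0, n_iter, qs.size)
    observed = float(_hits(qc, qs, qe, track_arr).mean())
    rnd = random_regions(
        query, chrom_lengths, n_iter=n_iter, seed=seed, gap_mask=gap_mask,
        chrom_matched=chrom_matched,
    )
    null = np.zeros(n_iter)
    names = np.array(rnd.chrom_names, dtype=object)
    for i in range(n_iter):
        null[i] = _hits(
            names[rnd.chrom_idx[i]], rnd.start[i], rnd.start[i] + rnd.lengths, track_arr
        ).mean()
    p = empirical_p(observed, null)
    nm = float(null.mean())
    return EnrichmentResult(
        track_name=track_name,
        observed=observed,
        null_mean=nm,
        null_sd=float(null.std(ddof=0)),
        p_value=p,
        fold=observed / nm if nm > 0 else float("inf") if observed > 0 else 0.0,
        n_iter=n_iter,
        n_regions=qs.size,
    )


def _point_stats(
    regions: pd.DataFrame, points: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region (count of points inside, distance to nearest point).

    Distance is measured from the nearest region boundary and is 0 when a
    point lies inside; NaN when the chromosome has no points.
    """
    n = len(regions)
    count = np.zeros(n, dtype=np.int64)
    dist = np.full(n, np.nan)
    for chrom, grp in regions.groupby("chrom"):
        pts = points.get(chrom)
        idx = grp.index.to_numpy()
        if pts is None or pts.size == 0:
            continue
        pts = np.sort(pts)
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        lo = np.searchsorted(pts, s, side="left")
        hi = np.searchsorted(pts, e, side="left")
        count[idx] = hi - lo
        d = np.full(idx.size, np.inf)
        inside = hi > lo
        d[inside] = 0
        left_ok = lo > 0
        d[left_ok & ~inside] = s[left_ok & ~inside] - pts[lo[left_ok & ~inside] - 1]
        right_ok = hi < pts.size
        sel = right_ok & ~inside
        d[sel] = np.minimum(d[sel], pts[hi[sel]] - e[sel] + 1)
        dist[idx] = d
    return count, dist


@dataclass
class ProximityStats:
    """SNV count / nearest-SNV distance per region, query vs matched random."""

    query: pd.DataFrame  # chrom, start, end, snv_count, snv_distance
    random: pd.DataFrame
    p_count: float  # rank-sum on counts, query vs random
    frac_contains_snv: float
    frac_within_1kb: float


def snv_stats(
    query: pd.DataFrame,
    snvs: pd.DataFrame,
    matched_random: pd.DataFrame,
) -> ProximityStats:
    """Local SNV burden of a region set versus size-matched random regions."""
    points = {c: g["pos"].to_numpy() for c, g in snvs.groupby("chrom")}
    out = {}
    for name, regs in (("query", query), ("random", matched_random)):
        regs = regs.reset_index(drop=True)
        count, dist = _point_stats(regs, points)
        df = regs[["chrom", "start", "end"]].copy()
        df["snv_count"] = count
        df["snv_distance"] = dist
        out[name] = df
    qd = out["query"]["snv_distance"].to_numpy()
    return ProximityStats(
        query=out["query"],
        random=out["random"],
        p_count=rank_sum_test(
            out["query"]["snv_count"].to_numpy().astype(float),
            out["random"]["snv_count"].to_numpy().astype(float),
        ),
        frac_contains_snv=float(np.mean(qd[~np.isnan(qd)] == 0)) if np.isfinite(qd).any() else float("nan"),
        frac_within_1kb=float(np.mean(qd[~np.isnan(qd)] <= 1000)) if np.isfinite(qd).any() else float("nan"),
    )


def tss_distance(
    query: pd.DataFrame, gene_models: pd.DataFrame, far_threshold: int = 10_000
) -> tuple[np.ndarray, float]:
    """Distance from each region to the nearest transcription start site.

    The TSS of a plus-strand gene is its start; of a minus-strand gene
    its 3'-most genomic coordinate (end - 1). Distance is 0 when a TSS
    falls inside the region. Returns (distances, fraction beyond
    ``far_threshold``).
    """
    if not len(gene_models):
        raise ValueError("empty gene model set")
    gm = gene_models.reset_index(drop=True)
    tss = np.where(gm["strand"] == "+", gm["start"], gm["end"] - 1)
    points: dict[str, np.ndarray] = {
        chrom: np.sort(tss[grp.index.to_numpy()]) for chrom, grp in gm.groupby("chrom")
    }
    _, dist = _point_stats(query.reset_index(drop=True), points)
    finite = dist[~np.isnan(dist)]
    frac_far = float(np.mean(finite > far_threshold)) if finite.size else float("nan")
    return dist, frac_far


def cpg_density(
    query: pd.DataFrame,
    genome: dict[str, np.ndarray],
    matched_random: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray | None, float]:
    """CpG dinucleotide density (count / bp) per region, with an optional
    size-matched random comparison (rank-sum p)."""
    from .genome import C, G

    prefix: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        is_cg = np.zeros(seq.size + 1, dtype=np.int64)
        is_cg[1:-1] = (seq[:-1] == C) & (seq[1:] == G)
        prefix[chrom] = np.cumsum(is_cg)

    def densities(regs: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(regs))
        for i, (chrom, s, e) in enumerate(
            regs[["chrom", "start", "end"]].itertuples(index=False)
        ):
            if e <= s:
                raise ValueError("zero-length region")
            cp = prefix[chrom]
            # CG starts fully inside [s, e): start position in [s, e-1)
            n_cg = int(cp[max(e - 1, s)] - cp[s])
            out[i] = n_cg / (e - s)
        return out

    q = densities(query)
    if matched_random is None:
        return q, None, float("nan")
    r = densities(matched_random)
    return q, r, rank_sum_test(q, r)
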