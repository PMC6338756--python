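"""Differential methylation calling, filtering and summaries.

Differentially methylated cytosines (DMCs) are called per site with a
two-sided exact test on pooled group counts at fixed thresholds
(p < 0.01 and group-mean difference >= 0.2 by default). Regions (DMRs)
come from a nonparametric segmentation caller: within gap-limited runs
of validated CpGs it finds maximal between-group mean-difference
windows, accepts them on a pooled weighted-score difference plus a
per-sample rank-sum test, and recurses into the flanks. Candidate or
imported regions then pass the filter suite: at least five CpGs, a
weighted-score difference of at least 20%, no group with average depth
above 500x, and no more than a 5-fold depth imbalance between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import MethylationCounts, per_sample_region_scores
from .stats import fisher_exact_2x2, rank_sum_test

FLAG_MIN_CPGS = "min_cpgs"
FLAG_MIN_DIFF = "min_diff"
FLAG_DEPTH_CAP = "depth_cap"
FLAG_DEPTH_RATIO = "depth_ratio"
FLAG_LOW_COVERAGE = "low_coverage"


@dataclass(frozen=True)
class GroupComparison:
    """Two disjoint sample groups to contrast (a vs b)."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each group needs >= 2 samples")

    def swapped(self) -> "GroupComparison":
        return GroupComparison(self.name, self.group_b, self.group_a)


@dataclass
class DMRegion:
    """A (candidate or reported) differentially methylated region."""

    chrom: str
    start: int  # 0-based half-open, covering the CpG dinucleotides
    end: int
    polarity: str  # "a>b" | "b>a"
    n_cpgs: int = 0
    score_a: float = float("nan")  # pooled weighted methylation scores
    score_b: float = float("nan")
    depth_a: float = float("nan")  # per-site average total group depth
    depth_b: float = float("nan")
    p_value: float = float("nan")
    filter_flags: set[str] = field(default_factory=set)
    source: str = "internal"  # "internal" | "imported"

    @property
    def diff(self) -> float:
        return self.score_a - self.score_b

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def passed(self) -> bool:
        return not self.filter_flags

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and self.end > start


def _group_stats(counts: MethylationCounts, comparison: GroupComparison):
    """Per-chromosome per-site group means, pooled counts and usability."""
    ia = counts.sample_index(comparison.group_a)
    ib = counts.sample_index(comparison.group_b)
    out = {}
    for chrom in counts.chroms:
        m = counts.meth[chrom].astype(np.float64)
        d = counts.depth[chrom].astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(d > 0, m / d, np.nan)
        covered_a = (d[:, ia] > 0).sum(axis=1)
        covered_b = (d[:, ib] > 0).sum(axis=1)
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_a = np.nanmean(np.where(d[:, ia] > 0, frac[:, ia], np.nan), axis=1)
            mean_b = np.nanmean(np.where(d[:, ib] > 0, frac[:, ib], np.nan), axis=1)
        out[chrom] = {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "covered_a": covered_a,
            "covered_b": covered_b,
            "pooled_meth_a": m[:, ia].sum(axis=1),
            "pooled_depth_a": d[:, ia].sum(axis=1),
            "pooled_meth_b": m[:, ib].sum(axis=1),
            "pooled_depth_b": d[:, ib].sum(axis=1),
        }
    return out


def call_dmcs(
    counts: MethylationCounts,
    comparison: GroupComparison,
    p_thresh: float = 0.01,
    min_diff: float = 0.2,
    bh: bool = False,
) -> pd.DataFrame:
    """Call differentially methylated cytosines.

    Group means are unweighted means of per-sample fractions over samples
    with depth > 0; the p-value is a two-sided exact test on the pooled
    2x2 (meth/unmeth x group) table. Sites lacking coverage in either
    group are skipped. With ``bh=True``, Benjamini-Hochberg-adjusted
    q-values replace raw p-values in the threshold.
    """
    stats = _group_stats(counts, comparison)
    rows = []
    for chrom in counts.chroms:
        st = stats[chrom]
        usable = (st["covered_a"] >= 1) & (st["covered_b"] >= 1)
        diff = st["mean_a"] - st["mean_b"]
        cand = np.flatnonzero(usable if bh else (usable & (np.abs(diff) >= min_diff)))
        for i in cand:
            ma = int(st["pooled_meth_a"][i])
            ua = int(st["pooled_depth_a"][i] - ma)
            mb = int(st["pooled_meth_b"][i])
            ub = int(st["pooled_depth_b"][i] - mb)
            p = fisher_exact_2x2(ma, ua, mb, ub)
            rows.append(
                (
                    chrom,
                    int(counts.positions[chrom][i]),
                    float(st["mean_a"][i]),
                    float(st["mean_b"][i]),
                    float(diff[i]),
                    p,
                )
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "mean_a", "mean_b", "diff", "p_value"]
    )
    if bh and len(df):
        df["q_value"] = sps.false_discovery_control(df["p_value"], method="bh")
        keep = (df["q_value"] < p_thresh) & (df["diff"].abs() >= min_diff)
    else:
        keep = df["p_value"] < p_thresh if len(df) else pd.Series(dtype=bool)
    return df[keep].reset_index(drop=True) if len(df) else df


def _best_window(d: np.ndarray, min_len: int) -> tuple[int, int, float]:
    """Max-mean window of length in [min_len, 2*min_len - 1].

    Any window of length >= min_len splits into two windows of length in
    this range, one of which has at least the same mean, so the search is
    exact for the max-mean-with-minimum-length problem.
    """
    n = d.size
    csum = np.concatenate([[0.0], np.cumsum(d)])
    best = (-np.inf, 0, min_len)
    for w in range(min_len, min(2 * min_len - 1, n) + 1):
        means = (csum[w:] - csum[:-w]) / w
        k = int(np.argmax(means))
        if means[k] > best[0]:
            best = (float(means[k]), k, w)
    return best[1], best[1] + best[2], best[0]


def _extend(d: np.ndarray, i: int, j: int, sign: float, thresh: float) -> tuple[int, int]:
    """Grow [i, j) while flanking per-site diffs stay informative; a single
    below-threshold site may be skipped when its neighbour rescues it."""
    while i > 0:
        if sign * d[i - 1] >= thresh:
            i -= 1
        elif i > 1 and sign * d[i - 2] >= thresh:
            i -= 2
        else:
            break
    n = d.size
    while j < n:
        if sign * d[j] >= thresh:
            j += 1
        elif j + 1 < n and sign * d[j + 1] >= thresh:
            j += 2
        else:
            break
    return i, j


def _evaluate_region(
    counts: MethylationCounts,
    comparison: GroupComparison,
    chrom: str,
    start: int,
    end: int,
) -> dict:
    ia = counts.sample_index(comparison.group_a)
    ib = counts.sample_index(comparison.group_b)
    scores = per_sample_region_scores(counts, chrom, start, end)
    sa, sb = scores[ia], scores[ib]
    sl = counts.region_index(chrom, start, end)
    da = counts.depth[chrom][sl][:, ia].sum(axis=1)
    db = counts.depth[chrom][sl][:, ib].sum(axis=1)
    ma = counts.meth[chrom][sl][:, ia].sum()
    mb = counts.meth[chrom][sl][:, ib].sum()
    return {
        "n_cpgs": sl.stop - sl.start,
        "scores_a": sa,
        "scores_b": sb,
        "covered_a": int((~np.isnan(sa)).sum()),
        "covered_b": int((~np.isnan(sb)).sum()),
        "score_a": float(ma / da.sum()) if da.sum() > 0 else float("nan"),
        "score_b": float(mb / db.sum()) if db.sum() > 0 else float("nan"),
        "depth_a": float(da.mean()) if da.size else float("nan"),
        "depth_b": float(db.mean()) if db.size else float("nan"),
    }


def segment_dmrs(
    counts: MethylationCounts,
    comparison: GroupComparison,
    min_cpgs: int = 5,
    max_gap: int = 300,
    min_diff: float = 0.2,
    p_thresh: float = 0.05,
) -> list[DMRegion]:
    """Segmentation DMR caller.

    Within each run of consecutive validated CpGs (inter-site gap
    <= ``max_gap``), finds the sub-window of >= ``min_cpgs`` sites
    maximising the absolute mean per-site group difference, extends it
    over informative flanking sites, and accepts it when the pooled
    weighted-score difference reaches ``min_diff`` and a two-sided
    rank-sum test on per-sample regional scores gives p < ``p_thresh``.
    Accepted windows are excised and the flanks are re-searched, so
    candidates never overlap. Candidates whose groups lack two covered
    samples are returned flagged rather than silently dropped.
    """
    stats = _group_stats(counts, comparison)
    out: list[DMRegion] = []
    for chrom in counts.chroms:
        st = stats[chrom]
        usable = np.flatnonzero((st["covered_a"] >= 1) & (st["covered_b"] >= 1))
        if usable.size < min_cpgs:
            continue
        pos = counts.positions[chrom][usable]
        d = (st["mean_a"] - st["mean_b"])[usable]
        run_breaks = np.flatnonzero(np.diff(pos) > max_gap)
        run_starts = np.concatenate([[0], run_breaks + 1])
        run_ends = np.concatenate([run_breaks + 1, [pos.size]])

        def search(lo: int, hi: int) -> None:
            if hi - lo < min_cpgs:
                return
            ip, jp, mp = _best_window(d[lo:hi], min_cpgs)
            im, jm, mm = _best_window(-d[lo:hi], min_cpgs)
            if mp >= mm:
                i, j, mean, sign = lo + ip, lo + jp, mp, 1.0
            else:
                i, j, mean, sign = lo + im, lo + jm, mm, -1.0
            if mean < min_diff:
                return
            i, j = _extend(d[lo:hi], i - lo, j - lo, sign, min_diff / 2.0)
            i, j = lo + i, lo + j
            start = int(pos[i])
            end = int(pos[j - 1]) + 2
            ev = _evaluate_region(counts, comparison, chrom, start, end)
            region = DMRegion(
                chrom=chrom,
                start=start,
                end=end,
                polarity="a>b" if sign > 0 else "b>a",
                n_cpgs=ev["n_cpgs"],
                score_a=ev["score_a"],
                score_b=ev["score_b"],
                depth_a=ev["depth_a"],
                depth_b=ev["depth_b"],
                source="internal",
            )
            if ev["covered_a"] < 2 or ev["covered_b"] < 2:
                region.filter_flags.add(FLAG_LOW_COVERAGE)
                out.append(region)
                return
            region.p_value = rank_sum_test(ev["scores_a"], ev["scores_b"])
            pooled_diff = region.diff
            if (
                np.isfinite(pooled_diff)
                and abs(pooled_diff) >= min_diff
                and region.p_value < p_thresh
            ):
                out.append(region)
                search(lo, i)
                search(j, hi)

        for lo, hi in zip(run_starts, run_ends):
            search(int(lo), int(hi))
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def import_dmrs(path: str, fmt: str = "bed") -> list[DMRegion]:
    """Ingest externally called DMRs (BED3+ or caller TSV with
    chrom/start/end columns); scores and depths are recomputed later by
    :func:`filter_dmrs`."""
    regions: list[DMRegion] = []
    bad: list[int] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if fmt == "tsv" and ln == 1 and not parts[1].isdigit():
                continue  # header row
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if end <= start:
                    raise ValueError
            except (IndexError, ValueError):
                bad.append(ln)
                continue
            polarity = parts[3] if len(parts) > 3 and parts[3] in ("a>b", "b>a") else "a>b"
            regions.append(
                DMRegion(chrom=chrom, start=start, end=end, polarity=polarity, source="imported")
            )
    if bad:
        raise ValueError(f"malformed lines in {path}: {bad}")
    return regions


def export_dmrs(dmrs: list[DMRegion], path: str) -> None:
    """Write reported DMRs as BED6 (name = polarity, score = 100|diff|)."""
    with open(path, "w") as fh:
        for r in dmrs:
            score = 0 if not np.isfinite(r.diff) else int(round(100 * abs(r.diff)))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.polarity}\t{score}\t+\n")


def filter_dmrs(
    candidates: list[DMRegion],
    counts: MethylationCounts,
    comparison: GroupComparison,
    min_cpgs: int = 5,
    min_diff: float = 0.2,
    max_depth: float = 500.0,
    max_depth_ratio: float = 5.0,
) -> list[DMRegion]:
    """Apply the filter suite; every filter is evaluated independently and
    each failure is recorded in ``filter_flags`` (reported DMRs are those
    with no flags). Region statistics are recomputed from ``counts``, so
    the operation is idempotent and works on imported regions."""
    out: list[DMRegion] = []
    for cand in candidates:
        ev = _evaluate_region(counts, comparison, cand.chrom, cand.start, cand.end)
        region = replace(
            cand,
            n_cpgs=ev["n_cpgs"],
            score_a=ev["score_a"],
            score_b=ev["score_b"],
            depth_a=ev["depth_a"],
            depth_b=ev["depth_b"],
            filter_flags=set(),
        )
        if ev["covered_a"] < 2 or ev["covered_b"] < 2:
            region.filter_flags.add(FLAG_LOW_COVERAGE)
        if region.n_cpgs < min_cpgs:
            region.filter_flags.add(FLAG_MIN_CPGS)
        if not (np.isfinite(region.diff) and abs(region.diff) >= min_diff):
            region.filter_flags.add(FLAG_MIN_DIFF)
        if np.isfinite(region.diff) and cand.source == "imported":
            region.polarity = "a>b" if region.diff > 0 else "b>a"
        if max(region.depth_a, region.depth_b) > max_depth:
            region.filter_flags.add(FLAG_DEPTH_CAP)
        lo_d = min(region.depth_a, region.depth_b)
        hi_d = max(region.depth_a, region.depth_b)
        if lo_d == 0 or not np.isfinite(hi_d):
            region.filter_flags.add(FLAG_LOW_COVERAGE)
        elif hi_d / lo_d > max_depth_ratio:
            region.filter_flags.add(FLAG_DEPTH_RATIO)
        out.append(region)
    return out


def reported(dmrs: list[DMRegion]) -> list[DMRegion]:
    return [r for r in dmrs if r.passed]


def summarize(
    dmcs: pd.DataFrame, dmrs: list[DMRegion], genome_size: int
) -> dict[str, float]:
    """Table-1-style summary: counts by polarity, DMC/DMR cross-statistics
    and DMR footprint as a fraction of the genome."""
    rep = reported(dmrs)
    n_dmcs = len(dmcs)
    n_dmrs = len(rep)
    by_pol = {
        "a>b": sum(1 for r in rep if r.polarity == "a>b"),
        "b>a": sum(1 for r in rep if r.polarity == "b>a"),
    }
    dmcs_in = 0
    if n_dmcs and n_dmrs:
        for chrom, grp in dmcs.groupby("chrom"):
            spans = [(r.start, r.end) for r in rep if r.chrom == chrom]
            if not spans:
                continue
            starts = np.array(sorted(s for s, _ in spans))
            ends = np.array(sorted(e for _, e in spans))
            p = grp["pos"].to_numpy()
            dmcs_in += int((np.searchsorted(starts, p, "right") > np.searchsorted(ends, p, "right")).sum())
    dmr_cpgs = sum(r.n_cpgs for r in rep)
    dmr_bp = sum(r.length for r in rep)
    return {
        "n_dmcs": float(n_dmcs),
        "n_dmrs": float(n_dmrs),
        "n_dmrs_a_gt_b": float(by_pol["a>b"]),
        "n_dmrs_b_gt_a": float(by_pol["b>a"]),
        "dmcs_in_dmrs": float(dmcs_in),
        "pct_dmcs_in_dmrs": 100.0 * dmcs_in / n_dmcs if n_dmcs else 0.0,
        "pct_dmr_cpgs_dmc": 100.0 * dmcs_in / dmr_cpgs if dmr_cpgs else 0.0,
        "dmr_pct_genome": 100.0 * dmr_bp / genome_size if genome_size else 0.0,
    }


def score_matrix(
    dmrs: list[DMRegion], counts: MethylationCounts, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-DMR per-sample weighted methylation scores (NaN = no coverage)."""
    if sample_ids is None:
        sample_ids = counts.sample_ids
    sub = counts.subset_samples(sample_ids)
    rows = {}
    for r in dmrs:
        rows[f"{r.chrom}:{r.start}-{r.end}"] = per_sample_region_scores(
            sub, r.chrom, r.start, r.end
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)


def quartile_groups(
    dmrs: list[DMRegion],
    matrix: pd.DataFrame,
    comparison: GroupComparison,
) -> pd.DataFrame:
    """Quartile assignment per polarity class.

    Within each polarity, DMRs are ordered by decreasing mean score of
    the hypermethylated group and split into four near-equal quartiles
    (sizes differ by at most one).
    """
    recs = []
    for r in dmrs:
        key = f"{r.chrom}:{r.start}-{r.end}"
        hyper = comparison.group_a if r.polarity == "a>b" else comparison.group_b
        hyper_score = matrix.loc[key, list(hyper)].mean()
        recs.append((key, r.polarity, float(hyper_score)))
    df = pd.DataFrame(recs, columns=["dmr", "polarity", "hyper_score"])
    df["quartile"] = -1
    for pol, grp in df.groupby("polarity"):
        order = grp.sort_values("hyper_score", ascending=False).index
        for q, chunk in enumerate(np.array_split(np.asarray(order), 4), start=1):
            df.loc[chunk, "quartile"] = q
    return df.set_index("dmr")
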