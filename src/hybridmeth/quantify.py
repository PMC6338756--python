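"""Per-CpG methylation quantification and variability analyses.

Extraction rules follow the study's processing: the first four and last
one base of every read2 are clipped (positional methylation bias), bases
covered by both mates of a pair are counted once (read1 wins), only
validated CpG sites are tallied, and plus-/minus-strand observations of
one CpG dinucleotide are merged onto the plus-strand C key.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SampleSpec
from .context import ValidatedSites
from .genome import LAMBDA_CHROM
from .reads import OB, ReadBatch

_Z, _z = ord("Z"), ord("z")
_METH = frozenset(b"ZXH")
_UNMETH = frozenset(b"zxh")


@dataclass
class RegionScore:
    """Pooled (coverage-weighted) methylation score of a region."""

    chrom: str
    start: int
    end: int
    score: float  # NaN when undefined
    total_depth: int
    n_cpgs: int

    @property
    def defined(self) -> bool:
        return self.total_depth > 0


@dataclass
class MethylationCounts:
    """Strand-merged per-CpG methylated/total counts for a set of samples.

    ``meth[chrom]`` and ``depth[chrom]`` are (n_sites, n_samples) arrays
    over ``positions[chrom]`` (validated CpG sites, plus-strand C key).
    """

    samples: list[SampleSpec]
    chroms: list[str]
    positions: dict[str, np.ndarray]
    meth: dict[str, np.ndarray]
    depth: dict[str, np.ndarray]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_ids) -> np.ndarray:
        ids = self.sample_ids
        return np.array([ids.index(s) for s in sample_ids])

    @property
    def n_sites(self) -> int:
        return int(sum(v.size for v in self.positions.values()))

    def frac(self, chrom: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.depth[chrom] > 0, self.meth[chrom] / self.depth[chrom], np.nan
            )

    def region_index(self, chrom: str, start: int, end: int) -> slice:
        pos = self.positions[chrom]
        return slice(
            int(np.searchsorted(pos, start)), int(np.searchsorted(pos, end))
        )

    def subset_samples(self, sample_ids) -> "MethylationCounts":
        idx = self.sample_index(sample_ids)
        return MethylationCounts(
            samples=[self.samples[i] for i in idx],
            chroms=self.chroms,
            positions=self.positions,
            meth={c: m[:, idx] for c, m in self.meth.items()},
            depth={c: d[:, idx] for c, d in self.depth.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for chrom in self.chroms:
            df = pd.DataFrame(
                {"chrom": chrom, "pos": self.positions[chrom]}
            )
            for j, sid in enumerate(self.sample_ids):
                df[f"{sid}.meth"] = self.meth[chrom][:, j]
                df[f"{sid}.depth"] = self.depth[chrom][:, j]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def extract_calls(
    batch: ReadBatch, validated: ValidatedSites
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Tally one sample's per-site (meth, depth) counts at validated CpGs.

    Returns ``{chrom: (meth, depth)}`` aligned to ``validated.cpg[chrom]``.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, val_pos in validated.cpg.items():
        if chrom not in batch.chroms:
            out[chrom] = (
                np.zeros(val_pos.size, dtype=np.int64),
                np.zeros(val_pos.size, dtype=np.int64),
            )
            continue
        sub = batch.for_chrom(chrom)
        meth = np.zeros(val_pos.size, dtype=np.int64)
        depth = np.zeros(val_pos.size, dtype=np.int64)
        for read, xmat in ((1, sub.r1_xm), (2, sub.r2_xm)):
            rows, cols, pos = sub.read_cells(read)
            if rows.size == 0:
                continue
            xm = xmat[rows, cols]
            zmask = (xm == _Z) | (xm == _z)
            if not zmask.any():
                continue
            rows, cols, pos, xm = rows[zmask], cols[zmask], pos[zmask], xm[zmask]
            # OT fragments observe the plus-strand C (site key = pos);
            # OB fragments observe the minus-strand C at the plus G (pos-1)
            site = pos - (sub.strand[rows] == OB)
            idx = np.searchsorted(val_pos, site)
            ok = (idx < val_pos.size) & (val_pos[np.minimum(idx, val_pos.size - 1)] == site)
            idx, xm = idx[ok], xm[ok]
            depth += np.bincount(idx, minlength=val_pos.size)
            meth += np.bincount(idx[xm == _Z], minlength=val_pos.size)
        out[chrom] = (meth, depth)
    return out


def build_counts(
    batches: dict[str, ReadBatch],
    samples: list[SampleSpec],
    validated: ValidatedSites,
) -> MethylationCounts:
    """Assemble the site x sample count matrices for a sample set."""
    chroms = list(validated.cpg)
    positions = {c: validated.cpg[c] for c in chroms}
    meth = {c: np.zeros((positions[c].size, len(samples)), dtype=np.int32) for c in chroms}
    depth = {c: np.zeros((positions[c].size, len(samples)), dtype=np.int32) for c in chroms}
    for j, sample in enumerate(samples):
        per_chrom = extract_calls(batches[sample.sample_id], validated)
        for c in chroms:
            m, d = per_chrom[c]
            meth[c][:, j] = m
            depth[c][:, j] = d
    return MethylationCounts(
        samples=list(samples), chroms=chroms, positions=positions, meth=meth, depth=depth
    )


@dataclass
class ConversionQC:
    rate: float  # fraction of cytosine calls converted (unmethylated)
    n_calls: int
    flag: str  # "pass" | "fail" | "no spike-in"


def conversion_rate(batch: ReadBatch, min_rate: float = 0.99) -> ConversionQC:
    """Bisulfite conversion rate from the unmethylated lambda spike-in.

    Rate = unmethylated calls / all cytosine calls over every lambda
    cytosine (all contexts). The QC flag fails at rate <= ``min_rate``
    (the study required > 99%).
    """
    if LAMBDA_CHROM not in batch.chroms:
        return ConversionQC(float("nan"), 0, "no spike-in")
    sub = batch.for_chrom(LAMBDA_CHROM)
    if sub.n_fragments == 0:
        return ConversionQC(float("nan"), 0, "no spike-in")
    n_meth = 0
    n_unmeth = 0
    for read, xmat in ((1, sub.r1_xm), (2, sub.r2_xm)):
        rows, cols, _ = sub.read_cells(read)
        xm = xmat[rows, cols]
        n_meth += int(np.isin(xm, np.frombuffer(b"ZXH", dtype=np.uint8)).sum())
        n_unmeth += int(np.isin(xm, np.frombuffer(b"zxh", dtype=np.uint8)).sum())
    total = n_meth + n_unmeth
    if total == 0:
        return ConversionQC(float("nan"), 0, "no spike-in")
    rate = n_unmeth / total
    return ConversionQC(rate, total, "pass" if rate > min_rate else "fail")


def weighted_score(
    counts: MethylationCounts,
    chrom: str,
    start: int,
    end: int,
    sample_ids: list[str] | None = None,
) -> RegionScore:
    """Pooled weighted methylation score: sum(meth) / sum(depth) over the
    region's validated CpGs and the given samples."""
    sl = counts.region_index(chrom, start, end)
    idx = (
        counts.sample_index(sample_ids)
        if sample_ids is not None
        else np.arange(len(counts.samples))
    )
    m = int(counts.meth[chrom][sl, :][:, idx].sum())
    d = int(counts.depth[chrom][sl, :][:, idx].sum())
    n = sl.stop - sl.start
    score = m / d if d > 0 else float("nan")
    return RegionScore(chrom=chrom, start=start, end=end, score=score, total_depth=d, n_cpgs=n)


def per_sample_region_scores(
    counts: MethylationCounts, chrom: str, start: int, end: int
) -> np.ndarray:
    """Per-sample pooled scores over a region (NaN where no coverage)."""
    sl = counts.region_index(chrom, start, end)
    m = counts.meth[chrom][sl].sum(axis=0).astype(np.float64)
    d = counts.depth[chrom][sl].sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(d > 0, m / d, np.nan)


DEFAULT_DEPTH_BINS = ((1, 10), (11, 20), (21, 50), (51, 100), (101, 400))


def replicate_sd(
    counts: MethylationCounts,
    group_sample_ids: list[str],
    bins=DEFAULT_DEPTH_BINS,
    n_per_bin: int = 20_000,
    seed: int = 0,
) -> dict[tuple[int, int], np.ndarray]:
    """Replicate-group SD of methylation percentage, binned by site depth.

    A site enters a bin only when *every* replicate's depth lies within
    that bin; up to ``n_per_bin`` eligible sites are sampled per bin.
    SDs are population SDs across replicates, on the percent scale.
    """
    if len(group_sample_ids) < 2:
        raise ValueError("replicate group must have >= 2 samples")
    rng = np.random.default_rng(seed)
    idx = counts.sample_index(group_sample_ids)
    depth = np.concatenate([counts.depth[c][:, idx] for c in counts.chroms])
    meth = np.concatenate([counts.meth[c][:, idx] for c in counts.chroms])
    out: dict[tuple[int, int], np.ndarray] = {}
    for lo, hi in bins:
        eligible = np.flatnonzero(((depth >= lo) & (depth <= hi)).all(axis=1))
        if eligible.size == 0:
            out[(lo, hi)] = np.array([])
            continue
        if eligible.size > n_per_bin:
            eligible = rng.choice(eligible, size=n_per_bin, replace=False)
        pct = 100.0 * meth[eligible] / depth[eligible]
        out[(lo, hi)] = pct.std(axis=1, ddof=0)
    return out


@dataclass
class VariableSiteResult:
    """Top-variable CpG sites, a size-matched random control, and their
    characterization (per-window density, methylation level, CpG-island
    overlap)."""

    variable: pd.DataFrame  # chrom, pos, sd, meth
    random: pd.DataFrame
    window_size: int
    window_counts: dict[str, pd.Series] = field(default_factory=dict)
    island_overlap: dict[str, float] = field(default_factory=dict)
    n_eligible: int = 0


def variable_sites(
    counts: MethylationCounts,
    top_fraction: float = 0.05,
    min_informative: int = 18,
    min_depth: int = 10,
    seed: int = 0,
    islands: pd.DataFrame | None = None,
    window: int = 500,
) -> VariableSiteResult:
    """All-animal methylation variability: top-``top_fraction`` most
    variable sites plus an equal-size random control.

    Per-site SD uses only animals with depth > ``min_depth``; a site is
    eligible only when at least ``min_informative`` animals qualify.
    """
    chrom_arr, pos_arr, sd_arr, meth_arr = [], [], [], []
    for chrom in counts.chroms:
        d = counts.depth[chrom].astype(np.float64)
        m = counts.meth[chrom].astype(np.float64)
        inf = d > min_depth
        n_inf = inf.sum(axis=1)
        elig = n_inf >= min_informative
        if not elig.any():
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(inf, m / d, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(frac, axis=1, ddof=0) * 100.0
            pooled = np.nansum(np.where(inf, m, 0), axis=1) / np.maximum(
                np.nansum(np.where(inf, d, 0), axis=1), 1
            )
        chrom_arr.append(np.full(int(elig.sum()), chrom, dtype=object))
        pos_arr.append(counts.positions[chrom][elig])
        sd_arr.append(sd[elig])
        meth_arr.append(pooled[elig])
    if not chrom_arr:
        raise ValueError("no sites meet the informative-sample requirement")
    df = pd.DataFrame(
        {
            "chrom": np.concatenate(chrom_arr),
            "pos": np.concatenate(pos_arr),
            "sd": np.concatenate(sd_arr),
            "meth": np.concatenate(meth_arr),
        }
    )
    n_eligible = len(df)
    k = int(np.ceil(top_fraction * n_eligible))
    if n_eligible < 2 * k:
        raise ValueError("not enough eligible sites for variable + random sets")
    # deterministic order: SD descending, ties broken by position
    df = df.sort_values(["sd", "chrom", "pos"], ascending=[False, True, True]).reset_index(
        drop=True
    )
    if k < n_eligible and df["sd"].iloc[k - 1] == df["sd"].iloc[k]:
        warnings.warn(
            "tied standard deviations at the selection cutoff; "
            "selection tie-broken deterministically by position",
            stacklevel=2,
        )
    var = df.iloc[:k].reset_index(drop=True)
    rest = df.iloc[k:]
    rng = np.random.default_rng(seed)
    rnd = rest.iloc[
        np.sort(rng.choice(len(rest), size=k, replace=False))
    ].reset_index(drop=True)

    result = VariableSiteResult(
        variable=var, random=rnd, window_size=window, n_eligible=n_eligible
    )
    for name, sites in (("variable", var), ("random", rnd)):
        win = sites["chrom"].astype(str) + ":" + (sites["pos"] // window).astype(str)
        result.window_counts[name] = win.value_counts()
        if islands is not None and len(islands):
            inside = np.zeros(len(sites), dtype=bool)
            for chrom, grp in sites.groupby("chrom"):
                isl = islands[islands["chrom"] == chrom]
                if not len(isl):
                    continue
                starts = isl["start"].to_numpy()
                ends = np.sort(isl["end"].to_numpy())
                p = grp["pos"].to_numpy()
                i1 = np.searchsorted(np.sort(starts), p, side="right")
                i2 = np.searchsorted(ends, p, side="right")
                inside[sites["chrom"].to_numpy() == chrom] = i1 > i2
            result.island_overlap[name] = float(inside.mean())
    return result
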