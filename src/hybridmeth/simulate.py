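"""Synthetic bisulfite study generator.

Produces, from a :class:`~hybridmeth.config.SimConfig`, the complete
synthetic study the downstream modules analyse: two strain assemblies
differing only at SNVs, per-animal per-haplotype CpG methylation truth
with planted genotype-, sex- and parity-DMRs, and aligned paired-end
bisulfite read sets per animal (plus fully unmethylated lambda spike-in
reads for conversion-rate QC).

Model summary
-------------
* Baseline CpG methylation is bimodal: ~``island_meth`` (default 0.1)
  inside CpG islands, ~``background_meth`` (default 0.85) elsewhere.
* Planted DMRs centre the two groups around intermediate methylation:
  the hypomethylated group sits at ``0.5 - delta/2`` and the
  hypermethylated group at ``0.5 + delta/2``, so the between-group truth
  difference is exactly ``delta``.
* Genotype-axis DMRs act in cis: an F1 haplotype carries the truth of
  the parental strain it was inherited from. Sex- and parity-axis DMRs
  depend only on the animal's sex / parity and affect both haplotypes.
* Biological replicate noise is one Gaussian(0, bio_sd) draw per
  (animal, site), shared by the animal's two haplotypes and clamped to
  [0, 1] after addition.
* Reads: fragments placed uniformly; F1 fragments draw their haplotype
  Bernoulli(0.5); each cytosine on the fragment's original strand is
  methylated with its site's truth probability; unmethylated cytosines
  convert to T with probability ``conversion_rate``; uniform sequencing
  errors at ``error_rate``; the XM call string is then derived from the
  final base, as an aligner's methylation extractor would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AXIS_POLARITIES, PlantedDMR, SampleSpec, SimConfig
from .genome import (
    A,
    C,
    CTX_CPG,
    G,
    LAMBDA_CHROM,
    T,
    GenomePair,
    context_codes,
    generate_genomes,
)
from .reads import OB, OT, ReadBatch

_XM_UPPER = {1: ord("Z"), 2: ord("X"), 3: ord("H")}
_XM_LOWER = {1: ord("z"), 2: ord("x"), 3: ord("h")}
_DOT = ord(".")

#: minimum bp separation enforced between planted DMRs so each is an
#: independently callable unit (larger than the caller's default max_gap)
_DMR_PADDING = 500


@dataclass
class TruthSet:
    """Simulator ground truth.

    ``truth[(sample_id, hap_label)][chrom]`` is a float32 array over
    ``sites[chrom]`` (plus-strand C positions of CpGs present in at least
    one assembly) giving the true methylation probability of that
    haplotype in that animal.
    """

    config: SimConfig
    genomes: GenomePair
    sites: dict[str, np.ndarray]
    truth: dict[tuple[str, str], dict[str, np.ndarray]]
    planted_dmrs: list[PlantedDMR]
    variable_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def truth_for(self, sample_id: str, hap: str, chrom: str) -> np.ndarray:
        return self.truth[(sample_id, hap)][chrom]

    def sample_truth(self, sample: SampleSpec, chrom: str) -> np.ndarray:
        """Haplotype-averaged truth for one animal."""
        h1, h2 = sample.haplotypes
        return 0.5 * (
            self.truth_for(sample.sample_id, h1, chrom)
            + self.truth_for(sample.sample_id, h2, chrom)
        )

    def apparent_truth(self, sample: SampleSpec, chrom: str) -> np.ndarray:
        """Expected *observed* methylation fraction: truth plus the
        conversion-failure background (unconverted unmethylated Cs read
        as methylated)."""
        p = self.sample_truth(sample, chrom)
        return p + (1.0 - p) * (1.0 - self.config.conversion_rate)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for (sid, hap), per_chrom in sorted(self.truth.items()):
            for chrom, vals in per_chrom.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": self.sites[chrom],
                            "sample": sid,
                            "haplotype": hap,
                            "truth": vals,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _hyper_group_member(sample: SampleSpec, hap: str, dmr: PlantedDMR) -> bool:
    """Is this (animal, haplotype) in the DMR's hypermethylated group?"""
    if dmr.axis == "genotype":
        return hap == dmr.polarity
    if dmr.axis == "sex":
        return sample.sex == dmr.polarity
    group = "dam" if sample.parity == "dam" else "virgin"
    return group == dmr.polarity


def plant_dmrs(config: SimConfig, genomes: GenomePair, rng: np.random.Generator) -> list[PlantedDMR]:
    """Place mutually non-overlapping DMRs with enough shared CpGs."""
    placed: list[PlantedDMR] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names}
    shared = {c: genomes.shared_cpg_sites(c) for c in config.chrom_names}
    for spec in config.dmr_specs:
        pol_first, pol_second = AXIS_POLARITIES[spec.axis]
        n_first = int(round(spec.count * spec.first_polarity_fraction))
        polarities = [pol_first] * n_first + [pol_second] * (spec.count - n_first)
        for polarity in polarities:
            ok = False
            for _ in range(2000):
                chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
                width = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
                if width >= config.chrom_length:
                    continue
                start = int(rng.integers(0, config.chrom_length - width))
                end = start + width
                if any(
                    end + _DMR_PADDING > s and start - _DMR_PADDING < e
                    for s, e in occupied[chrom]
                ):
                    continue
                n_cpg = int(
                    np.searchsorted(shared[chrom], end)
                    - np.searchsorted(shared[chrom], start)
                )
                if n_cpg < config.min_cpgs_per_dmr:
                    continue
                delta = float(rng.uniform(*spec.delta_range))
                placed.append(
                    PlantedDMR(chrom, start, end, spec.axis, polarity, round(delta, 4))
                )
                occupied[chrom].append((start, end))
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place a {spec.axis} DMR of width "
                    f"{spec.width_range} with >= {config.min_cpgs_per_dmr} shared CpGs"
                )
    return placed


def _check_dmrs(config: SimConfig, dmrs: list[PlantedDMR]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in dmrs:
        if d.chrom not in config.chrom_names:
            raise ValueError(f"DMR on unknown chromosome {d.chrom}")
        if d.start < 0 or d.end > config.chrom_length:
            raise ValueError(f"DMR {d} exceeds chromosome bounds")
        for s, e in by_chrom.get(d.chrom, []):
            if d.end > s and d.start < e:
                raise ValueError("planted DMRs overlap")
        by_chrom.setdefault(d.chrom, []).append((d.start, d.end))


def assign_methylation(
    config: SimConfig,
    genomes: GenomePair,
    planted_dmrs: list[PlantedDMR] | None = None,
) -> TruthSet:
    """Build the per-animal per-haplotype CpG methylation truth."""
    rng = np.random.default_rng([int(config.seed), 202])
    if planted_dmrs is None:
        planted_dmrs = plant_dmrs(config, genomes, rng)
    _check_dmrs(config, planted_dmrs)

    sites = {c: genomes.union_cpg_sites(c) for c in config.chrom_names}

    # shared baseline (before DMR overrides), per chrom
    baseline: dict[str, np.ndarray] = {}
    site_sd: dict[str, np.ndarray] = {}
    variable_sites: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        pos = sites[chrom]
        base = np.full(pos.size, config.background_meth, dtype=np.float64)
        sd = np.full(pos.size, config.bio_sd, dtype=np.float64)
        isl = genomes.islands[genomes.islands["chrom"] == chrom]
        in_island = np.zeros(pos.size, dtype=bool)
        for s, e in zip(isl["start"], isl["end"]):
            in_island |= (pos >= s) & (pos < e)
        base[in_island] = config.island_meth
        if config.variable_fraction > 0:
            n_var = int(round(config.variable_fraction * pos.size))
            var_idx = rng.choice(pos.size, size=n_var, replace=False)
            base[var_idx] = 0.5
            sd[var_idx] = config.variable_sd
            variable_sites[chrom] = np.sort(pos[var_idx])
        baseline[chrom] = base
        site_sd[chrom] = sd

    # DMR override masks, per chrom: list of (site mask, dmr)
    dmr_masks: dict[str, list[tuple[np.ndarray, PlantedDMR]]] = {
        c: [] for c in config.chrom_names
    }
    for d in planted_dmrs:
        pos = sites[d.chrom]
        dmr_masks[d.chrom].append(((pos >= d.start) & (pos < d.end), d))

    truth: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for sample in config.samples:
        eps = {
            chrom: rng.normal(0.0, 1.0, size=sites[chrom].size) * site_sd[chrom]
            for chrom in config.chrom_names
        }
        haps = sorted(set(sample.haplotypes))
        for hap in haps:
            per_chrom: dict[str, np.ndarray] = {}
            for chrom in config.chrom_names:
                vals = baseline[chrom].copy()
                for mask, d in dmr_masks[chrom]:
                    hyper = _hyper_group_member(sample, hap, d)
                    vals[mask] = 0.5 + (d.delta / 2.0 if hyper else -d.delta / 2.0)
                vals = np.clip(vals + eps[chrom], 0.0, 1.0)
                per_chrom[chrom] = vals.astype(np.float32)
            truth[(sample.sample_id, hap)] = per_chrom
        if len(haps) == 1:  # homozygous parent: both haplotypes identical
            truth[(sample.sample_id, haps[0])] = truth[(sample.sample_id, haps[0])]
    return TruthSet(
        config=config,
        genomes=genomes,
        sites=sites,
        truth=truth,
        planted_dmrs=planted_dmrs,
        variable_sites=variable_sites,
    )


def _allocate(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder allocation of `total` over weights (sums exactly)."""
    w = np.asarray(weights, dtype=np.float64)
    raw = total * w / w.sum()
    out = np.floor(raw).astype(int)
    rem = total - out.sum()
    order = np.argsort(-(raw - out))
    out[order[:rem]] += 1
    return out.tolist()


def simulate_reads(
    truth: TruthSet, sample: SampleSpec, config: SimConfig | None = None
) -> ReadBatch:
    """Simulate one animal's aligned paired-end bisulfite reads.

    Fragment count over the autosomes equals
    ``round(depth * genome_length / fragment_length_mean)`` exactly;
    lambda spike-in fragments are generated at the same depth on the
    lambda contig (truth 0 everywhere).
    """
    if config is None:
        config = truth.config
    sample_ids = [s.sample_id for s in config.samples]
    try:
        si = sample_ids.index(sample.sample_id)
    except ValueError as exc:
        raise KeyError(f"sample {sample.sample_id} not in config") from exc
    rng = np.random.default_rng([int(config.seed), 303, si])

    genomes = truth.genomes
    chroms = config.chrom_names + [LAMBDA_CHROM]
    chrom_lengths = [config.chrom_length] * config.n_chroms + [config.lambda_length]

    n_auto = int(round(config.depth * config.genome_length / config.fragment_length_mean))
    per_chrom = _allocate(n_auto, [config.chrom_length] * config.n_chroms)
    per_chrom.append(
        int(round(config.depth * config.lambda_length / config.fragment_length_mean))
    )

    rl = config.read_length
    flen_cap = int(config.fragment_length_mean + 5 * config.fragment_length_sd)
    h1, h2 = sample.haplotypes

    parts = {k: [] for k in (
        "chrom_idx", "frag_start", "frag_len", "strand", "hap",
        "r1_pos", "r2_pos", "r1_seq", "r2_seq", "r1_xm", "r2_xm",
    )}

    # cache per (chrom, hap): sequence, contexts, truth map
    ctx_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def chrom_arrays(chrom: str, hap_code: int):
        key = (chrom, hap_code)
        if key in ctx_cache:
            return ctx_cache[key]
        if chrom == LAMBDA_CHROM:
            seq = genomes.lambda_seq
        else:
            seq = (genomes.p1 if hap_code == 0 else genomes.p2)[chrom]
        ctx_plus, ctx_minus = context_codes(seq)
        ctx_cache[key] = (seq, ctx_plus, ctx_minus)
        return ctx_cache[key]

    def truth_map(chrom: str, hap_code: int, L: int) -> np.ndarray:
        tmap = np.zeros(L, dtype=np.float32)
        if chrom == LAMBDA_CHROM:
            return tmap
        hap_label = "P1" if hap_code == 0 else "P2"
        # for parental animals both haplotypes carry the strain's truth
        if not sample.is_f1:
            hap_label = h1
        tmap[truth.sites[chrom]] = truth.truth_for(sample.sample_id, hap_label, chrom)
        return tmap

    for ci, (chrom, L, n_frag) in enumerate(zip(chroms, chrom_lengths, per_chrom)):
        if n_frag == 0:
            continue
        flen = np.clip(
            np.rint(rng.normal(config.fragment_length_mean, config.fragment_length_sd, n_frag)),
            rl,
            min(flen_cap, L),
        ).astype(np.int32)
        start = (rng.random(n_frag) * (L - flen + 1)).astype(np.int64)
        strand = rng.integers(0, 2, size=n_frag, dtype=np.int64).astype(np.uint8)
        if sample.is_f1:
            hapc = rng.integers(0, 2, size=n_frag, dtype=np.int64).astype(np.uint8)
        else:
            hapc = np.full(n_frag, 0 if h1 == "P1" else 1, dtype=np.uint8)

        for hv in (0, 1):
            for sv in (OT, OB):
                sel = np.flatnonzero((hapc == hv) & (strand == sv))
                if sel.size == 0:
                    continue
                seq, ctx_plus, ctx_minus = chrom_arrays(chrom, hv)
                tmap = truth_map(chrom, hv, L)
                out = _simulate_group(
                    rng, config, seq, ctx_plus, ctx_minus, tmap,
                    start[sel], flen[sel], sv,
                )
                r1p, r2p, r1s, r2s, r1x, r2x = out
                parts["chrom_idx"].append(np.full(sel.size, ci, dtype=np.int32))
                parts["frag_start"].append(start[sel])
                parts["frag_len"].append(flen[sel])
                parts["strand"].append(np.full(sel.size, sv, dtype=np.uint8))
                parts["hap"].append(np.full(sel.size, hv, dtype=np.uint8))
                parts["r1_pos"].append(r1p)
                parts["r2_pos"].append(r2p)
                parts["r1_seq"].append(r1s)
                parts["r2_seq"].append(r2s)
                parts["r1_xm"].append(r1x)
                parts["r2_xm"].append(r2x)

    cat = {k: np.concatenate(v) if v else np.zeros((0,), dtype=np.int64) for k, v in parts.items()}
    batch = ReadBatch(
        sample_id=sample.sample_id,
        chroms=chroms,
        chrom_lengths=chrom_lengths,
        read_length=rl,
        **cat,
    )
    # deterministic coordinate order
    order = np.lexsort((batch.frag_start, batch.chrom_idx))
    return batch.subset(order)


def _simulate_group(
    rng: np.random.Generator,
    config: SimConfig,
    seq: np.ndarray,
    ctx_plus: np.ndarray,
    ctx_minus: np.ndarray,
    tmap: np.ndarray,
    start: np.ndarray,
    flen: np.ndarray,
    strand: int,
    chunk: int = 20_000,
):
    """Vectorised fragment conversion + read slicing for one (hap, strand)."""
    rl = config.read_length
    n = start.size
    L = seq.size
    outs = ([], [], [], [], [], [])
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        s = start[lo:hi]
        fl = flen[lo:hi]
        W = int(fl.max())
        colw = np.arange(W)
        pos = s[:, None] + colw[None, :]
        valid = colw[None, :] < fl[:, None]
        posc = np.minimum(pos, L - 1)
        base = seq[posc]
        if strand == OT:
            ctx = ctx_plus[posc]
            tidx = posc
            c_base, conv_to = C, T
        else:
            ctx = ctx_minus[posc]
            tidx = np.maximum(posc - 1, 0)
            c_base, conv_to = G, A
        is_c = valid & (base == c_base) & (ctx > 0)
        p = np.where(ctx == CTX_CPG, tmap[tidx], np.float32(config.non_cpg_meth))
        meth = (rng.random(p.shape) < p) & is_c
        convert = is_c & ~meth & (rng.random(p.shape) < config.conversion_rate)
        obs = base.copy()
        obs[convert] = conv_to
        if config.error_rate > 0:
            err = valid & (rng.random(p.shape) < config.error_rate)
            if err.any():
                obs[err] = (obs[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
        # methylation-call string from final base vs haplotype context
        xm = np.full(obs.shape, _DOT, dtype=np.uint8)
        has_ctx = valid & (ctx > 0) & (base == c_base)
        for code in (1, 2, 3):
            m = has_ctx & (ctx == code)
            xm[m & (obs == c_base)] = _XM_UPPER[code]
            xm[m & (obs == conv_to)] = _XM_LOWER[code]

        # read1 sits at the fragment's 5' end on its original strand
        if strand == OT:
            off1 = np.zeros(hi - lo, dtype=np.int64)
            off2 = (fl - rl).astype(np.int64)
        else:
            off1 = (fl - rl).astype(np.int64)
            off2 = np.zeros(hi - lo, dtype=np.int64)
        colr = np.arange(rl)
        idx1 = off1[:, None] + colr[None, :]
        idx2 = off2[:, None] + colr[None, :]
        outs[0].append(s + off1)
        outs[1].append(s + off2)
        outs[2].append(np.take_along_axis(obs, idx1, axis=1))
        outs[3].append(np.take_along_axis(obs, idx2, axis=1))
        outs[4].append(np.take_along_axis(xm, idx1, axis=1))
        outs[5].append(np.take_along_axis(xm, idx2, axis=1))
    return tuple(np.concatenate(o) for o in outs)


@dataclass
class Study:
    """A complete simulated study: genomes, truth, and per-sample reads."""

    config: SimConfig
    genomes: GenomePair
    truth: TruthSet
    batches: dict[str, ReadBatch]

    def group_batches(self, sample_ids: list[str]) -> list[ReadBatch]:
        return [self.batches[s] for s in sample_ids]


def simulate_study(
    config: SimConfig, planted_dmrs: list[PlantedDMR] | None = None
) -> Study:
    """Run the full generator: genomes -> truth -> reads for every sample."""
    genomes = generate_genomes(config)
    truth = assign_methylation(config, genomes, planted_dmrs=planted_dmrs)
    batches = {
        s.sample_id: simulate_reads(truth, s, config) for s in config.samples
    }
    return Study(config=config, genomes=genomes, truth=truth, batches=batches)
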