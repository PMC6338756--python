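"""High-level orchestration: run the simulated study end to end and
score the analysis against the simulator's ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .context import ValidatedSites, validate_contexts
from .dmr import DMRegion, GroupComparison, filter_dmrs, reported, segment_dmrs
from .quantify import MethylationCounts, build_counts
from .simulate import Study


def comparisons(config: SimConfig) -> dict[str, GroupComparison]:
    """The study's three contrasts: genotype (P1 vs P2 parents), sex
    (parental males vs parental females), parity (dams vs virgin females)."""
    samples = config.samples
    p1 = tuple(s.sample_id for s in samples if s.genotype == "P1")
    p2 = tuple(s.sample_id for s in samples if s.genotype == "P2")
    males = tuple(
        s.sample_id for s in samples if not s.is_f1 and s.sex == "M"
    )
    females = tuple(
        s.sample_id for s in samples if not s.is_f1 and s.sex == "F"
    )
    dams = tuple(s.sample_id for s in samples if s.parity == "dam")
    virgin_f = tuple(
        s.sample_id for s in samples if s.parity == "virgin" and s.sex == "F"
    )
    out = {}
    if len(p1) >= 2 and len(p2) >= 2:
        out["genotype"] = GroupComparison("genotype", p1, p2)
    if len(males) >= 2 and len(females) >= 2:
        out["sex"] = GroupComparison("sex", males, females)
    if len(dams) >= 2 and len(virgin_f) >= 2:
        out["parity"] = GroupComparison("parity", dams, virgin_f)
    return out


def validate_study(study: Study, threshold: float = 0.75, contexts=("CpG",)) -> ValidatedSites:
    """Context validation using the two parental groups' reads."""
    comp = comparisons(study.config)
    if "genotype" not in comp:
        raise ValueError("study lacks parental groups for validation")
    g1 = [study.batches[s] for s in comp["genotype"].group_a]
    g2 = [study.batches[s] for s in comp["genotype"].group_b]
    return validate_contexts(
        g1, g2, study.genomes.p1, study.genomes.p2, threshold=threshold,
        contexts=contexts,
    )


def study_counts(study: Study, validated: ValidatedSites) -> MethylationCounts:
    return build_counts(study.batches, list(study.config.samples), validated)


def call_and_filter(
    counts: MethylationCounts, comparison: GroupComparison, **kwargs
) -> list[DMRegion]:
    candidates = segment_dmrs(counts, comparison, **kwargs)
    return filter_dmrs(candidates, counts, comparison)


@dataclass
class RecoveryStats:
    """Planted-DMR recovery of one comparison axis."""

    sensitivity: float
    false_discovery_proportion: float
    n_planted: int
    n_called: int
    n_recovered: int
    boundary_offsets_cpg: np.ndarray  # |offset| in validated-CpG units, both edges
    frac_boundaries_within_2: float


def dmr_recovery(
    called: list[DMRegion],
    planted,
    counts: MethylationCounts,
    axis: str,
) -> RecoveryStats:
    """Score called DMRs against the planted truth for one axis.

    A planted DMR of the axis is recovered when a reported region
    overlaps it. A reported region is a false discovery only when it
    overlaps no planted DMR of *any* axis: the study design confounds
    parity with sex among parental animals (all dams are female, all
    sires male), so a sex contrast legitimately detects planted parity
    differences. Boundary accuracy is measured in validated-CpG units
    between the called edges and the planted edges.
    """
    rep = reported(called)
    truth = [d for d in planted if d.axis == axis]
    truth_any = list(planted)
    n_rec = 0
    offsets = []
    for t in truth:
        pos = counts.positions[t.chrom]
        t_sites = pos[(pos >= t.start) & (pos < t.end)]
        hits = [r for r in rep if r.overlaps(t.chrom, t.start, t.end)]
        if not hits or t_sites.size == 0:
            continue
        n_rec += 1
        r = max(hits, key=lambda r: min(r.end, t.end) - max(r.start, t.start))
        # boundary offset in CpG units (0 = exact)
        left = abs(
            int(np.searchsorted(pos, r.start)) - int(np.searchsorted(pos, t.start))
        )
        right = abs(
            int(np.searchsorted(pos, r.end)) - int(np.searchsorted(pos, t.end))
        )
        offsets.extend([left, right])
    fp = sum(
        1
        for r in rep
        if not any(r.overlaps(t.chrom, t.start, t.end) for t in truth_any)
    )
    offsets = np.array(offsets, dtype=int)
    return RecoveryStats(
        sensitivity=n_rec / len(truth) if truth else float("nan"),
        false_discovery_proportion=fp / len(rep) if rep else 0.0,
        n_planted=len(truth),
        n_called=len(rep),
        n_recovered=n_rec,
        boundary_offsets_cpg=offsets,
        frac_boundaries_within_2=float((offsets <= 2).mean()) if offsets.size else float("nan"),
    )


def planted_dmr_frame(planted) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "axis": d.axis,
                "polarity": d.polarity,
                "delta": d.delta,
            }
            for d in planted
        ]
    )
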