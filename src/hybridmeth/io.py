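"""Readers and writers for the pipeline's on-disk formats.

FASTA, minimal VCF (CHROM POS ID REF ALT; REF = P1 allele, ALT = P2),
BED tracks, per-sample bedGraph-style count TSVs, and YAML simulator
configs. Internal coordinates are 0-based half-open; VCF positions are
written 1-based, BED as-is.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from .config import DMRSpec, SampleSpec, SimConfig
from .genome import decode, encode


def write_fasta(seqs: dict[str, np.ndarray], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, arr in seqs.items():
            fh.write(f">{name}\n")
            s = decode(arr)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, np.ndarray]:
    fa = Fasta(path, rebuild=True)
    return {name: encode(str(fa[name][:])) for name in fa.keys()}


def write_vcf(snvs: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##INFO=<ID=.,Number=0,Type=Flag,Description=\"none\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in snvs[["chrom", "pos", "ref", "alt"]].itertuples(
            index=False
        ):
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def read_vcf(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[0], int(parts[1]) - 1, parts[3], parts[4]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def write_bed(df: pd.DataFrame, path: str, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str, extra_cols: list[str] | None = None) -> pd.DataFrame:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    return df


def write_counts_tsv(counts, sample_id: str, path: str) -> None:
    """bedGraph-style per-sample counts: chrom, pos, pos+2, meth, depth."""
    j = counts.sample_ids.index(sample_id)
    with open(path, "w") as fh:
        for chrom in counts.chroms:
            pos = counts.positions[chrom]
            m = counts.meth[chrom][:, j]
            d = counts.depth[chrom][:, j]
            for p, mi, di in zip(pos, m, d):
                fh.write(f"{chrom}\t{p}\t{p + 2}\t{mi}\t{di}\n")


def write_validated_bed(validated, path: str) -> None:
    """Validated CpG sites as BED3 + strand + context."""
    with open(path, "w") as fh:
        for chrom in validated.chroms:
            for p in validated.cpg.get(chrom, []):
                fh.write(f"{chrom}\t{p}\t{p + 2}\tCpG\t0\t+\n")


def config_to_yaml(config: SimConfig, path: str) -> None:
    d = dataclasses.asdict(config)
    d["samples"] = [dataclasses.asdict(s) for s in config.samples]
    d["dmr_specs"] = [dataclasses.asdict(s) for s in config.dmr_specs]
    for spec in d["dmr_specs"]:
        spec["width_range"] = list(spec["width_range"])
        spec["delta_range"] = list(spec["delta_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path: str) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "samples" in d:
        d["samples"] = tuple(SampleSpec(**s) for s in d["samples"])
    if "dmr_specs" in d:
        specs = []
        for s in d["dmr_specs"]:
            s = dict(s)
            s["width_range"] = tuple(s["width_range"])
            s["delta_range"] = tuple(s["delta_range"])
            specs.append(DMRSpec(**s))
        d["dmr_specs"] = tuple(specs)
    return SimConfig(**d)


def write_truth(truth, outdir: str) -> None:
    out = Path(outdir)
    truth.truth_frame().to_csv(out / "truth_cpg.tsv", sep="\t", index=False)
    rows = [
        (d.chrom, d.start, d.end, f"{d.axis}:{d.polarity}", int(round(100 * d.delta)), "+")
        for d in truth.planted_dmrs
    ]
    pd.DataFrame(rows).to_csv(out / "truth_dmrs.bed", sep="\t", header=False, index=False)
    truth.genomes.islands.to_csv(
        out / "cpg_islands.bed", sep="\t", header=False, index=False
    )
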