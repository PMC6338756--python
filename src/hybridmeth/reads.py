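"""Aligned bisulfite read-pair container and SAM interchange.

A :class:`ReadBatch` holds one sample's aligned paired-end fragments as
dense numpy arrays (fixed read length), which is the package's working
representation; SAM (via pysam) is the on-disk interchange format.

Conventions
-----------
* All reads are stored in forward (plus-strand) orientation, as in SAM.
  Both mates of an original-top (OT) fragment observe the converted top
  strand; both mates of an original-bottom (OB) fragment observe the
  converted bottom strand, which in forward orientation shows G->A
  conversion at unmethylated minus-strand cytosines.
* The per-base methylation-call string (``XM`` tag, Bismark convention:
  z/Z CpG, x/X CHG, h/H CHH, '.' otherwise) is stored in the same forward
  orientation as SEQ.
* ``XG:Z:CT`` marks OT fragments, ``XG:Z:GA`` OB fragments.
* ``XH:Z:P1|P2`` carries the simulator's true haplotype of origin. It is
  ground truth for scoring only; no analysis operation reads it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .genome import BASES, _CODE

OT, OB = 0, 1

_XM_DOT = ord(".")


@dataclass
class ReadBatch:
    """One sample's aligned read pairs as dense arrays."""

    sample_id: str
    chroms: list[str]  # chrom index -> name
    chrom_lengths: list[int]
    read_length: int
    chrom_idx: np.ndarray  # (n,) int32
    frag_start: np.ndarray  # (n,) int64 leftmost fragment base
    frag_len: np.ndarray  # (n,) int32
    strand: np.ndarray  # (n,) uint8, OT=0 / OB=1
    hap: np.ndarray  # (n,) uint8, truth haplotype 0=P1 / 1=P2
    r1_pos: np.ndarray  # (n,) int64 leftmost stored base of read1
    r2_pos: np.ndarray
    r1_seq: np.ndarray  # (n, read_length) uint8 base codes
    r2_seq: np.ndarray
    r1_xm: np.ndarray  # (n, read_length) uint8 ASCII XM bytes
    r2_xm: np.ndarray
    n_skipped: int = 0  # records dropped on import (e.g. missing XM)

    def __post_init__(self) -> None:
        n = self.n_fragments
        for name in ("frag_start", "frag_len", "strand", "hap", "r1_pos", "r2_pos"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} shape mismatch")
        for name in ("r1_seq", "r2_seq", "r1_xm", "r2_xm"):
            if getattr(self, name).shape != (n, self.read_length):
                raise ValueError(f"{name} shape mismatch")

    @property
    def n_fragments(self) -> int:
        return int(self.chrom_idx.size)

    def subset(self, mask_or_idx) -> "ReadBatch":
        return ReadBatch(
            sample_id=self.sample_id,
            chroms=self.chroms,
            chrom_lengths=self.chrom_lengths,
            read_length=self.read_length,
            chrom_idx=self.chrom_idx[mask_or_idx],
            frag_start=self.frag_start[mask_or_idx],
            frag_len=self.frag_len[mask_or_idx],
            strand=self.strand[mask_or_idx],
            hap=self.hap[mask_or_idx],
            r1_pos=self.r1_pos[mask_or_idx],
            r2_pos=self.r2_pos[mask_or_idx],
            r1_seq=self.r1_seq[mask_or_idx],
            r2_seq=self.r2_seq[mask_or_idx],
            r1_xm=self.r1_xm[mask_or_idx],
            r2_xm=self.r2_xm[mask_or_idx],
        )

    def for_chrom(self, chrom: str) -> "ReadBatch":
        ci = self.chroms.index(chrom)
        return self.subset(self.chrom_idx == ci)

    # ------------------------------------------------------------------
    # clipping / mate-overlap rules
    # ------------------------------------------------------------------
    def read_cells(
        self, read: int, clip_read2: bool = True, dedup: bool = True
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Retained (row, column, genomic position) cells for one mate.

        Applies the study's quantification rules: the first four and last
        one base of every read2 (in the read's own 5'->3' orientation) are
        clipped for positional methylation bias, and read2 positions also
        covered by the fragment's read1 are dropped (read1 wins the
        mate-overlap tie).
        """
        n, rl = self.r1_seq.shape if read == 1 else self.r2_seq.shape
        if n == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z, z
        cols = np.arange(rl)
        pos0 = self.r1_pos if read == 1 else self.r2_pos
        pos = pos0[:, None] + cols[None, :]
        keep = np.ones((n, rl), dtype=bool)
        if read == 2:
            if clip_read2:
                # read2 of an OT pair is reverse-mapped: its physical 5' end
                # is the rightmost stored column; OB read2 is forward-mapped.
                rev = self.strand == OT
                fwd = ~rev
                # reverse-mapped: clip stored-last 4 (physical first) and
                # stored-first 1 (physical last)
                keep[rev] &= (cols >= 1) & (cols < rl - 4)
                keep[fwd] &= (cols >= 4) & (cols < rl - 1)
            if dedup:
                r1_lo = self.r1_pos[:, None]
                keep &= ~((pos >= r1_lo) & (pos < r1_lo + self.read_length))
        rows, colsel = np.nonzero(keep)
        return rows, colsel, pos[keep]

    def base_pileup(
        self, chrom: str, clip_read2: bool = True, dedup: bool = True
    ) -> np.ndarray:
        """Per-position, per-strand base counts for one chromosome.

        Returns an int64 array of shape (2, 4, L): axis 0 = observation
        strand (OT, OB), axis 1 = base code, axis 2 = position.
        """
        sub = self.for_chrom(chrom)
        L = self.chrom_lengths[self.chroms.index(chrom)]
        out = np.zeros(8 * L, dtype=np.int64)
        for read, seqmat in ((1, sub.r1_seq), (2, sub.r2_seq)):
            rows, cols, pos = sub.read_cells(read, clip_read2=clip_read2, dedup=dedup)
            if rows.size == 0:
                continue
            base = seqmat[rows, cols]
            strand = sub.strand[rows].astype(np.int64)
            ok = base < 4
            flat = (strand[ok] * 4 + base[ok]) * L + pos[ok]
            out += np.bincount(flat, minlength=8 * L)
        return out.reshape(2, 4, L)

    # ------------------------------------------------------------------
    # SAM interchange
    # ------------------------------------------------------------------
    def write_sam(self, path: str) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": int(ln)}
                for c, ln in zip(self.chroms, self.chrom_lengths)
            ],
            "RG": [{"ID": self.sample_id, "SM": self.sample_id}],
        }
        rl = self.read_length
        qual = pysam.qualitystring_to_array("I" * rl)
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for i in range(self.n_fragments):
                strand = int(self.strand[i])
                qname = f"{self.sample_id}.{i}"
                tlen = int(self.frag_len[i])
                for read in (1, 2):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = qname
                    a.reference_id = int(self.chrom_idx[i])
                    a.next_reference_id = a.reference_id
                    pos = self.r1_pos if read == 1 else self.r2_pos
                    mpos = self.r2_pos if read == 1 else self.r1_pos
                    a.reference_start = int(pos[i])
                    a.next_reference_start = int(mpos[i])
                    seq = self.r1_seq[i] if read == 1 else self.r2_seq[i]
                    xm = self.r1_xm[i] if read == 1 else self.r2_xm[i]
                    a.query_sequence = BASES[seq].tobytes().decode("ascii")
                    a.query_qualities = qual
                    a.cigarstring = f"{rl}M"
                    a.mapping_quality = 42
                    if strand == OT:
                        a.flag = 99 if read == 1 else 147
                    else:
                        a.flag = 83 if read == 1 else 163
                    a.template_length = tlen if (a.reference_start <= int(mpos[i])) else -tlen
                    a.set_tag("XM", xm.tobytes().decode("ascii"))
                    a.set_tag("XG", "CT" if strand == OT else "GA")
                    a.set_tag("XH", "P1" if self.hap[i] == 0 else "P2")
                    a.set_tag("RG", self.sample_id)
                    out.write(a)

    @classmethod
    def read_sam(cls, path: str, sample_id: str | None = None) -> "ReadBatch":
        """Load a Bismark-convention SAM written by this package.

        Records without an XM tag are skipped and counted in
        ``n_skipped``. Both mates of a pair must be present and mapped to
        the same chromosome.
        """
        with pysam.AlignmentFile(path, "r", check_sq=False) as f:
            chroms = list(f.references)
            lengths = [int(x) for x in f.lengths]
            pairs: dict[str, list] = {}
            n_skipped = 0
            rl = None
            for rec in f:
                if rec.is_unmapped or rec.query_sequence is None:
                    n_skipped += 1
                    continue
                if not rec.has_tag("XM"):
                    n_skipped += 1
                    continue
                if rl is None:
                    rl = rec.query_length
                elif rec.query_length != rl:
                    raise ValueError("mixed read lengths in SAM input")
                pairs.setdefault(rec.query_name, []).append(rec)
        if rl is None:
            raise ValueError(f"no usable records in {path}")

        rows = []
        for qname, recs in pairs.items():
            if len(recs) != 2:
                n_skipped += len(recs)
                continue
            r1 = next((r for r in recs if r.is_read1), None)
            r2 = next((r for r in recs if r.is_read2), None)
            if r1 is None or r2 is None:
                n_skipped += 2
                continue
            if r1.reference_id != r2.reference_id:
                raise ValueError(f"mates of {qname} map to different chromosomes")
            rows.append((r1, r2))
        rows.sort(key=lambda pr: (pr[0].reference_id, min(pr[0].reference_start, pr[1].reference_start), pr[0].query_name))

        n = len(rows)
        chrom_idx = np.zeros(n, dtype=np.int32)
        frag_start = np.zeros(n, dtype=np.int64)
        frag_len = np.zeros(n, dtype=np.int32)
        strand = np.zeros(n, dtype=np.uint8)
        hap = np.zeros(n, dtype=np.uint8)
        r1_pos = np.zeros(n, dtype=np.int64)
        r2_pos = np.zeros(n, dtype=np.int64)
        r1_seq = np.zeros((n, rl), dtype=np.uint8)
        r2_seq = np.zeros((n, rl), dtype=np.uint8)
        r1_xm = np.full((n, rl), _XM_DOT, dtype=np.uint8)
        r2_xm = np.full((n, rl), _XM_DOT, dtype=np.uint8)
        for i, (r1, r2) in enumerate(rows):
            chrom_idx[i] = r1.reference_id
            r1_pos[i] = r1.reference_start
            r2_pos[i] = r2.reference_start
            lo = min(r1.reference_start, r2.reference_start)
            hi = max(r1.reference_start + rl, r2.reference_start + rl)
            frag_start[i] = lo
            frag_len[i] = abs(r1.template_length) or (hi - lo)
            xg = r1.get_tag("XG") if r1.has_tag("XG") else ("CT" if not r1.is_reverse else "GA")
            strand[i] = OT if xg == "CT" else OB
            if r1.has_tag("XH"):
                hap[i] = 0 if r1.get_tag("XH") == "P1" else 1
            r1_seq[i] = _CODE[np.frombuffer(r1.query_sequence.encode(), dtype=np.uint8)]
            r2_seq[i] = _CODE[np.frombuffer(r2.query_sequence.encode(), dtype=np.uint8)]
            r1_xm[i] = np.frombuffer(r1.get_tag("XM").encode(), dtype=np.uint8)
            r2_xm[i] = np.frombuffer(r2.get_tag("XM").encode(), dtype=np.uint8)

        sid = sample_id
        if sid is None:
            sid = rows[0][0].get_tag("RG") if rows and rows[0][0].has_tag("RG") else "sample"
        return cls(
            sample_id=sid,
            chroms=chroms,
            chrom_lengths=lengths,
            read_length=rl,
            chrom_idx=chrom_idx,
            frag_start=frag_start,
            frag_len=frag_len,
            strand=strand,
            hap=hap,
            r1_pos=r1_pos,
            r2_pos=r2_pos,
            r1_seq=r1_seq,
            r2_seq=r2_seq,
            r1_xm=r1_xm,
            r2_xm=r2_xm,
            n_skipped=n_skipped,
        )


def concat_batches(batches: list[ReadBatch]) -> ReadBatch:
    """Concatenate batches sharing chroms and read length (reads pooled)."""
    first = batches[0]
    for b in batches[1:]:
        if b.chroms != first.chroms or b.read_length != first.read_length:
            raise ValueError("batches are not compatible")
    return ReadBatch(
        sample_id=first.sample_id,
        chroms=first.chroms,
        chrom_lengths=first.chrom_lengths,
        read_length=first.read_length,
        chrom_idx=np.concatenate([b.chrom_idx for b in batches]),
        frag_start=np.concatenate([b.frag_start for b in batches]),
        frag_len=np.concatenate([b.frag_len for b in batches]),
        strand=np.concatenate([b.strand for b in batches]),
        hap=np.concatenate([b.hap for b in batches]),
        r1_pos=np.concatenate([b.r1_pos for b in batches]),
        r2_pos=np.concatenate([b.r2_pos for b in batches]),
        r1_seq=np.concatenate([b.r1_seq for b in batches]),
        r2_seq=np.concatenate([b.r2_seq for b in batches]),
        r1_xm=np.concatenate([b.r1_xm for b in batches]),
        r2_xm=np.concatenate([b.r2_xm for b in batches]),
        n_skipped=sum(b.n_skipped for b in batches),
    )
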