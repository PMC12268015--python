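"""Small-RNA read processing: adapter clipping, quality trimming and
mismatch-tolerant assignment of reads to annotated mature arms.

A read is trimmed by removing the 3' sequencing adapter (full adapter
anywhere, else the longest read-suffix match of at least 8 nt against an
adapter prefix), then trimming 3' bases below the Phred threshold, and
kept only if its final length lies in the configured insert range.

Assignment aligns the trimmed read ungapped at every offset of every
hairpin (sense strand only — small-RNA libraries are stranded), keeps
the hit with the fewest mismatches within the allowed maximum, and
attributes it to an arm when the read 5' end falls within a small window
of the annotated arm start. Equally good hits on different loci are
resolved by a seeded uniform random choice so counts stay integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    HairpinCatalog,
    MatureArmCountMatrix,
    ValidationError,
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TrimConfig:
    """Adapter/quality trimming parameters (TruSeq small-RNA defaults)."""

    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    quality_threshold: int = 20
    min_len: int = 18
    max_len: int = 33
    min_adapter_overlap: int = 8

    def __post_init__(self) -> None:
        if not self.adapter3:
            raise ValidationError("adapter must be non-empty")
        if not (0 < self.min_len <= self.max_len):
            raise ValidationError("need 0 < min_len <= max_len")


@dataclass(frozen=True)
class AssignmentPolicy:
    """Read-to-arm assignment parameters.

    ``max_mismatches`` counts substitutions only (ungapped matching
    within the hairpin); ``end_tolerance`` is the allowed distance in nt
    between the read 5' position on the hairpin and the annotated arm
    start, admitting common 5' isomiRs.
    """

    max_mismatches: int = 2
    end_tolerance: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.end_tolerance < 0:
            raise ValidationError("negative policy parameter")


def trim_read(
    seq: str, qual: Sequence[int], cfg: TrimConfig
) -> tuple[str, tuple[int, ...]] | None:
    """Trim one read; return (seq, quals) or None if discarded."""
    if len(seq) != len(qual):
        raise ValidationError("sequence and quality lengths differ")
    seq = seq.upper()
    adapter = cfg.adapter3.upper()
    cut = len(seq)
    pos = seq.find(adapter)
    if pos >= 0:
        cut = pos
    else:
        # longest read suffix equal to an adapter prefix, >= min overlap
        max_k = min(len(adapter) - 1, len(seq))
        for k in range(max_k, cfg.min_adapter_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = len(seq) - k
                break
    seq = seq[:cut]
    qual = tuple(qual[:cut])
    while seq and qual[-1] < cfg.quality_threshold:
        seq = seq[:-1]
        qual = qual[:-1]
    if cfg.min_len <= len(seq) <= cfg.max_len:
        return seq, qual
    return None


def _hairpin_hits(read: str, hairpin: str, max_mm: int) -> list[tuple[int, int]]:
    """All (mismatches, offset) of ungapped alignments with <= max_mm."""
    n, m = len(hairpin), len(read)
    if m > n:
        return []
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    h = np.frombuffer(hairpin.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(h, m)
    mism = (windows != r).sum(axis=1)
    return [(int(mm), int(off)) for off, mm in enumerate(mism) if mm <= max_mm]


def assign_read(
    read_seq: str,
    catalog: HairpinCatalog,
    policy: AssignmentPolicy,
    rng: np.random.Generator | None = None,
) -> tuple[str, str] | str:
    """Assign a trimmed read to a (locus_id, arm) or return ``'unassigned'``.

    Best hit = fewest mismatches over all offsets of all hairpins (sense
    strand); the hit maps to an arm when its 5' position is within
    ``end_tolerance`` of the annotated arm start. Ties across loci at
    equal mismatch count are broken by a seeded uniform choice. Hits
    inside a hairpin but outside both arm windows are unassigned.
    """
    if len(catalog) == 0:
        raise ValidationError("empty catalog")
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    read_seq = read_seq.upper()
    best_mm = policy.max_mismatches + 1
    best: list[tuple[str, int]] = []  # (locus, offset) at best_mm
    for entry in catalog:
        for mm, off in _hairpin_hits(read_seq, entry.hairpin_seq, policy.max_mismatches):
            if mm < best_mm:
                best_mm = mm
                best = [(entry.locus_id, off)]
            elif mm == best_mm:
                best.append((entry.locus_id, off))
    if not best:
        return UNASSIGNED
    # collapse to one hit per locus (a read rarely matches one hairpin twice;
    # keep the offset closest to an annotated arm start)
    per_locus: dict[str, tuple[int, int]] = {}
    for locus, off in best:
        entry = catalog[locus]
        starts = [entry.arm_interval(a).start - 1 for a in entry.arms]
        key = min((abs(off - s) for s in starts), default=0)
        if locus not in per_locus or key < per_locus[locus][0]:
            per_locus[locus] = (key, off)
    loci = sorted(per_locus)
    if len(loci) == 1:
        chosen = loci[0]
    else:
        chosen = loci[int(rng.integers(0, len(loci)))]
    entry = catalog[chosen]
    off = per_locus[chosen][1]
    pos1 = off + 1  # 1-based 5' position on the hairpin
    for arm in entry.arms:
        start = entry.arm_interval(arm).start
        if abs(pos1 - start) <= policy.end_tolerance:
            return (chosen, arm)
    return UNASSIGNED


@dataclass
class SampleQC:
    sample_id: str
    reads_in: int = 0
    reads_kept: int = 0
    assigned: int = 0
    unassigned: int = 0


def quantify(
    fastq_paths: dict[str, str | Path],
    catalog: HairpinCatalog,
    trim: TrimConfig | None = None,
    policy: AssignmentPolicy | None = None,
) -> tuple[MatureArmCountMatrix, pd.DataFrame]:
    """Count reads per mature arm for one FASTQ per sample.

    Returns the arm-by-sample count matrix (rows in catalog order) and a
    QC table with reads in/kept/assigned/unassigned per sample. For every
    sample, ``reads_kept == assigned + unassigned``.
    """
    trim = trim or TrimConfig()
    policy = policy or AssignmentPolicy()
    arm_ids = catalog.arm_ids()
    row_index = {a: i for i, a in enumerate(arm_ids)}
    sample_ids = list(fastq_paths)
    counts = np.zeros((len(arm_ids), len(sample_ids)), dtype=np.int64)
    qc_rows = []
    for j, sid in enumerate(sample_ids):
        path = Path(fastq_paths[sid])
        if not path.exists():
            raise ValidationError(f"missing FASTQ for sample {sid!r}: {path}")
        rng = np.random.default_rng(policy.seed)
        qc = SampleQC(sid)
        for rec in SeqIO.parse(str(path), "fastq"):
            qc.reads_in += 1
            trimmed = trim_read(
                str(rec.seq), rec.letter_annotations["phred_quality"], trim
            )
            if trimmed is None:
                continue
            qc.reads_kept += 1
            hit = assign_read(trimmed[0], catalog, policy, rng=rng)
            if hit == UNASSIGNED:
                qc.unassigned += 1
            else:
                counts[row_index[hit], j] += 1
                qc.assigned += 1
        qc_rows.append(qc)
    matrix = MatureArmCountMatrix(arm_ids, sample_ids, counts)
    qc_df = pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "reads_in": q.reads_in,
                "reads_kept": q.reads_kept,
                "assigned": q.assigned,
                "unassigned": q.unassigned,
            }
            for q in qc_rows
        ]
    )
    return matrix, qc_df
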