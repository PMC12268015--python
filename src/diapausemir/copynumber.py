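"""miR-430 genomic copy-number estimation from unassembled short reads.

The miR-430 family sits in a large repetitive cluster that short-read
assemblies collapse, so copy number is estimated directly from raw
reads: count the reads containing any of a set of conserved mature-miR
motifs (approximate infix match, edit distance <= 2, both strands), and
normalize by sequencing coverage:

    copies per haploid genome = h / (l / g) = h * g / l

with h the motif-containing read count, l the total sequenced bases and
g the haploid genome size. A Poisson standard error sqrt(h) * g / l is
attached. Genus groups (annual vs non-annual) are compared with an
exact two-sided Wilcoxon rank-sum test whose null distribution is built
by dynamic programming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import SeqIO

from .core import TestResult, ValidationError

#: Conserved motifs of the eight miR-430 isoforms identified in N. furzeri.
MIR430_MOTIFS = (
    "UAAGUGCUAUUUGUUGGGGAAG",
    "UAAGUGCUAACUGUUGGGGUAG",
    "UAAGUGCUAACUGUUGGGGUAU",
    "UAAGUGCUACAUGUUGGGGCAG",
    "CACCUCAAAGAAUCCACUGA",
    "ACUCUGACAAAGGCACUGACU",
    "UAAGUGCUACAUGUUGGAGUCA",
    "UAAGUGCUUCUCUUUGGGGUUG",
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MotifSet:
    motifs: tuple[str, ...] = MIR430_MOTIFS

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValidationError("empty motif set")
        for m in self.motifs:
            if not m or set(m.upper()) - set("ACGU"):
                raise ValidationError(f"motif {m!r} is not an RNA string")

    def dna(self) -> list[str]:
        """Both-strand DNA search patterns (motif and reverse complement)."""
        fwd = [m.upper().replace("U", "T") for m in self.motifs]
        return fwd + [_revcomp(m) for m in fwd]


@dataclass(frozen=True)
class CopyNumberInputs:
    species: str
    genus: str
    annual: bool
    h: int
    l: float
    g: float

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValidationError("hit count h must be >= 0")
        if self.l <= 0 or self.g <= 0:
            raise ValidationError("total read length l and genome size g must be > 0")


@dataclass(frozen=True)
class CopyNumberEstimate:
    inputs: CopyNumberInputs

    @property
    def copies(self) -> float:
        return self.inputs.h * self.inputs.g / self.inputs.l

    @property
    def poisson_se(self) -> float:
        return math.sqrt(self.inputs.h) * self.inputs.g / self.inputs.l

    @property
    def coverage(self) -> float:
        return self.inputs.l / self.inputs.g


def _read_matches(seq: str, patterns: Sequence[str], max_edits: int, mode: str) -> bool:
    if mode == "edit":
        for p in patterns:
            r = edlib.align(p, seq, mode="HW", task="distance", k=max_edits)
            if r["editDistance"] != -1:
                return True
        return False
    if mode == "hamming":
        n = len(seq)
        b = np.frombuffer(seq.encode(), dtype=np.uint8)
        for p in patterns:
            m = len(p)
            if m > n:
                continue
            q = np.frombuffer(p.encode(), dtype=np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(b, m)
            if ((win != q).sum(axis=1) <= max_edits).any():
                return True
        return False
    raise ValidationError(f"unknown match mode {mode!r}")


def scan_reads(
    fastq: str | Path,
    motifs: MotifSet = MotifSet(),
    max_edits: int = 2,
    mode: str = "edit",
) -> tuple[int, int]:
    """Count motif-containing reads and total read bases in a FASTQ.

    A read counts toward ``h`` at most once, however many motifs or
    strands it matches; ``l`` accumulates the length of every read,
    matching or not. ``mode='edit'`` (default) uses semi-global (infix)
    edit distance — substitutions and indels — as an edit-distance
    engine does; ``mode='hamming'`` restricts to substitutions for
    sensitivity analysis.
    """
    patterns = motifs.dna()
    h = 0
    l = 0
    for rec in SeqIO.parse(str(fastq), "fastq"):
        seq = str(rec.seq).upper()
        l += len(seq)
        if _read_matches(seq, patterns, max_edits, mode):
            h += 1
    return h, l


def estimate_copies(inputs: CopyNumberInputs) -> CopyNumberEstimate:
    """Copies per haploid genome, h normalized by coverage l/g."""
    return CopyNumberEstimate(inputs)


# ---------------------------------------------------------------------------
# exact Wilcoxon rank-sum test


@lru_cache(maxsize=None)
def _u_count(n: int, m: int, u: int) -> int:
    """Number of rank assignments of n-vs-m giving Mann-Whitney U = u."""
    if u < 0:
        return 0
    if n == 0 or m == 0:
        return 1 if u == 0 else 0
    return _u_count(n - 1, m, u - m) + _u_count(n, m - 1, u)


def exact_u_distribution(n: int, m: int) -> np.ndarray:
    """Null pmf of U over 0..n*m (no ties)."""
    total = math.comb(n + m, n)
    counts = np.array([_u_count(n, m, u) for u in range(n * m + 1)], dtype=float)
    return counts / total


def exact_u_pvalue(w: float, n: int, m: int) -> float:
    """Exact two-sided p for an observed U=w: 2*min(tails), capped at 1."""
    pmf = exact_u_distribution(n, m)
    lo = float(pmf[: int(math.floor(w)) + 1].sum())
    hi = float(pmf[int(math.ceil(w)) :].sum())
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic W is the number of (x, y) pairs with x > y (ties count
    half) — the U statistic of x. With no ties and n+m <= 30 (or
    ``mode='exact'``) the p-value is exact from the full DP-enumerated
    null distribution of U; otherwise a normal approximation with tie
    and continuity correction is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(n + m)
    # midranks for ties
    sorted_vals = combined[order]
    r = np.arange(1, n + m + 1, dtype=float)
    i = 0
    while i < n + m:
        j = i
        while j + 1 < n + m and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        r[i : j + 1] = (i + j) / 2 + 1
        i = j + 1
    ranks[order] = r
    rank_sum_x = float(ranks[:n].sum())
    w = rank_sum_x - n * (n + 1) / 2.0  # U statistic of x

    has_ties = len(np.unique(combined)) < n + m
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and not has_ties and n + m <= 30)
    if use_exact and has_ties:
        raise ValidationError("exact mode is undefined with tied observations")
    if use_exact:
        p = exact_u_pvalue(w, n, m)
        method = "wilcoxon_exact"
    else:
        mean = n * m / 2.0
        tie_sizes = np.array(
            [np.sum(combined == v) for v in np.unique(combined)], dtype=float
        )
        nm = n + m
        tie_term = (tie_sizes**3 - tie_sizes).sum() / ((nm) * (nm - 1))
        var = n * m / 12.0 * ((nm + 1) - tie_term)
        if var <= 0:
            return TestResult(statistic=w, p_value=1.0, method="wilcoxon_normal")
        z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
        from scipy.stats import norm

        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
        method = "wilcoxon_normal"
    return TestResult(statistic=w, p_value=p, method=method)


def compare_groups(
    estimates: Sequence[CopyNumberEstimate],
    contrasts: Mapping[str, tuple[Iterable[str], Iterable[str]]],
) -> dict[str, TestResult]:
    """Exact rank-sum comparison of copy estimates between genus groups.

    ``contrasts`` maps a contrast name to (group_x genera, group_y
    genera); the reported W is the U statistic of group_x. Default
    study contrasts compare the annual genus against its non-annual
    sister genera within each African clade.
    """
    by_genus: dict[str, list[float]] = {}
    for e in estimates:
        by_genus.setdefault(e.inputs.genus, []).append(e.copies)
    out: dict[str, TestResult] = {}
    for name, (gx, gy) in contrasts.items():
        xs = [v for g in gx for v in by_genus.get(g, [])]
        ys = [v for g in gy for v in by_genus.get(g, [])]
        if not xs or not ys:
            raise ValidationError(f"contrast {name!r}: a group resolves to no species")
        out[name] = wilcoxon_rank_sum(xs, ys)
    return out


#: The two genus contrasts examined in the study.
DEFAULT_CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "nothobranchius_vs_aphyosemion": (("Nothobranchius",), ("Aphyosemion",)),
    "callopanchax_vs_nonannual_west": (
        ("Callopanchax",),
        ("Scriptaphyosemion", "Archiaphyosemion", "Epiplatys"),
    ),
}
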