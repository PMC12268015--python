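"""Synthetic inputs with known planted truth for every pipeline stage.

Three generators:

* :func:`simulate_counts` — NB-distributed mature-arm counts for a
  two-group design, with optional planted differentially expressed arms
  (mean shifted by ``2**planted_lfc`` in group_a) and planted arm
  switches (5p/3p mass redistributed in group_a while the locus total
  mean is preserved exactly).
* :func:`simulate_small_rna_fastq` — small-RNA reads: a mature-arm
  sequence, optionally with planted substitutions, followed by the 3'
  sequencing adapter, with high-quality Phred scores and optionally
  degraded 3' tails.
* :func:`simulate_genome_reads` — a uniform-random background genome
  with non-overlapping planted motif copies (random strand), sampled
  into error-bearing short reads at a stated coverage.

Every generator is deterministic given its seed, and each returns (or
writes) a :class:`PlantedTruth` sufficient to score the downstream stage
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    ComparisonDesign,
    HairpinCatalog,
    HairpinEntry,
    Interval,
    MatureArmCountMatrix,
    ValidationError,
)

_DNA = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

#: 3' adapter of the TruSeq small-RNA protocol (RA3)
TRUSEQ_RA3 = "TGGAATTCTCGGGTGCCAAGG"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator.

    ``dem_arm_ids`` maps (locus_id, arm) -> signed planted log2FC;
    ``switch_locus_ids`` lists loci with a planted 5p/3p switch;
    ``copy_number`` maps species -> planted motif copies per haploid genome.
    """

    dem_arm_ids: dict = field(default_factory=dict)
    switch_locus_ids: list = field(default_factory=list)
    copy_number: dict = field(default_factory=dict)


@dataclass
class CountSimConfig:
    """Conditions for the NB count simulator.

    Defaults emulate the study design: 8 annual-diapause vs 7 non-annual
    libraries, a log-normal distribution of baseline arm means, and NB
    dispersion (var = mu + alpha*mu^2) drawn log-uniform over the range
    typical of small-RNA libraries. ``dispersion`` may be a float to fix
    alpha for calibration experiments, or None to draw per arm.
    """

    n_loci: int = 200
    n_a: int = 8
    n_b: int = 7
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    dispersion: float | None = None
    dispersion_range: tuple[float, float] = (0.01, 0.5)
    planted_dem_fraction: float = 0.0
    planted_lfc: float = 2.0
    planted_dem_mu: float | None = None
    planted_switch_loci: int = 0
    switch_mu: float = 500.0
    switch_frac_before: float = 0.7
    switch_frac_after: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci <= 0 or self.n_a <= 0 or self.n_b <= 0:
            raise ValidationError("n_loci and group sizes must be positive")
        if not (0.0 <= self.planted_dem_fraction <= 1.0):
            raise ValidationError("planted_dem_fraction must lie in [0,1]")
        if self.planted_switch_loci < 0 or self.planted_switch_loci > self.n_loci:
            raise ValidationError("planted_switch_loci out of range")
        lo, hi = self.dispersion_range
        if not (0 < lo <= hi):
            raise ValidationError("dispersion_range must be positive and ordered")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, var = mu + alpha*mu^2) via gamma-Poisson mixture."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        a = alpha[pos]
        m = mu[pos]
        lam = np.where(
            a > 1e-12, rng.gamma(shape=1.0 / np.maximum(a, 1e-12), scale=a * m), m
        )
        out[pos] = rng.poisson(lam)
    return out


def simulate_counts(
    cfg: CountSimConfig,
    design: ComparisonDesign | None = None,
    extra_ids: Sequence[str] = (),
) -> tuple[MatureArmCountMatrix, PlantedTruth, ComparisonDesign]:
    """Simulate an arm-level count matrix with planted DEMs and switches.

    Every locus carries both a 5p and a 3p arm. Planted DEMs shift the
    group_a mean of single arms by ``2**planted_lfc`` with random sign;
    planted switch loci move arm mass in group_a from the dominant 5p
    fraction ``switch_frac_before`` to ``switch_frac_after`` while the
    locus total mean stays exactly equal between groups. The two planted
    sets are disjoint.

    Returns the matrix, the planted truth, and the design used (the one
    given, or a fresh two-group design over generated sample ids).
    ``extra_ids`` appends samples drawn at the group_b (baseline) means,
    outside both design groups — e.g. diapause-skipped libraries.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if design is None:
        ids_a = [f"annual_{i+1}" for i in range(cfg.n_a)]
        ids_b = [f"nonannual_{i+1}" for i in range(cfg.n_b)]
        design = ComparisonDesign("simulated", ids_a, ids_b)
    else:
        ids_a = sorted(design.group_a)
        ids_b = sorted(design.group_b)
        if len(ids_a) != cfg.n_a or len(ids_b) != cfg.n_b:
            raise ValidationError("design group sizes disagree with config")
    loci = [f"mir-sim-{i+1}" for i in range(cfg.n_loci)]
    arm_ids = [(l, arm) for l in loci for arm in ("5p", "3p")]
    n_arms = len(arm_ids)

    base = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_arms)
    if cfg.dispersion is not None:
        alpha = np.full(n_arms, float(cfg.dispersion))
    else:
        lo, hi = cfg.dispersion_range
        alpha = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_arms))

    truth = PlantedTruth()
    mu_a = base.copy()
    mu_b = base.copy()

    # planted switches first: whole loci, totals preserved
    switch_loci = list(rng.choice(cfg.n_loci, size=cfg.planted_switch_loci, replace=False))
    for li in switch_loci:
        locus = loci[li]
        total = cfg.switch_mu / 0.5  # locus total so each arm averages switch_mu
        i5, i3 = 2 * li, 2 * li + 1
        mu_b[i5] = total * cfg.switch_frac_before
        mu_b[i3] = total * (1.0 - cfg.switch_frac_before)
        mu_a[i5] = total * cfg.switch_frac_after
        mu_a[i3] = total * (1.0 - cfg.switch_frac_after)
        truth.switch_locus_ids.append(locus)

    # planted DEMs on arms of non-switch loci
    if cfg.planted_dem_fraction > 0 and cfg.planted_lfc != 0:
        switch_set = set(switch_loci)
        eligible = [i for i in range(n_arms) if i // 2 not in switch_set]
        n_dem = int(round(cfg.planted_dem_fraction * n_arms))
        n_dem = min(n_dem, len(eligible))
        chosen = rng.choice(len(eligible), size=n_dem, replace=False)
        for j in chosen:
            i = eligible[j]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * cfg.planted_lfc
            if cfg.planted_dem_mu is not None:
                mu_b[i] = cfg.planted_dem_mu
            mu_a[i] = mu_b[i] * 2.0**lfc
            truth.dem_arm_ids[arm_ids[i]] = lfc

    extra_ids = list(extra_ids)
    counts = np.zeros((n_arms, cfg.n_a + cfg.n_b + len(extra_ids)), dtype=np.int64)
    for j in range(cfg.n_a):
        counts[:, j] = _nb_draw(rng, mu_a, alpha)
    for j in range(cfg.n_b):
        counts[:, cfg.n_a + j] = _nb_draw(rng, mu_b, alpha)
    for j in range(len(extra_ids)):
        counts[:, cfg.n_a + cfg.n_b + j] = _nb_draw(rng, mu_b, alpha)
    matrix = MatureArmCountMatrix(arm_ids, ids_a + ids_b + extra_ids, counts)
    return matrix, truth, design


def synthetic_catalog(
    n_loci: int = 20,
    hairpin_len: int = 70,
    arm_len: int = 22,
    conserved_fraction: float = 0.6,
    seed: int = 0,
) -> HairpinCatalog:
    """Random hairpin catalog with both arms annotated on every locus.

    Arm sequences are drawn i.i.d. uniform over ACGT, so distinct loci
    collide only with negligible probability at typical arm lengths.
    """
    rng = np.random.default_rng(seed)
    entries = []
    loop = hairpin_len - 2 * arm_len
    if loop < 3:
        raise ValidationError("hairpin too short for two arms")
    for i in range(n_loci):
        seq = "".join(rng.choice(_DNA, size=hairpin_len))
        conserved = bool(rng.random() < conserved_fraction)
        family = f"mir-fam-{i % max(1, n_loci // 2) + 1}"
        entries.append(
            HairpinEntry(
                locus_id=f"mir-syn-{i+1}",
                family=family,
                conserved=conserved,
                hairpin_seq=seq,
                arm5p=Interval(1, arm_len),
                arm3p=Interval(hairpin_len - arm_len + 1, hairpin_len),
            )
        )
    return HairpinCatalog(entries)


def simulate_small_rna_fastq(
    catalog: HairpinCatalog,
    abundances: dict[tuple[str, str], int],
    out_fastq: str | Path,
    adapter: str = TRUSEQ_RA3,
    n_substitutions: int = 0,
    degrade_tail: int = 0,
    seed: int = 0,
) -> PlantedTruth:
    """Write small-RNA reads with known per-arm abundances.

    Each arm contributes exactly ``abundances[arm_id]`` reads, each being
    the mature-arm sequence with ``n_substitutions`` planted substitutions
    at distinct positions, followed by the 3' adapter. Qualities are Q38
    except for ``degrade_tail`` 3'-terminal adapter bases at Q2 (below
    the Q20 trimming threshold). Read order is deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, str]] = []
    for (locus, arm), n in sorted(abundances.items()):
        if n < 0:
            raise ValidationError(f"negative abundance for {(locus, arm)}")
        if locus not in catalog:
            raise ValidationError(f"unknown locus {locus!r}")
        arm_seq = catalog[locus].arm_seq(arm)
        if arm_seq is None:
            raise ValidationError(f"locus {locus!r} has no annotated {arm} arm")
        for r in range(n):
            insert = list(arm_seq)
            if n_substitutions:
                pos = rng.choice(len(insert), size=n_substitutions, replace=False)
                for p in pos:
                    insert[p] = str(
                        rng.choice([b for b in "ACGT" if b != insert[p]])
                    )
            seq = "".join(insert) + adapter
            degrade = min(degrade_tail, len(adapter))
            qual = "G" * (len(insert) + len(adapter) - degrade) + "#" * degrade
            reads.append((f"{locus}|{arm}|read{r+1}", seq, qual))
    rng.shuffle(reads)
    with open(out_fastq, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    truth = PlantedTruth()
    truth.dem_arm_ids = {k: float(v) for k, v in abundances.items()}
    return truth


@dataclass
class GenomeSimConfig:
    """Conditions for the genomic-read simulator.

    ``read_length`` defaults to 100 nt (Illumina-like); note that the
    copy-number estimator's coverage normalization ignores read-edge
    effects, so recovery experiments should use reads much longer than
    the motif (see the methods note).
    """

    genome_length: int = 1_000_000
    motifs: Sequence[str] = ()
    copies_per_motif: int = 20
    read_length: int = 100
    coverage: float = 10.0
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0 or self.read_length <= 0:
            raise ValidationError("genome_length and read_length must be positive")
        if self.coverage <= 0:
            raise ValidationError("coverage must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValidationError("error_rate must lie in [0,1)")
        if not self.motifs:
            raise ValidationError("motif set must be non-empty")
        total = self.copies_per_motif * sum(len(m) for m in self.motifs)
        if total >= self.genome_length:
            raise ValidationError("planted copies exceed genome length")


def simulate_genome_reads(
    cfg: GenomeSimConfig, out_fastq: str | Path, species: str = "synthetic"
) -> PlantedTruth:
    """Write genomic short reads from a background genome with planted motifs.

    The genome is uniform i.i.d. ACGT with ``copies_per_motif``
    non-overlapping insertions of each motif (DNA form, random strand).
    Reads of fixed length start uniformly over the genome at the stated
    coverage, with i.i.d. substitution errors at ``error_rate``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    g = cfg.genome_length
    genome = rng.choice(_DNA, size=g)

    # non-overlapping planting positions for all copies of all motifs
    motifs_dna = [m.upper().replace("U", "T") for m in cfg.motifs]
    placements: list[tuple[int, int]] = []  # (start, length)
    total_copies = 0
    for m in motifs_dna:
        L = len(m)
        for _ in range(cfg.copies_per_motif):
            for _attempt in range(10_000):
                s = int(rng.integers(0, g - L))
                if all(s + L <= ps or s >= ps + pl for ps, pl in placements):
                    placements.append((s, L))
                    strand_m = m if rng.random() < 0.5 else revcomp(m)
                    genome[s : s + L] = list(strand_m)
                    total_copies += 1
                    break
            else:
                raise ValidationError("could not place motif copies without overlap")

    n_reads = int(round(cfg.coverage * g / cfg.read_length))
    L = cfg.read_length
    qual = "I" * L
    with open(out_fastq, "w") as fh:
        for i in range(n_reads):
            s = int(rng.integers(0, g - L + 1))
            read = genome[s : s + L].copy()
            if cfg.error_rate > 0:
                err = rng.random(L) < cfg.error_rate
                if err.any():
                    idx = np.flatnonzero(err)
                    shift = rng.integers(1, 4, size=idx.size)
                    codes = np.searchsorted(_DNA, read[idx])
                    read[idx] = _DNA[(codes + shift) % 4]
            if rng.random() < 0.5:
                seq = "".join(read)
            else:
                seq = revcomp("".join(read))
            fh.write(f"@read{i+1}\n{seq}\n+\n{qual}\n")
    truth = PlantedTruth()
    truth.copy_number[species] = total_copies
    return truth


def write_truth_tsv(truth: PlantedTruth, path: str | Path) -> None:
    """Sidecar TSV of the planted truth (kind, key, value)."""
    with open(path, "w") as fh:
        fh.write("kind\tkey\tvalue\n")
        for (locus, arm), lfc in sorted(truth.dem_arm_ids.items()):
            fh.write(f"dem\t{locus}|{arm}\t{lfc}\n")
        for locus in truth.switch_locus_ids:
            fh.write(f"switch\t{locus}\t.\n")
        for sp, c in sorted(truth.copy_number.items()):
            fh.write(f"copy_number\t{sp}\t{c}\n")
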