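"""Shared domain types for the killifish diapause miRNA analysis.

The objects here travel between every stage of the pipeline: the hairpin
(pre-miRNA) catalog with its annotated mature 5p/3p arms, per-sample
metadata (species, clade, annual life history, diapause status), the
arm-by-sample integer count matrix produced by quantification, and the
two-group comparison designs used for differential expression.

Coordinates are 1-based inclusive throughout, matching GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CLADES = ("south_america", "africa_west", "africa_east", "india")
STATUSES = ("diapause", "normal_development", "diapause_skipped")
ARMS = ("5p", "3p")


class ValidationError(ValueError):
    """Raised when an input object or file violates a documented invariant."""


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval on a hairpin sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"invalid interval [{self.start},{self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class HairpinEntry:
    """A single pre-miRNA locus with optional mature-arm annotations.

    ``conserved`` marks membership in a known (broadly conserved) miRNA
    family as opposed to a killifish-specific one.
    """

    locus_id: str
    family: str
    conserved: bool
    hairpin_seq: str
    arm5p: Interval | None = None
    arm3p: Interval | None = None

    def __post_init__(self) -> None:
        n = len(self.hairpin_seq)
        if n == 0:
            raise ValidationError(f"{self.locus_id}: empty hairpin sequence")
        for name, arm in (("5p", self.arm5p), ("3p", self.arm3p)):
            if arm is not None and arm.end > n:
                raise ValidationError(
                    f"{self.locus_id}: {name} arm [{arm.start},{arm.end}] exceeds "
                    f"hairpin length {n}"
                )
        if self.arm5p is not None and self.arm3p is not None:
            if self.arm5p.start >= self.arm3p.start:
                raise ValidationError(
                    f"{self.locus_id}: 5p arm must start before 3p arm"
                )
            if self.arm5p.overlaps(self.arm3p):
                raise ValidationError(f"{self.locus_id}: arms overlap")

    def arm_interval(self, arm: str) -> Interval | None:
        return self.arm5p if arm == "5p" else self.arm3p

    def arm_seq(self, arm: str) -> str | None:
        iv = self.arm_interval(arm)
        if iv is None:
            return None
        return self.hairpin_seq[iv.start - 1 : iv.end]

    @property
    def arms(self) -> tuple[str, ...]:
        out = []
        if self.arm5p is not None:
            out.append("5p")
        if self.arm3p is not None:
            out.append("3p")
        return tuple(out)


class HairpinCatalog:
    """Validated collection of hairpin loci, ordered as given."""

    def __init__(self, entries: Iterable[HairpinEntry]):
        self.entries: list[HairpinEntry] = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.locus_id in seen:
                raise ValidationError(f"duplicate locus_id {e.locus_id!r}")
            seen.add(e.locus_id)
        self._by_id = {e.locus_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, locus_id: str) -> HairpinEntry:
        return self._by_id[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def arm_ids(self) -> list[tuple[str, str]]:
        """All annotated (locus_id, arm) pairs in catalog order, 5p first."""
        out = []
        for e in self.entries:
            for arm in e.arms:
                out.append((e.locus_id, arm))
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, HairpinCatalog) and self.entries == other.entries


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    species: str
    clade: str
    annual: bool
    status: str
    replicate: int

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValidationError(
                f"{self.sample_id}: unknown clade {self.clade!r} (expected one of {CLADES})"
            )
        if self.status not in STATUSES:
            raise ValidationError(
                f"{self.sample_id}: unknown status {self.status!r} (expected one of {STATUSES})"
            )
        if self.status == "diapause" and not self.annual:
            raise ValidationError(
                f"{self.sample_id}: diapause status requires an annual species"
            )


def validate_metadata(samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id(s): {dup}")


class MatureArmCountMatrix:
    """Integer read counts per mature arm (rows) per sample (columns)."""

    def __init__(
        self,
        arm_ids: Sequence[tuple[str, str]],
        sample_ids: Sequence[str],
        counts: np.ndarray,
    ):
        self.arm_ids = [(str(l), str(a)) for l, a in arm_ids]
        self.sample_ids = list(sample_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(self.arm_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.arm_ids)} arms x {len(self.sample_ids)} samples"
            )
        if counts.size and (
            not np.issubdtype(counts.dtype, np.integer) or (counts < 0).any()
        ):
            raise ValidationError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64)
        for a in self.arm_ids:
            if a[1] not in ARMS:
                raise ValidationError(f"unknown arm label in {a}")
        if len(set(self.arm_ids)) != len(self.arm_ids):
            raise ValidationError("duplicate arm_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row_labels(self) -> list[str]:
        return [f"{l}|{a}" for l, a in self.arm_ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_labels(), columns=self.sample_ids
        )

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MatureArmCountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MatureArmCountMatrix(self.arm_ids, list(sample_ids), self.counts[:, idx])

    def validate_against(self, catalog: HairpinCatalog) -> None:
        """Every arm_id must name an annotated arm of the catalog."""
        annotated = set(catalog.arm_ids())
        for a in self.arm_ids:
            if a not in annotated:
                raise ValidationError(f"arm {a} not annotated in catalog")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MatureArmCountMatrix)
            and self.arm_ids == other.arm_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


COMPARISON_NAMES = ("large_interspecies", "intraspecies", "selected_interspecies")


@dataclass(frozen=True)
class ComparisonDesign:
    """Two-group contrast: group_a vs group_b (log2FC is a over b)."""

    name: str
    group_a: frozenset
    group_b: frozenset

    def __init__(self, name: str, group_a: Iterable[str], group_b: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "group_a", frozenset(group_a))
        object.__setattr__(self, "group_b", frozenset(group_b))
        if not self.group_a or not self.group_b:
            raise ValidationError(f"{name}: both groups must be non-empty")
        if self.group_a & self.group_b:
            raise ValidationError(f"{name}: groups overlap")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample hypothesis test."""

    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0,1]")


def standard_designs(samples: Sequence[SampleMeta]) -> dict[str, ComparisonDesign]:
    """Build the three study comparisons from sample metadata.

    I  (large_interspecies): annual-in-diapause vs all non-annual samples.
    II (intraspecies): N. furzeri diapause vs N. furzeri diapause-skipped.
    III (selected_interspecies): N. furzeri diapause vs its non-annual
        sister taxon A. striatum.
    """
    validate_metadata(samples)
    dia = {s.sample_id for s in samples if s.status == "diapause"}
    nonann = {s.sample_id for s in samples if not s.annual}
    designs: dict[str, ComparisonDesign] = {}
    if dia and nonann:
        designs["large_interspecies"] = ComparisonDesign(
            "large_interspecies", dia, nonann
        )
    nfu_dia = {
        s.sample_id
        for s in samples
        if s.species == "Nothobranchius_furzeri" and s.status == "diapause"
    }
    nfu_skip = {
        s.sample_id
        for s in samples
        if s.species == "Nothobranchius_furzeri" and s.status == "diapause_skipped"
    }
    if nfu_dia and nfu_skip:
        designs["intraspecies"] = ComparisonDesign("intraspecies", nfu_dia, nfu_skip)
    astr = {s.sample_id for s in samples if s.species == "Aphyosemion_striatum"}
    if nfu_dia and astr:
        designs["selected_interspecies"] = ComparisonDesign(
            "selected_interspecies", nfu_dia, astr
        )
    return designs
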