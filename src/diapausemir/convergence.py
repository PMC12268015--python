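"""Cross-comparison analyses: signed DEM-set overlap (convergent
regulation, diapause-vs-aging overlap), PCA sample ordination, and the
per-species tally of actively transcribed miRNAs.

A SignedSet is a pair of disjoint id sets (up- and downregulated). The
overlap of two signed sets splits their shared ids into concordant
(same direction in both) and discordant (opposite), with a
hypergeometric tail p-value for the total overlap against a stated
background universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    HairpinCatalog,
    MatureArmCountMatrix,
    SampleMeta,
    ValidationError,
)
from .diffexpr import ACTIVITY_THRESHOLD, DEResults
from .enrichment import EnrichmentQuery, hypergeom_tail


@dataclass(frozen=True)
class SignedSet:
    """Disjoint up/down id sets, e.g. the DEMs of one comparison."""

    label: str
    up: frozenset
    down: frozenset

    def __init__(self, label: str, up, down):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "up", frozenset(up))
        object.__setattr__(self, "down", frozenset(down))
        if self.up & self.down:
            raise ValidationError(
                f"{label}: ids in both up and down: {sorted(self.up & self.down)}"
            )

    @property
    def all(self) -> frozenset:
        return self.up | self.down

    @classmethod
    def from_de(cls, label: str, res: DEResults) -> "SignedSet":
        df = res.frame()
        sig = df[df.significant]
        return cls(
            label,
            set(sig[sig.log2FC > 0].arm_id),
            set(sig[sig.log2FC < 0].arm_id),
        )


@dataclass
class OverlapReport:
    concordant_up: frozenset
    concordant_down: frozenset
    discordant: frozenset
    background_size: int
    p_value: float

    @property
    def n_concordant(self) -> int:
        return len(self.concordant_up) + len(self.concordant_down)

    @property
    def n_discordant(self) -> int:
        return len(self.discordant)


def signed_overlap(a: SignedSet, b: SignedSet, background: int) -> OverlapReport:
    """Directional overlap of two signed sets.

    Concordant = same direction in both; discordant = opposite
    directions. The p-value is the hypergeometric upper tail for the
    total overlap |a ∩ b| given the background universe size.
    """
    union = a.all | b.all
    if background < len(union):
        raise ValidationError(
            f"background {background} smaller than union {len(union)}"
        )
    conc_up = a.up & b.up
    conc_dn = a.down & b.down
    disc = (a.up & b.down) | (a.down & b.up)
    inter = a.all & b.all
    q = EnrichmentQuery(
        N=background, R=len(a.all), n=len(b.all), r=len(inter)
    )
    return OverlapReport(
        concordant_up=frozenset(conc_up),
        concordant_down=frozenset(conc_dn),
        discordant=frozenset(disc),
        background_size=background,
        p_value=hypergeom_tail(q),
    )


def pca_ordination(
    counts: MatureArmCountMatrix,
    sf: np.ndarray,
    feature_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(normalized count + 1) features.

    Features (arms, by ``locus|arm`` label) are centered; scores come
    from the SVD of the sample-by-feature matrix. Each component's sign
    is fixed so that its loading on the first feature is non-negative
    (first nonzero loading decides). Returns (scores DataFrame indexed
    by sample with PC columns, variance-explained fractions).
    """
    labels = counts.row_labels()
    if feature_ids is None:
        rows = list(range(len(labels)))
    else:
        index = {l: i for i, l in enumerate(labels)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise ValidationError(f"unknown feature id(s): {missing[:5]}")
        rows = [index[f] for f in feature_ids]
    if len(rows) < 2 or len(counts.sample_ids) < 2:
        raise ValidationError("PCA needs at least two samples and two features")
    x = np.log2(counts.counts[rows].astype(float) / np.asarray(sf)[None, :] + 1.0).T
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValidationError("constant matrix: no variance to ordinate")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix sign per component by the first nonzero feature loading
    for k in range(vt.shape[0]):
        nz = np.flatnonzero(np.abs(vt[k]) > 1e-12)
        if nz.size and vt[k, nz[0]] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    var = s**2
    var_frac = var / var.sum() if var.sum() > 0 else var
    ncomp = scores.shape[1]
    df = pd.DataFrame(
        scores,
        index=counts.sample_ids,
        columns=[f"PC{k+1}" for k in range(ncomp)],
    )
    return df, var_frac


def per_species_active_summary(
    counts: MatureArmCountMatrix,
    meta: Sequence[SampleMeta],
    catalog: HairpinCatalog,
    sf: np.ndarray,
    reference_species: str | None = None,
    threshold: float = ACTIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-species counts of actively transcribed arms.

    An arm is active in a species when its mean normalized count over
    that species' samples exceeds the threshold. Split into conserved
    (known family) vs killifish-specific arms; when a reference species
    is given, also count arms active in the species but inactive in
    every sample of the reference.
    """
    by_species: dict[str, list[str]] = {}
    for s in meta:
        by_species.setdefault(s.species, []).append(s.sample_id)
    if reference_species is not None and reference_species not in by_species:
        raise ValidationError(f"unknown reference species {reference_species!r}")
    for sp, ids in by_species.items():
        for sid in ids:
            if sid not in counts.sample_ids:
                raise ValidationError(f"sample {sid!r} of {sp} absent from counts")
    conserved = np.array(
        [catalog[l].conserved if l in catalog else False for l, _ in counts.arm_ids]
    )
    sf = np.asarray(sf)
    norm = counts.counts / sf[None, :]
    active_by_species: dict[str, np.ndarray] = {}
    for sp, ids in by_species.items():
        idx = [counts.sample_ids.index(s) for s in ids]
        active_by_species[sp] = norm[:, idx].mean(axis=1) > threshold
    rows = []
    ref_active = (
        active_by_species[reference_species] if reference_species else None
    )
    for sp in sorted(by_species):
        act = active_by_species[sp]
        row = {
            "species": sp,
            "n_samples": len(by_species[sp]),
            "active_conserved": int((act & conserved).sum()),
            "active_specific": int((act & ~conserved).sum()),
            "active_total": int(act.sum()),
        }
        if ref_active is not None:
            row["active_not_in_reference"] = int((act & ~ref_active).sum())
        rows.append(row)
    return pd.DataFrame(rows)
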