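"""Negative-binomial two-group differential expression over mature arms.

The model follows the standard bulk count-data recipe: per-sample size
factors by the median-of-ratios method, per-arm NB dispersion estimated
by the method of moments and shrunk toward a fitted mean-dispersion
trend, a Wald test on the log2 fold change between the two groups, and
Benjamini-Hochberg control of the FDR across arms. Arms enter the test
only if they pass the activity filter (mean normalized count > 10 over
the compared samples).

The NB variance is parameterized as ``var = mu + alpha * mu**2``.

Usage::

    model = NBTwoGroupModel(counts, design)
    res = model.fit()
    res.frame()      # tidy per-arm table
    res.summary()    # text summary

``run_comparison`` wraps the full pipeline (size factors -> activity
filter -> test -> BH) for a design resolved against sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ComparisonDesign,
    MatureArmCountMatrix,
    SampleMeta,
    ValidationError,
    validate_metadata,
)

ALPHA_FLOOR = 1e-8
ACTIVITY_THRESHOLD = 10.0
SIG_LEVEL = 0.05


def size_factors(counts: MatureArmCountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference for each arm is its geometric mean across samples,
    computed over arms with no zero count; each sample's factor is the
    median ratio of its counts to the reference. If no arm is positive
    in every sample, falls back to a pseudo-reference over arms positive
    in at least half the samples, skipping zeros sample-wise.
    """
    k = counts.counts.astype(float)
    if k.size == 0:
        raise ValidationError("empty count matrix")
    all_pos = (k > 0).all(axis=1)
    if all_pos.any():
        kp = k[all_pos]
        ref = np.exp(np.log(kp).mean(axis=1))  # per-arm geometric mean
        sf = np.median(kp / ref[:, None], axis=0)
    else:
        mostly_pos = (k > 0).mean(axis=1) >= 0.5
        if not mostly_pos.any():
            raise ValidationError(
                "no arm is positive in every sample and none is positive in "
                ">=50% of samples; cannot compute size factors"
            )
        kp = k[mostly_pos]
        with np.errstate(divide="ignore"):
            logk = np.where(kp > 0, np.log(np.maximum(kp, 1e-300)), np.nan)
        logref = np.nanmean(logk, axis=1)
        ratios = logk - logref[:, None]
        sf = np.exp(np.nanmedian(ratios, axis=0))
        if np.isnan(sf).any():
            raise ValidationError("size factor undefined for an all-zero sample")
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def activity_filter(
    counts: MatureArmCountMatrix,
    sf: np.ndarray,
    sample_ids: Sequence[str],
    threshold: float = ACTIVITY_THRESHOLD,
) -> np.ndarray:
    """Arms actively transcribed: mean normalized count > threshold (strict).

    Mirrors the "more than ten normalized reads" rule used to call a
    mature miRNA actively transcribed.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValidationError("empty sample set for activity filter")
    idx = [counts.sample_ids.index(s) for s in sample_ids]
    norm = counts.counts[:, idx] / np.asarray(sf)[idx]
    return norm.mean(axis=1) > threshold


def _dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares on positive moment estimates.

    Returns the trend evaluated at every mu, clipped to be positive.
    """
    ok = (alpha_mom > 0) & (mu > 0)
    if ok.sum() >= 2:
        x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(x, alpha_mom[ok], rcond=None)
        a0, a1 = coef
    elif ok.any():
        a0, a1 = float(alpha_mom[ok].mean()), 0.0
    else:
        a0, a1 = 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-12)
    return np.clip(trend, ALPHA_FLOOR, None)


@dataclass
class DEResult:
    """Per-arm differential expression outcome."""

    arm_id: tuple[str, str]
    baseMean: float
    log2FC: float
    p_raw: float
    p_adj: float
    active: bool
    significant: bool


class NBTwoGroupModel:
    """NB Wald test of a two-group contrast on a mature-arm count matrix.

    Parameters
    ----------
    counts
        Arm-by-sample integer counts.
    design
        The two groups; log2FC is group_a over group_b.
    sf
        Optional precomputed size factors aligned to ``counts.sample_ids``;
        computed by median-of-ratios when omitted.
    """

    def __init__(
        self,
        counts: MatureArmCountMatrix,
        design: ComparisonDesign,
        sf: np.ndarray | None = None,
    ):
        missing = (design.group_a | design.group_b) - set(counts.sample_ids)
        if missing:
            raise ValidationError(f"design samples absent from counts: {sorted(missing)}")
        if len(design.group_a) < 2 or len(design.group_b) < 2:
            raise ValidationError("need at least two samples per group")
        self.counts = counts
        self.design = design
        self.sf = size_factors(counts) if sf is None else np.asarray(sf, dtype=float)
        if (self.sf <= 0).any() or self.sf.shape != (len(counts.sample_ids),):
            raise ValidationError("size factors must be positive, one per sample")
        # fixed sample order within groups for reproducibility
        self.idx_a = [counts.sample_ids.index(s) for s in sorted(design.group_a)]
        self.idx_b = [counts.sample_ids.index(s) for s in sorted(design.group_b)]

    def fit(self, active: np.ndarray | None = None) -> "DEResults":
        """Run the Wald test on every arm (or the ``active`` subset)."""
        k = self.counts.counts.astype(float)
        norm = k / self.sf[None, :]
        na, nb = len(self.idx_a), len(self.idx_b)
        ya = norm[:, self.idx_a]
        yb = norm[:, self.idx_b]
        ma = ya.mean(axis=1)
        mb = yb.mean(axis=1)
        mu = norm[:, self.idx_a + self.idx_b].mean(axis=1)

        # method-of-moments dispersion from pooled within-group variance
        # (unbiased, df = na+nb-2) of normalized counts
        ss = ((ya - ma[:, None]) ** 2).sum(axis=1) + ((yb - mb[:, None]) ** 2).sum(axis=1)
        s2 = ss / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_mom = (s2 - mu) / mu**2
        alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
        alpha_mom = np.maximum(alpha_mom, ALPHA_FLOOR)
        trend = _dispersion_trend(mu, alpha_mom)
        alpha = np.maximum(0.5 * alpha_mom + 0.5 * trend, ALPHA_FLOOR)

        lfc = np.log2(ma + 0.5) - np.log2(mb + 0.5)

        # Wald SE of log2FC via the NB observed information: the normalized
        # count k_ij/sf_j has variance mu/sf_j + alpha*mu^2, so the group
        # mean has variance sum_j(mu/sf_j + alpha*mu^2)/n^2
        inv_sf_a = np.sum(1.0 / self.sf[self.idx_a])
        inv_sf_b = np.sum(1.0 / self.sf[self.idx_b])
        var_ma = (ma * inv_sf_a + alpha * ma**2 * na) / na**2
        var_mb = (mb * inv_sf_b + alpha * mb**2 * nb) / nb**2
        ln2sq = np.log(2.0) ** 2
        se2 = (var_ma / (ma + 0.5) ** 2 + var_mb / (mb + 0.5) ** 2) / ln2sq
        se = np.sqrt(np.maximum(se2, 1e-300))
        z = lfc / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        # an arm at zero in both groups carries no evidence
        p = np.where((ma == 0) & (mb == 0), 1.0, p)
        p = np.clip(p, 0.0, 1.0)
        baseMean = norm.mean(axis=1)
        return DEResults(self, baseMean, lfc, se, p, alpha, active)


class DEResults:
    """Fitted results: per-arm estimates, Wald SEs and p-values.

    ``p_adj``/``significant`` are computed over the tested (active) arms;
    inactive arms carry ``p_adj = NaN`` and are never significant.
    """

    def __init__(self, model, baseMean, log2FC, se, p_raw, alpha, active):
        self.model = model
        self.baseMean = baseMean
        self.log2FC = log2FC
        self.se = se
        self.p_raw = p_raw
        self.alpha = alpha
        n = len(baseMean)
        self.active = np.ones(n, bool) if active is None else np.asarray(active, bool)
        self.p_adj = np.full(n, np.nan)
        if self.active.any():
            self.p_adj[self.active] = bh_adjust(self.p_raw[self.active])
        self.significant = self.active & (self.p_adj < SIG_LEVEL)

    def frame(self) -> pd.DataFrame:
        m = self.model.counts
        df = pd.DataFrame(
            {
                "arm_id": m.row_labels(),
                "baseMean": self.baseMean,
                "log2FC": self.log2FC,
                "lfcSE": self.se,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "active": self.active,
                "significant": self.significant,
            }
        )
        return df

    def results(self) -> list[DEResult]:
        return [
            DEResult(a, float(bm), float(l), float(pr), float(pa), bool(ac), bool(sg))
            for a, bm, l, pr, pa, ac, sg in zip(
                self.model.counts.arm_ids,
                self.baseMean,
                self.log2FC,
                self.p_raw,
                self.p_adj,
                self.active,
                self.significant,
            )
        ]

    def summary(self) -> str:
        d = self.model.design
        n_sig = int(self.significant.sum())
        n_up = int((self.significant & (self.log2FC > 0)).sum())
        n_dn = int((self.significant & (self.log2FC < 0)).sum())
        lines = [
            "NB two-group differential expression",
            f"  comparison : {d.name}",
            f"  group_a    : {len(d.group_a)} samples",
            f"  group_b    : {len(d.group_b)} samples",
            f"  arms tested: {int(self.active.sum())} / {len(self.active)} active",
            f"  DEMs (BH p_adj < {SIG_LEVEL:g}): {n_sig} ({n_up} up, {n_dn} down in group_a)",
        ]
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        df = self.frame().sort_values(
            ["p_adj", "p_raw"], na_position="last", kind="mergesort"
        )
        df.to_csv(path, sep="\t", index=False)


def run_comparison(
    counts: MatureArmCountMatrix,
    meta: Sequence[SampleMeta],
    design: ComparisonDesign,
    activity_threshold: float = ACTIVITY_THRESHOLD,
) -> DEResults:
    """Full DE pipeline for one comparison.

    Size factors are computed on the samples of the two groups; the
    activity filter uses the union of both groups; BH adjustment runs
    over the active arms only. No fold-change threshold is applied.
    """
    validate_metadata(meta)
    known = {s.sample_id for s in meta}
    missing = (design.group_a | design.group_b) - known
    if missing:
        raise ValidationError(f"design samples absent from metadata: {sorted(missing)}")
    used = sorted(design.group_a) + sorted(design.group_b)
    sub = counts.subset_samples(used)
    sf = size_factors(sub)
    active = activity_filter(sub, sf, used, threshold=activity_threshold)
    model = NBTwoGroupModel(sub, design, sf=sf)
    return model.fit(active=active)
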