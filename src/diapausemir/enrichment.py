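"""Hypergeometric enrichment of miRNA targets among differentially
expressed genes.

The global variant asks whether genes with predicted miRNA target sites
are over-represented among the differentially expressed genes (DEGs) of
a set; the per-miRNA variant restricts the universe to genes with any
predicted target site and asks the same question for the targets of one
miRNA. Both use the upper tail of the hypergeometric distribution,

    p = sum_{i=r}^{min(n,R)} C(R,i) C(N-R,n-i) / C(N,n)

with N the universe size, R the DEGs in the universe, n the genes with
(that miRNA's) target sites and r the DEGs among them. The sum is
evaluated in log-space (lgamma) with compensated summation so that
large N pose no overflow problem; an exact rational mode is provided
for small N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import ValidationError
from .diffexpr import SIG_LEVEL, bh_adjust


@dataclass(frozen=True)
class EnrichmentQuery:
    """Counts entering one hypergeometric test.

    N: universe size; R: differentially expressed genes in the universe;
    n: genes with predicted target sites; r: DE genes with target sites.
    """

    N: int
    R: int
    n: int
    r: int

    def __post_init__(self) -> None:
        if not (0 <= self.r <= min(self.n, self.R)):
            raise ValidationError(f"need 0 <= r <= min(n, R); got {self}")
        if not (self.n <= self.N and self.R <= self.N):
            raise ValidationError(f"need n <= N and R <= N; got {self}")
        if min(self.N, self.R, self.n) < 0:
            raise ValidationError(f"negative count in {self}")


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_tail(q: EnrichmentQuery, exact: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= r).

    ``exact=True`` evaluates the sum in exact rational arithmetic
    (practical for small N); otherwise terms are computed via lgamma
    and summed with :func:`math.fsum`.
    """
    hi = min(q.n, q.R)
    if q.r == 0:
        return 1.0
    if exact:
        denom = math.comb(q.N, q.n)
        num = sum(
            Fraction(math.comb(q.R, i) * math.comb(q.N - q.R, q.n - i))
            for i in range(q.r, hi + 1)
            if q.n - i <= q.N - q.R
        )
        return float(num / denom)
    log_denom = _log_comb(q.N, q.n)
    terms = []
    for i in range(q.r, hi + 1):
        if q.n - i > q.N - q.R:
            continue
        terms.append(
            math.exp(_log_comb(q.R, i) + _log_comb(q.N - q.R, q.n - i) - log_denom)
        )
    return min(1.0, math.fsum(terms))


def enrich_global(
    universe: Iterable[str],
    deg_set: Iterable[str],
    targeted_genes: Iterable[str],
) -> tuple[EnrichmentQuery, float]:
    """Global enrichment of targeted genes among DEGs over a gene universe."""
    uni = set(universe)
    degs = set(deg_set) & uni
    tg = set(targeted_genes) & uni
    q = EnrichmentQuery(N=len(uni), R=len(degs), n=len(tg), r=len(degs & tg))
    return q, hypergeom_tail(q)


def enrich_per_mirna(
    dem_ids: Iterable[str],
    target_map: Mapping[str, Iterable[str]],
    deg_set: Iterable[str],
    gene_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-DEM enrichment of its targets among the DEGs.

    Following the per-miRNA convention, the universe N is the set of
    genes with any predicted target site (unless an explicit universe is
    given) and n the genes with a site for the specific miRNA. DEMs with
    zero mapped targets are reported with p = 1 and flagged. BH
    adjustment runs across the tested miRNAs.
    """
    target_sets = {m: set(v) for m, v in target_map.items()}
    if gene_universe is None:
        uni: set[str] = set()
        for v in target_sets.values():
            uni |= v
    else:
        uni = set(gene_universe)
    degs = set(deg_set) & uni
    rows = []
    for dem in sorted(set(dem_ids)):
        targets = target_sets.get(dem, set()) & uni
        if not targets:
            rows.append(
                {
                    "mirna": dem, "N": len(uni), "R": len(degs), "n": 0, "r": 0,
                    "p_raw": 1.0, "no_targets": True,
                }
            )
            continue
        q = EnrichmentQuery(
            N=len(uni), R=len(degs), n=len(targets), r=len(degs & targets)
        )
        rows.append(
            {
                "mirna": dem, "N": q.N, "R": q.R, "n": q.n, "r": q.r,
                "p_raw": hypergeom_tail(q), "no_targets": False,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
        df["significant"] = df["p_adj"] < SIG_LEVEL
    return df
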