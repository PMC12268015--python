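"""Detection of 5p/3p arm switches between conditions.

An arm switch is a locus whose total hairpin-derived expression does not
change between the two groups while the two mature arms change in
opposite directions — the hallmark being the dominant arm trading places
with the minor one (as for miR-430-3p/-5p in diapause). Operationally a
locus is called a switch when:

* the locus-level (5p+3p) test is non-significant (BH p_adj >= 0.05),
* both arm-level tests are significant (BH p_adj < 0.05), and
* the two arm log2 fold changes have opposite signs.

A stricter "dominance flip" flag (the prevalent arm actually changes
between groups) is reported alongside but not required for the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ComparisonDesign,
    MatureArmCountMatrix,
    SampleMeta,
    ValidationError,
)
from .diffexpr import SIG_LEVEL, NBTwoGroupModel, activity_filter, size_factors


@dataclass
class SwitchCall:
    locus_id: str
    pre_log2FC: float
    pre_p_adj: float
    p5_log2FC: float
    p5_p_adj: float
    p3_log2FC: float
    p3_p_adj: float
    is_switch: bool
    dominance_flip: bool


def locus_level_counts(
    counts: MatureArmCountMatrix,
) -> tuple[MatureArmCountMatrix, list[str]]:
    """Sum 5p+3p counts per locus; loci with a single arm are excluded.

    Returns the locus-level matrix (rows keyed by locus, carried on the
    5p slot of the arm container) and the list of excluded single-arm
    loci. Column sums over the returned matrix equal the column sums of
    the included arms.
    """
    per_locus: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for i, (locus, arm) in enumerate(counts.arm_ids):
        if locus not in per_locus:
            per_locus[locus] = {}
            order.append(locus)
        per_locus[locus][arm] = i
    included = [l for l in order if len(per_locus[l]) == 2]
    excluded = [l for l in order if len(per_locus[l]) != 2]
    rows = np.zeros((len(included), len(counts.sample_ids)), dtype=np.int64)
    for r, locus in enumerate(included):
        i5 = per_locus[locus]["5p"]
        i3 = per_locus[locus]["3p"]
        rows[r] = counts.counts[i5] + counts.counts[i3]
    # reuse the arm container with a fixed placeholder arm label
    matrix = MatureArmCountMatrix([(l, "5p") for l in included], counts.sample_ids, rows)
    return matrix, excluded


def detect_switches(
    counts: MatureArmCountMatrix,
    meta: Sequence[SampleMeta],
    design: ComparisonDesign,
    sig_level: float = SIG_LEVEL,
) -> tuple[list[SwitchCall], list[str]]:
    """Run arm-level and locus-level DE and apply the switch criterion.

    Only loci with both arms active (mean normalized count > 10 over the
    compared samples) are tested; locus-level p-values are BH-adjusted
    over the tested loci. Output is sorted by min(arm p_adj). Returns
    (calls, excluded_loci).
    """
    used = sorted(design.group_a) + sorted(design.group_b)
    sub = counts.subset_samples(used)
    sf = size_factors(sub)
    active = activity_filter(sub, sf, used)

    arm_index = {a: i for i, a in enumerate(sub.arm_ids)}
    loci = []
    seen = set()
    for locus, _ in sub.arm_ids:
        if locus not in seen:
            seen.add(locus)
            loci.append(locus)
    both_armed = [
        l for l in loci if (l, "5p") in arm_index and (l, "3p") in arm_index
    ]
    excluded = [l for l in loci if l not in set(both_armed)]
    testable = [
        l
        for l in both_armed
        if active[arm_index[(l, "5p")]] and active[arm_index[(l, "3p")]]
    ]
    excluded += [l for l in both_armed if l not in set(testable)]
    if not testable:
        return [], excluded

    keep_rows = [arm_index[(l, a)] for l in testable for a in ("5p", "3p")]
    arm_sub = MatureArmCountMatrix(
        [sub.arm_ids[i] for i in keep_rows], used, sub.counts[keep_rows]
    )
    arm_res = NBTwoGroupModel(arm_sub, design, sf=sf).fit()

    locus_mat, _ = locus_level_counts(arm_sub)
    locus_res = NBTwoGroupModel(locus_mat, design, sf=sf).fit()
    locus_row = {l: i for i, (l, _) in enumerate(locus_mat.arm_ids)}
    arm_row = {a: i for i, a in enumerate(arm_sub.arm_ids)}

    calls: list[SwitchCall] = []
    for locus in testable:
        i5 = arm_row[(locus, "5p")]
        i3 = arm_row[(locus, "3p")]
        il = locus_row[locus]
        p5_lfc = float(arm_res.log2FC[i5])
        p3_lfc = float(arm_res.log2FC[i3])
        p5_adj = float(arm_res.p_adj[i5])
        p3_adj = float(arm_res.p_adj[i3])
        pre_adj = float(locus_res.p_adj[il])
        opposite = np.sign(p5_lfc) != np.sign(p3_lfc) and p5_lfc != 0 and p3_lfc != 0
        is_switch = bool(
            pre_adj >= sig_level
            and p5_adj < sig_level
            and p3_adj < sig_level
            and opposite
        )
        # dominance flip: the more abundant arm differs between groups
        norm = arm_sub.counts / sf[None, :]
        ia = [used.index(s) for s in sorted(design.group_a)]
        ib = [used.index(s) for s in sorted(design.group_b)]
        dom_a = norm[i5, ia].mean() > norm[i3, ia].mean()
        dom_b = norm[i5, ib].mean() > norm[i3, ib].mean()
        calls.append(
            SwitchCall(
                locus_id=locus,
                pre_log2FC=float(locus_res.log2FC[il]),
                pre_p_adj=pre_adj,
                p5_log2FC=p5_lfc,
                p5_p_adj=p5_adj,
                p3_log2FC=p3_lfc,
                p3_p_adj=p3_adj,
                is_switch=is_switch,
                dominance_flip=bool(dom_a != dom_b),
            )
        )
    calls.sort(key=lambda c: min(c.p5_p_adj, c.p3_p_adj))
    return calls, excluded


def switch_frame(calls: Sequence[SwitchCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
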