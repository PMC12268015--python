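"""Motif scanning, coverage-normalized copy estimation and the exact
Wilcoxon rank-sum test."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from diapausemir import (
    CopyNumberInputs,
    MotifSet,
    ValidationError,
    compare_groups,
    estimate_copies,
    scan_reads,
    wilcoxon_rank_sum,
)
from diapausemir.copynumber import (
    MIR430_MOTIFS,
    _revcomp,
    exact_u_pvalue,
)


def write_fastq(path, seqs):
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")


MOTIF1_DNA = MIR430_MOTIFS[0].replace("U", "T")


def embed(motif, total=100, seed=0):
    rng = np.random.default_rng(seed)
    flank = "".join(rng.choice(list("ACGT"), size=total - len(motif)))
    cut = (total - len(motif)) // 2
    return flank[:cut] + motif + flank[cut:]


class TestScanReads:
    def test_exact_motif_counts_once(self, tmp_path):
        fq = tmp_path / "a.fastq"
        write_fastq(fq, [embed(MOTIF1_DNA)])
        h, l = scan_reads(fq)
        assert (h, l) == (1, 100)

    def test_three_substitutions_not_counted(self, tmp_path):
        mut = list(MOTIF1_DNA)
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in (3, 9, 15):
            mut[i] = sub[mut[i]]
        fq = tmp_path / "b.fastq"
        write_fastq(fq, [embed("".join(mut))])
        h, _ = scan_reads(fq)
        assert h == 0

    def test_two_motifs_in_one_read_deduplicated(self, tmp_path):
        m2 = MIR430_MOTIFS[4].replace("U", "T")
        read = embed(MOTIF1_DNA + "ACGT" + m2, total=120, seed=1)
        fq = tmp_path / "c.fastq"
        write_fastq(fq, [read])
        h, _ = scan_reads(fq)
        assert h == 1

    def test_strand_symmetry(self, tmp_path):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(50)]
        seqs += [embed(MOTIF1_DNA, seed=i) for i in range(5)]
        seqs += [_revcomp(embed(MOTIF1_DNA, seed=10 + i)) for i in range(5)]
        a, b = tmp_path / "f.fastq", tmp_path / "r.fastq"
        write_fastq(a, seqs)
        write_fastq(b, [_revcomp(s) for s in seqs])
        assert scan_reads(a)[0] == scan_reads(b)[0] >= 10

    def test_matches_naive_dp_scanner(self, tmp_path):
        """Cross-check edlib infix matching against a hand-rolled DP."""

        def lev_infix_le(pattern, text, k):
            # semi-global DP: free gaps at both ends of the text
            prev = [0] * (len(text) + 1)
            for i, pc in enumerate(pattern, 1):
                cur = [i] + [0] * len(text)
                for j, tc in enumerate(text, 1):
                    cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                                 prev[j - 1] + (pc != tc))
                prev = cur
            return min(prev) <= k

        rng = np.random.default_rng(8)
        motifs = MotifSet(MIR430_MOTIFS[:2])
        patterns = motifs.dna()
        seqs = []
        for i in range(200):
            s = "".join(rng.choice(list("ACGT"), size=60))
            if i % 7 == 0:  # spike in near-matches with 0-3 errors
                m = list(MOTIF1_DNA)
                for p in rng.choice(len(m), size=rng.integers(0, 4), replace=False):
                    m[p] = "ACGT"[rng.integers(4)]
                s = s[:20] + "".join(m) + s[20:38]
            seqs.append(s)
        fq = tmp_path / "x.fastq"
        write_fastq(fq, seqs)
        h, _ = scan_reads(fq, motifs, max_edits=2)
        oracle = sum(
            any(lev_infix_le(p, s, 2) for p in patterns) for s in seqs
        )
        assert h == oracle

    def test_hamming_mode_is_stricter(self, tmp_path):
        # a deletion variant matches in edit mode but not hamming mode
        deleted = MOTIF1_DNA[:10] + MOTIF1_DNA[11:]
        fq = tmp_path / "d.fastq"
        write_fastq(fq, [embed(deleted)])
        assert scan_reads(fq, max_edits=2, mode="edit")[0] == 1
        assert scan_reads(fq, max_edits=0, mode="hamming")[0] == 0


class TestEstimate:
    def test_unit_coverage(self):
        est = estimate_copies(CopyNumberInputs("s", "G", True, h=100, l=1e9, g=1e9))
        assert est.copies == 100.0

    def test_half_coverage_scales(self):
        est = estimate_copies(CopyNumberInputs("s", "G", True, h=50, l=5e8, g=1e9))
        assert est.copies == 100.0
        assert math.isclose(est.poisson_se, math.sqrt(50) * 2, rel_tol=1e-12)

    def test_additive_over_batches(self):
        a = CopyNumberInputs("s", "G", True, h=30, l=2e8, g=1e9)
        b = CopyNumberInputs("s", "G", True, h=20, l=3e8, g=1e9)
        merged = CopyNumberInputs("s", "G", True, h=50, l=5e8, g=1e9)
        est = estimate_copies(merged)
        assert math.isclose(
            est.copies, (a.h + b.h) * 1e9 / (a.l + b.l), rel_tol=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            CopyNumberInputs("s", "G", True, h=1, l=0.0, g=1e9)
        with pytest.raises(ValidationError):
            CopyNumberInputs("s", "G", True, h=-1, l=1.0, g=1e9)


class TestWilcoxon:
    def test_single_observations_give_p_one(self):
        assert wilcoxon_rank_sum([1.0], [2.0]).p_value == 1.0

    def test_enumerated_2v3_w0(self):
        res = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0, 5.0])
        assert res.statistic == 0.0
        assert math.isclose(res.p_value, 0.2, rel_tol=1e-12)

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        for n, m in [(3, 4), (5, 5), (4, 8), (6, 6)]:
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            res = wilcoxon_rank_sum(x, y, mode="exact")
            # brute force: every assignment of ranks to group x
            combined = np.concatenate([x, y])
            ranks = combined.argsort().argsort() + 1
            obs_u = ranks[:n].sum() - n * (n + 1) / 2
            us = np.array(
                [
                    sum(ranks[list(pick)]) - n * (n + 1) / 2
                    for pick in itertools.combinations(range(n + m), n)
                ]
            )
            lo = np.mean(us <= obs_u)
            hi = np.mean(us >= obs_u)
            expected = min(1.0, 2 * min(lo, hi))
            assert abs(res.p_value - expected) < 1e-12

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(2, 9)))
            y = rng.normal(size=int(rng.integers(2, 9)))
            res = wilcoxon_rank_sum(x, y, mode="exact")
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.statistic == ref.statistic
            assert math.isclose(res.p_value, ref.pvalue, rel_tol=1e-12)

    def test_ties_fall_back_to_normal_approximation(self):
        res = wilcoxon_rank_sum([1, 2, 2, 3], [2, 3, 3, 4])
        assert res.method == "wilcoxon_normal"
        ref = mannwhitneyu([1, 2, 2, 3], [2, 3, 3, 4],
                           alternative="two-sided", method="asymptotic")
        assert math.isclose(res.p_value, ref.pvalue, rel_tol=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestCompareGroups:
    def _estimates(self, values, genus):
        return [
            estimate_copies(
                CopyNumberInputs(f"{genus}_{i}", genus, True, h=int(v), l=1e6, g=1e6)
            )
            for i, v in enumerate(values)
        ]

    def test_extreme_separation_hits_minimal_p(self):
        xs = self._estimates([1, 2, 3, 4], "Ann")
        ys = self._estimates([10, 20, 30, 40, 50], "Non")
        res = compare_groups(
            xs + ys, {"c": (("Ann",), ("Non",))}
        )["c"]
        assert res.statistic == 0.0
        assert math.isclose(res.p_value, 2 / math.comb(9, 4), rel_tol=1e-12)

    def test_missing_group_rejected(self):
        xs = self._estimates([1, 2], "Ann")
        with pytest.raises(ValidationError):
            compare_groups(xs, {"c": (("Ann",), ("Ghost",))})
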