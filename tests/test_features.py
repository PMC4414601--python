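"""PWM construction and scanning, conservation, matrix assembly, Eq-style
min-max normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from mirreg.annotations import RegulatoryRegion
from mirreg.features import (
    FEATURE_COLUMNS,
    FeatureMatrix,
    HomologyMap,
    PROB_FLOOR,
    build_feature_matrix,
    conservation_flag,
    extract_summit_window,
    motif_score,
    normalize_minmax,
    pwm_from_counts,
    read_jaspar_pfm,
    reverse_complement,
    write_jaspar_pfm,
)
from mirreg.intervals import GenomicInterval
from mirreg.peaks import CandidatePeak, Peak


def _cand(chrom, start, end, summit, mid="mir-a", pid="p1", dist=1000):
    peak = Peak(GenomicInterval(chrom, start, end), summit, 10, 5.0, 3.0, pid)
    return CandidatePeak(peak, mid, dist)


class TestPWM:
    def test_uniform_counts_give_zero_log_odds(self):
        pwm = pwm_from_counts(np.array([[10], [10], [10], [10]]), pseudocount=0.0)
        assert np.allclose(pwm.matrix, 0.0)

    def test_pure_column_hits_floor(self):
        pwm = pwm_from_counts(np.array([[40], [0], [0], [0]]), pseudocount=0.0)
        assert pwm.matrix[0, 0] == pytest.approx(2.0)  # log2(1/0.25)
        assert np.allclose(pwm.matrix[1:, 0], math.log2(PROB_FLOOR / 0.25))

    def test_random_counts_match_independent_formula(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 60, size=(4, 12))
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pc = 0.8
        pwm = pwm_from_counts(counts, background=bg, pseudocount=pc)
        for b in range(4):
            for j in range(12):
                p = (counts[b, j] + pc * bg[b]) / (counts[:, j].sum() + pc)
                expected = math.log2(max(p, PROB_FLOOR) / bg[b])
                assert pwm.matrix[b, j] == pytest.approx(expected)

    def test_zero_sum_column_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_counts(np.zeros((4, 3), dtype=int), pseudocount=0.0)

    def test_jaspar_round_trip(self, tmp_path):
        counts = np.array([[10, 0, 5], [2, 30, 5], [3, 5, 20], [25, 5, 10]])
        path = tmp_path / "m.jaspar"
        write_jaspar_pfm(counts, "MA9999.1", "TestTF", path)
        pwm = read_jaspar_pfm(path)
        direct = pwm_from_counts(counts, motif_id="MA9999.1")
        assert np.allclose(pwm.matrix, direct.matrix)


@pytest.fixture()
def genome(tmp_path):
    seq = "".join("ACGT"[i % 4] for i in range(1000))
    fa = tmp_path / "g.fa"
    fa.write_text(">chrT\n" + seq + "\n")
    return Fasta(str(fa)), seq


class TestSummitWindow:
    def test_center_clipped_at_zero(self, genome):
        fa, seq = genome
        w = extract_summit_window(fa, _cand("chrT", 50, 250, 100), width=200)
        # window exactly touches position 0 at full length: no truncation
        assert (w.start, w.end) == (0, 200) and len(w.seq) == 200
        assert not w.clipped

    def test_left_clip_shortens_window(self, genome):
        fa, seq = genome
        w = extract_summit_window(fa, _cand("chrT", 0, 100, 10), width=200)
        assert (w.start, w.end) == (0, 110) and w.clipped

    def test_matches_direct_slicing(self, genome):
        fa, seq = genome
        rng = np.random.default_rng(2)
        for _ in range(25):
            summit = int(rng.integers(0, 1000))
            w = extract_summit_window(fa, _cand("chrT", 0, 1000, summit), width=100)
            assert w.seq == seq[max(0, summit - 50):min(1000, summit + 50)]

    def test_unknown_chromosome(self, genome):
        fa, _ = genome
        with pytest.raises(KeyError):
            extract_summit_window(fa, _cand("chrX", 0, 100, 50), width=100)


def _brute_motif_score(seq, matrix, both):
    L = matrix.shape[1]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
    def scan(s):
        best = -np.inf
        for off in range(len(s) - L + 1):
            total = 0.0
            for j in range(L):
                b = idx[s[off + j]]
                total += matrix[b, j] if b >= 0 else 0.0
            best = max(best, total)
        return best
    best = scan(seq)
    if both:
        best = max(best, scan(reverse_complement(seq)))
    return best


class TestMotifScore:
    def test_zero_pwm_scores_zero(self):
        pwm = pwm_from_counts(np.array([[10], [10], [10], [10]]), pseudocount=0.0)
        assert motif_score("ACGTACGT", pwm) == 0.0

    def test_consensus_attains_columnwise_max(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(4, 6))
        pwm = pwm_from_counts(counts)
        assert motif_score(pwm.consensus(), pwm) == pytest.approx(
            float(np.max(pwm.matrix, axis=0).sum())
        )

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            L = int(rng.integers(1, 9))
            counts = rng.integers(0, 40, size=(4, L))
            pwm = pwm_from_counts(counts)
            n = int(rng.integers(L, 60))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
            assert motif_score(seq, pwm, True) == pytest.approx(
                _brute_motif_score(seq, pwm.matrix, True)
            )
            assert motif_score(seq, pwm, False) == pytest.approx(
                _brute_motif_score(seq, pwm.matrix, False)
            )

    def test_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 40, size=(4, 7))
        pwm = pwm_from_counts(counts)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        assert motif_score(seq, pwm, True) == pytest.approx(
            motif_score(reverse_complement(seq), pwm, True)
        )

    def test_sequence_shorter_than_motif_rejected(self):
        pwm = pwm_from_counts(np.ones((4, 5), dtype=int))
        with pytest.raises(ValueError, match="shorter"):
            motif_score("ACG", pwm)


class TestConservation:
    def _setup(self):
        cand = _cand("chr1", 100, 300, 200, mid="mmu-mir-x")
        region = RegulatoryRegion(
            "hsa-mir-x", GenomicInterval("hchr1", 0, 1_000_000), 1_000_000
        )
        homology = HomologyMap(
            pairs={("mmu-mir-x", "hsa-mir-x")},
            liftover={("chr1", 100, 300): GenomicInterval("hchr1", 500_100, 500_300)},
        )
        return cand, homology, [region]

    def test_homologous_region_hit(self):
        cand, homology, regions = self._setup()
        assert conservation_flag(cand, homology, regions) is True

    def test_non_homologous_region_rejected(self):
        cand, homology, regions = self._setup()
        homology.pairs = {("mmu-mir-other", "hsa-mir-x")}
        assert conservation_flag(cand, homology, regions) is False

    def test_unmapped_peak_not_conserved(self):
        cand, homology, regions = self._setup()
        homology.liftover = {}
        assert conservation_flag(cand, homology, regions) is False

    def test_monotone_in_homology_pairs(self):
        cand, homology, regions = self._setup()
        assert conservation_flag(cand, homology, regions)
        homology.pairs.add(("mmu-mir-y", "hsa-mir-z"))
        assert conservation_flag(cand, homology, regions)


class TestMatrix:
    def _cands(self, n=3):
        return [_cand("chr1", i * 1000, i * 1000 + 200, i * 1000 + 100,
                      mid=f"mir{i}", pid=f"p{i}", dist=100 * (i + 1))
                for i in range(n)]

    def test_assembly_places_values_by_column(self):
        cands = self._cands()
        fm = build_feature_matrix(cands, [True, False, True], [1.5, 2.5, 3.5],
                                  [False, False, True])
        assert list(fm.frame.columns) == ["mirna_id", "peak_id", *FEATURE_COLUMNS]
        assert fm.frame["motif_score"].tolist() == [1.5, 2.5, 3.5]
        assert fm.frame["dnase_flag"].tolist() == [1.0, 0.0, 1.0]
        assert fm.frame["distance_bp"].tolist() == [100.0, 200.0, 300.0]

    def test_empty_candidate_set_is_valid(self):
        fm = build_feature_matrix([], [], [], [])
        assert len(fm) == 0 and not fm.normalized

    def test_missing_motif_score_drops_row(self):
        cands = self._cands(2)
        fm = build_feature_matrix(cands, [1, 1], [None, 2.0], [0, 0])
        assert len(fm) == 1 and fm.frame["peak_id"].tolist() == ["p1"]

    def test_cardinality_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_feature_matrix(self._cands(2), [1], [1.0, 2.0], [0, 0])

    def test_shuffle_invariance(self):
        cands = self._cands(5)
        dn = [True, False, True, False, True]
        ms = [1.0, 2.0, 3.0, 4.0, 5.0]
        cf = [False, True, False, True, False]
        fm = build_feature_matrix(cands, dn, ms, cf)
        order = [3, 1, 4, 0, 2]
        fm2 = build_feature_matrix([cands[i] for i in order], [dn[i] for i in order],
                                   [ms[i] for i in order], [cf[i] for i in order])
        pd.testing.assert_frame_equal(fm.frame.sort_index(), fm2.frame.sort_index())


class TestNormalize:
    def _matrix(self, col_values):
        n = len(next(iter(col_values.values())))
        data = {c: col_values.get(c, list(np.linspace(0, 1, n))) for c in FEATURE_COLUMNS}
        frame = pd.DataFrame({"mirna_id": [f"m{i}" for i in range(n)],
                              "peak_id": [f"p{i}" for i in range(n)], **data},
                             index=[f"m{i}|p{i}" for i in range(n)])
        return FeatureMatrix(frame, normalized=False)

    def test_direct_arithmetic(self):
        fm = normalize_minmax(self._matrix({"tags": [0.0, 5.0, 10.0]}))
        assert fm.frame["tags"].tolist() == [0.0, 0.5, 1.0]
        assert fm.normalized

    def test_constant_column_becomes_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            fm = normalize_minmax(self._matrix({"tags": [7.0, 7.0, 7.0]}))
        assert fm.frame["tags"].tolist() == [0.0, 0.0, 0.0]

    def test_empty_matrix_rejected(self):
        empty = build_feature_matrix([], [], [], [])
        with pytest.raises(ValueError, match="empty"):
            normalize_minmax(empty)

    def test_columns_attain_zero_and_one(self):
        rng = np.random.default_rng(4)
        vals = {c: list(rng.uniform(-50, 50, 10)) for c in FEATURE_COLUMNS}
        fm = normalize_minmax(self._matrix(vals))
        arr = fm.values
        assert np.allclose(arr.min(axis=0), 0) and np.allclose(arr.max(axis=0), 1)

    def test_idempotent_on_normalized_values(self):
        rng = np.random.default_rng(6)
        vals = {c: list(rng.uniform(0, 10, 8)) for c in FEATURE_COLUMNS}
        once = normalize_minmax(self._matrix(vals))
        again = normalize_minmax(FeatureMatrix(once.frame.copy(), normalized=False))
        assert np.allclose(once.values, again.values)
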