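import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirasym.covariation import (
    FEATURE_KEYS,
    N_FEATURES,
    FeatureVector,
    build_feature_vector,
    covariation_scan,
    fisher_exact,
    scan_to_frame,
)
from mirasym.duplex_structure import pair_probabilities, pairing_status
from tests.conftest import fisher_exact_oracle


def _status(seq_a, seq_b):
    return pairing_status(pair_probabilities(seq_a, seq_b))


class TestBuildFeatureVector:
    def test_exactly_144_features(self):
        a, b = "U" + "GC" * 10 + "A", "U" + "GC" * 10  # 22 / 21 nt
        fv = build_feature_vector("d", a, b, _status(a, b))
        assert len(fv.values) == N_FEATURES

    def test_nt1_self_feature(self):
        a, b = "UAUCACAGCCAGCUUUGAUGAGC", "UCUCAAAGUGGUUGUGAAAUG"
        fv = build_feature_vector("d", a, b, _status(a, b))
        idx = FEATURE_KEYS.index(
            next(k for k in FEATURE_KEYS
                 if (k.strand, k.anchor, k.position, k.block) == ("miRNA", "5p", 1, "identity"))
        )
        assert fv.values[idx] == fv.nt1 == "U"

    def test_manual_transcription(self):
        # 21/21-nt duplex read off by hand against the written-out structure
        a = "GGGGGGGGGGCCCCCCCCCCA"
        b = "GGGGGGGGGGCCCCCCCCCCA"
        status = _status(a, b)
        fv = build_feature_vector("d", a, b, status)
        by_key = dict(zip(FEATURE_KEYS, fv.values))
        for k in FEATURE_KEYS:
            seq = a if k.strand == "miRNA" else b
            if k.position > len(seq):
                assert by_key[k] is None
                continue
            i = k.position - 1 if k.anchor == "5p" else len(seq) - k.position
            if k.block == "identity":
                assert by_key[k] == seq[i]
            else:
                paired = status.paired_a if k.strand == "miRNA" else status.paired_b
                assert by_key[k] == ("paired" if paired[i] else "unpaired")

    def test_short_strand_missing_values(self):
        a, b = "GCGCGCGCGC", "GCGCGCGCGC"  # 10 nt: positions 11-18 missing
        fv = build_feature_vector("d", a, b, _status(a, b))
        assert len(fv.values) == N_FEATURES
        missing = sum(v is None for v in fv.values)
        assert missing == 4 * 8 * 2  # 2 strands x 2 anchors x 8 positions x 2 blocks


class TestFisherExact:
    def test_perfect_independence(self):
        p, method = fisher_exact([[5, 5], [5, 5]])
        assert p == 1.0
        assert method == "exact_2xc"

    def test_2x2_vs_enumeration_oracle(self):
        table = [[8, 2], [1, 9]]
        p, _ = fisher_exact(table)
        assert p == pytest.approx(fisher_exact_oracle(table), rel=1e-9)

    def test_rxc_exact_vs_oracle(self):
        table = [[5, 2, 3], [1, 6, 2], [4, 1, 6]]
        p, method = fisher_exact(table, method="exact")
        assert method == "exact_network"
        assert p == pytest.approx(fisher_exact_oracle(table), rel=1e-9)

    def test_monte_carlo_agrees_with_exact(self):
        table = [[6, 2], [3, 5], [1, 7], [5, 1]]  # 4x2, n = 30
        pe, _ = fisher_exact(table, method="exact")
        n_mc = 100000
        pm, method = fisher_exact(table, method="monte_carlo", n_mc=n_mc, seed=0)
        assert method == "monte_carlo"
        se = np.sqrt(pe * (1 - pe) / n_mc)
        assert abs(pm - pe) <= 3 * se + 2 / n_mc

    def test_degenerate_table(self):
        p, method = fisher_exact([[3, 4]])
        assert p == 1.0 and method == "degenerate"
        p, _ = fisher_exact([[3], [4]])
        assert p == 1.0

    def test_negative_counts_fail(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    def test_mc_reproducible(self):
        table = [[6, 2, 1], [3, 5, 4], [1, 7, 2]]
        p1, _ = fisher_exact(table, method="monte_carlo", n_mc=2000, seed=7)
        p2, _ = fisher_exact(table, method="monte_carlo", n_mc=2000, seed=7)
        assert p1 == p2

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=6), min_size=2, max_size=3),
            min_size=2,
            max_size=3,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, rows):
        t = np.array(rows)
        if t.sum() == 0:
            return
        p, _ = fisher_exact(t)
        p_rows, _ = fisher_exact(t[::-1])
        p_cols, _ = fisher_exact(t[:, ::-1])
        assert p == pytest.approx(p_rows, rel=1e-9)
        assert p == pytest.approx(p_cols, rel=1e-9)

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=5), min_size=2, max_size=2),
            min_size=2,
            max_size=3,
        )
    )
    @settings(max_examples=20, deadline=None)
    def test_mc_matches_exact_within_error(self, rows):
        t = np.array(rows)
        if (t.sum(axis=1) > 0).sum() < 2 or (t.sum(axis=0) > 0).sum() < 2:
            return
        pe, me = fisher_exact(t, method="exact")
        if me == "degenerate":
            return
        n_mc = 20000
        pm, _ = fisher_exact(t, method="monte_carlo", n_mc=n_mc, seed=1)
        se = np.sqrt(pe * (1 - pe) / n_mc)
        assert abs(pm - pe) <= 4 * se + 2 / n_mc


def _random_fvs(n, rng, dep=None):
    """Independent null feature vectors; ``dep`` injects P(nt2=U|nt1=U)."""
    fvs = []
    for i in range(n):
        vals = []
        nt1 = "ACGU"[rng.integers(4)]
        for k in FEATURE_KEYS:
            if k.block == "identity":
                vals.append("ACGU"[rng.integers(4)])
            else:
                vals.append("paired" if rng.random() < 0.7 else "unpaired")
        idx1 = FEATURE_KEYS.index(
            next(k for k in FEATURE_KEYS
                 if (k.strand, k.anchor, k.position, k.block) == ("miRNA", "5p", 1, "identity"))
        )
        vals[idx1] = nt1
        if dep is not None:
            idx2 = FEATURE_KEYS.index(
                next(k for k in FEATURE_KEYS
                     if (k.strand, k.anchor, k.position, k.block) == ("miRNA", "5p", 2, "identity"))
            )
            p_u = dep[0] if nt1 == "U" else dep[1]
            vals[idx2] = "U" if rng.random() < p_u else "ACG"[rng.integers(3)]
        fvs.append(FeatureVector(f"d{i}", nt1, vals))
    return fvs


class TestCovariationScan:
    def test_injected_nt2_dependency_recovered(self):
        rng = np.random.default_rng(0)
        fvs = _random_fvs(150, rng, dep=(0.9, 0.25))
        results = covariation_scan(fvs, seed=0)
        non_self = [
            r for r in results
            if not (r.key.strand == "miRNA" and r.key.anchor == "5p"
                    and r.key.position == 1 and r.key.block == "identity")
        ]
        best = min(non_self, key=lambda r: r.p)
        assert (best.key.strand, best.key.anchor, best.key.position, best.key.block) == (
            "miRNA", "5p", 2, "identity",
        )

    def test_self_feature_is_extreme(self):
        rng = np.random.default_rng(1)
        fvs = _random_fvs(100, rng)
        results = covariation_scan(fvs, seed=1)
        self_res = next(
            r for r in results
            if (r.key.strand, r.key.anchor, r.key.position, r.key.block)
            == ("miRNA", "5p", 1, "identity")
        )
        assert self_res.p == min(r.p for r in results)

    def test_null_min_p_not_extreme(self):
        rng = np.random.default_rng(2)
        ok = 0
        n_runs = 10
        for run in range(n_runs):
            fvs = _random_fvs(80, rng)
            results = covariation_scan(fvs, n_mc=2000, seed=100 + run)
            non_self = [
                r.p for r in results
                if not (r.key.strand == "miRNA" and r.key.anchor == "5p"
                        and r.key.position == 1 and r.key.block == "identity")
            ]
            if min(non_self) > 0.001:
                ok += 1
        assert ok >= n_runs - 1

    def test_constant_nt1_fails(self):
        rng = np.random.default_rng(3)
        fvs = _random_fvs(20, rng)
        for fv in fvs:
            fv.nt1 = "U"
        with pytest.raises(ValueError, match="constant"):
            covariation_scan(fvs)

    def test_output_frame_shape(self):
        rng = np.random.default_rng(4)
        fvs = _random_fvs(40, rng)
        df = scan_to_frame(covariation_scan(fvs, n_mc=1000, seed=5))
        assert len(df) == N_FEATURES
        assert set(df.block) == {"identity", "pairing"}
        assert ((df.p > 0) & (df.p <= 1)).all()
        assert (df.p_bonferroni >= df.p).all()

    def test_margins_equal_nonmissing(self):
        rng = np.random.default_rng(6)
        fvs = _random_fvs(30, rng)
        results = covariation_scan(fvs, n_mc=1000, seed=6)
        for r in results:
            assert r.table.values.sum() == r.n_used
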