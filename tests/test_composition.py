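import numpy as np
import pytest
from scipy.stats import norm

from mirasym.annotation_io import PreMirnaRecord
from mirasym.composition import (
    MIRNA,
    STAR,
    analyze_composition,
    composition_pvalue,
    flanking_u_profile,
    resample_background,
    weighted_nt1_frequencies,
)
from mirasym.quantify import IsoformProfile, designate_strands


def _duplex(mirna_isoforms, star_isoforms, hid="h"):
    return designate_strands(
        [
            IsoformProfile(hid, "5p", mirna_isoforms),
            IsoformProfile(hid, "3p", star_isoforms),
        ]
    )


def _mk(seq_start_counts, arm="5p", hid="h"):
    return [(s, st, c) for s, st, c in seq_start_counts]


class TestWeightedNt1:
    def test_hand_arithmetic(self):
        # hairpin 1: all miRNA isoforms start U; hairpin 2: 75 U-start + 25 A-start
        d1 = _duplex([("U" * 20, 1, 40)], [("C" * 20, 40, 4)], "h1")
        d2 = _duplex(
            [("U" + "C" * 19, 1, 75), ("A" + "C" * 19, 2, 25)],
            [("C" * 20, 40, 10)],
            "h2",
        )
        freq = weighted_nt1_frequencies([d1, d2], MIRNA)
        assert freq[3] == pytest.approx((1 + 0.75) / 2)  # U
        assert freq[0] == pytest.approx(0.125)  # A

    def test_all_u_start(self):
        ds = [_duplex([("U" * 20, 1, 10)], [("U" * 20, 40, 1)], f"h{i}") for i in range(3)]
        assert weighted_nt1_frequencies(ds, MIRNA)[3] == 1.0
        assert weighted_nt1_frequencies(ds, STAR)[3] == 1.0

    def test_empty_stratum_fails(self):
        d = _duplex([("U" * 20, 1, 10)], [("C" * 20, 40, 1)])
        with pytest.raises(ValueError, match="stratum"):
            weighted_nt1_frequencies([d], MIRNA, stratum_filter=lambda d: False)

    def test_frequencies_sum_to_one(self, small_cohort):
        from mirasym.quantify import build_duplexes

        records, lib, _ = small_cohort
        dups, _ = build_duplexes(lib, records)
        for cls in (MIRNA, STAR):
            assert weighted_nt1_frequencies(dups, cls).sum() == pytest.approx(1.0)


class TestResampleBackground:
    def test_homopolymer_u(self):
        ds = [_duplex([("U" * 20, 1, 10)], [("U" * 20, 40, 5)], f"h{i}") for i in range(4)]
        m = resample_background(ds, MIRNA, n_sets=10, seed=0)
        assert m.shape == (10, 4)
        assert np.allclose(m[:, 3], 1.0)

    def test_rows_sum_to_one(self, small_cohort):
        from mirasym.quantify import build_duplexes

        records, lib, _ = small_cohort
        dups, _ = build_duplexes(lib, records)
        m = resample_background(dups, MIRNA, n_sets=50, seed=3)
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_set_size_equals_strand_count(self):
        # each set draws one nucleotide per hairpin-strand: with n hairpins the
        # achievable frequencies are multiples of 1/n
        n = 7
        ds = [_duplex([("UACG" * 5, 1, 3)], [("GCAU" * 5, 40, 1)], f"h{i}") for i in range(n)]
        m = resample_background(ds, MIRNA, n_sets=20, seed=1)
        assert np.allclose((m * n) - np.round(m * n), 0.0)

    def test_reproducible_given_seed(self, small_cohort):
        from mirasym.quantify import build_duplexes

        records, lib, _ = small_cohort
        dups, _ = build_duplexes(lib, records)
        a = resample_background(dups, MIRNA, n_sets=20, seed=11)
        b = resample_background(dups, MIRNA, n_sets=20, seed=11)
        c = resample_background(dups, MIRNA, n_sets=20, seed=12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestCompositionPvalue:
    def test_observed_equals_mean(self):
        res = np.tile([0.25, 0.25, 0.25, 0.25], (50, 1))
        res[::2] += [0.01, -0.01, 0, 0]
        res[1::2] -= [0.01, -0.01, 0, 0]
        obs = res.mean(axis=0)
        _, p_gauss = composition_pvalue(obs, res)
        assert p_gauss[0] == pytest.approx(0.5)

    def test_two_sd_closed_form(self):
        rng = np.random.default_rng(0)
        res = rng.normal(0.25, 0.02, size=(100000, 4))
        mean, sd = res.mean(axis=0), res.std(axis=0, ddof=1)
        obs = mean + 2 * sd
        _, p_gauss = composition_pvalue(obs, res)
        assert np.allclose(p_gauss, norm.sf(2.0), atol=1e-12)  # ~0.02275

    def test_empirical_never_zero(self):
        res = np.tile([0.25, 0.25, 0.25, 0.25], (100, 1))
        res += np.random.default_rng(1).normal(0, 1e-3, res.shape)
        p_emp, _ = composition_pvalue(np.array([0.9, 0.03, 0.03, 0.04]), res)
        assert np.all(p_emp >= 1 / 101)

    def test_zero_sd_with_deviation(self):
        res = np.tile([0.25, 0.25, 0.25, 0.25], (10, 1))
        _, p_gauss = composition_pvalue(np.array([0.5, 0.1, 0.2, 0.2]), res)
        assert p_gauss[0] == 0.0


class TestPower:
    def test_strong_u_bias_detected(self):
        from mirasym import SyntheticParams, generate_cohort
        from mirasym.quantify import build_duplexes

        hits = 0
        n_runs = 20
        for s in range(n_runs):
            params = SyntheticParams(
                n_hairpins=100, seed=1000 + s, mirna_nt1_probs=(0.0667, 0.0667, 0.0666, 0.8)
            )
            records, lib, _ = generate_cohort(params)
            dups, _ = build_duplexes(lib, records)
            res = analyze_composition(dups, MIRNA, seed=2000 + s)
            if res.p_gaussian[3] < 1e-3:
                hits += 1
        assert hits >= int(0.95 * n_runs)


class TestFlankingProfile:
    def _cohort(self, hairpin_core):
        """One-hairpin cohort with the miRNA starting at position 11."""
        hp = hairpin_core
        rec = PreMirnaRecord(
            id="h", hairpin_seq=hp, arm5p_start=11, arm5p_end=30,
            arm3p_start=35, arm3p_end=min(54, len(hp)),
        )
        d = _duplex([(hp[10:30], 11, 200)], [(hp[34:54], 35, 20)])
        return [rec], [d]

    def test_homopolymer_u(self):
        hp = "U" * 60
        records, dups = self._cohort(hp)
        prof = flanking_u_profile(records, dups, seed=0)
        assert np.allclose(prof.u_freq, 1.0)
        assert prof.background_mean == pytest.approx(1.0)
        assert prof.ci_low == prof.ci_high == pytest.approx(1.0)

    def test_constructed_enrichment(self):
        # U forced at offset 0, U-free flanks (oracle: construction)
        from mirasym.quantify import build_duplexes

        rng = np.random.default_rng(7)
        records, dups = [], []
        for i in range(30):
            body = list("".join(rng.choice(list("ACG"), 60)))
            # U at offset 0 (anchor pos 11), immediate flanks U-free, and U
            # at offsets +/-5 so the segment background is strictly positive
            body[10] = "U"
            body[5] = "U"
            body[15] = "U"
            hp = "".join(body)
            rec = PreMirnaRecord(
                id=f"h{i}", hairpin_seq=hp, arm5p_start=11, arm5p_end=30,
                arm3p_start=35, arm3p_end=54,
            )
            d = _duplex([(hp[10:30], 11, 150)], [(hp[34:54], 35, 15)], f"h{i}")
            records.append(rec)
            dups.append(d)
        prof = flanking_u_profile(records, dups, seed=3)
        mid = 10  # offset 0
        assert prof.u_freq[mid] == 1.0
        assert prof.u_freq[mid] > prof.ci_high
        assert prof.u_freq[mid - 1] < prof.ci_low
        assert prof.u_freq[mid + 1] < prof.ci_low

    def test_ci_brackets_mean(self, small_cohort):
        from mirasym.quantify import build_duplexes

        records, lib, _ = small_cohort
        dups, _ = build_duplexes(lib, records)
        prof = flanking_u_profile(records, dups, seed=5)
        assert prof.ci_low <= prof.background_mean <= prof.ci_high

    def test_negative_halfwidth_fails(self, small_cohort):
        records, lib, _ = small_cohort
        with pytest.raises(ValueError):
            flanking_u_profile(records, [], halfwidth=-1)


def test_null_calibration_small():
    """Null nt1 (same law as body): empirical rejection near nominal."""
    from mirasym import SyntheticParams, generate_cohort
    from mirasym.quantify import build_duplexes

    rej = 0
    n = 60
    for s in range(n):
        params = SyntheticParams(n_hairpins=40, seed=3000 + s)
        records, lib, _ = generate_cohort(params)
        dups, _ = build_duplexes(lib, records)
        res = analyze_composition(dups, MIRNA, seed=4000 + s)
        if res.p_empirical[3] <= 0.05:
            rej += 1
    assert 0.0 <= rej / n <= 0.15
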