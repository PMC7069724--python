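"""Alignment statistics, natural variants, BLOSUM, KS, two-proportion z + BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings
from hypothesis import strategies as st

from dmscompete import (
    blosum_score,
    column_entropy,
    extract_natural_variants,
    ks_two_sample,
    two_proportion_z_bh,
)
from dmscompete.evolution import (
    AMINO_ACIDS,
    alignment_column_stats,
    class_feature_comparison,
)

from conftest import make_selection_frame


def _aln(seqs: dict) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    )


class TestEntropy:
    def test_single_state_zero(self):
        assert column_entropy([1.0]) == 0.0

    def test_two_states_ln2(self):
        assert column_entropy([0.5, 0.5]) == pytest.approx(np.log(2))

    def test_uniform_twenty_ln20(self):
        assert column_entropy([0.05] * 20) == pytest.approx(np.log(20))

    def test_negative_frequency_errors(self):
        with pytest.raises(ValueError, match="negative"):
            column_entropy([0.5, -0.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20)
    )
    def test_bounds(self, freqs):
        h = column_entropy(freqs)
        assert 0.0 <= h <= np.log(20) + 1e-12


class TestAlignment:
    def test_identical_alignment_no_variants(self):
        aln = _aln({"ref": "MKVL", "s1": "MKVL", "s2": "MKVL"})
        assert extract_natural_variants(aln, "ref").empty

    def test_single_difference(self):
        aln = _aln({"ref": "MKVL", "s1": "MRVL"})
        nat = extract_natural_variants(aln, "ref")
        assert nat.to_dict("records") == [
            {"position": 2, "amino_acid": "R", "n_species": 1}
        ]

    def test_planted_differences_recovered(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        seqs = {"ref": ref}
        planted_positions = rng.choice(40, size=12, replace=False)
        planted = set()
        k = 0
        for name in [f"s{i}" for i in range(10)]:
            seq = list(ref)
            # 2-3 differences per sequence, 25 total, at the 12 chosen columns
            for _ in range(3 if k < 15 else 2):
                if len(planted) >= 999:
                    break
                pos = int(planted_positions[k % 12])
                alt = AMINO_ACIDS[(AMINO_ACIDS.index(ref[pos]) + 1 + k) % 20]
                if alt == ref[pos]:
                    alt = AMINO_ACIDS[(AMINO_ACIDS.index(alt) + 1) % 20]
                seq[pos] = alt
                planted.add((pos + 1, alt))
                k += 1
            seqs[name] = "".join(seq)
        nat = extract_natural_variants(_aln(seqs), "ref")
        found = set(map(tuple, nat[["position", "amino_acid"]].to_numpy()))
        assert found == planted
        assert nat["position"].nunique() <= 12

    def test_reference_gap_columns_skipped(self):
        aln = _aln({"ref": "M-KV", "s1": "MAKV"})
        nat = extract_natural_variants(aln, "ref")
        assert nat.empty  # the inserted A is not in reference coordinates
        stats = alignment_column_stats(aln, "ref")
        assert [s.position for s in stats] == [1, 2, 3]

    def test_gaps_excluded_from_frequencies(self):
        aln = _aln({"ref": "MK", "s1": "M-", "s2": "MR"})
        stats = alignment_column_stats(aln, "ref")
        assert stats[1].n_sequences == 2  # gap row not counted
        assert stats[1].frequencies == {"K": 0.5, "R": 0.5}

    def test_order_invariance(self):
        seqs = {"ref": "MKVL", "s1": "MRVL", "s2": "MKVI"}
        a = extract_natural_variants(_aln(seqs), "ref")
        rev = dict(reversed(list(seqs.items())))
        b = extract_natural_variants(_aln(rev), "ref")
        pd.testing.assert_frame_equal(a, b)

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="absent"):
            extract_natural_variants(_aln({"s1": "MK"}), "ref")


class TestBlosum:
    @pytest.mark.parametrize("a,b,score", [("A", "A", 4), ("W", "R", -3), ("E", "D", 2)])
    def test_known_entries(self, a, b, score):
        assert blosum_score(a, b) == score

    def test_symmetry_all_pairs(self):
        for a, b in itertools.combinations(AMINO_ACIDS, 2):
            assert blosum_score(a, b) == blosum_score(b, a)

    def test_nonstandard_letter_errors(self):
        with pytest.raises(ValueError, match="nonstandard"):
            blosum_score("A", "X")


class TestKS:
    def test_identical_samples(self):
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_disjoint_samples(self):
        d, _ = ks_two_sample([0, 0, 0], [1, 1, 1])
        assert d == 1.0

    def test_hand_enumerated_example(self):
        d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_exhaustive_small_instance_oracle(self):
        # brute-force sup|ECDF_A - ECDF_B| for all samples of size <= 3 over {0,1,2}
        def brute_d(a, b):
            grid = sorted(set(a) | set(b))
            return max(
                abs(
                    sum(x <= g for x in a) / len(a) - sum(x <= g for x in b) / len(b)
                )
                for g in grid
            )

        support = [0, 1, 2]
        for na, nb in itertools.product([1, 2, 3], repeat=2):
            for a in itertools.combinations_with_replacement(support, na):
                for b in itertools.combinations_with_replacement(support, nb):
                    d, _ = ks_two_sample(list(a), list(b))
                    assert d == pytest.approx(brute_d(a, b), abs=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestTwoProportion:
    def test_identical_proportions(self):
        out = two_proportion_z_bh([((50, 100), (50, 100))])
        assert out["z"][0] == 0.0 and out["p_raw"][0] == 1.0

    def test_contrasting_pair_significant_after_bh(self):
        out = two_proportion_z_bh([((50, 100), (50, 100)), ((90, 100), (10, 100))])
        assert out["p_adj"][0] == pytest.approx(1.0)
        assert out["p_adj"][1] < 0.05

    def test_z_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        out = two_proportion_z_bh([((30, 80), (45, 90))])
        z_sm, p_sm = proportions_ztest([30, 45], [80, 90])
        assert out["z"][0] == pytest.approx(z_sm)
        assert out["p_raw"][0] == pytest.approx(p_sm)

    def test_bh_step_up_recursion_by_hand(self):
        # hand step-up: adjusted_(i) = min_{j >= i} p_(j) * m / j, checked
        # against the adjustment our function applies to its own raw p-values
        pairs = [
            ((60, 100), (40, 100)),
            ((70, 100), (30, 100)),
            ((55, 100), (45, 100)),
            ((90, 100), (10, 100)),
        ]
        out = two_proportion_z_bh(pairs)
        p = out["p_raw"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        stepped = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.clip(stepped, 0, 1)
        assert np.allclose(out["p_adj"].to_numpy(), expected)

    def test_bh_preserves_order(self):
        rng = np.random.default_rng(0)
        pairs = [
            ((int(x), 100), (int(y), 100))
            for x, y in rng.integers(1, 99, size=(12, 2))
        ]
        out = two_proportion_z_bh(pairs)
        order_raw = np.argsort(out["p_raw"].to_numpy(), kind="stable")
        adj_sorted = out["p_adj"].to_numpy()[order_raw]
        assert (np.diff(adj_sorted) >= -1e-12).all()

    def test_degenerate_variance(self):
        out = two_proportion_z_bh([((0, 10), (0, 10))])
        assert out["p_raw"][0] == 1.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="positive"):
            two_proportion_z_bh([((0, 0), (1, 10))])


class TestClassFeature:
    def _classes(self, n_per_class=50, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for lab, mu in (("a", 0.0), ("b", shift)):
            for k in range(n_per_class):
                rows.append(
                    {
                        "position": len(rows) + 2,
                        "fitness_class": lab,
                        "is_stop": False,
                        "is_reference": False,
                    }
                )
        df = pd.DataFrame(rows)
        feats = pd.DataFrame(
            {
                "position": df["position"],
                "sasa": np.concatenate(
                    [
                        rng.normal(50, 10, n_per_class),
                        rng.normal(50 + shift, 10, n_per_class),
                    ]
                ),
            }
        )
        return df, feats

    def test_identical_feature_gives_zero_d(self):
        df, feats = self._classes()
        feats["sasa"] = 1.0
        out = class_feature_comparison(df, feats, "sasa")
        assert out["ks"]["a|b"]["D"] == 0.0

    def test_planted_shift_detected(self):
        df, feats = self._classes(n_per_class=200, shift=10.0, seed=1)
        out = class_feature_comparison(df, feats, "sasa")
        assert out["ks"]["a|b"]["p"] < 0.01

    def test_perfect_linear_r2(self):
        df = make_selection_frame(np.linspace(-1, 0, 20))
        df["fitness_class"] = "a"
        feats = pd.DataFrame(
            {"position": df["position"], "sasa": 3.0 * df["s_norm"] + 7.0}
        )
        out = class_feature_comparison(df, feats, "sasa")
        assert out["pearson"]["r2"] == pytest.approx(1.0)

    def test_interface_fraction(self):
        df, feats = self._classes(n_per_class=10)
        feats["interface"] = [1] * 10 + [0] * 10
        out = class_feature_comparison(df, feats, "sasa", interface_col="interface")
        assert out["interface_fraction"] == {"a": 1.0, "b": 0.0}

    def test_empty_join_errors(self):
        df, feats = self._classes(n_per_class=5)
        feats["position"] += 1000
        with pytest.raises(ValueError, match="empty class"):
            class_feature_comparison(df, feats, "sasa")
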