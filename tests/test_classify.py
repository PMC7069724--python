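"""Variant fitness classes, ts screen, position categories, condition overlaps."""

import numpy as np
import pandas as pd
import pytest

from dmscompete import (
    ClassThresholds,
    classify_table,
    classify_variants,
    condition_sets,
    identify_ts,
    summarize_positions,
)
from dmscompete.classify import BENEFICIAL, DELETERIOUS, INTERMEDIATE, WT_LIKE

from conftest import make_selection_frame

TH = ClassThresholds(wt_mean=0.0, wt_sd=0.02, stop_mean=-1.0, stop_sd=0.05)


class TestVariantClasses:
    @pytest.mark.parametrize(
        "s,expected",
        [
            (0.0, WT_LIKE),  # at the wild-type mean
            (0.02 * 2.5, BENEFICIAL),  # above two SD of wt synonyms
            (-1.0, DELETERIOUS),  # at the stop mean
            (-1.0 + 2 * 0.05, DELETERIOUS),  # boundary of the stop band
            (-0.5, INTERMEDIATE),  # between the bands
            (0.04, WT_LIKE),  # exactly two SD is still within
        ],
    )
    def test_band_assignment(self, s, expected):
        assert classify_variants(np.array([s]), TH)[0] == expected

    def test_partition_every_variant_one_label(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(-1.5, 0.5, size=500)
        labels = classify_variants(s, TH)
        assert set(labels) <= {WT_LIKE, BENEFICIAL, DELETERIOUS, INTERMEDIATE}
        assert len(labels) == len(s)

    def test_monotone_never_demotes_above_beneficial(self):
        # once a coefficient clears the beneficial cutoff, any higher value
        # stays beneficial; and above the stop band the rank never decreases
        order = {DELETERIOUS: 0, INTERMEDIATE: 1, WT_LIKE: 2, BENEFICIAL: 3}
        s = np.sort(np.linspace(-1.3, 0.3, 400))
        labels = classify_variants(s, TH)
        first_ben = next(i for i, lab in enumerate(labels) if lab == BENEFICIAL)
        assert all(lab == BENEFICIAL for lab in labels[first_ben:])
        above_stop = s > TH.stop_high
        ranks = [order[lab] for lab in labels[above_stop]]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))

    def test_overlapping_bands_warn_and_apply_precedence(self):
        th = ClassThresholds(wt_mean=0.0, wt_sd=0.3, stop_mean=-0.5, stop_sd=0.3)
        with pytest.warns(RuntimeWarning, match="overlap"):
            labels = classify_variants(np.array([-0.3]), th)
        # -0.3 is inside both bands; strongly deleterious wins
        assert labels[0] == DELETERIOUS

    def test_invalid_threshold_order(self):
        with pytest.raises(ValueError):
            ClassThresholds(wt_mean=-1.0, wt_sd=0.1, stop_mean=0.0, stop_sd=0.1)


class TestTsScreen:
    def _frames(self, pairs):
        std = make_selection_frame([p[0] for p in pairs])
        stress = make_selection_frame([p[1] for p in pairs])
        return std, stress

    @pytest.mark.parametrize(
        "s_std,s_37,is_ts",
        [
            (0.0, -1.0, True),  # archetype: wild-type-like then null
            (-0.12, -1.0, False),  # below the standard floor of -0.11
            (-0.11, -1.0, True),  # floor is inclusive
            (0.0, -0.46, False),  # above the stress ceiling of -0.47
            (0.0, -0.47, True),  # ceiling is inclusive
        ],
    )
    def test_printed_cutoffs(self, s_std, s_37, is_ts):
        std, stress = self._frames([(s_std, s_37)])
        ts, tally = identify_ts(std, stress)
        assert (len(ts) == 1) == is_ts
        assert tally["evaluated"] == 1

    def test_stops_excluded(self):
        std = make_selection_frame([0.0], is_stop=[True])
        stress = make_selection_frame([-1.0], is_stop=[True])
        ts, tally = identify_ts(std, stress)
        assert len(ts) == 0 and tally["evaluated"] == 0

    def test_missing_variants_tallied(self):
        std = make_selection_frame([0.0, 0.0], positions=[2, 3])
        stress = make_selection_frame([-1.0], positions=[2])
        ts, tally = identify_ts(std, stress)
        assert tally["standard_only"] == 1
        assert len(ts) == 1

    def test_degenerate_bounds_return_all(self):
        std, stress = self._frames([(-5.0, 5.0), (2.0, -3.0), (0.0, 0.0)])
        th = ClassThresholds(
            wt_mean=0.0,
            wt_sd=0.02,
            stop_mean=-1.0,
            stop_sd=0.05,
            ts_standard_floor=-np.inf,
            ts_stress_ceiling=np.inf,
        )
        ts, _ = identify_ts(std, stress, thresholds=th)
        assert len(ts) == 3

    def test_planted_ts_recovered_through_inference(self, small_cfg, small_truth):
        # plant: same library, truth switched to null at "stress" for a known set
        import copy

        from dmscompete import SelectionModel, simulate_competition_counts

        stress_truth = copy.deepcopy(small_truth)
        planted = set()
        for tv in stress_truth:
            if tv.is_reference or tv.is_stop or tv.is_wt_synonym:
                continue
            if abs(tv.true_s) < 0.04 and len(planted) < 15:
                planted.add((tv.position, tv.codon))
                tv.true_s, tv.true_rate = -1.0, 0.0
        assert len(planted) >= 10
        stress_table = simulate_competition_counts(
            stress_truth, small_cfg, np.random.default_rng(21)
        )
        res = SelectionModel(stress_table).fit(samples=2000, seed=4)
        stress_sel = res.normalize()
        std_sel = pd.DataFrame(
            {
                "position": [tv.position for tv in small_truth],
                "codon": [tv.codon for tv in small_truth],
                "aa": [tv.aa for tv in small_truth],
                "s_norm": [tv.true_s for tv in small_truth],
                "is_stop": [tv.is_stop for tv in small_truth],
                "is_wt_synonym": [tv.is_wt_synonym for tv in small_truth],
                "is_reference": [tv.is_reference for tv in small_truth],
            }
        )
        ts, _ = identify_ts(std_sel, stress_sel, keys=("position", "codon"))
        found = set(map(tuple, ts[["position", "codon"]].to_numpy()))
        recall = len(found & planted) / len(planted)
        assert recall >= 0.95


class TestPositionSummary:
    def _tables(self, position_means):
        # position_means: {pos: {cond: mean}} realized as 3 mutations per position
        conds = sorted({c for v in position_means.values() for c in v})
        tables = {}
        for cond in conds:
            rows = []
            for pos, means in position_means.items():
                for k in range(3):
                    rows.append(
                        {
                            "position": pos,
                            "aa": "AVL"[k],
                            "s_norm": means[cond],
                            "is_stop": False,
                            "is_wt_synonym": False,
                            "is_reference": False,
                        }
                    )
            tables[cond] = pd.DataFrame(rows)
        thresholds = {
            c: ClassThresholds(wt_mean=0.0, wt_sd=0.02, stop_mean=-1.0, stop_sd=0.05)
            for c in conds
        }
        return tables, thresholds

    def test_categories(self):
        conds = ["standard", "c1", "c2", "c3", "c4", "c5"]
        spec = {
            10: {c: -1.0 for c in conds},  # null everywhere -> critical
            11: {c: (-0.5 if c in ("c1", "c2", "c3") else 0.0) for c in conds},  # ER
            12: {c: 0.0 for c in conds},  # tolerant
            13: {c: (-0.5 if c == "c1" else 0.0) for c in conds},  # shifted once
        }
        tables, thresholds = self._tables(spec)
        out = summarize_positions(tables, thresholds).set_index("position")
        assert out.loc[10, "category"] == "critical"
        assert out.loc[11, "category"] == "environmentally_responsive"
        assert out.loc[12, "category"] == "tolerant"
        assert out.loc[13, "category"] == "other"

    def test_position_mean_excludes_stops(self):
        tables, thresholds = self._tables({10: {"standard": 0.0, "c1": 0.0}})
        stop_row = pd.DataFrame(
            [
                {
                    "position": 10,
                    "aa": "*",
                    "s_norm": -1.0,
                    "is_stop": True,
                    "is_wt_synonym": False,
                    "is_reference": False,
                }
            ]
        )
        tables = {c: pd.concat([t, stop_row]) for c, t in tables.items()}
        out = summarize_positions(tables, thresholds)
        assert out["mean_standard"].iloc[0] == pytest.approx(0.0)

    def test_requires_standard(self):
        tables, thresholds = self._tables({10: {"c1": 0.0, "c2": 0.0}})
        with pytest.raises(ValueError, match="standard"):
            summarize_positions(tables, thresholds)


class TestConditionSets:
    def _classified(self, spec):
        out = {}
        for cond, dele_positions in spec.items():
            rows = []
            for pos in range(2, 12):
                rows.append(
                    {
                        "position": pos,
                        "aa": "A",
                        "s_norm": -0.5 if pos in dele_positions else 0.0,
                        "fitness_class": DELETERIOUS
                        if pos in dele_positions
                        else WT_LIKE,
                        "is_stop": False,
                        "is_wt_synonym": False,
                        "is_reference": False,
                    }
                )
            out[cond] = pd.DataFrame(rows)
        return out

    def test_identical_conditions_no_exclusive(self):
        spec = {"standard": {2, 3}, "c1": {2, 3}}
        res = condition_sets(self._classified(spec))
        assert res["exclusive_counts"] == {"standard": 0, "c1": 0}
        assert res["intersections"]["standard&c1"] == 2

    def test_disjoint_conditions(self):
        spec = {"standard": {2, 3}, "c1": {4, 5, 6}}
        res = condition_sets(self._classified(spec))
        assert res["intersections"]["standard&c1"] == 0
        assert res["exclusive_counts"] == {"standard": 2, "c1": 3}

    def test_planted_three_way_overlap(self):
        spec = {"standard": {2, 3, 4}, "c1": {3, 4, 5}, "c2": {4, 5, 6}}
        res = condition_sets(self._classified(spec))
        assert res["deleterious_counts"] == {"standard": 3, "c1": 3, "c2": 3}
        assert res["intersections"]["standard&c1"] == 2
        assert res["intersections"]["standard&c1&c2"] == 1
        assert res["exclusive_counts"]["standard"] == 1

    def test_mean_shift_vs_standard(self):
        spec = {"standard": {2, 3}, "c1": {2, 3, 4, 5}}
        res = condition_sets(self._classified(spec))
        assert res["mean_shift_vs_standard"]["standard"] == pytest.approx(0.0)
        assert res["mean_shift_vs_standard"]["c1"] == pytest.approx(-0.1)


def test_classify_table_adds_single_column(small_fit):
    sel = small_fit.selection_table()
    th = ClassThresholds.from_anchors(
        small_fit.anchors, small_fit.params["s_norm"].to_numpy()
    )
    out = classify_table(sel, th)
    assert "fitness_class" in out.columns
    assert len(out) == len(sel)
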