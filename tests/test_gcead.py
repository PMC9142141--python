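"""Kovats indices, peak alignment, the EAD-active criterion and quantitation."""

import numpy as np
import pandas as pd
import pytest

from glomcode import gcead, synthetic
from glomcode.gcead import AlkaneLadder


@pytest.fixture
def ladder():
    # irregular spacing on purpose
    return AlkaneLadder(
        carbons=(8, 9, 10, 11, 12, 14),
        retention_times=(4.0, 5.5, 7.5, 8.5, 10.0, 13.0),
    )


class TestKovats:
    def test_alkane_knots_give_exact_hundreds(self, ladder):
        for n, rt in zip(ladder.carbons, ladder.retention_times):
            assert gcead.kovats_ri(rt, ladder) == pytest.approx(100 * n)

    def test_midpoint_between_c10_and_c11(self, ladder):
        assert gcead.kovats_ri(8.0, ladder) == pytest.approx(1050.0)

    def test_irregular_ladder_matches_direct_formula(self, ladder):
        """Oracle: direct evaluation of the bracketing-alkane formula."""
        rng = np.random.default_rng(2)
        carbons = np.array(ladder.carbons, dtype=float)
        rts = np.array(ladder.retention_times)
        for rt in rng.uniform(4.0, 13.0, 40):
            i = int(np.searchsorted(rts, rt, side="right") - 1)
            i = min(max(i, 0), len(rts) - 2)
            expected = 100 * (
                carbons[i]
                + (carbons[i + 1] - carbons[i]) * (rt - rts[i]) / (rts[i + 1] - rts[i])
            )
            assert gcead.kovats_ri(rt, ladder) == pytest.approx(expected)

    def test_strictly_increasing_in_rt(self, ladder):
        rts = np.linspace(4.0, 13.0, 50)
        ris = gcead.kovats_ri(rts, ladder)
        assert np.all(np.diff(ris) > 0)

    def test_extrapolation_warns(self, ladder):
        with pytest.warns(UserWarning, match="extrapolat"):
            gcead.kovats_ri(3.0, ladder)

    def test_non_monotone_ladder_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            AlkaneLadder(carbons=(9, 10), retention_times=(5.0, 4.0))


class TestBlankClassification:
    def _counts(self, values):
        return pd.DataFrame(
            {"sample": ["s"] * len(values), "n_peaks": values}
        )

    @pytest.mark.parametrize(
        "sample_mean,expected",
        [(5.0, "within"), (9.0, "outside"), (8.0, "within"), (2.0, "within")],
    )
    def test_closed_interval_decision(self, sample_mean, expected):
        out = gcead.count_peaks_vs_blank(self._counts([sample_mean]), [2, 8])
        assert out["classification"].iloc[0] == expected


def clustering_oracle(ris, tolerance):
    """Brute-force all-pairs connected components within tolerance."""
    n = len(ris)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(ris[i] - ris[j]) <= tolerance:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


class TestMatchAcrossAntennae:
    def _peaks(self, ris, antennae=None, headspace="hsA"):
        n = len(ris)
        return pd.DataFrame(
            {
                "antenna_id": antennae or [f"ant{i}" for i in range(n)],
                "headspace": [headspace] * n,
                "ri": ris,
                "amplitude": np.ones(n),
            }
        )

    def test_one_compound_zero_jitter_full_support(self):
        out = gcead.match_across_antennae(self._peaks([1100.0] * 5))
        assert out["group_id"].nunique() == 1
        assert (out["support"] == 5).all()

    def test_two_distant_compounds_two_groups(self):
        out = gcead.match_across_antennae(
            self._peaks([1000.0, 1000.1, 1300.0, 1300.2],
                        antennae=["a", "b", "a", "b"])
        )
        assert out["group_id"].nunique() == 2

    def test_jittered_grouping_matches_brute_force_oracle(self, rng):
        true_ris = [1000.0, 1012.0, 1030.0, 1047.0, 1100.0]
        ris, owners = [], []
        for k, ri in enumerate(true_ris):
            for a in range(4):
                ris.append(ri + rng.normal(0, 1.0))
                owners.append(k)
        peaks = self._peaks(ris, antennae=[f"ant{i % 4}" for i in range(len(ris))])
        out = gcead.match_across_antennae(peaks, tolerance=5.0)
        oracle = clustering_oracle(out["ri"].to_numpy(), 5.0)
        # same partition: group labels must be a bijection of oracle roots
        pairs = set(zip(out["group_id"], oracle))
        assert len(pairs) == out["group_id"].nunique() == len(set(oracle))

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            gcead.match_across_antennae(self._peaks([1000.0]), tolerance=0.0)


class TestEadActiveCriterion:
    def _groups(self, support, ri=1100.0, headspace="hsA"):
        peaks = pd.DataFrame(
            {
                "antenna_id": [f"ant{i}" for i in range(support)],
                "headspace": [headspace] * support,
                "ri": [ri] * support,
                "amplitude": np.ones(support),
            }
        )
        return gcead.match_across_antennae(peaks)

    def _fid(self, ri=1100.0, replicates=(0, 1), headspace="hsA"):
        return pd.DataFrame(
            {
                "headspace": [headspace] * len(replicates),
                "replicate": list(replicates),
                "ri": [ri] * len(replicates),
                "area": [1e5] * len(replicates),
            }
        )

    def test_support_two_is_inactive(self):
        out = gcead.call_ead_active(self._groups(2), self._fid())
        assert out["status"].iloc[0] == "inactive"

    def test_support_three_with_replicate_presence_is_active(self):
        out = gcead.call_ead_active(self._groups(3), self._fid())
        assert out["status"].iloc[0] == "active"

    def test_no_replicate_information_is_indeterminate(self):
        out = gcead.call_ead_active(self._groups(5), None)
        assert out["status"].iloc[0] == "indeterminate"

    def test_single_replicate_presence_not_enough(self):
        out = gcead.call_ead_active(self._groups(4), self._fid(replicates=(0,)))
        assert out["status"].iloc[0] == "inactive"

    def test_never_active_below_min_support_property(self, rng):
        """Random datasets: active groups always have support >= 3."""
        for seed in range(10):
            truth = synthetic.EadGroundTruth(
                compounds=tuple(
                    (float(rt), float(a), f"hs{h}")
                    for h, (rt, a) in enumerate(
                        zip(
                            np.random.default_rng(seed).uniform(5, 20, 6),
                            np.random.default_rng(seed + 1).uniform(0.1, 2, 6),
                        )
                    )
                ),
                detect_prob=0.5,
                n_antennae=5,
                seed=seed,
            )
            ds = synthetic.generate_gcead_dataset(truth)
            if ds.ead_peaks.empty:
                continue
            ladder = AlkaneLadder(
                carbons=tuple(range(5, 26)),
                retention_times=tuple(np.linspace(2.0, 30.0, 21)),
            )
            peaks = ds.ead_peaks.assign(
                ri=gcead.kovats_ri(ds.ead_peaks["rt"].to_numpy(), ladder)
            )
            fid = ds.fid_peaks.assign(
                ri=gcead.kovats_ri(ds.fid_peaks["rt"].to_numpy(), ladder)
            )
            groups = gcead.match_across_antennae(peaks)
            out = gcead.call_ead_active(groups, fid)
            active = out[out["status"] == "active"]
            assert (active["support"] >= 3).all()

    def test_planted_actives_recovered_exactly(self):
        """Generator truth: full detection makes every compound active."""
        truth = synthetic.EadGroundTruth(
            compounds=(
                (6.0, 1.0, "hsA"),
                (9.0, 0.5, "hsA"),
                (12.0, 2.0, "hsB"),
            ),
            detect_prob=1.0,
            rt_jitter_sd=0.0,
            replicate_presence_prob=1.0,
            n_antennae=4,
            seed=1,
        )
        ds = synthetic.generate_gcead_dataset(truth)
        ladder = AlkaneLadder(
            carbons=tuple(range(5, 26)),
            retention_times=tuple(np.linspace(2.0, 30.0, 21)),
        )
        peaks = ds.ead_peaks.assign(
            ri=gcead.kovats_ri(ds.ead_peaks["rt"].to_numpy(), ladder)
        )
        fid = ds.fid_peaks.assign(
            ri=gcead.kovats_ri(ds.fid_peaks["rt"].to_numpy(), ladder)
        )
        groups = gcead.match_across_antennae(peaks)
        out = gcead.call_ead_active(groups, fid)
        assert (out["status"] == "active").all()
        assert len(out) == 3


class TestAmplitudeMatrixAndAmounts:
    def test_median_of_single_antenna_is_its_amplitude(self):
        peaks = pd.DataFrame(
            {
                "antenna_id": ["a"],
                "headspace": ["hsA"],
                "ri": [1000.0],
                "amplitude": [1.7],
            }
        )
        groups = gcead.match_across_antennae(peaks)
        mat = gcead.median_amplitude_matrix(groups)
        assert mat.iloc[0, 0] == 1.7

    def test_median_of_three(self):
        peaks = pd.DataFrame(
            {
                "antenna_id": ["a", "b", "c"],
                "headspace": ["hsA"] * 3,
                "ri": [1000.0, 1000.5, 999.5],
                "amplitude": [1.0, 2.0, 10.0],
            }
        )
        groups = gcead.match_across_antennae(peaks)
        mat = gcead.median_amplitude_matrix(groups)
        assert mat.iloc[0, 0] == 2.0

    def test_invariant_to_antenna_ordering(self, rng):
        peaks = pd.DataFrame(
            {
                "antenna_id": ["a", "b", "c", "a", "b"],
                "headspace": ["hsA"] * 3 + ["hsB"] * 2,
                "ri": [1000.0, 1001.0, 999.0, 1200.0, 1201.0],
                "amplitude": [1.0, 3.0, 2.0, 0.5, 0.7],
            }
        )
        shuffled = peaks.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = gcead.median_amplitude_matrix(gcead.match_across_antennae(peaks))
        b = gcead.median_amplitude_matrix(gcead.match_across_antennae(shuffled))
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize(
        "area,istd,expected", [(1e5, 1e5, 5.0), (2e5, 1e5, 10.0), (0.0, 1e5, 0.0)]
    )
    def test_internal_standard_amounts(self, area, istd, expected):
        assert gcead.estimate_amount(area, istd) == pytest.approx(expected)

    def test_zero_istd_area_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gcead.estimate_amount(1.0, 0.0)


class TestFeatureTable:
    def _peaks(self, sample_ris):
        rows = []
        for sample, ris in sample_ris.items():
            for ri in ris:
                rows.append({"sample_id": sample, "ri": ri, "area": 10.0})
        return pd.DataFrame(rows)

    def test_identical_samples_identical_rows(self):
        table = gcead.build_feature_table(
            self._peaks({"s1": [1000.0, 1200.0], "s2": [1000.0, 1200.0]})
        )
        assert np.allclose(table.loc["s1"], table.loc["s2"])

    def test_disjoint_peak_sets_block_diagonal(self):
        table = gcead.build_feature_table(
            self._peaks({"s1": [1000.0], "s2": [1500.0]})
        )
        assert table.shape == (2, 2)
        assert table.loc["s1"].to_numpy().tolist() == [10.0, 0.0]
        assert table.loc["s2"].to_numpy().tolist() == [0.0, 10.0]

    def test_matches_oracle_construction(self, rng):
        """Naive oracle: union-find features, per-sample summed areas."""
        samples = {f"s{i}": rng.uniform(900, 1600, 6).tolist() for i in range(4)}
        peaks = self._peaks(samples)
        table = gcead.build_feature_table(peaks, ri_tolerance=8.0)
        roots = clustering_oracle(peaks["ri"].to_numpy(), 8.0)
        oracle = {}
        for (_, row), root in zip(peaks.iterrows(), roots):
            oracle.setdefault(root, {}).setdefault(row["sample_id"], 0.0)
            oracle[root][row["sample_id"]] += row["area"]
        assert table.shape == (4, len(set(roots)))
        assert table.to_numpy().sum() == pytest.approx(peaks["area"].sum())
        # per-sample totals must match the oracle's
        for sample in samples:
            oracle_total = sum(d.get(sample, 0.0) for d in oracle.values())
            assert table.loc[sample].sum() == pytest.approx(oracle_total)

    def test_stable_under_sample_permutation(self, rng):
        samples = {f"s{i}": rng.uniform(900, 1600, 5).tolist() for i in range(3)}
        peaks = self._peaks(samples)
        shuffled = peaks.sample(frac=1.0, random_state=0).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            gcead.build_feature_table(peaks), gcead.build_feature_table(shuffled)
        )
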