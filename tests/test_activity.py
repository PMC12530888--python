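import math
from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sfactivity as sfa
from sfactivity import ValidationError
from sfactivity.activity import ONCOGENIC, TUMOR_SUPPRESSOR


# --- independent brute-force oracle (pure python, no scipy) -----------------


def oracle_nes(signature: dict, targets, mor, likelihood) -> float:
    """Naive re-derivation of the rank-quantile enrichment score."""
    obs = {k: v for k, v in signature.items() if v == v}  # drop NaN
    n = len(obs)
    ordered = sorted(obs.items(), key=lambda kv: kv[1])
    ranks = {}
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j][1] == ordered[i][1]:
            j += 1
        avg = (i + 1 + j) / 2.0  # average of ranks i+1 .. j
        for k in range(i, j):
            ranks[ordered[k][0]] = avg
        i = j
    nd = NormalDist()
    t2 = {k: r / (n + 1) for k, r in ranks.items()}
    t1raw = {k: 2 * abs(t - 0.5) for k, t in t2.items()}
    shift = (1 - max(t1raw.values())) / 2
    q2 = {k: nd.inv_cdf(t) for k, t in t2.items()}
    q1 = {k: nd.inv_cdf(t + shift) for k, t in t1raw.items()}
    kept = [(t, m, l) for t, m, l in zip(targets, mor, likelihood) if t in obs]
    lmax = max(l for _, _, l in kept)
    w = [l / lmax for _, _, l in kept]
    d = sum(w)
    sum1 = sum(wi * m * q2[t] for wi, (t, m, _) in zip(w, kept)) / d
    sum2 = sum(wi * (1 - abs(m)) * q1[t] for wi, (t, m, _) in zip(w, kept)) / d
    es = abs(sum1) + max(sum2, 0.0)
    sign = 1.0 if sum1 >= 0 else -1.0
    return sign * es * d / math.sqrt(sum(wi**2 for wi in w))


class TestQuantileTransform:
    def test_directional_scores_of_worked_example(self, toy_signature):
        qs = sfa.quantile_transform(toy_signature)
        assert qs.q2 == pytest.approx(
            [0.9674, 0.4307, 0.0, -0.4307, -0.9674], abs=1e-4
        )

    def test_magnitude_scores_of_worked_example(self, toy_signature):
        qs = sfa.quantile_transform(toy_signature)
        assert qs.q1 == pytest.approx([0.9674, 0.0, -0.9674, 0.0, 0.9674], abs=1e-4)

    def test_all_tied_signature_maps_to_zero(self):
        s = pd.Series([3.0, 3.0, 3.0], index=list("abc"))
        assert sfa.quantile_transform(s).q2 == pytest.approx([0.0, 0.0, 0.0])

    def test_too_few_observed_rejected(self):
        s = pd.Series([1.0, np.nan], index=["a", "b"])
        with pytest.raises(ValidationError):
            sfa.quantile_transform(s)


class TestNes:
    def test_worked_example(self, toy_signature):
        reg = sfa.Regulon("X", ("A", "E"), np.array([1.0, -1.0]), np.ones(2))
        assert sfa.nes(toy_signature, reg, min_targets=1) == pytest.approx(
            1.3681, abs=1e-3
        )

    def test_opposing_targets_cancel_to_zero(self, toy_signature):
        reg = sfa.Regulon("X", ("A", "E"), np.array([1.0, 1.0]), np.ones(2))
        assert sfa.nes(toy_signature, reg, min_targets=1) == pytest.approx(0.0)

    def test_signature_negation_negates_nes(self, toy_signature):
        reg = sfa.Regulon(
            "X", ("A", "B", "E"), np.array([1.0, -1.0, 1.0]), np.array([1.0, 2.0, 0.5])
        )
        fwd = sfa.nes(toy_signature, reg, min_targets=1)
        rev = sfa.nes(-toy_signature, reg, min_targets=1)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_too_few_observed_targets_gives_missing(self, toy_signature):
        reg = sfa.Regulon("X", ("A", "Z"), np.array([1.0, 1.0]), np.ones(2))
        assert np.isnan(sfa.nes(toy_signature, reg, min_targets=2))

    def test_all_zero_likelihood_rejected(self, toy_signature):
        reg = sfa.Regulon("X", ("A", "E"), np.ones(2), np.zeros(2))
        with pytest.raises(ValidationError):
            sfa.nes(toy_signature, reg, min_targets=1)

    def test_increasing_activating_target_weakly_increases_nes(self):
        rng = np.random.default_rng(7)
        s = pd.Series(rng.normal(size=10), index=[f"f{i}" for i in range(10)])
        reg = sfa.Regulon(
            "X", ("f0", "f1", "f2"), np.array([1.0, -1.0, 1.0]), np.ones(3)
        )
        base = sfa.nes(s, reg, min_targets=1)
        bumped = s.copy()
        bumped["f0"] = s.max() + 1.0  # move f0 to the top rank
        assert sfa.nes(bumped, reg, min_targets=1) >= base

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(min_value=4, max_value=10))
        values = data.draw(
            st.lists(
                st.floats(min_value=-5, max_value=5, allow_nan=False),
                min_size=n,
                max_size=n,
            )
        )
        k = data.draw(st.integers(min_value=2, max_value=n))
        mor = data.draw(
            st.lists(
                st.sampled_from([-1.0, -0.5, 0.0, 0.5, 1.0]), min_size=k, max_size=k
            )
        )
        lik = data.draw(
            st.lists(
                st.floats(min_value=0.1, max_value=3.0), min_size=k, max_size=k
            )
        )
        features = [f"f{i}" for i in range(n)]
        s = pd.Series(values, index=features)
        targets = tuple(features[:k])
        reg = sfa.Regulon("X", targets, np.array(mor), np.array(lik))
        expected = oracle_nes(dict(s), targets, mor, lik)
        assert sfa.nes(s, reg, min_targets=1) == pytest.approx(expected, abs=1e-9)


class TestActivityMatrix:
    def _signature(self, seed=0, n=60, cols=("c1", "c2")):
        rng = np.random.default_rng(seed)
        return sfa.FeatureMatrix(
            pd.DataFrame(
                rng.normal(size=(n, len(cols))),
                index=[f"f{i}" for i in range(n)],
                columns=list(cols),
            ),
            "signature",
        )

    def _regulon(self, name, seed):
        rng = np.random.default_rng(seed)
        targets = tuple(f"f{i}" for i in rng.choice(60, 30, replace=False))
        return sfa.Regulon(
            name, targets, rng.choice([-1.0, 1.0], 30), rng.uniform(0.5, 2, 30)
        )

    def test_single_network_equals_per_regulon_nes(self):
        sig = self._signature()
        reg = self._regulon("SF1", 1)
        acts = sfa.activity_matrix(sig, sfa.NetworkSet({"n": [reg]}), min_targets=25)
        for col in sig.data.columns:
            assert acts.data.loc["SF1", col] == pytest.approx(
                sfa.nes(sig.data[col], reg, 25), abs=1e-12
            )

    def test_two_networks_integrate_by_unweighted_mean(self):
        sig = self._signature()
        r1, r2 = self._regulon("SF1", 1), self._regulon("SF1", 2)
        net = sfa.NetworkSet({"a": [r1], "b": [r2]})
        acts = sfa.activity_matrix(sig, net, min_targets=25)
        for col in sig.data.columns:
            expected = (
                sfa.nes(sig.data[col], r1, 25) + sfa.nes(sig.data[col], r2, 25)
            ) / 2
            assert acts.data.loc["SF1", col] == pytest.approx(expected, abs=1e-12)

    def test_regulator_short_of_targets_is_missing_not_zero(self):
        sig = self._signature()
        reg = self._regulon("SF1", 1)
        acts = sfa.activity_matrix(sig, sfa.NetworkSet({"n": [reg]}), min_targets=40)
        assert acts.data.loc["SF1"].isna().all()


class TestPrograms:
    def _programs(self):
        return sfa.ProgramDefinition(
            {
                "O1": ONCOGENIC,
                "O2": ONCOGENIC,
                "O3": ONCOGENIC,
                "T1": TUMOR_SUPPRESSOR,
                "T2": TUMOR_SUPPRESSOR,
            }
        )

    def _acts(self, onc, tsupp):
        data = {"c": list(onc) + list(tsupp)}
        return sfa.FeatureMatrix(
            pd.DataFrame(data, index=["O1", "O2", "O3", "T1", "T2"]), "activity"
        )

    def test_odd_and_even_count_medians(self):
        acts4 = sfa.FeatureMatrix(
            pd.DataFrame({"c": [1.0, 2.0, 3.0, 4.0]}, index=["O1", "O2", "O3", "O4"]),
            "activity",
        )
        programs = sfa.ProgramDefinition({f"O{i}": ONCOGENIC for i in range(1, 5)})
        med = sfa.program_activity(acts4, programs, (ONCOGENIC,))
        assert med.loc[ONCOGENIC, "c"] == 2.5

    def test_missing_member_ignored_in_median(self):
        acts = self._acts([1.0, np.nan, 3.0], [0.0, 0.0])
        med = sfa.program_activity(acts, self._programs())
        assert med.loc[ONCOGENIC, "c"] == 2.0

    def test_difference_reporter(self):
        acts = self._acts([1.0, 2.0, 3.0], [-1.0, 0.0])
        diff = sfa.program_difference(acts, self._programs())
        assert diff["c"] == pytest.approx(2.5)

    def test_identical_programs_give_zero_difference(self):
        acts = self._acts([1.0, 1.0, 1.0], [1.0, 1.0])
        assert sfa.program_difference(acts, self._programs())["c"] == 0.0

    def test_swapping_labels_negates_reporter(self):
        acts = self._acts([1.0, 2.0, 3.0], [-1.0, 0.0])
        swapped = sfa.ProgramDefinition(
            {
                "O1": TUMOR_SUPPRESSOR,
                "O2": TUMOR_SUPPRESSOR,
                "O3": TUMOR_SUPPRESSOR,
                "T1": ONCOGENIC,
                "T2": ONCOGENIC,
            }
        )
        assert sfa.program_difference(acts, swapped)["c"] == pytest.approx(
            -sfa.program_difference(acts, self._programs())["c"]
        )


class TestNormalizeVsControl:
    def _fm(self, cols):
        return sfa.FeatureMatrix(pd.DataFrame(cols, index=["SF1"]), "activity")

    def test_subtraction_on_matched_pairs(self):
        out = sfa.normalize_vs_control(
            self._fm({"t1": [2.0]}), self._fm({"c1": [0.5]}), {"t1": "c1"}
        )
        assert out.data.loc["SF1", "t1"] == 1.5

    def test_equal_treated_and_control_gives_zero(self):
        out = sfa.normalize_vs_control(
            self._fm({"t1": [2.0]}), self._fm({"c1": [2.0]}), {"t1": "c1"}
        )
        assert out.data.loc["SF1", "t1"] == 0.0

    def test_missing_control_entry_gives_missing_output(self):
        out = sfa.normalize_vs_control(
            self._fm({"t1": [2.0]}), self._fm({"c1": [np.nan]}), {"t1": "c1"}
        )
        assert np.isnan(out.data.loc["SF1", "t1"])

    def test_unmatched_condition_rejected(self):
        with pytest.raises(ValidationError, match="t1"):
            sfa.normalize_vs_control(
                self._fm({"t1": [2.0]}), self._fm({"c1": [0.0]}), {}
            )
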