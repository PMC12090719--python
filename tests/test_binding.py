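"""In-vitro binding model: Hill curves, multi-box partition function,
bootstrap augmentation, Kh fitting and cooperativity selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spo0areg as s
from spo0areg.binding import _validate_emsa


class TestFractionBoundSingle:
    @pytest.mark.parametrize("n", [1, 2, 4, 6])
    @pytest.mark.parametrize("kh", [0.1, 0.5, 2.0])
    def test_anchor_values(self, kh, n):
        assert s.fraction_bound_single(0.0, kh, n) == 0.0
        assert s.fraction_bound_single(kh, kh, n) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form(self):
        # c=1, kh=0.5, n=4: (1/0.5)^4 / (1 + (1/0.5)^4) = 16/17
        assert s.fraction_bound_single(1.0, 0.5, 4) == pytest.approx(16 / 17, abs=1e-12)

    @pytest.mark.parametrize("bad", [dict(kh=0.0), dict(kh=-1.0), dict(n=0)])
    def test_invalid_parameters(self, bad):
        kwargs = dict(conc=1.0, kh=0.5, n=4)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            s.fraction_bound_single(kwargs["conc"], kwargs["kh"], kwargs["n"])

    @settings(max_examples=200, derandomize=True)
    @given(
        c1=st.floats(0.0, 50.0),
        dc=st.floats(0.0, 50.0),
        kh=st.floats(0.01, 10.0),
        dk=st.floats(0.0, 10.0),
        n=st.integers(1, 6),
    )
    def test_monotone_in_conc_and_kh(self, c1, dc, kh, dk, n):
        assert s.fraction_bound_single(c1 + dc, kh, n) >= s.fraction_bound_single(
            c1, kh, n
        )
        assert s.fraction_bound_single(c1, kh + dk, n) <= s.fraction_bound_single(
            c1, kh, n
        ) + 1e-15


def brute_force_multi(boxes, params, conc):
    """P(at least one box bound) by explicit 2^k state enumeration."""
    idx = [s.BOXES.index(b) for b in boxes]
    z = 0.0
    bound = 0.0
    for state in itertools.product((0, 1), repeat=len(idx)):
        w = 1.0
        for b, sb in zip(boxes, state):
            if sb:
                w *= (conc / params.kh[b]) ** params.n
        for (i, bi), (j, bj) in itertools.combinations(enumerate(boxes), 2):
            if state[i] and state[j]:
                w *= math.exp(-params.eps.get(tuple(sorted((bi, bj))), 0.0))
        z += w
        if any(state):
            bound += w
    return bound / z


class TestFractionBoundMulti:
    def test_single_site_reduction(self):
        bp = s.BindingParams(n=4, kh={"0A1": 0.4, "0A2": 0.6, "0A3": 0.2})
        for c in (0.0, 0.2, 0.4, 1.0):
            assert s.fraction_bound_multi(("0A1",), bp, c) == pytest.approx(
                s.fraction_bound_single(c, 0.4, 4), abs=1e-14
            )

    def test_independence_two_sites_at_kh(self):
        bp = s.BindingParams(n=3, kh={"0A1": 0.5, "0A2": 0.5, "0A3": 0.2})
        assert s.fraction_bound_multi(("0A1", "0A2"), bp, 0.5) == pytest.approx(
            0.75, abs=1e-12
        )

    def test_matches_enumeration_with_interactions(self):
        bp = s.BindingParams(
            n=4,
            kh={"0A1": 0.4, "0A2": 0.6, "0A3": 0.2},
            eps={p: -2.0 for p in s.PAIRS},
        )
        boxes = ("0A1", "0A2", "0A3")
        expected = brute_force_multi(boxes, bp, 0.3)
        assert s.fraction_bound_multi(boxes, bp, 0.3) == pytest.approx(
            expected, abs=1e-12
        )

    @settings(max_examples=60, derandomize=True)
    @given(
        conc=st.floats(0.0, 3.0),
        khs=st.tuples(*[st.floats(0.05, 2.0)] * 3),
        epsv=st.tuples(*[st.floats(-4.0, 3.0)] * 3),
        n=st.integers(1, 5),
    )
    def test_enumeration_oracle_property(self, conc, khs, epsv, n):
        bp = s.BindingParams(
            n=n,
            kh=dict(zip(s.BOXES, khs)),
            eps=dict(zip(s.PAIRS, epsv)),
        )
        boxes = ("0A1", "0A2", "0A3")
        assert s.fraction_bound_multi(boxes, bp, conc) == pytest.approx(
            brute_force_multi(boxes, bp, conc), abs=1e-12
        )

    def test_empty_subset_rejected(self):
        bp = s.BindingParams(n=4, kh={"0A1": 0.4, "0A2": 0.6, "0A3": 0.2})
        with pytest.raises(ValueError):
            s.fraction_bound_multi((), bp, 0.5)


def _emsa_frame(rows):
    return pd.DataFrame(rows, columns=["box_subset", "conc_uM", "replicate", "frac_bound"])


class TestAugmentDataset:
    def _toy(self):
        rows = []
        for c in (0.0, 0.2, 0.5, 1.0):
            for rep, jitter in ((1, -0.01), (2, 0.01)):
                f = min(max(s.fraction_bound_single(c, 0.4, 4) + jitter, 0), 1)
                rows.append(("1", c, rep, f))
        return _emsa_frame(rows)

    def test_zero_sd_returns_means(self):
        df = self._toy()
        df["frac_bound"] = df.groupby("conc_uM")["frac_bound"].transform("mean")
        out = s.augment_dataset(df, n_augment=1, seed=1)[0]
        means = df.groupby("conc_uM")["frac_bound"].mean()
        for _, row in out.iterrows():
            assert row["frac_bound"] == pytest.approx(means[row["conc_uM"]], abs=1e-15)

    def test_deterministic_given_seed(self):
        df = self._toy()
        a = s.augment_dataset(df, n_augment=3, seed=42)
        b = s.augment_dataset(df, n_augment=3, seed=42)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_law_of_large_numbers(self):
        from scipy import stats

        df = self._toy()
        aug = s.augment_dataset(df, n_augment=1000, seed=0)
        stacked = pd.concat(aug)
        for (subset, conc), g in df.groupby(["box_subset", "conc_uM"])["frac_bound"]:
            mean, sd = g.mean(), g.std()
            # truncation to [0,1] shifts the law's mean near the boundaries;
            # compare against the truncated normal's own mean
            a, b = (0 - mean) / sd, (1 - mean) / sd
            theo_mean = stats.truncnorm.mean(a, b, loc=mean, scale=sd)
            theo_sd = stats.truncnorm.std(a, b, loc=mean, scale=sd)
            emp = stacked[
                (stacked["box_subset"] == subset) & (stacked["conc_uM"] == conc)
            ]["frac_bound"]
            se = theo_sd / np.sqrt(1000)
            assert abs(emp.mean() - theo_mean) < 3 * se

    def test_single_replicate_fallback(self):
        df = _emsa_frame([("1", 0.4, 1, 0.5)])
        out = s.augment_dataset(df, n_augment=200, seed=0, fallback_rel_sd=0.1)
        vals = np.array([d["frac_bound"].iloc[0] for d in out])
        assert vals.std() > 0.01  # fallback noise actually applied

    def test_values_stay_in_unit_interval(self):
        df = _emsa_frame(
            [("1", 1.0, 1, 0.98), ("1", 1.0, 2, 0.90), ("1", 0.0, 1, 0.02),
             ("1", 0.0, 2, 0.10)]
        )
        for d in s.augment_dataset(df, n_augment=300, seed=5):
            assert d["frac_bound"].between(0, 1).all()


class TestFitKh:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_exact_recovery_on_clean_curve(self, n):
        conc = np.linspace(0, 2, 9)
        rows = [("2", c, 1, s.fraction_bound_single(c, 0.5, n)) for c in conc]
        res = s.fit_kh(_emsa_frame(rows), n=n, n_augment=10, seed=0)
        assert res["boxes"]["0A2"]["kh_uM"] == pytest.approx(0.5, rel=1e-6)

    def test_noisy_recovery_and_ordering(self, truth):
        # truth ordering: Kh(0A3) < Kh(0A1) < Kh(0A2)
        df = s.gen_emsa_dataset(truth, seed=11)
        res = s.fit_kh(df, n=4, n_augment=50, seed=1)
        kh = {b: v["kh_uM"] for b, v in res["boxes"].items()}
        for b in s.BOXES:
            assert kh[b] == pytest.approx(truth.kh_vitro[b], rel=0.10)
        assert kh["0A3"] < kh["0A1"] < kh["0A2"]

    def test_ci_bounds_bracket_estimate(self, truth):
        df = s.gen_emsa_dataset(truth, seed=3)
        res = s.fit_kh(df, n=4, n_augment=80, seed=2)
        for v in res["boxes"].values():
            assert v["ci95_low"] <= v["kh_uM"] <= v["ci95_high"]


class TestSelectCooperativity:
    def test_recovers_generating_stoichiometry(self, emsa_data):
        best, errors = s.select_cooperativity(emsa_data, candidates=range(1, 7))
        assert best == 4
        assert set(errors) == set(range(1, 7))

    def test_dimer_fits_worse_than_tetramer(self, emsa_data):
        _, errors = s.select_cooperativity(emsa_data, candidates=(2, 4))
        assert errors[2] / errors[4] > 1.0

    def test_non_cooperative_control(self):
        conc = np.linspace(0, 2, 9)
        rows = [
            (lbl, c, 1, s.fraction_bound_single(c, kh, 1))
            for lbl, kh in (("1", 0.4), ("2", 0.6), ("3", 0.2))
            for c in conc
        ]
        best, _ = s.select_cooperativity(_emsa_frame(rows), candidates=range(1, 7))
        assert best == 1


class TestEstimators:
    def test_hill_model_sklearn_roundtrip(self):
        conc = np.linspace(0, 2, 12)
        y = s.fraction_bound_single(conc, 0.7, 4)
        m = s.HillBindingModel(n=4).fit(conc, y)
        assert m.kh_ == pytest.approx(0.7, rel=1e-6)
        assert m.get_params() == {"n": 4}
        np.testing.assert_allclose(m.predict(conc), y, atol=1e-8)

    def test_emsa_estimator_matches_function(self, emsa_data):
        est = s.EmsaKhEstimator(n=4, n_augment=30, random_state=0).fit(emsa_data)
        res = s.fit_kh(emsa_data, n=4, n_augment=30, seed=0)
        for b in s.BOXES:
            assert est.kh_[b] == pytest.approx(res["boxes"][b]["kh_uM"])
        bp = est.binding_params()
        assert bp.n == 4 and not bp.eps

    def test_cooperativity_selector(self, emsa_data):
        sel = s.CooperativitySelector(candidates=(2, 4)).fit(emsa_data)
        assert sel.n_ == 4


def test_validate_rejects_bad_tables():
    with pytest.raises(ValueError):
        _validate_emsa(_emsa_frame([("1", -0.1, 1, 0.5)]))
    with pytest.raises(ValueError):
        _validate_emsa(_emsa_frame([("1", 0.1, 1, 1.5)]))
    with pytest.raises(ValueError):
        _validate_emsa(_emsa_frame([("none", 0.1, 1, 0.5)]))
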