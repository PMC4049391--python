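"""Densitometry -> per-variant abundance conversion and group statistics."""

import numpy as np
import pytest
from scipy import stats

from capskit import gelquant as gq
from capskit import restriction as rx
from capskit import simulate as sim
from capskit.errors import ValidationError


class TestBuildIncidence:
    def test_trio_shape_and_column_sums(self, trio_incidence):
        M = trio_incidence.matrix
        assert M.shape == (5, 3)
        assert M["a"].sum() == 1968
        assert M["b"].sum() == 1959
        assert M["c"].sum() == 1959

    def test_trio_rank_full(self, trio_incidence):
        assert np.linalg.matrix_rank(trio_incidence.matrix.to_numpy()) == 3

    def test_single_uncut_variant(self, clai):
        v = rx.SequenceVariant("only", "ACGT" * 100)
        bands = rx.classify_bands([rx.digest(v, clai)], 0.02)
        inc = gq.build_incidence(bands, [v])
        assert inc.matrix.shape == (1, 1)
        assert inc.matrix.iloc[0, 0] == 400

    def test_variant_mismatch_rejected(self, trio_bands):
        stranger = rx.SequenceVariant("z", "ACGT" * 10)
        with pytest.raises(ValidationError):
            gq.build_incidence(trio_bands, [stranger])


class TestQuantify:
    def test_least_squares_recovers_forward_simulation(self, trio_incidence):
        lane = sim.simulate_lane(
            {"a": 1.0, "b": 2.0, "c": 3.0}, trio_incidence,
            reference_intensity=1.0, noise_sd=0.0,
        )
        out = gq.quantify(lane, trio_incidence, mode="least_squares")
        values = np.array([a.normalized for a in out])
        np.testing.assert_allclose(values, [1.0, 2.0, 3.0], rtol=1e-9)

    def test_intensity_only_in_uncut_band(self, trio_incidence):
        lane = gq.LaneDensitometry("L1", "ctrl", [(1968.0, 5000.0)], 1.0)
        out = {a.variant: a.normalized for a in
               gq.quantify(lane, trio_incidence, mode="least_squares")}
        assert out["b"] == 0.0 and out["c"] == 0.0 and out["a"] > 0

    def test_modes_agree_on_noise_free_data(self, trio_incidence, rng):
        for _ in range(20):
            x = dict(zip("abc", rng.uniform(0.5, 5.0, size=3)))
            lane = sim.simulate_lane(x, trio_incidence, reference_intensity=1.0,
                                     noise_sd=0.0)
            dg = np.array([a.normalized for a in
                           gq.quantify(lane, trio_incidence, mode="diagnostic")])
            ls = np.array([a.normalized for a in
                           gq.quantify(lane, trio_incidence, mode="least_squares")])
            np.testing.assert_allclose(dg, ls, rtol=1e-6)

    def test_diagnostic_mode_requires_diagnostic_band(self, clai):
        seq = "A" * 100 + "ATCGAT" + "A" * 100
        twins = [rx.SequenceVariant("v1", seq), rx.SequenceVariant("v2", seq)]
        bands = rx.classify_bands([rx.digest(v, clai) for v in twins])
        inc = gq.build_incidence(bands, twins)
        lane = gq.LaneDensitometry("L", "c", [(101.0, 10.0)], 1.0)
        with pytest.raises(ValidationError, match="v1"):
            gq.quantify(lane, inc, mode="diagnostic")

    def test_all_zero_intensities_warn_and_return_zero(self, trio_incidence):
        lane = gq.LaneDensitometry(
            "L", "c", [(ln, 0.0) for ln in trio_incidence.band_lengths], 1.0
        )
        with pytest.warns(UserWarning, match="zero"):
            out = gq.quantify(lane, trio_incidence, mode="least_squares")
        assert all(a.normalized == 0.0 for a in out)

    def test_scale_equivariance(self, trio_incidence):
        lane = sim.simulate_lane({"a": 1.0, "b": 0.5, "c": 2.0}, trio_incidence,
                                 reference_intensity=300.0, noise_sd=0.03, seed=7)
        scaled = gq.LaneDensitometry(
            lane.lane_id, lane.condition,
            [(ln, 10.0 * it) for ln, it in lane.bands],
            10.0 * lane.reference_intensity,
        )
        a = [x.normalized for x in gq.quantify(lane, trio_incidence, "least_squares")]
        b = [x.normalized for x in gq.quantify(scaled, trio_incidence, "least_squares")]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_nonnegativity_under_noise(self, trio_incidence):
        for s in range(30):
            lane = sim.simulate_lane({"a": 0.01, "b": 3.0, "c": 0.0}, trio_incidence,
                                     noise_sd=0.3, seed=s)
            out = gq.quantify(lane, trio_incidence, mode="least_squares")
            assert all(a.normalized >= 0 for a in out)

    def test_noisy_recovery_median_error(self, trio_incidence):
        """5% multiplicative noise: median relative abundance error <= 10%."""
        truth = np.array([1.0, 2.0, 3.0])
        errs = []
        for s in range(200):
            lane = sim.simulate_lane(dict(zip("abc", truth)), trio_incidence,
                                     reference_intensity=1.0, noise_sd=0.05, seed=s)
            est = np.array([a.normalized for a in
                            gq.quantify(lane, trio_incidence, "least_squares")])
            errs.extend(np.abs(est - truth) / truth)
        assert np.median(errs) <= 0.10


class TestPercentChange:
    @pytest.mark.parametrize(
        "treated, control, expected",
        [(2.0, 1.0, 100.0), (1.0, 1.0, 0.0), (3.17, 1.0, 217.0)],
    )
    def test_formula(self, treated, control, expected):
        assert gq.percent_change(treated, control) == pytest.approx(expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            gq.percent_change(1.0, 0.0)


class TestCompareGroups:
    def test_identical_groups_share_one_letter(self):
        g = {"c1": [1.0, 1.1, 0.9], "c2": [1.0, 1.1, 0.9], "c3": [1.0, 1.1, 0.9]}
        comp = gq.compare_groups(g)
        assert not comp.table["significant"].any()
        assert len(set(comp.letters.values())) == 1

    def test_bonferroni_comparison_count(self):
        g = {f"g{i}": [0.0, 1.0, 2.0] for i in range(3)}
        comp = gq.compare_groups(g, alpha=0.05)
        assert comp.n_comparisons == 3
        assert comp.adjusted_alpha == pytest.approx(0.05 / 3)

    def test_separated_groups_significant_at_strict_alpha(self, rng):
        a = rng.normal(0.0, 1.0, size=9)
        b = rng.normal(5.0, 1.0, size=9)
        comp = gq.compare_groups({"ctrl": a, "trt": b}, alpha=0.001)
        assert comp.table["significant"].all()
        assert comp.letters["ctrl"] != comp.letters["trt"]

    def test_zero_variance_identical_means_not_significant(self):
        comp = gq.compare_groups({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert not comp.table["significant"].any()

    def test_letter_display_orders_distinct_groups(self, rng):
        g = {
            "low": rng.normal(0, 0.1, 9),
            "mid": rng.normal(5, 0.1, 9),
            "high": rng.normal(10, 0.1, 9),
        }
        comp = gq.compare_groups(g, alpha=0.05)
        assert len({comp.letters[k] for k in g}) == 3

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValidationError):
            gq.compare_groups({"a": [1.0], "b": [1.0, 2.0]})


def test_summarize_conditions_percent_changes(trio_incidence, rng):
    """End-to-end: simulated control/treated lanes reproduce the generating
    fold changes within a few percent."""
    truth = {"control": {"a": 1.0, "b": 1.0, "c": 1.0},
             "treated": {"a": 1.0, "b": 6.85, "c": 4.01}}
    tables = {}
    for ci, (cond, x) in enumerate(truth.items()):
        reps = {v: [] for v in "abc"}
        for r in range(9):
            lane = sim.simulate_lane(x, trio_incidence, reference_intensity=500.0,
                                     noise_sd=0.02, seed=1000 * ci + r,
                                     condition=cond)
            for ab in gq.quantify(lane, trio_incidence, "diagnostic"):
                reps[ab.variant].append(ab.normalized)
        tables[cond] = reps
    df = gq.summarize_conditions(tables, control="control")
    treated = df[df.condition == "treated"].set_index("variant")
    assert treated.loc["b", "percent_change"] == pytest.approx(585, abs=30)
    assert treated.loc["c", "percent_change"] == pytest.approx(301, abs=20)
    assert treated.loc["a", "percent_change"] == pytest.approx(0, abs=5)
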