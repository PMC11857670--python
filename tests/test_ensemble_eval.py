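import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esdm.ensemble_eval import (
    EnsembleModel,
    auc_score,
    build_ensemble,
    ensemble_weights,
    evaluate_replicates,
    jackknife_contribution,
    tss_score,
)
from esdm.env_layers import EnvStack, GridSpec
from esdm.errors import ContractError, NoAdmissibleModelError
from esdm.occurrence import add_pseudo_absences
from esdm.sdm_core import predict_sdm
from esdm.synthetic_data import (
    LandscapeSpec,
    LayerSpec,
    Response,
    VirtualSpecies,
    generate_landscape,
    sample_virtual_occurrences,
)

from conftest import make_layer

FAST_CFG = {
    "replicates": 4,
    "hyperparams": {"random_forest": {"n_estimators": 30}},
}


def brute_force_auc(labels, scores):
    wins = ties = 0
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def exhaustive_tss(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    sweep = []
    for t in sorted(set(scores)):
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        sweep.append((t, sens + spec - 1))
    best = max(v for _, v in sweep)
    best_t = max(t for t, v in sweep if abs(v - best) < 1e-12)  # ties: larger t
    return best, best_t


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0

    def test_all_ties_is_half(self):
        assert auc_score([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_two_pair_hand_case(self):
        # pairs: (0.9 vs 0.5) win, (0.2 vs 0.5) loss -> 0.5
        assert auc_score([1, 1, 0], [0.9, 0.2, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            auc_score([1, 1], [0.1, 0.2])

    def test_against_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 25)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert auc_score(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores)
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_negation_symmetry_tie_free(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            return
        scores = rng.permutation(np.arange(n, dtype=float))  # tie-free
        assert auc_score(labels, scores) + auc_score(labels, -scores) == pytest.approx(1.0)


class TestTss:
    def test_perfect_separation(self):
        tss, _ = tss_score([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2])
        assert tss == pytest.approx(1.0)

    def test_exhaustive_sweep_case(self):
        tss, t = tss_score([1, 0, 1, 0], [0.4, 0.3, 0.2, 0.1])
        assert tss == pytest.approx(0.5)
        assert t == pytest.approx(0.4)

    def test_confusion_arithmetic_case(self):
        # best threshold realizes TP=8 FN=2 TN=6 FP=4 -> 0.8 + 0.6 - 1 = 0.4
        labels = [1] * 10 + [0] * 10
        scores = [0.9] * 8 + [0.1] * 2 + [0.9] * 4 + [0.1] * 6
        tss, t = tss_score(labels, scores)
        assert tss == pytest.approx(0.4)
        assert t == pytest.approx(0.9)

    def test_tss_is_one_iff_perfectly_separable(self):
        tss, _ = tss_score([1, 0, 1, 0], [0.9, 0.2, 0.8, 0.1])
        assert tss == pytest.approx(1.0)
        tss2, _ = tss_score([1, 0, 1, 0], [0.9, 0.95, 0.8, 0.1])
        assert tss2 < 1.0

    def test_against_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)
            tss, t = tss_score(labels, scores)
            o_tss, o_t = exhaustive_tss(labels, scores)
            assert tss == pytest.approx(o_tss)
            assert t == pytest.approx(o_t)


class TestEnsembleWeights:
    def test_equal_auc_equal_weights(self):
        assert ensemble_weights({"A": 0.9, "B": 0.9}) == {"A": 0.5, "B": 0.5}

    def test_hand_computed_exclusion_case(self):
        w = ensemble_weights({"A": 0.90, "B": 0.84, "C": 0.86})
        assert set(w) == {"A", "C"}
        assert w["A"] == pytest.approx(0.90 / 1.76)
        assert w["C"] == pytest.approx(0.86 / 1.76)

    def test_all_below_cutoff_raises(self):
        with pytest.raises(NoAdmissibleModelError):
            ensemble_weights({"A": 0.80, "B": 0.84})

    def test_boundary_inclusive_by_default(self):
        assert "A" in ensemble_weights({"A": 0.85})
        with pytest.raises(NoAdmissibleModelError):
            ensemble_weights({"A": 0.85}, strict=True)

    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.floats(0.5, 1.0),
            min_size=1,
            max_size=4,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_properties(self, aucs):
        try:
            w = ensemble_weights(aucs)
        except NoAdmissibleModelError:
            assert all(v < 0.85 for v in aucs.values())
            return
        assert set(w) == {k for k, v in aucs.items() if v >= 0.85}
        assert sum(w.values()) == pytest.approx(1.0)
        for a in w:
            for b in w:
                if aucs[a] == aucs[b]:
                    assert w[a] == pytest.approx(w[b])


def small_scene(seed=0, n=40, n_presence=150, weight=5.0, intercept=-6.0):
    grid = GridSpec(n, n, 30.0, 0.0, n * 30.0)
    spec = LandscapeSpec(
        grid=grid,
        layers=[
            LayerSpec("elev", "gaussian_field", correlation_length=6.0),
            LayerSpec("moisture", "gaussian_field", correlation_length=4.0),
            LayerSpec("noise", "gaussian_field", correlation_length=3.0),
        ],
        seed=seed,
    )
    stack = generate_landscape(spec)
    vs = VirtualSpecies("v", {"elev": Response("linear", weight)}, intercept=intercept)
    occ = sample_virtual_occurrences(vs, stack, n_presence, seed=seed + 1)
    add_pseudo_absences(occ, stack, seed=seed + 2)
    return stack, occ


class TestEvaluateReplicates:
    def test_replicate_count_and_stratification(self):
        stack, occ = small_scene()
        ev = evaluate_replicates(
            occ, stack, algorithms=["maxent_like"], n_rep=20, holdout=0.2, seed=3
        )
        assert len(ev.results) == 20
        n_pos = len(occ.presences)
        expected_test_pos = int(np.ceil(0.2 * n_pos))
        for rep, labels in ev.holdout_labels.items():
            assert labels.sum() == expected_test_pos

    def test_strong_signal_high_auc(self):
        stack, occ = small_scene(seed=5)
        ev = evaluate_replicates(
            occ,
            stack,
            n_rep=4,
            seed=4,
            hyperparams={"random_forest": {"n_estimators": 30}},
        )
        for algo, auc in ev.mean_auc().items():
            assert auc > 0.8, (algo, auc)

    def test_too_few_records_rejected(self, grid10):
        stack = EnvStack([make_layer(grid10, "a", np.random.default_rng(0).normal(size=(10, 10)))])
        from esdm.occurrence import OccurrenceSet

        occ = OccurrenceSet("sp", presences=[(0, 0, i) for i in range(5)], absences=[90, 91, 92, 93, 94])
        with pytest.raises(ContractError):
            evaluate_replicates(occ, stack, n_rep=2, seed=0)

    def test_deterministic(self):
        stack, occ = small_scene(seed=6)
        kw = dict(algorithms=["maxent_like", "svm"], n_rep=3, seed=9)
        a = evaluate_replicates(occ, stack, **kw)
        b = evaluate_replicates(occ, stack, **kw)
        assert [r.auc for r in a.results] == [r.auc for r in b.results]


class TestBuildEnsemble:
    def test_single_admissible_model_is_identity(self):
        stack, occ = small_scene(seed=7)
        model, ens_map = build_ensemble(
            occ, stack, algorithms=["maxent_like"], config=FAST_CFG, seed=10
        )
        assert model.weights == {"maxent_like": 1.0}
        solo = predict_sdm(model.fits["maxent_like"], stack)
        np.testing.assert_allclose(ens_map.values, solo.values)

    def test_per_cell_weighted_mean_oracle(self):
        stack, occ = small_scene(seed=8)
        model, ens_map = build_ensemble(occ, stack, config=FAST_CFG, seed=11)
        assert model.h == len(model.weights) >= 1
        expected = np.zeros_like(ens_map.values)
        for algo, w in model.weights.items():
            expected = expected + w * predict_sdm(model.fits[algo], stack).values
        np.testing.assert_allclose(ens_map.values, np.clip(expected, 0, 1))

    def test_map_in_unit_interval(self):
        stack, occ = small_scene(seed=12)
        _, ens_map = build_ensemble(occ, stack, config=FAST_CFG, seed=13)
        vals = ens_map.values[np.isfinite(ens_map.values)]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_weights_sum_to_one_and_cutoff_respected(self):
        stack, occ = small_scene(seed=14)
        model, _ = build_ensemble(occ, stack, config=FAST_CFG, seed=15)
        assert sum(model.weights.values()) == pytest.approx(1.0)
        for algo in model.weights:
            assert model.mean_auc[algo] >= model.cutoff

    def test_bitwise_determinism(self):
        stack, occ = small_scene(seed=16)
        _, m1 = build_ensemble(occ, stack, config=FAST_CFG, seed=17)
        _, m2 = build_ensemble(occ, stack, config=FAST_CFG, seed=17)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_unmodellable_species_raises(self):
        stack, occ = small_scene(seed=18, weight=0.2, intercept=0.0)  # no signal
        with pytest.raises(NoAdmissibleModelError):
            build_ensemble(occ, stack, config=FAST_CFG, seed=19)

    def test_weighted_member_metrics_exposed(self):
        stack, occ = small_scene(seed=20)
        model, _ = build_ensemble(occ, stack, config=FAST_CFG, seed=21)
        lo = min(model.mean_auc[a] for a in model.weights)
        hi = max(model.mean_auc[a] for a in model.weights)
        assert lo <= model.weighted_member_auc() <= hi


class TestJackknife:
    def test_dominant_variable_ranks_first_and_sums_to_100(self):
        stack, occ = small_scene(seed=22)
        contrib = jackknife_contribution(occ, stack, config=FAST_CFG, seed=23)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-9)
        assert all(v >= 0 for v in contrib.values())
        assert max(contrib, key=contrib.get) == "elev"

    def test_needs_two_variables(self):
        stack, occ = small_scene(seed=24)
        with pytest.raises(ContractError):
            jackknife_contribution(occ, stack, kept_variables=["elev"], seed=0)

    def test_reuses_precomputed_full_ensemble(self):
        stack, occ = small_scene(seed=25)
        full = build_ensemble(occ, stack, config=FAST_CFG, seed=26)
        c1 = jackknife_contribution(occ, stack, config=FAST_CFG, seed=26, full=full)
        c2 = jackknife_contribution(occ, stack, config=FAST_CFG, seed=26)
        for k in c1:
            assert c1[k] == pytest.approx(c2[k])
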