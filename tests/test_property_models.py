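import numpy as np
import pytest

from mtasepred.data_model import ProteinRecord, TrainingTable
from mtasepred.property_models import (
    CategoricalModel,
    SmoothingSpec,
    SteppedModel,
    fit_categorical,
    fit_stepped,
    single_property_posterior,
    step_prob,
)

CLASSES = ("RNA", "PROTEIN", "OTHER")


class TestFitCategorical:
    def test_hard_association_without_pseudocount(self, composition_table):
        model = fit_categorical(composition_table, "SET", alpha=0.0)
        assert model.values == (False, True)
        table = {c: model.table[CLASSES.index(c)] for c in CLASSES}
        assert table["PROTEIN"][1] == pytest.approx(8 / 24)
        assert table["RNA"][1] == 0.0
        assert table["OTHER"][1] == 0.0

    def test_pseudocount_formula(self, composition_table):
        model = fit_categorical(composition_table, "SET", alpha=0.5)
        # (0 + 0.5) / (26 + 0.5 * 2) for the never-observed RNA x SET cell
        assert model.table[0, 1] == pytest.approx(0.5 / 27, abs=1e-12)
        assert model.table[1, 1] == pytest.approx(8.5 / 25, abs=1e-12)

    def test_equal_counts_symmetry(self):
        recs = [ProteinRecord(id=f"r{i}", fold_group="SET", label="RNA") for i in range(3)]
        recs += [ProteinRecord(id=f"p{i}", fold_group="SET", label="PROTEIN") for i in range(3)]
        recs += [ProteinRecord(id=f"q{i}", fold_group="ROSSMANN", label="RNA") for i in range(2)]
        recs += [ProteinRecord(id=f"s{i}", fold_group="ROSSMANN", label="PROTEIN") for i in range(2)]
        table = TrainingTable(recs, classes=("RNA", "PROTEIN"))
        model = fit_categorical(table, "SET", alpha=0.5)
        assert model.table[0, 1] == pytest.approx(model.table[1, 1])

    def test_absent_property_raises(self, composition_table):
        with pytest.raises(ValueError, match="absent"):
            fit_categorical(composition_table, "pi_global")

    def test_rows_normalized(self, composition_table):
        model = fit_categorical(composition_table, "fold_group", alpha=0.5)
        assert np.allclose(model.table.sum(axis=1), 1.0, atol=1e-12)


class TestStepProb:
    @pytest.fixture()
    def two_level(self):
        return SteppedModel(
            "pi_global", ("A", "B"), (6.95,),
            np.array([[0.75, 0.25], [0.25, 0.75]]),
            domain=(0.0, 14.0), smoothing=SmoothingSpec(k=0.99),
        )

    def test_far_from_threshold_approaches_level(self, two_level):
        steep = SteppedModel(
            "pi_global", ("A", "B"), (6.95,),
            np.array([[0.75, 0.25], [0.25, 0.75]]),
            domain=(0.0, 14.0), smoothing=SmoothingSpec(k=50.0),
        )
        assert step_prob(0.5, steep, "A") == pytest.approx(0.75, abs=1e-9)
        assert step_prob(13.5, steep, "A") == pytest.approx(0.25, abs=1e-9)

    def test_at_threshold_is_level_midpoint(self, two_level):
        assert step_prob(6.95, two_level, "A") == pytest.approx(0.5, abs=1e-12)

    def test_hard_step_limit(self):
        hard = SteppedModel(
            "pi_global", ("A", "B"), (6.95,),
            np.array([[0.75, 0.25], [0.25, 0.75]]),
            domain=(0.0, 14.0), smoothing=SmoothingSpec(enabled=False),
        )
        assert step_prob(8.0, hard, "A") == 0.25
        assert step_prob(6.95, hard, "A") == 0.25  # threshold joins upper interval

    def test_outside_domain_raises(self, two_level):
        with pytest.raises(ValueError, match="domain"):
            step_prob(14.5, two_level, "A")

    def test_continuity_everywhere(self, two_level):
        xs = np.linspace(0.001, 13.999, 5000)
        vals = two_level.likelihood_array(xs)[:, 0]
        assert np.max(np.abs(np.diff(vals))) < 0.01

    def test_circular_wrap_continuity(self):
        model = SteppedModel(
            "onset_min", ("A", "B"), (10.0, 183.0),
            np.array([[0.22, 0.78], [0.56, 0.44]]),
            periodic=True, period=300.0, smoothing=SmoothingSpec(k=0.99),
        )
        near_wrap = model.likelihood(299.999999)
        at_zero = model.likelihood(0.0)
        assert np.allclose(near_wrap, at_zero, atol=1e-6)
        # periodicity: any value is equivalent mod the period
        assert np.allclose(model.likelihood(83.0), model.likelihood(383.0), atol=1e-12)

    def test_invalid_model_construction(self):
        with pytest.raises(ValueError, match="increasing"):
            SteppedModel("x", ("A", "B"), (7.0, 7.0),
                         np.array([[0.2, 0.3, 0.5], [0.5, 0.3, 0.2]]), domain=(0, 14))
        with pytest.raises(ValueError, match="sum"):
            SteppedModel("x", ("A", "B"), (7.0,),
                         np.array([[0.2, 0.3], [0.5, 0.5]]), domain=(0, 14))


def _two_clump_table(seed: int, n_per_class: int = 300) -> TrainingTable:
    rng = np.random.default_rng(seed)
    recs = []
    for i, x in enumerate(np.clip(rng.normal(5.0, 0.5, n_per_class), 0.1, 13.9)):
        recs.append(ProteinRecord(id=f"a{i}", pi_global=float(x), label="LOW"))
    for i, x in enumerate(np.clip(rng.normal(9.0, 0.5, n_per_class), 0.1, 13.9)):
        recs.append(ProteinRecord(id=f"b{i}", pi_global=float(x), label="HIGH"))
    return TrainingTable(recs, classes=("LOW", "HIGH"))


class TestFitStepped:
    def test_recovers_separating_threshold(self):
        table = _two_clump_table(seed=42)
        model = fit_stepped(table, "pi_global", m=1)
        assert 6.0 < model.thresholds[0] < 8.0

    def test_all_values_identical_raises(self):
        recs = [ProteinRecord(id=f"r{i}", pi_global=7.0,
                              label="RNA" if i % 2 else "PROTEIN") for i in range(10)]
        table = TrainingTable(recs, classes=("RNA", "PROTEIN"))
        with pytest.raises(ValueError, match="distinct"):
            fit_stepped(table, "pi_global", m=1)

    def test_circular_shift_by_period_is_identity(self):
        rng = np.random.default_rng(3)
        recs = [
            ProteinRecord(id=f"r{i}", onset_min=float(x),
                          label="RNA" if i % 2 else "PROTEIN")
            for i, x in enumerate(rng.uniform(0, 300, 80))
        ]
        table = TrainingTable(recs, classes=("RNA", "PROTEIN"))
        shifted = TrainingTable(
            [ProteinRecord(id=r.id, onset_min=(r.onset_min + 300.0) % 300.0,
                           label=r.label) for r in recs],
            classes=("RNA", "PROTEIN"),
        )
        m1 = fit_stepped(table, "onset_min", m=2)
        m2 = fit_stepped(shifted, "onset_min", m=2)
        assert np.allclose(m1.thresholds, m2.thresholds, atol=1e-6)
        assert np.allclose(m1.levels, m2.levels, atol=1e-9)

    def test_optimum_beats_threshold_grid(self):
        """Optimizer sanity oracle: the fitted threshold's classification
        log-likelihood is at least that of every point on a 200-point grid."""
        table = _two_clump_table(seed=7, n_per_class=150)
        model = fit_stepped(table, "pi_global", m=1)
        xs = np.array([r.pi_global for r in table.labeled])
        labels = np.array([("LOW", "HIGH").index(r.label) for r in table.labeled])
        priors = table.priors

        def objective(candidate: SteppedModel) -> float:
            like = candidate.likelihood_array(xs)
            post = like * priors[None, :]
            post /= post.sum(axis=1, keepdims=True)
            return float(np.log(post[np.arange(len(xs)), labels]).sum())

        def at_threshold(t: float) -> SteppedModel:
            idx = (xs >= t).astype(int)
            counts = np.zeros((2, 2))
            np.add.at(counts, (labels, idx), 1.0)
            levels = (counts + 0.5) / (counts.sum(axis=1, keepdims=True) + 1.0)
            return SteppedModel("pi_global", ("LOW", "HIGH"), (t,), levels,
                                domain=model.domain, smoothing=model.smoothing)

        best_grid = max(objective(at_threshold(t))
                        for t in np.linspace(0.1, 13.9, 200))
        assert objective(model) >= best_grid - 1e-6

    def test_parameter_recovery_median_error(self):
        """Median threshold-recovery error over seeded replicates stays small
        (scaled-down version of the full recovery study)."""
        from mtasepred.predictor import FittedModel
        from mtasepred.synthetic_data import generate_from_fitted

        generative = FittedModel(
            classes=CLASSES, priors=np.array([26, 24, 11]) / 61,
            submodels={"pi_global": SteppedModel(
                "pi_global", CLASSES, (7.0,),
                np.array([[0.15, 0.85], [0.8, 0.2], [0.5, 0.5]]), domain=(0, 14))},
        )
        errors = []
        for seed in range(10):
            table = generate_from_fitted(generative, 600, seed)
            fitted = fit_stepped(table, "pi_global", m=1)
            errors.append(abs(fitted.thresholds[0] - 7.0))
        assert np.median(errors) < 0.15


class TestSinglePropertyPosterior:
    def test_equal_likelihoods_return_priors(self):
        model = CategoricalModel("SET", CLASSES, (False, True),
                                 np.array([[0.7, 0.3]] * 3))
        priors = np.array([26, 24, 11]) / 61
        post = single_property_posterior(True, model, priors)
        assert np.allclose(post.probs, priors, atol=1e-12)

    def test_hard_zero_concentrates_posterior(self, composition_table):
        model = fit_categorical(composition_table, "SET", alpha=0.0)
        post = single_property_posterior(True, model, composition_table.priors)
        assert np.allclose(post.probs, [0.0, 1.0, 0.0], atol=1e-12)
        assert post.argmax_class == "PROTEIN"

    def test_matches_hand_summed_bayes(self):
        like = np.array([0.3, 0.5, 0.1])
        priors = np.array([0.2, 0.5, 0.3])
        model = CategoricalModel("x", CLASSES, ("v", "w"),
                                 np.column_stack([like, 1 - like]))
        post = single_property_posterior("v", model, priors)
        products = like * priors  # brute-force oracle over the three terms
        assert np.allclose(post.probs, products / products.sum(), atol=1e-15)

    def test_bad_priors_raise(self):
        model = CategoricalModel("x", CLASSES, ("v", "w"),
                                 np.array([[0.5, 0.5]] * 3))
        with pytest.raises(ValueError, match="priors"):
            single_property_posterior("v", model, [0.5, 0.4, 0.3])
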