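import math

import numpy as np
import pytest

from mtasepred.data_model import ProteinRecord, TrainingTable
from mtasepred.model_search import ModelFamily, PropertySpec, SearchConfig, fit_family
from mtasepred.predictor import FittedModel, posterior, predict, training_log_likelihood
from mtasepred.property_models import (
    CategoricalModel,
    SteppedModel,
    fit_categorical,
    single_property_posterior,
)

CLASSES = ("RNA", "PROTEIN", "OTHER")
PRIORS = np.array([26, 24, 11]) / 61


def _cat(name, p_true):
    """Binary categorical submodel from per-class P(true)."""
    p = np.asarray(p_true, float)
    return CategoricalModel(name, CLASSES, (False, True), np.column_stack([1 - p, p]))


def test_record_without_properties_falls_back_to_priors():
    model = FittedModel(classes=CLASSES, priors=PRIORS,
                        submodels={"SET": _cat("SET", [0.02, 0.33, 0.04])})
    post = posterior(ProteinRecord(id="bare"), model)
    assert np.allclose(post.probs, PRIORS, atol=1e-15)
    assert post.used_properties == ()
    assert post.probs[0] == pytest.approx(26 / 61)


def test_single_property_consistency(composition_table):
    sub = fit_categorical(composition_table, "SET", alpha=0.5)
    model = FittedModel(classes=CLASSES, priors=composition_table.priors,
                        submodels={"SET": sub})
    rec = ProteinRecord(id="x", fold_group="SET")
    combined = posterior(rec, model)
    single = single_property_posterior(True, sub, composition_table.priors)
    assert np.allclose(combined.probs, single.probs, atol=1e-15)
    assert combined.used_properties == ("SET",)


def test_two_property_joint_table_oracle():
    """On a population whose within-class joint counts factorize, the naive
    posterior equals exact Bayes on the full joint contingency table."""
    # class -> (n, P(a=True), P(b=True)) chosen so every joint count is integral
    pops = {"RNA": (4, 0.5, 0.5), "PROTEIN": (2, 1.0, 0.5), "OTHER": (2, 0.0, 1.0)}
    records, joint = [], {}
    i = 0
    for cls, (n, pa, pb) in pops.items():
        for a in (True, False):
            for b in (True, False):
                count = n * (pa if a else 1 - pa) * (pb if b else 1 - pb)
                assert count == int(count)
                joint[(cls, a, b)] = int(count)
                for _ in range(int(count)):
                    i += 1
                    records.append(ProteinRecord(
                        id=f"r{i}", fold_group="SET" if a else "ROSSMANN",
                        ymc_cluster="R/C" if b else "none", label=cls))
    table = TrainingTable(records, classes=CLASSES)
    fitted = fit_family(
        table, ModelFamily((PropertySpec("SET", "categorical"),
                            PropertySpec("R/C", "categorical"))),
        SearchConfig(alpha=0.0))
    for a in (True, False):
        for b in (True, False):
            denom = sum(joint[(c, a, b)] for c in CLASSES)
            if denom == 0:
                continue
            expected = np.array([joint[(c, a, b)] / denom for c in CLASSES])
            rec = ProteinRecord(id="q", fold_group="SET" if a else "ROSSMANN",
                                ymc_cluster="R/C" if b else "none")
            assert np.allclose(fitted.posterior(rec).probs, expected, atol=1e-12)


def test_predict_argmax_and_tie_rule():
    model = FittedModel(classes=CLASSES, priors=np.array([0.5, 0.3, 0.2]),
                        submodels={})
    cls, post = predict(ProteinRecord(id="x"), model)
    assert cls == "RNA" and post.prob("RNA") == 0.5
    tied = FittedModel(classes=CLASSES, priors=np.array([0.4, 0.4, 0.2]),
                       submodels={})
    cls, _ = predict(ProteinRecord(id="y"), tied)
    assert cls == "RNA"  # exact tie breaks by fixed class order


def test_fold_family_without_spout_property(composition_table):
    """A model family lacking any SPOUT property judges a SPOUT-fold record
    by its other evidence: low pI pushes the prediction to protein even
    though every training SPOUT enzyme methylates RNA."""
    records = [
        ProteinRecord(id=r.id, fold_group=r.fold_group, label=r.label,
                      pi_global=5.5 if r.label == "PROTEIN"
                      else (8.5 if r.label == "RNA" else 7.0))
        for r in composition_table.records
    ]
    table = TrainingTable(records, classes=CLASSES)
    family = ModelFamily((
        PropertySpec("pi_global", "continuous", m=1),
        PropertySpec("SET", "categorical"),
        PropertySpec("other fold", "categorical"),
    ))
    fitted = fit_family(table, family, SearchConfig(seed=0))
    assert not fitted.failed
    spout_low_pi = ProteinRecord(id="candidate", fold_group="SPOUT", pi_global=5.2)
    cls, post = predict(spout_low_pi, fitted)
    assert cls == "PROTEIN"
    assert "SPOUT" not in post.used_properties


def test_posterior_sums_to_one_and_permutation_invariance():
    subs = {
        "SET": _cat("SET", [0.02, 0.33, 0.04]),
        "R/C": _cat("R/C", [0.05, 0.05, 0.4]),
        "nucleolus": _cat("nucleolus", [0.3, 0.01, 0.01]),
    }
    m_fwd = FittedModel(classes=CLASSES, priors=PRIORS, submodels=dict(subs))
    m_rev = FittedModel(classes=CLASSES, priors=PRIORS,
                        submodels=dict(reversed(list(subs.items()))))
    rec = ProteinRecord(id="x", fold_group="SET", ymc_cluster="R/C",
                        localization_class="OTHER_LOC")
    p_fwd, p_rev = posterior(rec, m_fwd), posterior(rec, m_rev)
    assert abs(p_fwd.probs.sum() - 1.0) < 1e-12
    assert np.allclose(p_fwd.probs, p_rev.probs, atol=1e-15)
    assert sorted(p_fwd.used_properties) == sorted(p_rev.used_properties)


def test_monotone_evidence():
    """Raising one likelihood ratio toward a class never lowers that class's
    posterior."""
    rec = ProteinRecord(id="x", fold_group="SET")
    last = 0.0
    for p_set_protein in (0.1, 0.3, 0.5, 0.7, 0.9):
        model = FittedModel(
            classes=CLASSES, priors=PRIORS,
            submodels={"SET": _cat("SET", [0.05, p_set_protein, 0.05])})
        prob = posterior(rec, model).prob("PROTEIN")
        assert prob >= last
        last = prob


def test_training_log_likelihood_closed_forms(composition_table):
    priors_only = FittedModel(classes=CLASSES,
                              priors=composition_table.priors, submodels={})
    expected = (26 * math.log(26 / 61) + 24 * math.log(24 / 61)
                + 11 * math.log(11 / 61))
    assert training_log_likelihood(composition_table, priors_only) == pytest.approx(
        expected, abs=1e-9)

    uniform = FittedModel(classes=CLASSES, priors=np.ones(3) / 3, submodels={})
    one = TrainingTable([ProteinRecord(id="only", label="OTHER")], classes=CLASSES)
    assert training_log_likelihood(one, uniform) == pytest.approx(
        math.log(1 / 3), abs=1e-12)


def test_informative_property_improves_on_priors(composition_table):
    cfg = SearchConfig(seed=0)
    base = fit_family(composition_table, ModelFamily(()), cfg)
    with_fold = fit_family(
        composition_table, ModelFamily((PropertySpec("SET", "categorical"),)), cfg)
    assert with_fold.logL >= base.logL


def test_model_json_round_trip(tmp_path, composition_table):
    from mtasepred.data_model import load_model_json, save_model_json

    fitted = fit_family(
        composition_table,
        ModelFamily((PropertySpec("SET", "categorical"),
                     PropertySpec("fold_group", "categorical"))),
        SearchConfig(seed=0))
    path = tmp_path / "model.json"
    save_model_json(fitted, path)
    back = load_model_json(path)
    assert back.classes == fitted.classes
    assert back.aic == pytest.approx(fitted.aic, abs=1e-9)
    rec = ProteinRecord(id="x", fold_group="SET")
    assert np.allclose(back.posterior(rec).probs, fitted.posterior(rec).probs,
                       atol=1e-9)
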