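"""DeepLIFT Rescale engine, DeepSHAP averaging, fragment/atom mapping."""

import json

import numpy as np
import pytest
from scipy.stats import spearmanr

from rxnlift.attribution import (
    AbsentFragment,
    BackgroundSet,
    PresentFragment,
    atom_contributions,
    deeplift_rescale,
    deepshap_contributions,
    explain_reaction,
    explanation_to_json,
    sample_background,
    split_fragment_contributions,
)
from rxnlift.classifier import ModelBundle
from rxnlift.drfp import FingerprintParams, FragmentOccurrence, MappedFingerprint
from rxnlift.errors import InputError, UnsupportedActivationError

from conftest import random_relu_net


# ---------------------------------------------------------------------------
# Rescale rule
# ---------------------------------------------------------------------------

def test_zero_delta_gives_zero_contributions():
    rng = np.random.default_rng(0)
    model = random_relu_net(rng)
    x = rng.random(model.W1.shape[0])
    c = deeplift_rescale(model, x, x, 0)
    assert np.all(c == 0.0)


def test_linear_regime_matches_closed_form():
    """With hidden pre-activations forced positive, the network is linear and
    contributions reduce to (combined weight) * (x - ref)."""
    rng = np.random.default_rng(1)
    d, h, c = 5, 4, 3
    model = ModelBundle(
        W1=rng.standard_normal((d, h)),
        b1=np.full(h, 100.0),  # ReLU always active
        W2=rng.standard_normal((h, c)),
        b2=np.zeros(c),
        hidden_activation="relu",
        label_vocabulary=["a", "b", "c"],
        fingerprint_params=FingerprintParams(dim=d),
    )
    x, ref = rng.random(d), rng.random(d)
    combined = model.W1 @ model.W2[:, 1]
    np.testing.assert_allclose(
        deeplift_rescale(model, x, ref, 1), (x - ref) * combined, atol=1e-12
    )


def test_completeness_on_random_networks():
    """sum(contributions) == score(x) - score(ref) for >= 50 random ReLU nets."""
    rng = np.random.default_rng(2)
    for _ in range(50):
        model = random_relu_net(rng)
        d = model.W1.shape[0]
        for _ in range(3):
            x, ref = rng.random(d), rng.random(d)
            ci = int(rng.integers(model.W2.shape[1]))
            contribs = deeplift_rescale(model, x, ref, ci)
            diff = model.logits(x)[0][ci] - model.logits(ref)[0][ci]
            assert abs(contribs.sum() - diff) < 1e-5


def test_rescale_requires_relu(fixture_model):
    bad = ModelBundle(
        W1=fixture_model.W1, b1=fixture_model.b1, W2=fixture_model.W2,
        b2=fixture_model.b2, hidden_activation="tanh",
        label_vocabulary=fixture_model.label_vocabulary,
        fingerprint_params=fixture_model.fingerprint_params,
    )
    with pytest.raises(UnsupportedActivationError):
        deeplift_rescale(bad, np.zeros(bad.W1.shape[0]), np.zeros(bad.W1.shape[0]), 0)


def test_dimension_mismatch_rejected(fixture_model):
    with pytest.raises(InputError):
        deeplift_rescale(fixture_model, np.zeros(3), np.zeros(3), 0)


# ---------------------------------------------------------------------------
# DeepSHAP averaging
# ---------------------------------------------------------------------------

def test_self_background_gives_zero(fixture_model, corpus_index):
    x = corpus_index.matrix[0].astype(np.float64)
    contribs, expected = deepshap_contributions(
        fixture_model, x, BackgroundSet(X=x[None, :]), 0
    )
    assert np.all(contribs == 0.0)
    assert expected == pytest.approx(float(fixture_model.logits(x)[0][0]))


def test_single_reference_background_degenerates_to_rescale(fixture_model, corpus_index):
    x = corpus_index.matrix[0].astype(np.float64)
    ref = corpus_index.matrix[1].astype(np.float64)
    a, _ = deepshap_contributions(fixture_model, x, BackgroundSet(X=ref[None, :]), 2)
    b = deeplift_rescale(fixture_model, x, ref, 2)
    np.testing.assert_allclose(a, b)


def test_averaged_completeness(fixture_model, corpus_index, background):
    for i in (0, 7, 21):
        x = corpus_index.matrix[i].astype(np.float64)
        for ci in range(3):
            contribs, expected = deepshap_contributions(fixture_model, x, background, ci)
            score = float(fixture_model.logits(x)[0][ci])
            assert abs(contribs.sum() - (score - expected)) < 1e-5


def test_background_sampling_is_seeded(corpus_index):
    X = corpus_index.matrix.astype(np.float64)
    a = sample_background(X, 10, seed=4)
    b = sample_background(X, 10, seed=4)
    np.testing.assert_array_equal(a.X, b.X)
    assert sample_background(X, 100, seed=0).X.shape[0] == X.shape[0]  # capped


def test_diagnostic_bit_dominates_true_class(
    cv_summary, fixture_records, corpus_index, background, diag_shingle_sets
):
    """For >= 90% of fixture reactions, the top positive present fragment of
    the true class is a diagnostic-derived shingle."""
    model = cv_summary.models[0]
    hits = 0
    for i, rec in enumerate(fixture_records):
        lab = rec.ec.render()
        ci = model.label_vocabulary.index(lab)
        contribs, _ = deepshap_contributions(
            model, corpus_index.matrix[i].astype(np.float64), background, ci
        )
        present, _ = split_fragment_contributions(
            contribs, corpus_index.fingerprints[i], corpus_index
        )
        top = max(present, key=lambda p: p.weight)
        hits += bool(set(top.fragments) & diag_shingle_sets[lab])
    assert hits >= 0.9 * len(fixture_records)


def test_attributions_are_label_sensitive(
    cv_summary, fixture_records, corpus_index, background
):
    """Contributions for two different classes on the same input rank-disagree
    on the most influential bits (diagnostic bits swap sign)."""
    model = cv_summary.models[0]
    x = corpus_index.matrix[0].astype(np.float64)
    ca, _ = deepshap_contributions(model, x, background, 0)
    cb, _ = deepshap_contributions(model, x, background, 1)
    top = np.argsort(-np.abs(ca))[:10]
    rho = spearmanr(ca[top], cb[top]).statistic
    assert rho < 0


def test_zeroing_top_positive_bit_lowers_score(
    fixture_model, corpus_index, background
):
    x = corpus_index.matrix[0].astype(np.float64)
    fp = corpus_index.fingerprints[0]
    ci = int(np.argmax(fixture_model.logits(x)[0]))
    contribs, _ = deepshap_contributions(fixture_model, x, background, ci)
    present, _ = split_fragment_contributions(contribs, fp, corpus_index)
    top_bit = max(present, key=lambda p: p.weight).bit
    x2 = x.copy()
    x2[top_bit] = 0.0
    assert fixture_model.logits(x2)[0][ci] < fixture_model.logits(x)[0][ci]


# ---------------------------------------------------------------------------
# Fragment / atom mapping
# ---------------------------------------------------------------------------

def _fp_stub(bit_to_fragments, occurrences, dim=32):
    bits = np.zeros(dim, dtype=np.uint8)
    for b in bit_to_fragments:
        bits[b] = 1
    return MappedFingerprint(
        bits=bits,
        on_bits=frozenset(bit_to_fragments),
        bit_to_fragments={b: set(fs) for b, fs in bit_to_fragments.items()},
        fragment_to_occurrences=occurrences,
        params=FingerprintParams(dim=dim),
    )


def test_split_present_absent(corpus_index):
    fp = corpus_index.fingerprints[0]
    contribs = np.zeros(fp.params.dim)
    on = sorted(fp.bit_to_fragments)
    contribs[on[0]] = 0.5
    off = [b for b in range(fp.params.dim) if b not in fp.bit_to_fragments]
    contribs[off[0]], contribs[off[1]] = -0.9, 0.1
    present, absent = split_fragment_contributions(contribs, fp, corpus_index, absent_top_k=5)
    assert {p.bit for p in present} == set(on)  # every on bit reported
    assert [a.bit for a in absent][:2] == [off[0], off[1]]  # ranked by |w|
    assert all(len(p.fragments) >= 1 for p in present)


def test_zero_contributions_give_no_absent_fragments(corpus_index):
    fp = corpus_index.fingerprints[0]
    _, absent = split_fragment_contributions(np.zeros(fp.params.dim), fp, corpus_index)
    assert absent == []


def test_collided_bit_lists_all_fragments():
    occ = {
        "CC": [FragmentOccurrence("CC", 0, frozenset({0, 1}), "reactant")],
        "OO": [FragmentOccurrence("OO", 1, frozenset({0, 1}), "product")],
    }
    fp = _fp_stub({3: {"CC", "OO"}}, occ)
    contribs = np.zeros(32)
    contribs[3] = 1.0
    present, _ = split_fragment_contributions(contribs, fp)
    assert present[0].collided and present[0].fragments == ("CC", "OO")


def test_atom_weight_examples():
    occ = {
        "f1": [FragmentOccurrence("f1", 0, frozenset({0, 1}), "reactant")],
        "f2": [FragmentOccurrence("f2", 0, frozenset({1, 2}), "reactant")],
    }
    fp = _fp_stub({1: {"f1"}, 2: {"f2"}}, occ)
    weights = atom_contributions(
        [PresentFragment(1, 0.2, ("f1",)), PresentFragment(2, -0.1, ("f2",))], fp
    )
    assert weights == {(0, 0): pytest.approx(0.2), (0, 1): pytest.approx(0.1),
                       (0, 2): pytest.approx(-0.1)}
    assert atom_contributions([], fp) == {}


def test_atom_weights_match_brute_force_double_loop():
    """Sum over atoms equals sum over bits of w * |covered atom union|."""
    rng = np.random.default_rng(9)
    for _ in range(20):
        occurrences, bit_map, present = {}, {}, []
        for b in range(int(rng.integers(1, 6))):
            frags = [f"frag{b}_{j}" for j in range(int(rng.integers(1, 3)))]
            bit_map[b] = set(frags)
            for f in frags:
                occurrences[f] = [
                    FragmentOccurrence(
                        f, int(rng.integers(2)),
                        frozenset(int(a) for a in rng.integers(0, 6, size=rng.integers(1, 4))),
                        "reactant",
                    )
                    for _ in range(int(rng.integers(1, 3)))
                ]
            present.append(PresentFragment(b, float(rng.normal()), tuple(sorted(frags))))
        fp = _fp_stub(bit_map, occurrences)
        weights = atom_contributions(present, fp)
        # brute force: per bit, union of covered atoms; each gets w once
        expected_total = 0.0
        for p in present:
            covered = set()
            for f in p.fragments:
                for o in occurrences[f]:
                    covered |= {(o.molecule_index, a) for a in o.atom_indices}
            expected_total += p.weight * len(covered)
        assert sum(weights.values()) == pytest.approx(expected_total)


# ---------------------------------------------------------------------------
# End-to-end explanation contract
# ---------------------------------------------------------------------------

def test_explanation_json_schema(fixture_model, fixture_records, corpus_index, background):
    rec = fixture_records[0]
    results = explain_reaction(
        fixture_model, rec, background, corpus=corpus_index, top_k_classes=2
    )
    assert [r.class_rank for r in results] == [1, 2]
    assert results[0].probability >= results[1].probability
    doc = json.loads(explanation_to_json(rec, results, model_id="m0"))
    assert doc["reaction_smiles"] == rec.reaction_smiles
    for entry in doc["explanations"]:
        assert set(entry) >= {"label", "rank", "probability", "expected_value",
                              "present", "absent", "atoms"}
        for a in entry["atoms"]:
            assert set(a) == {"molecule", "atom", "weight"}
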