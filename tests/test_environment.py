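import numpy as np
import pytest
from rdkit import Chem
from sklearn.model_selection import cross_val_score

from molgrow import (
    AffinityModel,
    Environment,
    MoleculeRecord,
    compute_descriptors,
    sa_score,
    train_affinity_model,
)
from molgrow.environment import DESCRIPTOR_LENGTH, N_FP_BITS, PHYSCHEM


class TestDescriptors:
    def test_vector_length_is_2067(self):
        vec = compute_descriptors(MoleculeRecord("CCO"))
        assert vec.shape == (DESCRIPTOR_LENGTH,) == (2067,)
        assert len(PHYSCHEM) == 19

    def test_fingerprint_bits_are_binary(self, small_library):
        for rec in small_library[:10]:
            bits = compute_descriptors(rec)[:N_FP_BITS]
            assert set(np.unique(bits)) <= {0.0, 1.0}

    def test_methane_counts(self):
        vec = compute_descriptors(MoleculeRecord("C"))
        named = dict(zip([n for n, _ in PHYSCHEM], vec[N_FP_BITS:]))
        assert named["heavy_atoms"] == 1
        assert named["total_rings"] == 0
        assert named["rotatable_bonds"] == 0

    def test_benzene_counts(self):
        vec = compute_descriptors(MoleculeRecord("c1ccccc1"))
        named = dict(zip([n for n, _ in PHYSCHEM], vec[N_FP_BITS:]))
        assert named["aromatic_rings"] == 1
        assert named["heteroatoms"] == 0
        assert named["valence_electrons"] == 30

    def test_deterministic(self):
        a = compute_descriptors(MoleculeRecord("CCc1ccccc1O"))
        b = compute_descriptors(MoleculeRecord("CCc1ccccc1O"))
        assert np.array_equal(a, b)


class TestSaScore:
    def test_range_and_monotone_flavor(self, small_library):
        for rec in small_library:
            s = sa_score(rec.mol())
            assert 1.0 <= s <= 10.0
        simple = sa_score(Chem.MolFromSmiles("CCO"))
        complex_ = sa_score(
            Chem.MolFromSmiles("CC12CC3(C)CC(C)(C1)CC(C2)C3")  # adamantane-like cage
        )
        assert complex_ > simple


class TestAffinityModel:
    def test_recovers_planted_signal(self, training_library):
        model = AffinityModel(n_estimators=100, random_state=0)
        X = training_library
        feats = np.stack([compute_descriptors(r) for r in X])
        y = np.array([r.pX for r in X])
        fitted = model.fit(X)
        scores = cross_val_score(fitted.model_, feats, y, cv=3, scoring="r2")
        assert scores.mean() > 0.3  # clearly beats the mean predictor

    def test_predictions_finite_and_deterministic(self, affinity_model, small_library):
        a = affinity_model.predict(small_library[:10])
        b = affinity_model.predict(small_library[:10])
        assert np.isfinite(a).all()
        assert np.array_equal(a, b)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            train_affinity_model([MoleculeRecord("CCO", pX=6.0)] * 10)

    def test_constant_activity_rejected(self):
        records = [
            MoleculeRecord("C" * (i + 1), pX=5.0) for i in range(30)
        ]
        with pytest.raises(ValueError):
            train_affinity_model(records)


class TestScoring:
    def test_desired_follows_inclusive_threshold(self, affinity_env, monkeypatch):
        env = affinity_env
        scored = env.score_population(["CCO"])
        # force the three boundary cases through a stub predictor
        class Stub:
            def __init__(self, value):
                self.value = value

            def predict(self, X):
                return np.full(len(X), self.value)

        for px, want in ((7.0, True), (6.5, True), (6.49, False)):
            stub_env = Environment(model=Stub(px), objectives=("affinity",))
            out = stub_env.score_population(["CCO", "c1ccccc1"])
            assert (out.desired == want).all()

    def test_invalid_smiles_get_worst_scores(self, affinity_env):
        out = affinity_env.score_population(["CCO", "not_a_smiles"])
        bad = out[~out.valid].iloc[0]
        assert not bad.desired
        assert bad.qed == 0.0 and bad.sa == 10.0

    def test_scoring_is_permutation_equivariant(self, affinity_env, small_library):
        smiles = [r.smiles for r in small_library[:12]]
        fwd = affinity_env.score_population(smiles)
        rev = affinity_env.score_population(smiles[::-1])
        assert list(fwd.affinity) == list(rev.affinity)[::-1]

    def test_qed_in_unit_interval(self, affinity_env, small_library):
        out = affinity_env.score_population([r.smiles for r in small_library[:12]])
        assert ((out.qed >= 0) & (out.qed <= 1)).all()

    def test_qed_cutoff_tightens_desirability(self, affinity_model, small_library):
        smiles = [r.smiles for r in small_library]
        plain = Environment(model=affinity_model).score_population(smiles)
        strict = Environment(
            model=affinity_model, qed_cutoff=1.0
        ).score_population(smiles)
        assert strict.desired.sum() <= plain.desired.sum()
        assert not strict.desired.any()
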