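"""Shared fixtures: a small diagnostic-fragment corpus, its encoding, one
cross-validated model set, and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from rdkit import Chem
from rdkit import RDLogger

from rxnlift.attribution import sample_background
from rxnlift.chem_io import default_fixture_config, generate_fixture_corpus
from rxnlift.classifier import TrainConfig, run_cv
from rxnlift.drfp import FingerprintParams, encode_corpus, extract_shingles

RDLogger.DisableLog("rdApp.*")

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Fixture corpus + encodings
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def fp_params():
    # fingerprint of reduced length: the shingle chemistry is identical, only
    # the folding space is smaller, which keeps test models small
    return FingerprintParams(dim=2048, radius=2)


@pytest.fixture(scope="session")
def fixture_config():
    return default_fixture_config(n_classes=3, n_per_class=10, seed=7)


@pytest.fixture(scope="session")
def fixture_records(fixture_config):
    return generate_fixture_corpus(fixture_config)


@pytest.fixture(scope="session")
def corpus_index(fixture_records, fp_params):
    return encode_corpus(fixture_records, fp_params)


@pytest.fixture(scope="session")
def diag_shingle_sets(fixture_config, fp_params):
    """Class label -> shingle SMILES unique to its diagnostic molecule.

    Generic shingles (a lone carbon, a lone hydrogen) also occur in the
    scaffold/co-substrate pools and cancel in the symmetric difference, so
    the class signature is the diagnostic's shingles minus every pool
    molecule's shingles.
    """
    pool_shingles = set()
    pool = set()
    for t in fixture_config.templates:
        pool.update(t.scaffolds)
    pool.update(fixture_config.cosubstrates)
    pool.update(fixture_config.byproducts)
    for smi in pool:
        pool_shingles.update(
            o.smiles for o in extract_shingles(Chem.MolFromSmiles(smi), fp_params)
        )
    out = {}
    for c, template in enumerate(fixture_config.templates, start=1):
        occ = extract_shingles(Chem.MolFromSmiles(template.diagnostic), fp_params)
        out[f"{c}.1.1"] = {o.smiles for o in occ} - pool_shingles
        assert out[f"{c}.1.1"], "diagnostic must have class-unique shingles"
    return out


@pytest.fixture(scope="session")
def train_config():
    # hidden layer and batch scaled to the 30-reaction corpus
    return TrainConfig(hidden_size=256, batch_size=8, seed=3)


@pytest.fixture(scope="session")
def cv_summary(fixture_records, fp_params, train_config, corpus_index):
    return run_cv(
        fixture_records,
        level=3,
        k=4,
        params=fp_params,
        config=train_config,
        X=corpus_index.matrix.astype(np.float32),
    )


@pytest.fixture(scope="session")
def fixture_model(cv_summary):
    return cv_summary.models[0]


@pytest.fixture(scope="session")
def background(corpus_index):
    return sample_background(corpus_index.matrix.astype(np.float64), 100, seed=1)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_shingles(mol, radius: int, include_hydrogens: bool) -> set[tuple[str, frozenset]]:
    """Distance-matrix enumeration of circular environments, independent of
    the production extractor's environment walker.

    Returns {(fragment SMILES, projected heavy-atom index set)}.  A radius-r
    environment exists only when it contains a bond absent at radius r-1.
    """
    n_heavy = mol.GetNumAtoms()
    work = Chem.AddHs(mol) if include_hydrogens else mol
    dm = Chem.GetDistanceMatrix(work)

    def project(atoms):
        out = set()
        for a in atoms:
            if a < n_heavy:
                out.add(a)
            else:
                out.add(work.GetAtomWithIdx(a).GetNeighbors()[0].GetIdx())
        return frozenset(out)

    results = set()
    bonds = [(b.GetIdx(), b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in work.GetBonds()]
    for center in range(work.GetNumAtoms()):
        results.add(
            (Chem.MolFragmentToSmiles(work, atomsToUse=[center]), project([center]))
        )
        prev_bonds: frozenset = frozenset()
        for r in range(1, radius + 1):
            sel = frozenset(
                bi for bi, a, b in bonds if min(dm[center][a], dm[center][b]) <= r - 1
            )
            if sel == prev_bonds:
                continue  # nothing new at this radius: environment absent
            prev_bonds = sel
            atoms = set()
            for bi, a, b in bonds:
                if bi in sel:
                    atoms.update((a, b))
            smiles = Chem.MolFragmentToSmiles(
                work, atomsToUse=sorted(atoms), bondsToUse=sorted(sel), canonical=True
            )
            results.add((smiles, project(atoms)))
    return results


def random_reaction_pool(rng: np.random.Generator, n: int) -> list[str]:
    """Random plausible reaction SMILES assembled from a small molecule pool."""
    pool = [
        "CCO", "CC=O", "CC(=O)O", "CCN", "C1CCCCC1", "c1ccccc1", "c1ccccc1O",
        "CC(C)O", "CCOC(C)=O", "OCC(O)CO", "NC(C)C(=O)O", "O", "CO", "N",
        "CSC", "C=CC=O", "OC1CCCCC1",
    ]
    reactions = []
    for _ in range(n):
        n_r = int(rng.integers(1, 3))
        n_p = int(rng.integers(1, 3))
        lhs = [pool[int(i)] for i in rng.integers(len(pool), size=n_r)]
        rhs = [pool[int(i)] for i in rng.integers(len(pool), size=n_p)]
        reactions.append(".".join(lhs) + ">>" + ".".join(rhs))
    return reactions


def rewrite_reaction(smiles: str, rng: np.random.Generator) -> str:
    """The same reaction written differently: atoms renumbered, SMILES
    emitted non-canonically, molecule order shuffled within each side."""
    parts = smiles.split(">")
    out_parts = []
    for part in parts:
        mols = []
        for token in part.split(".") if part else []:
            mol = Chem.MolFromSmiles(token)
            perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
            mol = Chem.RenumberAtoms(mol, perm)
            mols.append(Chem.MolToSmiles(mol, canonical=False))
        rng.shuffle(mols)
        out_parts.append(".".join(mols))
    return ">".join(out_parts)


def random_relu_net(rng: np.random.Generator):
    """A random small ReLU MLP bundle for attribution property checks."""
    from rxnlift.classifier import ModelBundle

    d = int(rng.integers(3, 9))
    h = int(rng.integers(2, 7))
    c = int(rng.integers(2, 5))
    return ModelBundle(
        W1=rng.standard_normal((d, h)),
        b1=rng.standard_normal(h),
        W2=rng.standard_normal((h, c)),
        b2=rng.standard_normal(c),
        hidden_activation="relu",
        label_vocabulary=[str(i) for i in range(c)],
        fingerprint_params=FingerprintParams(dim=d),
    )
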