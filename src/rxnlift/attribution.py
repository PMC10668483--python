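"""DeepLIFT (Rescale rule) feature attribution mapped back to fragments and atoms.

For the two-linear-layer ReLU MLP, a contribution of input feature ``v_i``
to the explained class score is computed against a reference input by
backpropagating multipliers: linear layers pass their weight matrices
through unchanged, and the hidden ReLU uses the Rescale rule

    m_h = (relu(z_h) - relu(z_ref_h)) / (z_h - z_ref_h)

with a gradient fallback when |z - z_ref| is tiny.  The contributions are
complete: they sum exactly (to float tolerance) to score(x) - score(ref).
Averaging over a background set of encoded training reactions (DeepSHAP
style) yields contributions against the expected model output.

Because every fingerprint bit remembers its fragment SMILES and atom
coverage, contributions split into *present* fragments (bit = 1 in this
reaction), *absent* fragments (bit = 0, but the corpus knows which
fragments hash there), and per-atom weights

    w_a = sum of w_f over present fragments whose occurrences cover atom a.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem_io import ReactionRecord
from .classifier import ModelBundle, predict_proba
from .drfp import CorpusIndex, MappedFingerprint, encode_reaction
from .errors import InputError, IntegrityError, UnsupportedActivationError

__all__ = [
    "BackgroundSet",
    "PresentFragment",
    "AbsentFragment",
    "AttributionResult",
    "sample_background",
    "deeplift_rescale",
    "deepshap_contributions",
    "split_fragment_contributions",
    "atom_contributions",
    "explain_reaction",
    "explanation_to_json",
]

_RESCALE_EPS = 1e-7


@dataclass
class BackgroundSet:
    """Encoded reactions whose mean prediction is the attribution baseline."""

    X: np.ndarray  # (n, dim)
    seed: Optional[int] = None
    source: str = "train"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.shape[0] < 1:
            raise InputError("background set must contain >= 1 sample")


def sample_background(
    X_train: np.ndarray, size: int = 100, seed: int = 0
) -> BackgroundSet:
    """Uniform sample without replacement from the training fold (default 100)."""
    X_train = np.atleast_2d(X_train)
    rng = np.random.default_rng(seed)
    n = min(size, X_train.shape[0])
    idx = rng.choice(X_train.shape[0], size=n, replace=False)
    return BackgroundSet(X=X_train[idx], seed=seed)


@dataclass(frozen=True)
class PresentFragment:
    bit: int
    weight: float
    fragments: tuple[str, ...]  # >1 entries = within-reaction bit collision

    @property
    def collided(self) -> bool:
        return len(self.fragments) > 1


@dataclass(frozen=True)
class AbsentFragment:
    bit: int
    weight: float
    candidates: tuple[str, ...]  # corpus-wide fragments hashing to this bit


@dataclass
class AttributionResult:
    class_label: str
    class_rank: int
    probability: float
    feature_contributions: np.ndarray
    expected_value: float
    present_fragments: list[PresentFragment] = field(default_factory=list)
    absent_fragments: list[AbsentFragment] = field(default_factory=list)
    atom_weights: dict[tuple[int, int], float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Core DeepLIFT
# --------------------------------------------------------------------------

def _check_model(model: ModelBundle) -> None:
    if model.hidden_activation != "relu":
        raise UnsupportedActivationError(
            f"Rescale-rule engine supports 'relu' hidden activation, "
            f"got {model.hidden_activation!r}"
        )


def deeplift_rescale(
    model: ModelBundle,
    x: np.ndarray,
    reference: np.ndarray,
    class_index: int,
    explain_probability: bool = False,
) -> np.ndarray:
    """Per-feature contributions to class score(x) - score(reference).

    The explained quantity is the pre-softmax class score by default, which
    makes completeness exact.  With ``explain_probability`` the contributions
    are rescaled so they sum to the softmax-probability difference instead.
    """
    _check_model(model)
    x = np.asarray(x, dtype=np.float64).ravel()
    reference = np.asarray(reference, dtype=np.float64).ravel()
    d = model.W1.shape[0]
    if x.shape[0] != d or reference.shape[0] != d:
        raise InputError(f"x/reference length must equal model input dim {d}")
    W1 = model.W1.astype(np.float64)
    W2c = model.W2[:, class_index].astype(np.float64)
    b1 = model.b1.astype(np.float64)

    z = x @ W1 + b1
    z_ref = reference @ W1 + b1
    dz = z - z_ref
    a, a_ref = np.maximum(z, 0.0), np.maximum(z_ref, 0.0)
    small = np.abs(dz) < _RESCALE_EPS
    m = np.where(small, (z > 0).astype(np.float64), np.divide(a - a_ref, np.where(small, 1.0, dz)))

    contrib = (x - reference) * (W1 @ (m * W2c))

    if explain_probability:
        # rescale through softmax so contributions sum to p(x) - p(ref);
        # an approximation (softmax couples classes), documented as such
        logits_x = model.logits(x)[0]
        logits_r = model.logits(reference)[0]
        s_diff = float(logits_x[class_index] - logits_r[class_index])
        p_diff = float(
            _softmax1(logits_x)[class_index] - _softmax1(logits_r)[class_index]
        )
        if abs(s_diff) >= _RESCALE_EPS:
            contrib = contrib * (p_diff / s_diff)
    return contrib


def _softmax1(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def deepshap_contributions(
    model: ModelBundle,
    x: np.ndarray,
    background: BackgroundSet,
    class_index: int,
    explain_probability: bool = False,
) -> tuple[np.ndarray, float]:
    """Mean-over-background DeepLIFT contributions and the expected value.

    Returns (feature_contributions, expected_value) where expected_value is
    the mean class score (or probability) over the background set, so
    completeness reads: sum(contribs) = score(x) - expected_value.
    """
    _check_model(model)
    refs = background.X
    contribs = np.zeros(model.W1.shape[0], dtype=np.float64)
    for ref in refs:
        contribs += deeplift_rescale(model, x, ref, class_index, explain_probability)
    contribs /= refs.shape[0]
    if explain_probability:
        outs = predict_proba(model, refs)[:, class_index]
    else:
        outs = model.logits(refs)[:, class_index]
    return contribs, float(np.mean(outs))


# --------------------------------------------------------------------------
# Fragment / atom mapping
# --------------------------------------------------------------------------

def split_fragment_contributions(
    contribs: np.ndarray,
    fp: MappedFingerprint,
    corpus: Optional[CorpusIndex] = None,
    absent_top_k: int = 10,
) -> tuple[list[PresentFragment], list[AbsentFragment]]:
    """Split per-bit contributions into present and absent fragments.

    Present: every on bit, carrying this reaction's fragment set for the bit
    (more than one SMILES = within-reaction collision, flagged not resolved).
    Absent: off bits ranked by |contribution|, top-k with non-zero weight,
    annotated with the corpus-wide candidate fragments for that bit.
    """
    contribs = np.asarray(contribs).ravel()
    if contribs.shape[0] != fp.params.dim:
        raise InputError("contribution vector length must equal fingerprint dim")
    present = [
        PresentFragment(bit=bit, weight=float(contribs[bit]), fragments=tuple(sorted(frags)))
        for bit, frags in sorted(fp.bit_to_fragments.items())
    ]
    global_map = corpus.global_bit_to_fragments if corpus is not None else {}
    off = [
        (abs(float(contribs[b])), b)
        for b in range(fp.params.dim)
        if b not in fp.bit_to_fragments and contribs[b] != 0.0
    ]
    off.sort(key=lambda t: (-t[0], t[1]))
    absent = [
        AbsentFragment(
            bit=b,
            weight=float(contribs[b]),
            candidates=tuple(sorted(global_map.get(b, ()))),
        )
        for _, b in off[:absent_top_k]
    ]
    return present, absent


def atom_contributions(
    present_fragments: Sequence[PresentFragment],
    fp: MappedFingerprint,
) -> dict[tuple[int, int], float]:
    """Per-atom weights: each atom sums the w_f of present fragments covering it.

    A bit's weight is counted once per atom in the union of all its
    fragments' occurrence atom sets (collisions are not split).  Keys are
    (molecule_index, atom_index); atoms covered by no fragment get 0 and are
    omitted.
    """
    weights: dict[tuple[int, int], float] = {}
    n_atoms_cache: dict[int, int] = {}
    for frag in present_fragments:
        covered: set[tuple[int, int]] = set()
        for smi in frag.fragments:
            for occ in fp.fragment_to_occurrences.get(smi, ()):
                for a in occ.atom_indices:
                    if a < 0:
                        raise IntegrityError(
                            f"occurrence of {smi!r} references atom {a}"
                        )
                    covered.add((occ.molecule_index, a))
        for key in covered:
            weights[key] = weights.get(key, 0.0) + frag.weight
    return weights


# --------------------------------------------------------------------------
# End-to-end explanation
# --------------------------------------------------------------------------

def explain_reaction(
    model: ModelBundle,
    record: ReactionRecord | str,
    background: BackgroundSet,
    corpus: Optional[CorpusIndex] = None,
    top_k_classes: int = 3,
    absent_top_k: int = 10,
    explain_probability: bool = False,
    fp: Optional[MappedFingerprint] = None,
) -> list[AttributionResult]:
    """Explain the top-k predicted classes of one reaction."""
    if fp is None:
        fp = encode_reaction(record, model.fingerprint_params)
    x = fp.bits.astype(np.float64)
    proba = predict_proba(model, x)[0]
    order = np.argsort(-proba, kind="stable")[:top_k_classes]
    results = []
    for rank, ci in enumerate(order, start=1):
        contribs, expected = deepshap_contributions(
            model, x, background, int(ci), explain_probability
        )
        present, absent = split_fragment_contributions(contribs, fp, corpus, absent_top_k)
        atoms = atom_contributions(present, fp)
        results.append(
            AttributionResult(
                class_label=model.label_vocabulary[int(ci)],
                class_rank=rank,
                probability=float(proba[ci]),
                feature_contributions=contribs,
                expected_value=expected,
                present_fragments=present,
                absent_fragments=absent,
                atom_weights=atoms,
            )
        )
    return results


def explanation_to_json(
    record: ReactionRecord | str,
    results: Sequence[AttributionResult],
    model_id: str = "",
) -> str:
    """Serialise explanations to the JSON contract consumed by depiction/CLI."""
    smiles = record if isinstance(record, str) else record.reaction_smiles
    doc = {
        "reaction_smiles": smiles,
        "model_id": model_id,
        "explanations": [
            {
                "label": r.class_label,
                "rank": r.class_rank,
                "probability": r.probability,
                "expected_value": r.expected_value,
                "present": [
                    {
                        "smiles": list(p.fragments),
                        "bit": p.bit,
                        "weight": p.weight,
                        "collisions": p.collided,
                    }
                    for p in r.present_fragments
                ],
                "absent": [
                    {"bit": a.bit, "weight": a.weight, "candidates": list(a.candidates)}
                    for a in r.absent_fragments
                ],
                "atoms": [
                    {"molecule": m, "atom": a, "weight": w}
                    for (m, a), w in sorted(r.atom_weights.items())
                ],
            }
            for r in results
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)
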