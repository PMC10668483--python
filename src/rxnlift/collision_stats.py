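"""Hash- and folding-collision accounting for the fragment fingerprint.

Hashing fragment SMILES to 32-bit integers can collide (birthday problem);
folding those integers modulo the fingerprint length collides far more
often.  Both regimes are quantified here: the analytic expectation for the
hash stage and exact empirical counts for the folding stage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .drfp import CorpusIndex
from .errors import InputError

__all__ = [
    "CollisionEstimate",
    "expected_hash_collisions",
    "count_multi_fragment_bits",
    "count_within_reaction_collisions",
]

HASH_SPACE_32 = 2**32


@dataclass(frozen=True)
class CollisionEstimate:
    n_fragments: int
    hash_space: int
    expected_pair_collisions: float

    def rounded(self, digits: int = 2) -> float:
        return round(self.expected_pair_collisions, digits)


def expected_hash_collisions(n: int, hash_space: int = HASH_SPACE_32) -> float:
    """Expected number of colliding pairs among n uniform draws from
    ``hash_space`` buckets: n(n-1) / (2 * hash_space).

    This is the birthday-problem pair count; for n << hash_space it agrees
    with the occupancy form n - M(1 - (1 - 1/M)^n) to relative order n/M.
    """
    if n < 0 or hash_space < 1:
        raise InputError("need n >= 0 and hash_space >= 1")
    return n * (n - 1) / (2.0 * hash_space)


def estimate(n: int, hash_space: int = HASH_SPACE_32) -> CollisionEstimate:
    return CollisionEstimate(n, hash_space, expected_hash_collisions(n, hash_space))


def count_multi_fragment_bits(corpus: CorpusIndex) -> int:
    """Number of fingerprint entries representing more than one fragment
    corpus-wide (folding collisions)."""
    return sum(1 for frags in corpus.global_bit_to_fragments.values() if len(frags) >= 2)


def count_within_reaction_collisions(corpus: CorpusIndex) -> tuple[int, float]:
    """(count, fraction) of same-bit fragment co-occupation inside reactions.

    count: number of (reaction, bit) pairs where two or more of that
    reaction's own present fragments share the bit; fraction: reactions
    affected / total reactions.  Requires the corpus to have been built with
    per-reaction fingerprints retained.
    """
    if not corpus.fingerprints:
        raise InputError(
            "corpus was built without per-reaction fingerprints "
            "(encode_corpus(..., keep_fingerprints=True))"
        )
    count = 0
    affected = 0
    for fp in corpus.fingerprints:
        hits = sum(1 for frags in fp.bit_to_fragments.values() if len(frags) >= 2)
        count += hits
        if hits:
            affected += 1
    return count, affected / len(corpus.fingerprints)
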