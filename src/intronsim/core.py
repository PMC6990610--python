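"""Sequence primitives and the stochastic edit operators the simulators build on.

Sequences are immutable value objects over the DNA alphabet whose first and
last two bases are pinned to ``GT``/``AG``, mimicking the canonical splice
sites of a spliceosomal intron.  Three elementary events act on them:

* point substitution, driven by a transition/transversion-biased sampler
  (transition probability ``R/(R+1)`` at every event),
* deletion of one contiguous internal block,
* insertion of one contiguous block of uniform random bases at an internal
  junction.

All randomness is drawn from caller-supplied :class:`numpy.random.Generator`
streams, so a whole simulation replays bit-for-bit from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHABET",
    "Sequence",
    "SubstitutionSampler",
    "MutationLedger",
    "AlphabetError",
    "InvalidLengthError",
    "InfeasibleEventError",
    "RangeError",
    "random_sequence",
    "cap_termini",
    "substitute_base",
    "mutate",
    "delete_block",
    "insert_block",
    "draw_from_range",
]

ALPHABET = "ACGT"

# base codes: A=0 C=1 G=2 T=3; transition partner = code ^ 2 (A<->G, C<->T)
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CODE_OF[ord(_c)] = _i


class AlphabetError(ValueError):
    """A character outside {A,C,G,T} was encountered."""


class InvalidLengthError(ValueError):
    """Sequence too short to carry GT...AG termini (minimum 4 bases)."""


class InfeasibleEventError(ValueError):
    """An edit event cannot be applied to the current sequence."""


class RangeError(ValueError):
    """An integer range with lo > hi."""


def encode(bases: str) -> np.ndarray:
    """Map a base string to a uint8 code array (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    codes = _CODE_OF[raw]
    if codes.size and codes.max() == 255:
        bad = sorted(set(bases) - set(ALPHABET))
        raise AlphabetError(f"invalid base symbol(s): {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _BASE_BYTES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class Sequence:
    """An unaligned nucleotide string with an identifying label.

    Labels follow the species-abbreviation-plus-target-length convention
    ("Cm376") for tree leaves, or "AS_1" ... for ancestral nodes.
    """

    bases: str
    id: str = ""

    def __post_init__(self) -> None:
        encode(self.bases)  # alphabet check only

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_capped(self) -> bool:
        return (
            len(self.bases) >= 4
            and self.bases[:2] == "GT"
            and self.bases[-2:] == "AG"
        )

    def with_bases(self, bases: str) -> "Sequence":
        return Sequence(bases, self.id)


@dataclass
class SubstitutionSampler:
    """Draws replacement bases with transition probability ``R/(R+1)``.

    ``R`` is the transition/transversion ratio; the two possible
    transversions of a base are equiprobable.  ``R=0`` never produces a
    transition; large ``R`` almost always does.
    """

    R: float = 1.5
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def p_transition(self) -> float:
        return self.R / (self.R + 1.0)

    def substitute_codes(self, codes: np.ndarray) -> tuple[np.ndarray, int, int]:
        """Vectorised substitution of every code; returns (new, n_ts, n_tv)."""
        n = codes.size
        is_ts = self.rng.random(n) < self.p_transition
        choice = self.rng.integers(0, 2, n).astype(np.uint8)
        ts_partner = codes ^ 2
        # transversion partners: purines {A,G} <-> pyrimidines {C,T}
        tv_partner = (((codes & 1) ^ 1) + 2 * choice).astype(np.uint8)
        new = np.where(is_ts, ts_partner, tv_partner).astype(np.uint8)
        n_ts = int(is_ts.sum())
        return new, n_ts, n - n_ts


@dataclass
class MutationLedger:
    """Bookkeeping of substitution events: counts by class and site indices."""

    n_transitions: int = 0
    n_transversions: int = 0
    positions: list[int] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.n_transitions + self.n_transversions

    @property
    def ratio(self) -> float:
        """Observed ts/tv ratio (nan when no transversions recorded)."""
        if self.n_transversions == 0:
            return float("nan")
        return self.n_transitions / self.n_transversions

    def record(self, positions: np.ndarray, n_ts: int, n_tv: int) -> None:
        self.positions.extend(int(p) for p in positions)
        self.n_transitions += n_ts
        self.n_transversions += n_tv

    def absorb(self, other: "MutationLedger") -> None:
        self.positions.extend(other.positions)
        self.n_transitions += other.n_transitions
        self.n_transversions += other.n_transversions


def _check_length(length: int) -> None:
    if length < 4:
        raise InvalidLengthError(f"length {length} < 4 cannot carry GT...AG termini")


def _cap_codes(codes: np.ndarray) -> np.ndarray:
    codes[0], codes[1] = 2, 3  # G T
    codes[-2], codes[-1] = 0, 2  # A G
    return codes


def random_sequence(length: int, rng: np.random.Generator, id: str = "") -> Sequence:
    """A sequence of ``length`` i.i.d. uniform bases, terminally capped."""
    _check_length(length)
    codes = rng.integers(0, 4, length).astype(np.uint8)
    return Sequence(decode(_cap_codes(codes)), id)


def cap_termini(seq: Sequence) -> Sequence:
    """Overwrite the first two bases with GT and the last two with AG."""
    _check_length(len(seq))
    return seq.with_bases(decode(_cap_codes(encode(seq.bases))))


def substitute_base(base: str, sampler: SubstitutionSampler) -> str:
    """Replace one base; never returns the input base."""
    code = encode(base)
    if code.size != 1:
        raise AlphabetError("substitute_base expects a single base")
    new, _, _ = sampler.substitute_codes(code)
    return decode(new)


def mutate(
    seq: Sequence,
    n: int,
    sampler: SubstitutionSampler,
    protect_termini: bool = True,
) -> tuple[Sequence, MutationLedger]:
    """Substitute ``n`` distinct positions chosen uniformly without replacement.

    With ``protect_termini`` (the default) only internal positions
    ``[2, len-2)`` are eligible, so the GT/AG caps survive every call.
    """
    ledger = MutationLedger()
    if n == 0:
        return seq, ledger
    length = len(seq)
    offset = 2 if protect_termini else 0
    n_mutable = length - 4 if protect_termini else length
    if n > n_mutable:
        raise InfeasibleEventError(
            f"cannot mutate {n} positions: only {n_mutable} mutable"
        )
    positions = sampler.rng.choice(n_mutable, size=n, replace=False) + offset
    codes = encode(seq.bases)
    new, n_ts, n_tv = sampler.substitute_codes(codes[positions])
    codes[positions] = new
    ledger.record(positions, n_ts, n_tv)
    return seq.with_bases(decode(codes)), ledger


def delete_block(seq: Sequence, block_len: int, rng: np.random.Generator) -> Sequence:
    """Remove one contiguous internal block of ``block_len`` bases.

    The start position is uniform over all placements that leave the GT/AG
    termini untouched.
    """
    if block_len == 0:
        return seq
    length = len(seq)
    if block_len > length - 4:
        raise InfeasibleEventError(
            f"cannot delete {block_len} bases from length {length} (termini preserved)"
        )
    start = int(rng.integers(2, length - 2 - block_len + 1))
    codes = encode(seq.bases)
    return seq.with_bases(decode(np.delete(codes, np.s_[start : start + block_len])))


def insert_block(seq: Sequence, block_len: int, rng: np.random.Generator) -> Sequence:
    """Insert ``block_len`` i.i.d. uniform bases at a uniform internal junction."""
    if block_len < 0:
        raise InfeasibleEventError("negative insertion length")
    if block_len == 0:
        return seq
    length = len(seq)
    _check_length(length)
    junction = int(rng.integers(2, length - 1))
    block = rng.integers(0, 4, block_len).astype(np.uint8)
    codes = encode(seq.bases)
    return seq.with_bases(decode(np.insert(codes, junction, block)))


def draw_from_range(lo: int, hi: int, rng: np.random.Generator) -> int:
    """Uniform integer on [lo, hi] inclusive."""
    if lo > hi:
        raise RangeError(f"empty range [{lo}, {hi}]")
    return int(rng.integers(lo, hi + 1))
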