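"""Core data types and per-clonal-family profile construction.

A clonal family (CF) is a set of equal-length heavy-chain amino-acid
sequences descending from one inferred naive ancestor.  All profiles live on
a fixed 149-position antibody numbering coordinate system (the AHo scheme),
so that sequences of different lengths are comparable: each CF carries a
strictly increasing ``numbering`` vector mapping its sequence positions onto
1..149.  Positions of the coordinate system not touched by any sequence of a
CF are *undefined* (gap) positions; they are represented by an explicit
boolean mask plus all-zero frequency rows, and are excluded from every loss
and metric downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Number of positions in the fixed antibody numbering scheme.
N_POSITIONS = 149

#: The 20 standard one-letter amino-acid codes, alphabetically ordered, so
#: that index 0 is alanine.
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
N_AA = len(AA_LETTERS)
AA_INDEX = {aa: i for i, aa in enumerate(AA_LETTERS)}

DNA_BASES = "ACGT"

#: Default minimum number of unique amino-acid sequences a CF must contain.
DEFAULT_MIN_UNIQUE = 5
#: Default width (in nt) of the read edges within which ambiguous bases are
#: tolerated (the length of potentially masked PCR primers).
DEFAULT_EDGE_WINDOW = 30


class AmbiguityError(ValueError):
    """An ambiguous base occurs outside the tolerated edge windows."""


class AlphabetError(ValueError):
    """A residue is not one of the 20 standard amino acids."""


@dataclass(frozen=True)
class AminoAlphabet:
    """Ordered amino-acid alphabet defining the column order of profiles."""

    symbols: tuple[str, ...] = tuple(AA_LETTERS)

    def __post_init__(self) -> None:
        if len(self.symbols) != 20 or len(set(self.symbols)) != 20:
            raise ValueError("alphabet must contain exactly 20 distinct symbols")
        if self.symbols[0] != "A":
            raise ValueError("first alphabet symbol must be alanine ('A')")

    def index(self, aa: str) -> int:
        try:
            return self.symbols.index(aa)
        except ValueError:
            raise AlphabetError(f"residue {aa!r} not in amino-acid alphabet") from None

    def __len__(self) -> int:
        return 20


DEFAULT_ALPHABET = AminoAlphabet()


@dataclass(frozen=True)
class ClonalFamily:
    """A clonal family: sequences plus naive ancestor and annotation.

    Parameters
    ----------
    cf_id, donor_id
        Opaque identifiers; a CF is defined by its naive sequence and donor.
    sequences
        Equal-length amino-acid sequences (the observed CF members).
    naive_aa, naive_dna
        Inferred naive ancestor at amino-acid and nucleotide level
        (``len(naive_dna) == 3 * len(naive_aa)``).
    v_gene, v_subgroup
        Germline V annotation labels (opaque strings).
    numbering
        Strictly increasing 1-based positions in 1..149, one per sequence
        position, shared by every member (no indels allowed).
    """

    cf_id: str
    donor_id: str
    sequences: tuple[str, ...]
    naive_aa: str
    naive_dna: str
    v_gene: str
    v_subgroup: str
    numbering: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        object.__setattr__(self, "numbering", tuple(int(j) for j in self.numbering))
        L = len(self.naive_aa)
        if len(self.naive_dna) != 3 * L:
            raise ValueError(
                f"CF {self.cf_id}: naive_dna length {len(self.naive_dna)} != 3*{L}"
            )
        for seq in self.sequences:
            if len(seq) != L:
                raise ValueError(
                    f"CF {self.cf_id}: sequence length {len(seq)} != naive length {L}"
                )
        if len(self.numbering) != L:
            raise ValueError(f"CF {self.cf_id}: numbering length != sequence length")
        nums = self.numbering
        if any(not (1 <= j <= N_POSITIONS) for j in nums):
            raise ValueError(f"CF {self.cf_id}: numbering outside 1..{N_POSITIONS}")
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"CF {self.cf_id}: numbering not strictly increasing")

    @property
    def length(self) -> int:
        return len(self.naive_aa)

    def replace_sequences(self, sequences: Iterable[str]) -> "ClonalFamily":
        return ClonalFamily(
            self.cf_id,
            self.donor_id,
            tuple(sequences),
            self.naive_aa,
            self.naive_dna,
            self.v_gene,
            self.v_subgroup,
            self.numbering,
        )


@dataclass
class SubstitutionProfile:
    """Site-wise amino-acid frequency matrix on the 149-position system.

    ``freqs`` is a (149, 20) array; rows at ``defined`` positions sum to 1,
    rows at undefined positions are all zeros.
    """

    freqs: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.freqs.shape != (N_POSITIONS, N_AA):
            raise ValueError(f"freqs must be ({N_POSITIONS}, {N_AA})")
        if self.defined.shape != (N_POSITIONS,):
            raise ValueError(f"defined must be ({N_POSITIONS},)")

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.freqs < -atol) or np.any(self.freqs > 1 + atol):
            raise ValueError("frequencies outside [0, 1]")
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums[self.defined], 1.0, atol=atol):
            raise ValueError("defined rows must sum to 1")
        if np.any(self.freqs[~self.defined] != 0.0):
            raise ValueError("undefined rows must be all zeros")

    @classmethod
    def one_hot(cls, aa_seq: str, numbering: Sequence[int],
                alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> "SubstitutionProfile":
        """Profile of a single sequence: zeros and ones."""
        freqs = np.zeros((N_POSITIONS, N_AA))
        defined = np.zeros(N_POSITIONS, dtype=bool)
        for aa, j in zip(aa_seq, numbering):
            freqs[j - 1, alphabet.index(aa)] = 1.0
            defined[j - 1] = True
        return cls(freqs, defined)


@dataclass
class ProfileTensor:
    """A stack of substitution profiles over ``n_cf`` clonal families.

    ``freqs`` has shape (n_cf, 149, 20) and ``defined`` (n_cf, 149).
    """

    freqs: np.ndarray
    defined: np.ndarray
    cf_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        n = self.freqs.shape[0]
        if n < 1:
            raise ValueError("tensor must contain at least one CF")
        if self.freqs.shape != (n, N_POSITIONS, N_AA):
            raise ValueError("freqs must have shape (n_cf, 149, 20)")
        if self.defined.shape != (n, N_POSITIONS):
            raise ValueError("defined must have shape (n_cf, 149)")
        if not self.cf_ids:
            self.cf_ids = tuple(f"cf{i}" for i in range(n))
        self.cf_ids = tuple(self.cf_ids)
        if len(self.cf_ids) != n:
            raise ValueError("cf_ids length mismatch")
        if len(set(self.cf_ids)) != n:
            raise ValueError("cf_ids must be unique")

    def __len__(self) -> int:
        return self.freqs.shape[0]

    def profile(self, i: int) -> SubstitutionProfile:
        return SubstitutionProfile(self.freqs[i].copy(), self.defined[i].copy())

    @classmethod
    def from_profiles(cls, profiles: Sequence[SubstitutionProfile],
                      cf_ids: Sequence[str] | None = None) -> "ProfileTensor":
        freqs = np.stack([p.freqs for p in profiles])
        defined = np.stack([p.defined for p in profiles])
        return cls(freqs, defined, tuple(cf_ids) if cf_ids else ())

    def subset(self, idx: Sequence[int]) -> "ProfileTensor":
        idx = np.asarray(idx, dtype=int)
        return ProfileTensor(self.freqs[idx], self.defined[idx],
                             tuple(self.cf_ids[i] for i in idx))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def dedup_and_filter(cfs: Iterable[ClonalFamily],
                     min_unique: int = DEFAULT_MIN_UNIQUE) -> list[ClonalFamily]:
    """De-duplicate amino-acid sequences within each CF and drop small CFs.

    Duplicate sequences are removed within each CF (first occurrence kept,
    order preserved); CFs with fewer than ``min_unique`` unique sequences
    are discarded.  Input order of CFs is preserved.
    """
    if min_unique < 1:
        raise ValueError("min_unique must be >= 1")
    out: list[ClonalFamily] = []
    for cf in cfs:
        unique = list(dict.fromkeys(cf.sequences))
        if len(unique) < min_unique:
            logger.debug("dropping CF %s: %d unique sequences < %d",
                         cf.cf_id, len(unique), min_unique)
            continue
        out.append(cf if len(unique) == len(cf.sequences)
                   else cf.replace_sequences(unique))
    return out


def resolve_ambiguous_dna(seq_dna: str, naive_dna: str,
                          edge_window: int = DEFAULT_EDGE_WINDOW) -> str:
    """Resolve ambiguous bases by substituting whole codons from the naive.

    Ambiguous bases (anything outside ACGT, e.g. N from primer masking) are
    tolerated only within the first or last ``edge_window`` nucleotides;
    otherwise :class:`AmbiguityError` is raised (the read is rejected).  Every
    codon containing at least one ambiguity is replaced wholesale by the
    aligned naive codon.
    """
    if len(seq_dna) != len(naive_dna):
        raise ValueError("sequence and naive DNA lengths differ")
    seq_dna = seq_dna.upper()
    L = len(seq_dna)
    ambiguous = [i for i, b in enumerate(seq_dna) if b not in DNA_BASES]
    if not ambiguous:
        return seq_dna
    for i in ambiguous:
        if i >= edge_window and i < L - edge_window:
            raise AmbiguityError(
                f"ambiguous base at position {i + 1} outside the "
                f"first/last {edge_window} nt"
            )
    codons = [seq_dna[i:i + 3] for i in range(0, L, 3)]
    for i in ambiguous:
        c = i // 3
        codons[c] = naive_dna[3 * c:3 * c + 3]
    return "".join(codons)


def count_profile(cf: ClonalFamily,
                  alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """Amino-acid usage counts of a CF as a (149, 20) integer matrix.

    Each sequence contributes one count per mapped position; positions not
    covered by the CF numbering stay all-zero.
    """
    counts = np.zeros((N_POSITIONS, N_AA), dtype=np.int64)
    cols = np.array([j - 1 for j in cf.numbering], dtype=int)
    for seq in cf.sequences:
        rows = np.array([alphabet.index(aa) for aa in seq], dtype=int)
        np.add.at(counts, (cols, rows), 1)
    return counts


def normalize(counts: np.ndarray) -> SubstitutionProfile:
    """Normalize a count matrix to a frequency profile.

    Rows with positive totals become frequency vectors summing to 1; all-zero
    rows are flagged undefined.
    """
    counts = np.asarray(counts)
    if counts.shape != (N_POSITIONS, N_AA):
        raise ValueError(f"counts must be ({N_POSITIONS}, {N_AA})")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    defined = totals > 0
    freqs = np.zeros((N_POSITIONS, N_AA))
    freqs[defined] = counts[defined] / totals[defined, None]
    return SubstitutionProfile(freqs, defined)


def cf_profile(cf: ClonalFamily,
               alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> SubstitutionProfile:
    """Convenience: normalized substitution profile of a clonal family."""
    return normalize(count_profile(cf, alphabet))
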