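"""Context-sensitive neutral somatic-hypermutation (SHM) simulator.

Somatic hypermutation targets DNA non-uniformly: the mutability of a site
and the distribution of its substitutions depend on the surrounding 5-mer
nucleotide context (hot/cold spots such as WRC/GYW).  Given a naive DNA
sequence and an observed SHM count ``m``, this module repeatedly introduces
``m`` mutations sequentially — each time sampling a site proportionally to
the *current* sequence's 5-mer mutabilities and a target base from that
site's substitution distribution, then recomputing the affected contexts —
translates each mutated replicate, and aggregates the amino-acid counts
into the "neutral" substitution profile: what the clonal family would look
like under SHM alone, with no selection.

The 5-mer model is user-supplied as a TSV table (mutability plus a
probability vector over the three alternative bases per 5-mer); a uniform
synthetic model is available for testing.  Sequence-edge contexts are padded
with N and resolved by averaging over all compatible fully-determined
5-mers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .profiles import AA_INDEX, DNA_BASES, N_AA, N_POSITIONS, SubstitutionProfile

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}
_N_CODE = 4  # padding symbol in the base-5 5-mer encoding

_POW5 = 5 ** np.arange(4, -1, -1)


def _codon_table() -> np.ndarray:
    """(4, 4, 4) int8 array mapping codon base indices to amino-acid index
    (-1 for stop codons), via the standard genetic code."""
    tab = np.zeros((4, 4, 4), dtype=np.int8)
    for i, a in enumerate(DNA_BASES):
        for j, b in enumerate(DNA_BASES):
            for k, c in enumerate(DNA_BASES):
                aa = str(Seq(a + b + c).translate())
                tab[i, j, k] = AA_INDEX.get(aa, -1)
    return tab


_CODON_TABLE = _codon_table()


def translate_dna(dna: str) -> str:
    """Translate unambiguous DNA (length divisible by 3); '*' marks stops."""
    return str(Seq(dna).translate())


def count_shm(seq_dna: str, naive_dna: str) -> int:
    """Number of somatic hypermutations: nucleotide Hamming distance."""
    if len(seq_dna) != len(naive_dna):
        raise ValueError("sequences must have equal length")
    return sum(a != b for a, b in zip(seq_dna.upper(), naive_dna.upper()))


@dataclass
class ContextModel:
    """5-mer mutability and substitution model.

    ``mutability`` maps each fully-determined 5-mer (ACGT alphabet) to a
    nonnegative targeting weight; ``substitution`` maps it to a length-4
    probability vector over target bases (A, C, G, T order) with zero mass
    on the center base itself.  Lookup tables over the base-5 (ACGTN)
    encoding are compiled on first use, with N entries averaged over all
    compatible fully-determined 5-mers.
    """

    mutability: dict[str, float]
    substitution: dict[str, tuple[float, float, float, float]]
    _mut5: np.ndarray | None = field(default=None, repr=False)
    _sub5: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for fm, row in self.substitution.items():
            row = np.asarray(row, dtype=float)
            if row.shape != (4,):
                raise ValueError(f"substitution row for {fm} must have 4 entries")
            if abs(row.sum() - 1.0) > 1e-6:
                raise ValueError(f"substitution row for {fm} must sum to 1")
            if row[_BASE_INDEX[fm[2]]] != 0.0:
                raise ValueError(f"self-transition must be 0 for {fm}")
        missing = [fm for fm in self.mutability if fm not in self.substitution]
        if missing:
            raise ValueError(f"5-mers lacking substitution rows: {missing[:5]}")

    def _compile(self) -> None:
        mut = np.full((5,) * 5, np.nan)
        sub = np.full((5,) * 5 + (4,), np.nan)
        for fm, w in self.mutability.items():
            idx = tuple(_BASE_INDEX[b] for b in fm)
            mut[idx] = w
            sub[idx] = np.asarray(self.substitution[fm], dtype=float)
        if np.isnan(mut[:4, :4, :4, :4, :4]).any():
            raise ValueError("model must resolve all 1024 fully-determined 5-mers")
        # Average over N positions one axis at a time (flanks only; the
        # center base of a real sequence is never ambiguous).
        for axis in (0, 1, 3, 4):
            idx_n = [slice(None)] * 5
            idx_n[axis] = 4
            idx_d = [slice(None)] * 5
            idx_d[axis] = slice(0, 4)
            mut[tuple(idx_n)] = mut[tuple(idx_d)].mean(axis=axis)
            sub[tuple(idx_n)] = sub[tuple(idx_d)].mean(axis=axis)
        # Renormalize substitution rows (averaging preserves the zero on the
        # center base, but guard against numerical drift).  Rows whose
        # center base is N stay NaN: a real sequence never queries them.
        tot = sub.sum(axis=-1, keepdims=True)
        ok = np.isfinite(tot) & (tot > 0)
        sub = np.divide(sub, tot, out=np.full_like(sub, np.nan), where=ok)
        self._mut5 = mut.reshape(-1)
        self._sub5 = sub.reshape(-1, 4)

    @property
    def mut5(self) -> np.ndarray:
        if self._mut5 is None:
            self._compile()
        return self._mut5

    @property
    def sub5(self) -> np.ndarray:
        if self._sub5 is None:
            self._compile()
        return self._sub5

    @classmethod
    def uniform(cls) -> "ContextModel":
        """Synthetic context-free model: equal mutability everywhere and
        uniform substitution over the three alternative bases."""
        mut: dict[str, float] = {}
        sub: dict[str, tuple[float, float, float, float]] = {}
        for fm in map("".join, itertools.product(DNA_BASES, repeat=5)):
            mut[fm] = 1.0
            row = [1.0 / 3.0] * 4
            row[_BASE_INDEX[fm[2]]] = 0.0
            sub[fm] = tuple(row)
        return cls(mut, sub)

    @classmethod
    def from_tsv(cls, path) -> "ContextModel":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        required = ["fivemer", "mutability",
                    "prob_to_A", "prob_to_C", "prob_to_G", "prob_to_T"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"model table missing columns: {missing}")
        mut = dict(zip(df["fivemer"], df["mutability"].astype(float)))
        sub = {fm: (ra, rc, rg, rt) for fm, ra, rc, rg, rt in zip(
            df["fivemer"], df["prob_to_A"], df["prob_to_C"],
            df["prob_to_G"], df["prob_to_T"])}
        return cls(mut, sub)

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [(fm, self.mutability[fm], *self.substitution[fm])
                for fm in sorted(self.mutability)]
        pd.DataFrame(rows, columns=["fivemer", "mutability", "prob_to_A",
                                    "prob_to_C", "prob_to_G", "prob_to_T"]
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class NeutralSimConfig:
    """Simulation settings: replicate count, seed, and stop-codon policy."""

    n_samples: int = 10000
    seed: int = 0
    allow_resampling_stops: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _encode(dna: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in dna], dtype=np.int64)


def _replicate_uniforms(seed: int, indices: np.ndarray, m: int,
                        attempt: int = 0) -> np.ndarray:
    """Per-replicate uniform draws, shape (len(indices), m, 2).

    Each replicate owns a Philox counter-based stream keyed by
    (seed, replicate index, attempt), so its draws do not depend on
    ``n_samples`` or on the other replicates.
    """
    out = np.empty((len(indices), m, 2))
    for row, i in enumerate(indices):
        key = (int(attempt) << 96) | (int(i) << 34) | int(seed)
        out[row] = np.random.Generator(np.random.Philox(key=key)).random((m, 2))
    return out


def _mutate_batch(seqs: np.ndarray, m: int, model: ContextModel,
                  u: np.ndarray) -> np.ndarray:
    """Apply m sequential context-sensitive mutations to each row of seqs."""
    n, L = seqs.shape
    mut5, sub5 = model.mut5, model.sub5
    padded = np.full((n, L + 4), _N_CODE, dtype=np.int64)
    padded[:, 2:-2] = seqs
    # 5-mer code per site, base-5.
    codes = sum(padded[:, off:off + L] * _POW5[off] for off in range(5))
    mut = mut5[codes]
    rows = np.arange(n)
    for step in range(m):
        cs = np.cumsum(mut, axis=1)
        total = cs[:, -1]
        r = u[:, step, 0] * total
        sites = np.minimum((cs <= r[:, None]).sum(axis=1), L - 1)
        probs = sub5[codes[rows, sites]]
        cps = np.cumsum(probs, axis=1)
        targets = np.minimum((cps <= u[:, step, 1, None]).sum(axis=1), 3)
        padded[rows, sites + 2] = targets
        # Refresh codes/mutabilities at the <=5 affected positions.
        for off in range(-2, 3):
            pos = sites + off
            ok = (pos >= 0) & (pos < L)
            pr, pp = rows[ok], pos[ok]
            new = np.zeros(len(pp), dtype=np.int64)
            for w in range(5):
                new += padded[pr, pp + w] * _POW5[w]
            codes[pr, pp] = new
            mut[pr, pp] = mut5[new]
    return padded[:, 2:-2]


def simulate_neutral_profile(naive_dna: str, numbering: Sequence[int], m: int,
                             model: ContextModel,
                             cfg: NeutralSimConfig) -> SubstitutionProfile:
    """Monte-Carlo neutral substitution profile for one clonal family.

    Each of ``cfg.n_samples`` replicates receives ``m`` sequential mutations
    of the naive DNA under the 5-mer model (sites may mutate repeatedly;
    back-mutation is possible), is translated, and tallied on the positions
    given by ``numbering``.  Replicates whose translation contains a stop
    codon keep their non-stop codons (the stop position is simply not
    tallied) unless ``cfg.allow_resampling_stops`` requests redrawing the
    replicate.  The defined mask of the result equals the naive sequence's
    mapped positions.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if len(naive_dna) % 3 != 0:
        raise ValueError("naive DNA length must be divisible by 3")
    naive_dna = naive_dna.upper()
    if any(b not in DNA_BASES for b in naive_dna):
        raise ValueError("naive DNA must be unambiguous")
    n_codons = len(naive_dna) // 3
    if len(numbering) != n_codons:
        raise ValueError("numbering must have one entry per codon")

    base = _encode(naive_dna)
    n = cfg.n_samples
    if m == 0:
        seqs = np.tile(base, (n, 1))
    else:
        u = _replicate_uniforms(cfg.seed, np.arange(n), m)
        seqs = _mutate_batch(np.tile(base, (n, 1)), m, model, u)
        if cfg.allow_resampling_stops:
            for attempt in range(1, 101):
                aa = _CODON_TABLE[seqs[:, 0::3], seqs[:, 1::3], seqs[:, 2::3]]
                bad = np.where((aa < 0).any(axis=1))[0]
                if len(bad) == 0:
                    break
                u = _replicate_uniforms(cfg.seed, bad, m, attempt=attempt)
                seqs[bad] = _mutate_batch(np.tile(base, (len(bad), 1)), m,
                                          model, u)
            else:
                raise RuntimeError("could not resample stop-free replicates")

    aa = _CODON_TABLE[seqs[:, 0::3], seqs[:, 1::3], seqs[:, 2::3]]  # (n, codons)
    counts = np.zeros((N_POSITIONS, N_AA), dtype=np.int64)
    cols = np.asarray(numbering, dtype=int) - 1
    valid = aa >= 0  # stop positions are mask-safe: not tallied
    pos_idx = np.broadcast_to(cols, aa.shape)[valid]
    np.add.at(counts, (pos_idx, aa[valid]), 1)

    totals = counts.sum(axis=1)
    freqs = np.zeros((N_POSITIONS, N_AA))
    has = totals > 0
    freqs[has] = counts[has] / totals[has, None]
    defined = np.zeros(N_POSITIONS, dtype=bool)
    defined[cols] = True
    # A position where every replicate stopped would have no tallies; keep
    # it in the mask but as the naive one-hot (no information gained).
    empty = defined & ~has
    if empty.any():
        naive_aa = translate_dna(naive_dna)
        for ci in np.where(empty[cols])[0]:
            freqs[cols[ci], AA_INDEX[naive_aa[ci]]] = 1.0
    return SubstitutionProfile(freqs, defined)


def enumerate_single_mutants(naive_dna: str, numbering: Sequence[int],
                             model: ContextModel) -> SubstitutionProfile:
    """Exact m=1 neutral profile by enumeration over all single-nt mutants.

    Independent oracle for the Monte-Carlo simulator: weights every
    single-nucleotide mutant by its exact probability (site mutability times
    substitution probability) and aggregates translated amino acids.
    """
    naive_dna = naive_dna.upper()
    L = len(naive_dna)
    base = _encode(naive_dna)
    padded = np.full(L + 4, _N_CODE, dtype=np.int64)
    padded[2:-2] = base
    codes = np.array([int((padded[i:i + 5] * _POW5).sum()) for i in range(L)])
    site_w = model.mut5[codes]
    site_p = site_w / site_w.sum()
    counts = np.zeros((N_POSITIONS, N_AA))
    cols = np.asarray(numbering, dtype=int) - 1
    for i in range(L):
        probs = model.sub5[codes[i]]
        for b in range(4):
            if probs[b] == 0:
                continue
            mutant = base.copy()
            mutant[i] = b
            aa = _CODON_TABLE[mutant[0::3], mutant[1::3], mutant[2::3]]
            w = site_p[i] * probs[b]
            for ci, a in enumerate(aa):
                if a >= 0:
                    counts[cols[ci], a] += w
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    has = totals > 0
    freqs[has] = counts[has] / totals[has, None]
    defined = np.zeros(N_POSITIONS, dtype=bool)
    defined[cols] = True
    return SubstitutionProfile(freqs, defined)
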