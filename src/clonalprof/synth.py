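"""Synthetic datasets with known ground truth for every pipeline stage.

The generator emulates exactly the statistical structure the predictor
assumes: per clonal family, each external source contributes a Dirichlet
site-wise amino-acid distribution, the true CF profile is the per-site
convex combination of those sources (with the configured weights
``alpha_true``) and a CF-specific Dirichlet "input-only" component, and the
observed sequences are positionwise-multinomial draws from the true
profile.  The observed target ``Y`` is the empirical profile of the drawn
sequences; the input ``X`` is either the exact input-only component
(default; noise-free, so fitting recovers ``alpha_true``) or the one-hot
profile of a single randomly chosen sequence (the repertoire-subsampling
regime).  An inactive block of positions centered in CDR3 emulates the gap
structure of real numbering data.

No germinal-center phylogeny or selection is simulated; the structure is
the model's assumed form plus sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .external import InputTensor, ProfileSourceSpec
from .profiles import (
    AA_LETTERS,
    DNA_BASES,
    N_AA,
    N_POSITIONS,
    ClonalFamily,
    ProfileTensor,
    SubstitutionProfile,
    count_profile,
    normalize,
)

_CDR3_CENTER = 122  # gap block is centered here (1-based)


def _reverse_codon_table() -> dict[str, str]:
    from Bio.Seq import Seq
    import itertools

    table: dict[str, str] = {}
    for codon in map("".join, itertools.product(DNA_BASES, repeat=3)):
        aa = str(Seq(codon).translate())
        if aa in AA_LETTERS and aa not in table:
            table[aa] = codon
    return table


_AA_TO_CODON = _reverse_codon_table()


def reverse_translate(aa_seq: str) -> str:
    """Deterministic DNA back-translation (first codon per amino acid)."""
    return "".join(_AA_TO_CODON[aa] for aa in aa_seq)


def active_positions(n_active: int) -> np.ndarray:
    """1-based positions kept active; the complement is a contiguous gap
    block centered in CDR3 (mimicking uncovered numbering positions)."""
    if not 1 <= n_active <= N_POSITIONS:
        raise ValueError("n_positions_active must be in 1..149")
    n_drop = N_POSITIONS - n_active
    start = _CDR3_CENTER - n_drop // 2
    start = min(max(start, 2), N_POSITIONS - n_drop)
    dropped = set(range(start, start + n_drop))
    return np.array([j for j in range(1, N_POSITIONS + 1) if j not in dropped])


def piecewise_constant_alpha(p: int, levels: np.ndarray | None = None
                             ) -> np.ndarray:
    """A feasible piecewise-constant weight matrix (149, p).

    Each source's weight takes two levels over two halves of the sequence,
    so fused-lasso fits have a genuinely blocky truth to recover.
    """
    alpha = np.zeros((N_POSITIONS, p))
    if p == 0:
        return alpha
    half = N_POSITIONS // 2
    for l in range(p):
        hi, lo = 0.6 / p, 0.15 / p
        if l % 2 == 0:
            alpha[:half, l], alpha[half:, l] = hi, lo
        else:
            alpha[:half, l], alpha[half:, l] = lo, hi
    if levels is not None:
        alpha = np.asarray(levels, dtype=float)
    sums = alpha.sum(axis=1)
    if (alpha < 0).any() or (alpha > 1).any() or (sums > 1 + 1e-12).any():
        raise ValueError("alpha_true must be feasible")
    return alpha


@dataclass
class SynthConfig:
    """Generator settings; defaults give a model-fitting-scale dataset."""

    n_cf: int = 500
    seqs_per_cf: int = 100
    p_true: int = 2
    alpha_true: np.ndarray | None = None
    dirichlet_conc: float = 0.5
    n_positions_active: int = 120
    v_labels: tuple[str, ...] = ("IGHV1-2", "IGHV3-7", "IGHV4-34")
    seed: int = 0
    input_kind: str = "component"  # or "subsample"

    def __post_init__(self) -> None:
        if self.n_cf < 1:
            raise ValueError("n_cf must be >= 1")
        if self.seqs_per_cf < 1:
            raise ValueError("seqs_per_cf must be >= 1")
        if self.dirichlet_conc <= 0:
            raise ValueError("dirichlet_conc must be positive")
        if self.input_kind not in ("component", "subsample"):
            raise ValueError("input_kind must be 'component' or 'subsample'")
        if self.alpha_true is None:
            self.alpha_true = piecewise_constant_alpha(self.p_true)
        self.alpha_true = np.asarray(self.alpha_true, dtype=float)
        if self.alpha_true.shape != (N_POSITIONS, self.p_true):
            raise ValueError("alpha_true must have shape (149, p_true)")
        if ((self.alpha_true < 0).any() or (self.alpha_true > 1).any()
                or (self.alpha_true.sum(axis=1) > 1 + 1e-12).any()):
            raise ValueError("alpha_true must be feasible (box and sum <= 1)")


@dataclass
class SynthDataset:
    """Generated dataset plus its full ground-truth record."""

    cfs: list[ClonalFamily]
    x: ProfileTensor
    y: ProfileTensor
    xstar: InputTensor
    truth: dict = field(default_factory=dict)

    @property
    def x_subsample(self) -> ProfileTensor:
        return self.truth["x_subsample"]


def _dirichlet_rows(rng: np.random.Generator, conc: float,
                    cols: np.ndarray) -> np.ndarray:
    freqs = np.zeros((N_POSITIONS, N_AA))
    freqs[cols] = rng.dirichlet(np.full(N_AA, conc), size=len(cols))
    return freqs


def gen_dataset(cfg: SynthConfig) -> SynthDataset:
    """Generate CFs, profiles, and the stacked source tensor.

    All randomness flows from ``cfg.seed``; a fixed config reproduces the
    dataset bit-for-bit.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = active_positions(cfg.n_positions_active)  # 1-based
    cols = pos - 1
    defined_row = np.zeros(N_POSITIONS, dtype=bool)
    defined_row[cols] = True

    n, p = cfg.n_cf, cfg.p_true
    alpha = cfg.alpha_true
    rest = 1.0 - alpha.sum(axis=1)

    sources = np.zeros((n, N_POSITIONS, N_AA, p))
    base = np.zeros((n, N_POSITIONS, N_AA))
    true = np.zeros((n, N_POSITIONS, N_AA))
    y = np.zeros((n, N_POSITIONS, N_AA))
    x = np.zeros((n, N_POSITIONS, N_AA))
    x_sub = np.zeros((n, N_POSITIONS, N_AA))
    cfs: list[ClonalFamily] = []

    for i in range(n):
        for l in range(p):
            sources[i, :, :, l] = _dirichlet_rows(rng, cfg.dirichlet_conc, cols)
        base[i] = _dirichlet_rows(rng, cfg.dirichlet_conc, cols)
        true[i] = np.einsum("jl,jkl->jk", alpha, sources[i]) \
            + rest[:, None] * base[i]
        true[i, ~defined_row] = 0.0

        # positionwise-multinomial sequence sampling from the true profile
        seq_idx = np.empty((cfg.seqs_per_cf, len(cols)), dtype=np.int64)
        for c, j in enumerate(cols):
            seq_idx[:, c] = rng.choice(N_AA, size=cfg.seqs_per_cf,
                                       p=true[i, j])
        seqs = ["".join(AA_LETTERS[a] for a in row) for row in seq_idx]

        v_gene = cfg.v_labels[i % len(cfg.v_labels)]
        naive_aa = "".join(AA_LETTERS[a] for a in true[i][cols].argmax(axis=1))
        cf = ClonalFamily(
            cf_id=f"synthCF{i:04d}",
            donor_id=f"donor{i % 10}",
            sequences=tuple(seqs),
            naive_aa=naive_aa,
            naive_dna=reverse_translate(naive_aa),
            v_gene=v_gene,
            v_subgroup=v_gene.split("-")[0],
            numbering=tuple(int(j) for j in pos),
        )
        cfs.append(cf)

        counts = count_profile(cf)
        y[i] = normalize(counts).freqs
        pick = int(rng.integers(cfg.seqs_per_cf))
        x_sub[i] = SubstitutionProfile.one_hot(seqs[pick], cf.numbering).freqs
        x[i] = base[i] if cfg.input_kind == "component" else x_sub[i]

    defined = np.tile(defined_row, (n, 1))
    cf_ids = tuple(cf.cf_id for cf in cfs)
    specs = tuple(ProfileSourceSpec("custom", label=f"source{l + 1}")
                  for l in range(p))
    ds = SynthDataset(
        cfs=cfs,
        x=ProfileTensor(x, defined.copy(), cf_ids),
        y=ProfileTensor(y, defined.copy(), cf_ids),
        xstar=InputTensor(sources, specs, defined.copy()),
        truth={
            "alpha_true": alpha.copy(),
            "true_profiles": true,
            "base_profiles": base,
            "source_profiles": sources,
            "active_positions": pos,
            "seed": cfg.seed,
            "x_subsample": ProfileTensor(x_sub, defined.copy(), cf_ids),
        },
    )
    return ds


def add_decoy_sources(ds: SynthDataset, n_decoys: int, seed: int,
                      conc: float = 0.5) -> SynthDataset:
    """Append pure-noise Dirichlet sources (no relation to Y) to xstar."""
    rng = np.random.default_rng(seed)
    n = len(ds.x)
    cols = np.asarray(ds.truth["active_positions"]) - 1
    extra = np.zeros((n, N_POSITIONS, N_AA, n_decoys))
    for i in range(n):
        for l in range(n_decoys):
            extra[i, :, :, l] = _dirichlet_rows(rng, conc, cols)
    values = np.concatenate([ds.xstar.values, extra], axis=3)
    specs = ds.xstar.sources + tuple(
        ProfileSourceSpec("custom", label=f"decoy{l + 1}")
        for l in range(n_decoys))
    return SynthDataset(ds.cfs, ds.x, ds.y,
                        InputTensor(values, specs, ds.xstar.defined.copy()),
                        dict(ds.truth))


# ---------------------------------------------------------------------------
# Hand-written worked-example fixture
# ---------------------------------------------------------------------------

#: Hand-computed count matrix of the toy CF below, rows = its 12 mapped
#: positions in numbering order, columns keyed by amino acid.
TOY_COUNTS = {
    # position: {aa: count}  (6 sequences)
    5: {"E": 6},
    6: {"V": 5, "I": 1},
    7: {"Q": 6},
    8: {"L": 4, "M": 2},
    9: {"V": 6},
    10: {"E": 3, "D": 3},
    11: {"S": 6},
    12: {"G": 6},
    25: {"A": 4, "T": 2},
    26: {"E": 6},
    27: {"V": 5, "A": 1},
    28: {"K": 6},
}


def gen_toy_cf() -> ClonalFamily:
    """A 6-sequence, 12-position hand-written CF used in docs and tests."""
    naive_aa = "EVQLVESGAEVK"
    # the last sequence intentionally duplicates the first (dedup leaves 5)
    seqs = (
        "EVQLVESGAEVK",
        "EVQLVDSGAEVK",
        "EIQLVDSGTEVK",
        "EVQMVESGAEVK",
        "EVQMVDSGTEAK",
        "EVQLVESGAEVK",
    )
    return ClonalFamily(
        cf_id="toyCF",
        donor_id="toyDonor",
        sequences=seqs,
        naive_aa=naive_aa,
        naive_dna=reverse_translate(naive_aa),
        v_gene="IGHV3-23",
        v_subgroup="IGHV3",
        numbering=(5, 6, 7, 8, 9, 10, 11, 12, 25, 26, 27, 28),
    )
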