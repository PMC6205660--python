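"""Per-region metrics, mode-prediction contingency analysis, bootstrap SEs.

Antibody heavy-chain positions partition into framework regions (FWK1-4)
and complementarity-determining regions (CDR1-3).  The shipped boundary
table follows the AHo scheme's region definitions on the 149-position
coordinate system; the conserved tryptophan at position 43 sits immediately
after the end of CDR1, which is used as a consistency anchor.  The table is
overridable for users with a different regional convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import WeightMatrix, jaccard_exact, l2_error
from .profiles import N_POSITIONS, ProfileTensor

REGION_ORDER = ("FWK1", "CDR1", "FWK2", "CDR2", "FWK3", "CDR3", "FWK4")

#: Inclusive 1-based (start, end) boundaries per region on the AHo scheme.
DEFAULT_REGION_BOUNDS = {
    "FWK1": (1, 26),
    "CDR1": (27, 42),
    "FWK2": (43, 56),
    "CDR2": (57, 69),
    "FWK3": (70, 106),
    "CDR3": (107, 138),
    "FWK4": (139, 149),
}


@dataclass
class RegionMap:
    """Region label per position; contiguous blocks in canonical order."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != N_POSITIONS:
            raise ValueError(f"labels must cover all {N_POSITIONS} positions")
        seen = [self.labels[0]]
        for lab in self.labels[1:]:
            if lab != seen[-1]:
                seen.append(lab)
        if tuple(seen) != tuple(r for r in REGION_ORDER if r in set(self.labels)):
            raise ValueError("regions must be contiguous blocks in canonical order")

    @classmethod
    def default(cls) -> "RegionMap":
        return cls.from_bounds(DEFAULT_REGION_BOUNDS)

    @classmethod
    def from_bounds(cls, bounds: dict[str, tuple[int, int]]) -> "RegionMap":
        labels = [""] * N_POSITIONS
        for region, (a, b) in bounds.items():
            for j in range(a, b + 1):
                labels[j - 1] = region
        if "" in labels:
            raise ValueError("bounds must cover 1..149")
        return cls(tuple(labels))

    @classmethod
    def single(cls, label: str = "FWK1") -> "RegionMap":
        """Trivial one-region map (reproduces global metrics)."""
        return cls((label,) * N_POSITIONS)

    def mask(self, region: str) -> np.ndarray:
        return np.array([lab == region for lab in self.labels])

    @property
    def regions(self) -> tuple[str, ...]:
        out = []
        for lab in self.labels:
            if not out or out[-1] != lab:
                out.append(lab)
        return tuple(out)


def _restrict(t: ProfileTensor, pos_mask: np.ndarray) -> ProfileTensor:
    defined = t.defined & pos_mask[None, :]
    freqs = np.where(defined[:, :, None], t.freqs, 0.0)
    return ProfileTensor(freqs, defined, t.cf_ids)


def region_metrics(y: ProfileTensor, yhat: ProfileTensor, regions: RegionMap,
                   metric: str = "l2", t: float = 0.2) -> dict[str, float]:
    """Metric per region, position sums restricted to the region.

    For L2 the normalizer is (region length x n_cf), so the whole-sequence
    L2 error equals the region-length-weighted mean of the region values.
    Jaccard is the mean over the region's defined cells.
    """
    if metric not in ("l2", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    out: dict[str, float] = {}
    for region in regions.regions:
        pm = regions.mask(region)
        yr = _restrict(y, pm)
        yhr = _restrict(yhat, pm)
        if metric == "l2":
            # l2_error normalizes by 149 * n; rescale to region length.
            out[region] = l2_error(yr, yhr) * N_POSITIONS / int(pm.sum())
        else:
            if not yr.defined.any():
                out[region] = float("nan")
            else:
                out[region] = jaccard_exact(yr, yhr, t)
    return out


def bootstrap_se(y: ProfileTensor, yhat: ProfileTensor, metric: str = "l2",
                 B: int = 200, seed: int = 0,
                 regions: RegionMap | None = None,
                 t: float = 0.2) -> dict[str, float]:
    """Bootstrap standard errors of (per-region) metrics over CF resampling.

    CFs are resampled with replacement B times; the SE is the standard
    deviation of the metric across replicates.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 CFs to bootstrap")
    regions = regions or RegionMap.single()
    rng = np.random.default_rng(seed)
    reps: dict[str, list[float]] = {r: [] for r in regions.regions}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        # resampling may repeat cf_ids; bypass uniqueness via raw arrays
        yb = ProfileTensor(y.freqs[idx], y.defined[idx])
        yhb = ProfileTensor(yhat.freqs[idx], yhat.defined[idx])
        vals = region_metrics(yb, yhb, regions, metric, t)
        for r, v in vals.items():
            reps[r].append(v)
    return {r: float(np.std(np.asarray(v), ddof=0)) for r, v in reps.items()}


@dataclass
class ModeTable:
    """2 x 2 x 2 mode-prediction contingency counts.

    Axes: (input amino acid is the true mode?, predicted mode correct?,
    predicted mode is the germline/naive amino acid?).  Indices 0 = yes,
    1 = no on the first two axes; on the third, 0 = germline, 1 = non-
    germline.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2, 2):
            raise ValueError("counts must be (2, 2, 2)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def cell(self, input_is_mode: bool, prediction_correct: bool,
             germline: bool) -> int:
        return int(self.counts[0 if input_is_mode else 1,
                               0 if prediction_correct else 1,
                               0 if germline else 1])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for im in (True, False):
            for pc in (True, False):
                rows.append({
                    "input_is_mode": im,
                    "prediction_correct": pc,
                    "germline": self.cell(im, pc, True),
                    "non_germline": self.cell(im, pc, False),
                })
        return pd.DataFrame(rows)


def mode_table(x: ProfileTensor, yhat: ProfileTensor, y: ProfileTensor,
               naive_profiles: ProfileTensor) -> ModeTable:
    """Tally mode-prediction outcomes over jointly-defined CF-positions.

    Per cell: the actual mode is the argmax of the observed row, the
    predicted mode the argmax of the predicted row, and the input amino
    acid the argmax of the (one-hot) input row; argmax ties break by
    alphabet order.  The germline flag marks predictions equal to the naive
    amino acid at that position.
    """
    mask = x.defined & yhat.defined & y.defined & naive_profiles.defined
    counts = np.zeros((2, 2, 2), dtype=np.int64)
    actual = y.freqs.argmax(axis=2)
    pred = yhat.freqs.argmax(axis=2)
    inp = x.freqs.argmax(axis=2)
    germ = naive_profiles.freqs.argmax(axis=2)
    im = (inp == actual)
    pc = (pred == actual)
    gl = (pred == germ)
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                sel = (im == (a == 0)) & (pc == (b == 0)) & (gl == (c == 0)) & mask
                counts[a, b, c] = int(sel.sum())
    return ModeTable(counts)


def aggregate_weights(w: WeightMatrix, source_names: tuple[str, ...],
                      groups: dict[str, tuple[str, ...]] | None = None
                      ) -> pd.DataFrame:
    """Stacked-area table of per-position weights, optionally grouped.

    Default grouping merges the germline-segment sources (vgene, vsubgrp)
    and the naive-sequence-derived sources (naiveAA, neut); ungrouped
    sources keep their own column.  The residual input-sequence weight
    1 - sum_l alpha[j, l] is always included.
    """
    if groups is None:
        groups = {"germline_segment": ("vgene", "vsubgrp"),
                  "naive_derived": ("naiveAA", "neut")}
    data: dict[str, np.ndarray] = {}
    used: set[str] = set()
    for gname, members in groups.items():
        idx = [i for i, n in enumerate(source_names) if n in members]
        if idx:
            data[gname] = w.alpha[:, idx].sum(axis=1)
            used.update(source_names[i] for i in idx)
    for i, n in enumerate(source_names):
        if n not in used:
            data[n] = w.alpha[:, i]
    data["input_sequence"] = 1.0 - w.alpha.sum(axis=1)
    df = pd.DataFrame(data)
    df.insert(0, "aho_pos", np.arange(1, N_POSITIONS + 1))
    return df
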