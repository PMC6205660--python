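"""External profile sources and assembly of the 4-way input tensor.

Six kinds of external information can back the predictor, all expressed as
substitution profiles on the common 149-position coordinate system:

* ``vgene`` / ``vsubgrp`` — public profiles averaged by germline V-gene /
  V-subgroup label and matched to the query by its own label;
* ``naiveAA`` — the one-hot profile of the query's inferred naive sequence;
* ``naiveAA-clust`` / ``clust`` — K-means centroids of the public set
  (clustered on naive one-hot encodings resp. frequency profiles), the query
  being assigned to its nearest centroid;
* ``neut`` — a simulated neutral somatic-hypermutation profile (see
  :mod:`clonalprof.neutral`).

The assembled input tensor stacks, for each query CF, one profile per
requested source: shape (n_cf, 149, 20, p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .profiles import (
    DEFAULT_ALPHABET,
    N_AA,
    N_POSITIONS,
    ClonalFamily,
    ProfileTensor,
    SubstitutionProfile,
)

SOURCE_KINDS = ("vgene", "vsubgrp", "naiveAA", "naiveAA-clust", "clust", "neut")

#: "custom" sources carry an opaque label and are supplied pre-built (used
#: by the synthetic-data generator and by user-provided profile stacks).
EXTENDED_KINDS = SOURCE_KINDS + ("custom",)

KMIN, KMAX = 2, 120


class UnknownGermlineError(KeyError):
    """Query CF carries a V label never observed in the public dataset."""


@dataclass(frozen=True)
class ProfileSourceSpec:
    """Identifies one external profile source; clustered kinds carry K."""

    kind: str
    k: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EXTENDED_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.kind in ("naiveAA-clust", "clust"):
            if self.k is None or not (KMIN <= self.k <= KMAX):
                raise ValueError(f"cluster count K must be in [{KMIN}, {KMAX}]")
        elif self.k is not None:
            raise ValueError(f"source kind {self.kind!r} takes no K")
        if self.kind == "custom" and not self.label:
            raise ValueError("custom sources require a label")

    @property
    def name(self) -> str:
        if self.kind == "custom":
            return self.label
        return self.kind if self.k is None else f"{self.kind}-{self.k}"

    @classmethod
    def parse(cls, name: str) -> "ProfileSourceSpec":
        for kind in ("naiveAA-clust", "clust"):
            if name.startswith(kind + "-"):
                return cls(kind, int(name[len(kind) + 1:]))
        if name in SOURCE_KINDS:
            return cls(name)
        return cls("custom", label=name)


@dataclass
class InputTensor:
    """4-way tensor of external profiles: (n_cf, 149, 20, p).

    ``values[i, j, k, l]`` is the frequency of amino acid ``k`` at position
    ``j`` for CF ``i`` in the ``l``-th source; each defined (i, j, :, l)
    slice is a probability vector.  ``defined`` is the per-CF position mask
    shared with the query profiles.
    """

    values: np.ndarray
    sources: tuple[ProfileSourceSpec, ...]
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        self.sources = tuple(self.sources)
        n = self.values.shape[0]
        p = len(self.sources)
        if self.values.shape != (n, N_POSITIONS, N_AA, p):
            raise ValueError("values must have shape (n_cf, 149, 20, p)")
        if self.defined.shape != (n, N_POSITIONS):
            raise ValueError("defined must have shape (n_cf, 149)")

    @property
    def p(self) -> int:
        return len(self.sources)

    def subset_sources(self, idx: Sequence[int]) -> "InputTensor":
        idx = list(idx)
        return InputTensor(self.values[:, :, :, idx],
                           tuple(self.sources[i] for i in idx), self.defined)

    def subset_cfs(self, idx: Sequence[int]) -> "InputTensor":
        idx = np.asarray(idx, dtype=int)
        return InputTensor(self.values[idx], self.sources, self.defined[idx])


def _renormalize(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Renormalize rows to sum 1; rows with no mass become undefined."""
    totals = freqs.sum(axis=-1)
    defined = totals > 1e-12
    out = np.zeros_like(freqs)
    out[defined] = freqs[defined] / totals[defined, None]
    return out, defined


def average_by_label(public: ProfileTensor,
                     labels: Mapping[str, str]) -> dict[str, SubstitutionProfile]:
    """Average public CF profiles within each label.

    The mean at each position is unweighted over the member CFs *defined at
    that position* (members undefined there are excluded) and renormalized
    to sum 1.  Labels with zero members are never emitted.
    """
    missing = [cid for cid in public.cf_ids if cid not in labels]
    if missing:
        raise KeyError(f"public CFs without a label: {missing[:5]}")
    out: dict[str, SubstitutionProfile] = {}
    by_label: dict[str, list[int]] = {}
    for i, cid in enumerate(public.cf_ids):
        by_label.setdefault(labels[cid], []).append(i)
    for label, idx in by_label.items():
        freqs = public.freqs[idx]
        defined = public.defined[idx]
        n_def = defined.sum(axis=0)
        mean = np.zeros((N_POSITIONS, N_AA))
        has = n_def > 0
        mean[has] = freqs.sum(axis=0)[has] / n_def[has, None]
        mean, has2 = _renormalize(mean)
        out[label] = SubstitutionProfile(mean, has & has2)
    return out


def naive_profile(cf: ClonalFamily) -> SubstitutionProfile:
    """One-hot profile of the CF's inferred naive amino-acid sequence."""
    return SubstitutionProfile.one_hot(cf.naive_aa, cf.numbering, DEFAULT_ALPHABET)


@dataclass
class KMeansProfiles:
    """Fitted K-means over flattened (149*20)-dimensional profile space.

    ``centers`` holds the raw cluster centers used for nearest-centroid
    assignment (kept separate from the renormalized ``centroids`` so a
    registry reloaded from disk assigns identically); ``kmeans`` is the
    fitted estimator when available, None after deserialization.
    """

    centroids: list[SubstitutionProfile]
    centers: np.ndarray
    encoding: str  # "naive_onehot" | "frequency"
    kmeans: KMeans | None = None

    def assign(self, query: SubstitutionProfile) -> int:
        """Index of the euclidean-nearest centroid for a query profile."""
        vec = query.freqs.reshape(1, -1)
        d = np.linalg.norm(self.centers - vec, axis=1)
        return int(np.argmin(d))

    def profile_for(self, query: SubstitutionProfile) -> SubstitutionProfile:
        return self.centroids[self.assign(query)]


def kmeans_profiles(public: ProfileTensor, encoding: str, k: int, seed: int,
                    n_restarts: int = 10, allow_small_k: bool = False) -> KMeansProfiles:
    """Cluster public profiles with K-means (euclidean, flattened space).

    ``public`` must already be in the requested encoding: the frequency
    profiles for ``encoding="frequency"``, the naive one-hot profiles for
    ``encoding="naive_onehot"``.  Centroid rows are renormalized to valid
    frequency vectors; positions undefined in every contributing CF stay
    undefined.
    """
    if encoding not in ("naive_onehot", "frequency"):
        raise ValueError(f"unknown encoding {encoding!r}")
    if not allow_small_k and k < KMIN:
        raise ValueError(f"K must be >= {KMIN}")
    if k > len(public):
        raise ValueError(f"K={k} exceeds number of public CFs ({len(public)})")
    X = public.freqs.reshape(len(public), -1)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    centroids = []
    for c in range(k):
        members = km.labels_ == c
        raw = km.cluster_centers_[c].reshape(N_POSITIONS, N_AA)
        freqs, has_mass = _renormalize(np.clip(raw, 0.0, None))
        defined = public.defined[members].any(axis=0) & has_mass
        freqs[~defined] = 0.0
        centroids.append(SubstitutionProfile(freqs, defined))
    return KMeansProfiles(centroids, km.cluster_centers_.copy(), encoding, km)


@dataclass
class SourceRegistry:
    """Fitted external-profile sources derived from the public dataset.

    Holds the per-label averaged profiles, the fitted K-means models (keyed
    by K), and an optional map of precomputed neutral profiles for query
    CFs.  Acts as the lookup used both in batch tensor assembly and in
    single-sequence prediction.
    """

    vgene: dict[str, SubstitutionProfile] = field(default_factory=dict)
    vsubgrp: dict[str, SubstitutionProfile] = field(default_factory=dict)
    clust: dict[int, KMeansProfiles] = field(default_factory=dict)
    naive_clust: dict[int, KMeansProfiles] = field(default_factory=dict)
    neutral: dict[str, SubstitutionProfile] = field(default_factory=dict)
    seed: int = 0
    n_restarts: int = 10

    @classmethod
    def from_public(cls, public: ProfileTensor,
                    v_gene_labels: Mapping[str, str] | None = None,
                    v_subgroup_labels: Mapping[str, str] | None = None,
                    public_naive: ProfileTensor | None = None,
                    clust_ks: Sequence[int] = (),
                    naive_clust_ks: Sequence[int] = (),
                    neutral: Mapping[str, SubstitutionProfile] | None = None,
                    seed: int = 0, n_restarts: int = 10) -> "SourceRegistry":
        reg = cls(seed=seed, n_restarts=n_restarts)
        if v_gene_labels is not None:
            reg.vgene = average_by_label(public, v_gene_labels)
        if v_subgroup_labels is not None:
            reg.vsubgrp = average_by_label(public, v_subgroup_labels)
        for k in clust_ks:
            reg.clust[k] = kmeans_profiles(public, "frequency", k, seed, n_restarts)
        for k in naive_clust_ks:
            if public_naive is None:
                raise ValueError("naive_clust_ks requires public_naive profiles")
            reg.naive_clust[k] = kmeans_profiles(public_naive, "naive_onehot",
                                                 k, seed, n_restarts)
        if neutral is not None:
            reg.neutral = dict(neutral)
        return reg

    def source_profile(self, spec: ProfileSourceSpec, cf: ClonalFamily,
                       query: SubstitutionProfile) -> SubstitutionProfile:
        """Profile of one source for one query CF.

        ``query`` is the CF's own (subsampled) frequency profile, used for
        nearest-centroid assignment of the ``clust`` kind.
        """
        if spec.kind == "naiveAA":
            return naive_profile(cf)
        if spec.kind == "vgene":
            try:
                return self.vgene[cf.v_gene]
            except KeyError:
                raise UnknownGermlineError(
                    f"CF {cf.cf_id}: V gene {cf.v_gene!r} not observed in the "
                    "public dataset; no prediction can be made") from None
        if spec.kind == "vsubgrp":
            try:
                return self.vsubgrp[cf.v_subgroup]
            except KeyError:
                raise UnknownGermlineError(
                    f"CF {cf.cf_id}: V subgroup {cf.v_subgroup!r} not observed "
                    "in the public dataset; no prediction can be made") from None
        if spec.kind == "clust":
            return self.clust[spec.k].profile_for(query)
        if spec.kind == "naiveAA-clust":
            return self.naive_clust[spec.k].profile_for(naive_profile(cf))
        if spec.kind == "neut":
            try:
                return self.neutral[cf.cf_id]
            except KeyError:
                raise KeyError(f"no neutral profile registered for CF "
                               f"{cf.cf_id}") from None
        raise ValueError(f"unknown source kind {spec.kind!r}")


def assemble_input_tensor(x: ProfileTensor, cfs: Sequence[ClonalFamily],
                          sources: Sequence[ProfileSourceSpec],
                          registry: SourceRegistry) -> InputTensor:
    """Stack one external profile per (query CF, source) into a 4-way tensor.

    At positions where the query is defined but a source profile is not
    (e.g. a public average never observed there), the query's own profile
    row is substituted for that source, which is locally equivalent to a
    zero weight and keeps predicted rows on the probability simplex.
    """
    if len(cfs) != len(x):
        raise ValueError("cfs and x must be parallel")
    n, p = len(x), len(sources)
    values = np.zeros((n, N_POSITIONS, N_AA, p))
    for i, cf in enumerate(cfs):
        query = x.profile(i)
        for l, spec in enumerate(sources):
            prof = registry.source_profile(spec, cf, query)
            slab = prof.freqs.copy()
            fallback = x.defined[i] & ~prof.defined
            if fallback.any():
                slab[fallback] = x.freqs[i][fallback]
            slab[~x.defined[i]] = 0.0
            values[i, :, :, l] = slab
    return InputTensor(values, tuple(sources), x.defined.copy())
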