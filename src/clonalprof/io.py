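"""Readers and writers for the on-disk formats.

On disk everything is plain text:

* sequences — FASTA with ``cf_id|seq_id`` headers (multi-CF files allowed,
  records may interleave);
* CF annotation — a tab-separated sidecar with columns ``cf_id, donor_id,
  v_gene, v_subgroup, naive_aa, naive_dna, numbering`` (numbering is a
  comma-joined list of 1-based positions in 1..149);
* profiles — one TSV per CF: ``aho_pos`` + the 20 one-letter amino-acid
  columns + ``defined``, frequencies printed with 6 decimals; tensors add a
  manifest TSV listing cf_id and file name;
* fitted models — a single JSON with the alpha matrix, source names,
  penalty configuration, optimizer diagnostics, and seeds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .external import (
    InputTensor,
    ProfileSourceSpec,
    SourceRegistry,
    assemble_input_tensor,
)
from .model import PenaltyConfig, WeightMatrix, predict
from .profiles import (
    AA_LETTERS,
    N_POSITIONS,
    ClonalFamily,
    ProfileTensor,
    SubstitutionProfile,
)

SIDECAR_COLUMNS = ["cf_id", "donor_id", "v_gene", "v_subgroup",
                   "naive_aa", "naive_dna", "numbering"]


# ---------------------------------------------------------------------------
# Clonal families: FASTA + sidecar
# ---------------------------------------------------------------------------

def write_dataset(cfs: Sequence[ClonalFamily], fasta_path, sidecar_path) -> None:
    records = []
    for cf in cfs:
        for s, seq in enumerate(cf.sequences):
            records.append(SeqRecord(Seq(seq), id=f"{cf.cf_id}|seq{s}",
                                     description=""))
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [{
        "cf_id": cf.cf_id, "donor_id": cf.donor_id, "v_gene": cf.v_gene,
        "v_subgroup": cf.v_subgroup, "naive_aa": cf.naive_aa,
        "naive_dna": cf.naive_dna,
        "numbering": ",".join(str(j) for j in cf.numbering),
    } for cf in cfs]
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(sidecar_path, sep="\t",
                                                       index=False)


def read_dataset(fasta_path, sidecar_path) -> list[ClonalFamily]:
    """Load CFs from FASTA + sidecar; malformed records raise with the
    offending cf_id named."""
    side = pd.read_csv(sidecar_path, sep="\t", dtype=str)
    missing = [c for c in SIDECAR_COLUMNS if c not in side.columns]
    if missing:
        raise ValueError(f"sidecar missing columns: {missing}")
    seqs: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"FASTA header {rec.id!r} lacks 'cf_id|seq_id'")
        cf_id = rec.id.split("|", 1)[0]
        seqs.setdefault(cf_id, []).append(str(rec.seq))
    cfs = []
    for lineno, row in enumerate(side.itertuples(index=False), start=2):
        cf_id = row.cf_id
        if cf_id not in seqs:
            raise ValueError(f"sidecar line {lineno}: no FASTA sequences for "
                             f"CF {cf_id!r}")
        try:
            numbering = tuple(int(tok) for tok in row.numbering.split(","))
            cfs.append(ClonalFamily(
                cf_id=cf_id, donor_id=row.donor_id,
                sequences=tuple(seqs[cf_id]),
                naive_aa=row.naive_aa, naive_dna=row.naive_dna,
                v_gene=row.v_gene, v_subgroup=row.v_subgroup,
                numbering=numbering))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"sidecar line {lineno} (CF {cf_id!r}): {exc}"
                             ) from exc
    return cfs


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def profile_to_frame(profile: SubstitutionProfile) -> pd.DataFrame:
    df = pd.DataFrame(profile.freqs, columns=list(AA_LETTERS))
    df.insert(0, "aho_pos", np.arange(1, N_POSITIONS + 1))
    df["defined"] = profile.defined.astype(int)
    return df


def write_profile(profile: SubstitutionProfile, path) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False,
                                     float_format="%.6f")


def read_profile(path) -> SubstitutionProfile:
    df = pd.read_csv(path, sep="\t")
    expected = ["aho_pos"] + list(AA_LETTERS) + ["defined"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: unexpected profile columns")
    freqs = df[list(AA_LETTERS)].to_numpy(dtype=float)
    defined = df["defined"].to_numpy().astype(bool)
    freqs[~defined] = 0.0
    # re-normalize defined rows to absorb 6-decimal rounding
    sums = freqs.sum(axis=1)
    ok = defined & (sums > 0)
    freqs[ok] /= sums[ok, None]
    return SubstitutionProfile(freqs, defined)


def write_tensor(tensor: ProfileTensor, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, cf_id in enumerate(tensor.cf_ids):
        fname = f"profile_{i:05d}.tsv"
        write_profile(tensor.profile(i), out_dir / fname)
        rows.append({"cf_id": cf_id, "file": fname})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)


def read_tensor(in_dir) -> ProfileTensor:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t", dtype=str)
    profiles = [read_profile(in_dir / f) for f in manifest["file"]]
    return ProfileTensor.from_profiles(profiles, tuple(manifest["cf_id"]))


# ---------------------------------------------------------------------------
# Source registries
# ---------------------------------------------------------------------------

def save_registry(registry: SourceRegistry, out_dir) -> None:
    """Serialize a fitted source registry: labels map to profile TSV files,
    K-means centers are stored inline."""
    from .external import KMeansProfiles  # noqa: F401  (documented layout)

    out = Path(out_dir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    payload: dict = {"format": "clonalprof-registry",
                     "seed": registry.seed,
                     "n_restarts": registry.n_restarts,
                     "vgene": {}, "vsubgrp": {}, "clust": {},
                     "naive_clust": {}, "neutral": {}}
    for section in ("vgene", "vsubgrp", "neutral"):
        for i, (label, prof) in enumerate(sorted(getattr(registry,
                                                         section).items())):
            fname = f"profiles/{section}_{i:04d}.tsv"
            write_profile(prof, out / fname)
            payload[section][label] = fname
    for section in ("clust", "naive_clust"):
        for k, km in getattr(registry, section).items():
            files = []
            for c, prof in enumerate(km.centroids):
                fname = f"profiles/{section}_{k}_{c:03d}.tsv"
                write_profile(prof, out / fname)
                files.append(fname)
            payload[section][str(k)] = {"encoding": km.encoding,
                                        "centers": km.centers.tolist(),
                                        "centroids": files}
    (out / "registry.json").write_text(json.dumps(payload))


def load_registry(in_dir) -> SourceRegistry:
    from .external import KMeansProfiles

    in_dir = Path(in_dir)
    payload = json.loads((in_dir / "registry.json").read_text())
    if payload.get("format") != "clonalprof-registry":
        raise ValueError(f"{in_dir} is not a source registry")
    reg = SourceRegistry(seed=int(payload.get("seed", 0)),
                         n_restarts=int(payload.get("n_restarts", 10)))
    for section in ("vgene", "vsubgrp", "neutral"):
        setattr(reg, section, {label: read_profile(in_dir / fname)
                               for label, fname in payload[section].items()})
    for section in ("clust", "naive_clust"):
        out = {}
        for k, entry in payload[section].items():
            centroids = [read_profile(in_dir / f)
                         for f in entry["centroids"]]
            out[int(k)] = KMeansProfiles(
                centroids, np.asarray(entry["centers"], dtype=float),
                entry["encoding"])
        setattr(reg, "clust" if section == "clust" else "naive_clust", out)
    return reg


# ---------------------------------------------------------------------------
# Fitted models
# ---------------------------------------------------------------------------

def save_model(path, weights: WeightMatrix, sources: Sequence[str],
               pcfg: PenaltyConfig | None = None, objective: str = "l2",
               seeds: Mapping[str, int] | None = None,
               diagnostics: Mapping | None = None) -> None:
    from . import __version__

    payload = {
        "format": "clonalprof-model",
        "version": __version__,
        "objective": objective,
        "sources": list(sources),
        "alpha": weights.alpha.tolist(),
        "penalty": None if pcfg is None else {
            "lambda1": pcfg.lambda1, "lambda2": pcfg.lambda2, "d": pcfg.d},
        "seeds": dict(seeds or {}),
        "diagnostics": dict(diagnostics or {}),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path) -> tuple[WeightMatrix, list[str], dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "clonalprof-model":
        raise ValueError(f"{path} is not a fitted model file")
    w = WeightMatrix(np.asarray(payload["alpha"], dtype=float))
    return w, list(payload["sources"]), payload


# ---------------------------------------------------------------------------
# Single-sequence prediction
# ---------------------------------------------------------------------------

def predict_single(cf: ClonalFamily, weights: WeightMatrix,
                   sources: Sequence[str], registry: SourceRegistry
                   ) -> tuple[SubstitutionProfile, pd.DataFrame]:
    """Predict the CF-specific profile for one annotated input sequence.

    The input profile is the one-hot encoding of the (single) sequence; the
    requested sources are assembled from the registry (a precomputed
    neutral profile must be registered under the CF id when the model uses
    ``neut``).  Returns the predicted profile plus a position x amino-acid
    frequency table suitable for logo rendering.
    """
    seq = cf.sequences[0]
    x = ProfileTensor.from_profiles(
        [SubstitutionProfile.one_hot(seq, cf.numbering)], [cf.cf_id])
    specs = tuple(ProfileSourceSpec.parse(s) for s in sources)
    xstar = assemble_input_tensor(x, [cf], specs, registry)
    yhat = predict(x, xstar, weights)
    profile = yhat.profile(0)
    logo = profile_to_frame(profile)
    return profile, logo
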