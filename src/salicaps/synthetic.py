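"""Synthetic motif-implanted protein datasets.

The generator emulates the statistical structure the classifier relies on:
positive sequences carry a terminal signal-like motif (with per-position
substitution noise, mimicking degenerate sorting signals), negatives come
from protein families with family-specific residue composition and a family
signature k-mer (mimicking Pfam-style family structure), and per-protein
profiles are per-position residue-composition vectors perturbed with
Dirichlet noise (mimicking the conservation structure of an alignment-derived
PSSM without running any profile search).

The module also implements the negative-set construction rule used for real
data: sample a fixed number of members from each sufficiently large family,
and greedily remove mutually similar sequences with a fast k-mer-containment
redundancy filter (a stand-in for an exact-identity clustering tool such as
CD-HIT; see :func:`redundancy_filter`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from salicaps.encoding import (
    AMINO_ACIDS,
    ProfileMatrix,
    ProteinRecord,
    encode_records,
)
from salicaps.training import LabeledDataset

_AA = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults give the desk-scale study conditions used throughout the test
    suite: 100 positives, 500 negatives drawn from 25 families, sequence
    lengths 50-300, a 12-residue N-terminal motif with 10% per-position
    substitution noise, and Dirichlet-concentration-30 profile noise around a
    0.8-peaked per-position composition.
    """

    n_positives: int = 100
    n_negatives: int = 500
    n_families: int = 25
    family_size_distribution: tuple[int, int] = (10, 30)
    motif_length: int = 12
    motif_position: str = "n_terminal"
    motif_substitution_rate: float = 0.1
    background_composition: tuple[float, ...] = field(
        default_factory=lambda: tuple([0.05] * 20)
    )
    profile_noise: float = 30.0
    profile_peak: float = 0.8
    sequence_length_distribution: tuple[int, int] = (50, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_position not in ("n_terminal", "c_terminal", "internal"):
            raise ValueError(f"unknown motif_position {self.motif_position!r}")
        for name in ("n_positives", "n_negatives", "n_families", "motif_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        comp = np.asarray(self.background_composition)
        if comp.shape != (20,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("background_composition must be a 20-vector summing to 1")
        lo, hi = self.sequence_length_distribution
        if self.motif_length > lo:
            raise ValueError("motif longer than the minimum sequence length")
        if lo < 1 or hi < lo:
            raise ValueError("invalid sequence_length_distribution")


@dataclass
class SyntheticDataset:
    """Generated records, profiles, labels and family assignments."""

    records: list[ProteinRecord]
    profiles: list[ProfileMatrix]
    labels: np.ndarray
    family_of: dict[str, str]
    motif: str

    def to_labeled(self, input_len: int = 100) -> LabeledDataset:
        """Encode profiles to fixed-size inputs for training."""
        profile_map = {r.id: p for r, p in zip(self.records, self.profiles)}
        inputs = encode_records(self.records, profile_map, max_len=input_len)
        return LabeledDataset(
            inputs=inputs, labels=self.labels, ids=[r.id for r in self.records]
        )

    def split(self, idx: Sequence[int]) -> "SyntheticDataset":
        idx = list(idx)
        return SyntheticDataset(
            records=[self.records[i] for i in idx],
            profiles=[self.profiles[i] for i in idx],
            labels=self.labels[idx],
            family_of=self.family_of,
            motif=self.motif,
        )


def _draw_sequence(rng: np.random.Generator, length: int, comp: np.ndarray) -> str:
    return "".join(rng.choice(_AA, size=length, p=comp))


def _mutate(rng: np.random.Generator, seq: str, rate: float, comp: np.ndarray) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(_AA, p=comp))
    return "".join(out)


def _implant(seq: str, motif: str, position: str, rng: np.random.Generator) -> str:
    if position == "n_terminal":
        return motif + seq[len(motif) :]
    if position == "c_terminal":
        return seq[: -len(motif)] + motif
    start = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:start] + motif + seq[start + len(motif) :]


def _scrub_motif(seq: str, motif: str, comp: np.ndarray,
                 rng: np.random.Generator) -> str:
    # negatives must not contain the exact implanted motif
    while motif in seq:
        pos = seq.index(motif)
        replacement = str(rng.choice(_AA, p=comp))
        seq = seq[:pos] + replacement + seq[pos + 1 :]
    return seq


def _profile_for(
    seq: str, cfg: SyntheticConfig, rng: np.random.Generator
) -> ProfileMatrix:
    comp = np.asarray(cfg.background_composition)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    rows = np.empty((len(seq), 20))
    for i, aa in enumerate(seq):
        target = (1.0 - cfg.profile_peak) * comp.copy()
        target[aa_index[aa]] += cfg.profile_peak
        rows[i] = rng.dirichlet(cfg.profile_noise * target)
    return ProfileMatrix(values=rows, source="pssm")


def _family_sizes(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.family_size_distribution
    sizes = rng.integers(lo, hi + 1, size=cfg.n_families).astype(float)
    # rescale to hand out exactly n_negatives members (largest remainder)
    scaled = sizes * cfg.n_negatives / sizes.sum()
    out = np.floor(scaled).astype(int)
    remainder = cfg.n_negatives - out.sum()
    order = np.argsort(scaled - np.floor(scaled))[::-1]
    out[order[:remainder]] += 1
    return out


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a labeled dataset; byte-identical for a fixed seed.

    Positives (label 1) carry the noisy implanted motif at the configured
    terminus; negatives (label 0) are grouped into families sharing a
    composition bias and a signature 5-mer, and never contain the exact
    motif.
    """
    rng = np.random.default_rng(cfg.seed)
    comp = np.asarray(cfg.background_composition)
    lo, hi = cfg.sequence_length_distribution
    motif = _draw_sequence(rng, cfg.motif_length, comp)

    records: list[ProteinRecord] = []
    profiles: list[ProfileMatrix] = []
    labels: list[int] = []
    family_of: dict[str, str] = {}

    for i in range(cfg.n_positives):
        length = int(rng.integers(lo, hi + 1))
        seq = _draw_sequence(rng, length, comp)
        noisy_motif = _mutate(rng, motif, cfg.motif_substitution_rate, comp)
        seq = _implant(seq, noisy_motif, cfg.motif_position, rng)
        rec = ProteinRecord(id=f"POS{i:05d}", sequence=seq)
        records.append(rec)
        profiles.append(_profile_for(seq, cfg, rng))
        labels.append(1)
        family_of[rec.id] = "positives"

    sizes = _family_sizes(cfg, rng)
    member = 0
    for fam, size in enumerate(sizes):
        fam_name = f"FAM{fam:04d}"
        fam_comp = rng.dirichlet(10.0 * comp * 20.0)
        signature = _draw_sequence(rng, 5, fam_comp)
        for _ in range(size):
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_sequence(rng, length, fam_comp)
            start = int(rng.integers(0, length - 5 + 1))
            seq = seq[:start] + signature + seq[start + 5 :]
            seq = _scrub_motif(seq, motif, comp, rng)
            rec = ProteinRecord(id=f"NEG{member:05d}", sequence=seq)
            records.append(rec)
            profiles.append(_profile_for(seq, cfg, rng))
            labels.append(0)
            family_of[rec.id] = fam_name
            member += 1

    return SyntheticDataset(
        records=records,
        profiles=profiles,
        labels=np.asarray(labels, dtype=np.int64),
        family_of=family_of,
        motif=motif,
    )


def sample_negative_families(
    families: Mapping[str, Sequence[str]],
    min_size: int = 10,
    per_family: int = 3,
    seed: int = 0,
) -> list[str]:
    """Sample candidate negatives from sufficiently populated families.

    Families with fewer than ``min_size`` members are excluded (small
    families carry little evidence of being a coherent group); from each
    retained family ``per_family`` members are drawn without replacement
    (the whole family when it has fewer than ``per_family`` members).
    """
    if not families:
        raise ValueError("family map is empty")
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for name in sorted(families):
        members = list(families[name])
        if len(members) < min_size:
            continue
        take = min(per_family, len(members))
        idx = rng.choice(len(members), size=take, replace=False)
        selected.extend(members[i] for i in sorted(idx))
    if not selected:
        warnings.warn(
            f"no family reached min_size={min_size}; returning empty selection",
            stacklevel=2,
        )
    return selected


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def approximate_identity(a: str, b: str, k: int = 3) -> float:
    """Shared-k-mer containment: |kmers(a) & kmers(b)| / min(|kmers|).

    A fast proxy for alignment identity, adequate for redundancy filtering of
    synthetic fixtures; it is not an alignment.
    """
    ka, kb = _kmers(a, k), _kmers(b, k)
    if not ka or not kb:
        return 1.0 if a == b else 0.0
    return len(ka & kb) / min(len(ka), len(kb))


def redundancy_filter(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.30,
    k: int = 3,
) -> list[ProteinRecord]:
    """Greedy longest-first redundancy removal.

    Sequences are visited longest first; each either joins the cluster of the
    first retained representative it resembles above ``identity_threshold``
    (k-mer containment estimate) or becomes a new representative.  One
    representative per cluster is kept, returned in input order.  This is a
    deterministic stand-in for exact-identity clustering tools (CD-HIT style).
    """
    if not 0.0 < identity_threshold < 1.0:
        raise ValueError("identity_threshold must lie in (0, 1)")
    order = sorted(
        range(len(records)), key=lambda i: (-len(records[i]), records[i].id)
    )
    representatives: list[int] = []
    for i in order:
        seq = records[i].sequence
        if not any(
            approximate_identity(seq, records[j].sequence, k=k)
            > identity_threshold
            for j in representatives
        ):
            representatives.append(i)
    return [records[i] for i in sorted(representatives)]
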