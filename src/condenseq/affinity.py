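"""Per-monomer protein-binding affinity profiles for the four DNA models.

Sequence heterogeneity enters the model purely through the monomer-protein
attraction strength eps_MP along the chain contour.  Four landscapes are
supported:

* ``homogeneous`` -- every monomer binds proteins at 2.0 kBT (null model).
* ``het1`` -- an A-B-A block copolymer: a central high-affinity half of the
  chain at 2.25 kBT flanked by two quarter-length blocks at 1.75 kBT, so the
  chain-average affinity equals the homogeneous 2.0 kBT.
* ``het2`` -- two high-affinity blocks (2.25 kBT) separated and flanked by
  low-affinity blocks (0.1 kBT), five equal blocks in total.
* ``sequence_mapped`` -- affinities assigned from the AT content of
  consecutive non-overlapping 10-bp windows of a real nucleotide sequence,
  linearly interpolated over eleven classes between 0.1 and 4.0 kBT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AFFINITY_MIN = 0.1  # kBT, AT count 0
AFFINITY_MAX = 4.0  # kBT, AT count 10
HOMOGENEOUS_EPS = 2.0  # kBT
HIGH_EPS = 2.25  # kBT
LOW_EPS_HET1 = 1.75  # kBT
LOW_EPS_HET2 = 0.1  # kBT

BLOCK_MODELS = ("homogeneous", "het1", "het2")


@dataclass
class AffinityProfile:
    """Monomer-protein binding energies along the DNA contour.

    Attributes
    ----------
    affinities : ndarray of float
        eps_MP per monomer, kBT, each in [0.1, 4.0].
    kind_labels : ndarray of int
        Integer class per monomer (for sequence-mapped profiles the AT count
        0-10; for block models an index over the distinct blocks' levels).
    model_name : str
        One of ``homogeneous | het1 | het2 | sequence_mapped``.
    """

    affinities: np.ndarray
    kind_labels: np.ndarray
    model_name: str

    def __post_init__(self) -> None:
        self.affinities = np.asarray(self.affinities, dtype=float)
        self.kind_labels = np.asarray(self.kind_labels, dtype=int)
        if self.affinities.shape != self.kind_labels.shape:
            raise ValueError("affinities and kind_labels must have equal length")
        if self.affinities.size == 0:
            raise ValueError("empty affinity profile")
        lo, hi = self.affinities.min(), self.affinities.max()
        if lo < AFFINITY_MIN - 1e-12 or hi > AFFINITY_MAX + 1e-12:
            raise ValueError(
                f"affinities must lie in [{AFFINITY_MIN}, {AFFINITY_MAX}] kBT, "
                f"got range [{lo}, {hi}]")

    @property
    def length(self) -> int:
        """Number of monomers (10 bp each)."""
        return self.affinities.size

    def distinct_levels(self) -> np.ndarray:
        """Sorted distinct affinity values present in the profile."""
        return np.unique(self.affinities)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "monomer_index": np.arange(self.length),
            "at_count": self.kind_labels,
            "affinity_kBT": self.affinities,
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class LayoutError(ValueError):
    """Chain length incompatible with the requested block layout."""


def build_block_profile(model_name: str, n_monomers: int = 500) -> AffinityProfile:
    """Construct one of the three block-copolymer affinity landscapes.

    ``het1`` needs ``n_monomers`` divisible by 4 (25% / 50% / 25% blocks);
    ``het2`` needs divisibility by 5 (five equal blocks, alternating
    low-high-low-high-low).  Scaled-down chains keep the same proportions.
    """
    if model_name not in BLOCK_MODELS:
        raise ValueError(f"unknown block model {model_name!r}; expected one of {BLOCK_MODELS}")
    if n_monomers < 1:
        raise LayoutError(f"need at least one monomer, got {n_monomers}")
    if model_name == "homogeneous":
        aff = np.full(n_monomers, HOMOGENEOUS_EPS)
        kinds = np.zeros(n_monomers, dtype=int)
    elif model_name == "het1":
        if n_monomers % 4 != 0:
            raise LayoutError(
                f"het1 layout (25%/50%/25%) needs a chain length divisible by 4, got {n_monomers}")
        q = n_monomers // 4
        aff = np.concatenate([
            np.full(q, LOW_EPS_HET1),
            np.full(2 * q, HIGH_EPS),
            np.full(q, LOW_EPS_HET1),
        ])
        kinds = (aff == HIGH_EPS).astype(int)
    else:  # het2
        if n_monomers % 5 != 0:
            raise LayoutError(
                f"het2 layout (5 equal blocks) needs a chain length divisible by 5, got {n_monomers}")
        b = n_monomers // 5
        aff = np.concatenate([
            np.full(b, LOW_EPS_HET2),
            np.full(b, HIGH_EPS),
            np.full(b, LOW_EPS_HET2),
            np.full(b, HIGH_EPS),
            np.full(b, LOW_EPS_HET2),
        ])
        kinds = (aff == HIGH_EPS).astype(int)
    return AffinityProfile(aff, kinds, model_name)


def at_count_to_affinity(at_count: int) -> float:
    """Map the AT count of a 10-bp window (0-10) to a binding energy in kBT.

    Eleven equally spaced levels spanning [0.1, 4.0] kBT: AT-free windows
    bind weakest, all-AT windows strongest.
    """
    if not 0 <= at_count <= 10:
        raise ValueError(f"AT count must be in 0..10, got {at_count}")
    return AFFINITY_MIN + at_count * (AFFINITY_MAX - AFFINITY_MIN) / 10.0


def sequence_to_profile(dna_sequence: str) -> AffinityProfile:
    """Build an affinity profile from a nucleotide sequence.

    The sequence is partitioned into consecutive non-overlapping 10-bp
    windows from the 5' end (one monomer per window, trailing remainder
    dropped); each monomer's affinity follows the AT count of its window.
    ``N`` bases count as non-AT.
    """
    seq = dna_sequence.strip().upper()
    if len(seq) < 10:
        raise ValueError(f"sequence must be at least 10 bp, got {len(seq)}")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    if set(seq) == {"N"}:
        raise ValueError("sequence is all N; no AT content defined")
    n_mono = len(seq) // 10
    counts = np.empty(n_mono, dtype=int)
    for m in range(n_mono):
        window = seq[10 * m: 10 * (m + 1)]
        counts[m] = window.count("A") + window.count("T")
    aff = np.array([at_count_to_affinity(c) for c in counts])
    return AffinityProfile(aff, counts, "sequence_mapped")


def profile_from_fasta(path: str | Path, record_id: str | None = None,
                       last_bp: int | None = None) -> AffinityProfile:
    """Read a FASTA file and map one record to an affinity profile.

    The first record is used unless ``record_id`` names another.  With
    ``last_bp`` only the trailing ``last_bp`` bases are mapped (e.g. the last
    5 kb of a phage genome).
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    seq = str(rec.seq)
    if last_bp is not None:
        seq = seq[-last_bp:]
    return sequence_to_profile(seq)
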