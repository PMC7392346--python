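"""Synthetic riboswitch-like sequence families with known ground truth.

Each family is a :class:`FamilyProfile`: a background nucleotide composition,
a set of signature k-mers (length 3-6), a per-signature insertion rate
(expected insertions per 100 nt, Poisson-distributed per sequence), and a
length range inside the 50-250 nt band typical of riboswitches. Sequences
are drawn from the background and signatures are written over the background
at uniform random positions, so lengths stay exact and the planted signal is
countable.

The ``paper_shaped_preset`` reproduces the shape of a severely imbalanced
16-family collection — family sizes geometrically interpolated from
round(4826 * scale) down to max(5, round(39 * scale)) — with distinct random
signature sets per family. At scale 1 that is the 4,826-vs-39 imbalance of
the real collection; at scale 0.02 it is a 97-vs-5 desk-sized analogue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._random import substream
from .io import RNA_ALPHABET, SequenceRecord, write_fasta, write_labels_tsv

__all__ = ["FamilyProfile", "DatasetConfig", "generate_dataset", "paper_shaped_preset"]

LENGTH_BAND = (50, 250)  # nt; the riboswitch size range


@dataclass(frozen=True)
class FamilyProfile:
    """Generative recipe for one sequence family."""

    name: str
    signatures: tuple[str, ...]
    insertion_rate: float = 4.0  # expected insertions per signature per 100 nt
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    length_range: tuple[int, int] = (50, 250)

    def __post_init__(self) -> None:
        if self.insertion_rate < 0:
            raise ValueError(f"{self.name}: insertion rate must be >= 0")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: composition must sum to 1")
        lo, hi = self.length_range
        if not (LENGTH_BAND[0] <= lo <= hi <= LENGTH_BAND[1]):
            raise ValueError(
                f"{self.name}: length range {self.length_range} outside the "
                f"{LENGTH_BAND[0]}-{LENGTH_BAND[1]} nt riboswitch band"
            )
        for sig in self.signatures:
            if not (3 <= len(sig) <= 6):
                raise ValueError(f"{self.name}: signature {sig!r} must be 3-6 nt")
            if set(sig) - set(RNA_ALPHABET):
                raise ValueError(f"{self.name}: signature {sig!r} not over {{A,C,G,U}}")
            if len(sig) > lo:
                raise ValueError(f"{self.name}: signature {sig!r} longer than min length")


@dataclass(frozen=True)
class DatasetConfig:
    families: tuple[FamilyProfile, ...]
    counts: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.families) != len(self.counts):
            raise ValueError("families and counts differ in length")
        if any(c < 1 for c in self.counts):
            raise ValueError("family counts must be >= 1")
        names = [p.name for p in self.families]
        if len(set(names)) != len(names):
            raise ValueError("family names must be unique")


def _generate_sequence(profile: FamilyProfile, rng: np.random.Generator) -> str:
    lo, hi = profile.length_range
    length = int(rng.integers(lo, hi + 1))
    seq = rng.choice(np.array(list(RNA_ALPHABET)), size=length, p=profile.composition)
    for sig in profile.signatures:
        n_ins = rng.poisson(profile.insertion_rate * length / 100.0)
        for _ in range(n_ins):
            pos = int(rng.integers(0, length - len(sig) + 1))
            seq[pos : pos + len(sig)] = list(sig)
    return "".join(seq)


def generate_dataset(
    config: DatasetConfig, out_dir: str | Path | None = None
) -> list[SequenceRecord]:
    """Draw the configured number of sequences per family, reproducibly.

    With ``out_dir`` the dataset is also written to disk as
    ``sequences.fasta``, ``labels.tsv`` and ``truth.json`` (the profiles and
    planted signatures, i.e. the ground truth a recovery analysis checks
    against).
    """
    rng = substream(config.seed, "simulate")
    records: list[SequenceRecord] = []
    for profile, count in zip(config.families, config.counts):
        for i in range(count):
            records.append(
                SequenceRecord(
                    id=f"{profile.name}_{i:05d}",
                    family=profile.name,
                    residues=_generate_sequence(profile, rng),
                )
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "sequences.fasta")
        write_labels_tsv(records, out_dir / "labels.tsv")
        truth = {
            "seed": config.seed,
            "families": [
                {
                    "name": p.name,
                    "count": c,
                    "signatures": list(p.signatures),
                    "insertion_rate": p.insertion_rate,
                    "composition": list(p.composition),
                    "length_range": list(p.length_range),
                }
                for p, c in zip(config.families, config.counts)
            ],
        }
        (out_dir / "truth.json").write_text(
            json.dumps(truth, sort_keys=True, indent=2) + "\n"
        )
    return records


def _random_signatures(
    rng: np.random.Generator, n: int, taken: set[str], lengths: Sequence[int] = (4, 5, 6)
) -> tuple[str, ...]:
    sigs: list[str] = []
    while len(sigs) < n:
        k = int(rng.choice(lengths))
        sig = "".join(rng.choice(np.array(list(RNA_ALPHABET)), size=k))
        if sig not in taken:
            taken.add(sig)
            sigs.append(sig)
    return tuple(sigs)


def paper_shaped_preset(
    scale: float = 0.02,
    seed: int = 0,
    n_families: int = 16,
    insertion_rate: float = 4.0,
    length_range: tuple[int, int] = (50, 250),
) -> DatasetConfig:
    """A 16-family collection with the 4,826-to-39 imbalance shape.

    Family sizes interpolate geometrically between ``round(4826 * scale)`` and
    ``max(5, round(39 * scale))``; each family gets two distinct random
    signature k-mers over a uniform background.
    """
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    hi = int(round(4826 * scale))
    lo = max(5, int(round(39 * scale)))
    if hi < lo:
        raise ValueError(f"scale {scale} too small: largest family {hi} < smallest {lo}")
    ratio = (lo / hi) ** (1.0 / (n_families - 1)) if n_families > 1 else 1.0
    counts = tuple(max(lo, int(round(hi * ratio**i))) for i in range(n_families))

    rng = substream(seed, "preset-profiles")
    taken: set[str] = set()
    families = tuple(
        FamilyProfile(
            name=f"FAM{i + 1:02d}",
            signatures=_random_signatures(rng, 2, taken),
            insertion_rate=insertion_rate,
            length_range=length_range,
        )
        for i in range(n_families)
    )
    return DatasetConfig(families=families, counts=counts, seed=seed)
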