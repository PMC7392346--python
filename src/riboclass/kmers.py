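"""k-mer featurization of RNA sequences.

Every overlapping window of length k (k_min <= k <= k_max) is counted with
stride 1. Over the 4-letter RNA alphabet and the default 1 <= k <= 6 range
this yields 4 + 16 + ... + 4096 = 5460 features. Columns are ordered by
ascending k and lexicographically (A < C < G < U) within each k, so a count
vector is reproducible from the column list alone. Windows containing an
ambiguous residue (N) contribute to no k-mer.

The module also derives two presentation matrices used for interpreting a
selected feature subset: a row-normalized family profile (mean k-mer count
per family, min-max scaled per feature) and a per-base coverage track that
maps selected k-mers back onto a single sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .io import RNA_ALPHABET, SequenceRecord

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def enumerate_kmers(
    alphabet: Sequence[str] = RNA_ALPHABET, k_min: int = 1, k_max: int = 6
) -> list[str]:
    """All k-mers over `alphabet`, ascending k, lexicographic within each k."""
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("alphabet contains duplicate characters")
    if not (1 <= k_min <= k_max):
        raise ValueError(f"need 1 <= k_min <= k_max, got ({k_min}, {k_max})")
    return [
        "".join(p)
        for k in range(k_min, k_max + 1)
        for p in itertools.product(alphabet, repeat=k)
    ]


def _residues(x: SequenceRecord | str) -> str:
    return x.residues if isinstance(x, SequenceRecord) else x


def _encode(seq: str) -> np.ndarray:
    """Map residues to {0..3}; ambiguous characters become -1."""
    return np.fromiter((_BASE_CODE.get(c, -1) for c in seq), dtype=np.int64, count=len(seq))


def count_kmers(
    record: SequenceRecord | str, k_min: int = 1, k_max: int = 6
) -> np.ndarray:
    """Overlapping k-mer counts aligned to :func:`enumerate_kmers` order.

    k-mers longer than the sequence get zero counts; windows spanning an
    ambiguous residue are skipped.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError(f"need 1 <= k_min <= k_max, got ({k_min}, {k_max})")
    enc = _encode(_residues(record))
    sizes = [4**k for k in range(k_min, k_max + 1)]
    out = np.zeros(sum(sizes), dtype=np.int64)
    offset = 0
    for k, size in zip(range(k_min, k_max + 1), sizes):
        if len(enc) >= k:
            windows = sliding_window_view(enc, k)
            valid = (windows >= 0).all(axis=1)
            if valid.any():
                powers = 4 ** np.arange(k - 1, -1, -1)
                codes = windows[valid] @ powers
                out[offset : offset + size] = np.bincount(codes, minlength=size)
        offset += size
    return out


@dataclass
class KmerFeatureMatrix:
    """n_sequences x n_kmers count matrix with family labels per row."""

    X: pd.DataFrame  # index: sequence ids; columns: k-mer strings
    families: pd.Series  # index: sequence ids
    k_range: tuple[int, int]

    @property
    def ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def kmers(self) -> list[str]:
        return list(self.X.columns)

    def to_tsv(self, path: str | Path) -> None:
        df = self.X.copy()
        df.insert(0, "family", self.families)
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerFeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        families = df["family"].astype(str)
        X = df.drop(columns=["family"])
        lengths = [len(c) for c in X.columns]
        return cls(X=X, families=families, k_range=(min(lengths), max(lengths)))


class KmerCounter(TransformerMixin, BaseEstimator):
    """Stateless transformer from sequences to k-mer count vectors.

    Accepts :class:`~riboclass.io.SequenceRecord` objects or plain strings.
    ``fit`` only freezes the feature name list; ``transform`` returns an
    integer array of shape (n_sequences, n_kmers).
    """

    def __init__(self, k_min: int = 1, k_max: int = 6, alphabet: Sequence[str] = RNA_ALPHABET):
        self.k_min = k_min
        self.k_max = k_max
        self.alphabet = alphabet

    def fit(self, X: Iterable[SequenceRecord | str], y=None) -> "KmerCounter":
        self.feature_names_ = enumerate_kmers(self.alphabet, self.k_min, self.k_max)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Iterable[SequenceRecord | str]) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        return np.vstack([count_kmers(x, self.k_min, self.k_max) for x in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_, dtype=object)


def build_feature_matrix(
    records: Sequence[SequenceRecord], k_min: int = 1, k_max: int = 6
) -> KmerFeatureMatrix:
    """Count k-mers for every record; rows in input order, fixed column order."""
    if not records:
        raise ValueError("need at least one record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in record set")
    counter = KmerCounter(k_min=k_min, k_max=k_max).fit(records)
    X = pd.DataFrame(counter.transform(records), index=ids, columns=counter.feature_names_)
    families = pd.Series([r.family for r in records], index=ids, name="family")
    return KmerFeatureMatrix(X=X, families=families, k_range=(k_min, k_max))


def family_profile_matrix(
    matrix: KmerFeatureMatrix, kmer_subset: Sequence[str]
) -> pd.DataFrame:
    """Feature x family matrix of mean counts, min-max scaled per feature row.

    This is the row-normalized heatmap view of a selected subset: each cell is
    the mean count of a k-mer over one family's sequences, rescaled within the
    feature row to [0, 1]. Rows that are constant across families map to 0.
    """
    if len(kmer_subset) == 0:
        raise ValueError("kmer_subset must be non-empty")
    missing = [m for m in kmer_subset if m not in matrix.X.columns]
    if missing:
        raise ValueError(f"k-mers not in matrix columns: {missing!r}")
    means = matrix.X[list(kmer_subset)].groupby(matrix.families).mean().T
    lo = means.min(axis=1)
    span = means.max(axis=1) - lo
    scaled = means.sub(lo, axis=0).div(span.where(span > 0, 1.0), axis=0)
    scaled[span == 0] = 0.0
    return scaled


@dataclass
class CoverageTrack:
    """Per-base k-mer hit counts for one sequence, plus a [0,1] normalization."""

    id: str
    raw: np.ndarray
    normalized: np.ndarray


def kmer_coverage(
    record: SequenceRecord, kmer_subset: Sequence[str]
) -> CoverageTrack:
    """How many (k-mer, occurrence) windows from the subset cover each base.

    The normalized track divides by the maximum raw value (all zeros when no
    k-mer hits), giving the per-base color scale of a coverage figure.
    """
    if len(kmer_subset) == 0:
        raise ValueError("kmer_subset must be non-empty")
    seq = record.residues
    raw = np.zeros(len(seq), dtype=np.int64)
    for kmer in kmer_subset:
        start = seq.find(kmer)
        while start != -1:
            raw[start : start + len(kmer)] += 1
            start = seq.find(kmer, start + 1)
    peak = raw.max()
    normalized = raw / peak if peak > 0 else np.zeros_like(raw, dtype=float)
    return CoverageTrack(id=record.id, raw=raw, normalized=normalized)
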