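"""Contiguous and pseudo k-mer compositional encodings of nucleotide sequences.

Two encodings are provided:

* **CkM** (contiguous k-mer): for each window size ``k`` the normalized
  sliding-window k-mer frequencies ``f_1 .. f_{4^k}``; concatenating
  k = 1..4 gives 4 + 16 + 64 + 256 = 340 features.

* **PkM** (pseudo k-mer): the CkM block extended with ``d`` tier-correlation
  terms.  The j-th tier correlation is the mean squared difference between
  the global proportions of the k-mers occupying windows j positions apart,

      rho_j = 1/(N - j - k + 1) * sum_i [p(window_i) - p(window_{i+j})]^2 ,

  and the block ``(f_1 .. f_{4^k}, w*rho_1 .. w*rho_d)`` is jointly
  renormalized by ``D = sum_i f_i + w * sum_j rho_j`` so each per-k block
  sums to 1.  With d = 1 and k = 1..4 this gives 344 features.

Windows containing non-ACGT characters are excluded from both numerator and
denominator, so prediction still works on sequences with ambiguity codes.
Feature order is fixed (lexicographic A<C<G<T within each k, ascending k,
correlation terms after composition terms) so matrices and models are
portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .seqio import LabeledDataset, SequenceRecord

__all__ = [
    "KmerEncodingSpec",
    "FeatureMatrix",
    "enumerate_kmers",
    "kmer_frequencies",
    "tier_correlation",
    "ckm_encode",
    "pkm_encode",
    "encode_dataset",
    "feature_names",
]

_ALPHABET = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_ALPHABET):
    _BASE_INDEX[ord(_b)] = _i


@dataclass(frozen=True)
class KmerEncodingSpec:
    """Declarative description of an encoding.

    mode: "contiguous" (CkM) or "pseudo" (PkM).
    k_set: strictly ascending window sizes, default (1, 2, 3, 4).
    tier: number of correlation tiers d (pseudo only), default 1.
    weight: correlation weight factor w (pseudo only), default 0.1.
    """

    mode: str = "contiguous"
    k_set: tuple[int, ...] = (1, 2, 3, 4)
    tier: int = 1
    weight: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("contiguous", "pseudo"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if not self.k_set:
            raise ValueError("k_set must be non-empty")
        if any(k < 1 for k in self.k_set):
            raise ValueError("every k must be >= 1")
        if list(self.k_set) != sorted(set(self.k_set)):
            raise ValueError("k_set must be strictly ascending")
        if self.mode == "pseudo":
            if self.tier < 1:
                raise ValueError("tier d must be >= 1")
            if self.weight < 0:
                raise ValueError("weight w must be >= 0")

    @property
    def n_features(self) -> int:
        per_k = sum(4**k for k in self.k_set)
        if self.mode == "pseudo":
            per_k += self.tier * len(self.k_set)
        return per_k

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k_set": list(self.k_set),
            "tier": self.tier,
            "weight": self.weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KmerEncodingSpec":
        return cls(d["mode"], tuple(d["k_set"]), d["tier"], d["weight"])


@dataclass
class FeatureMatrix:
    """Named, deterministically ordered numeric features per sequence."""

    feature_names: list[str]
    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.feature_names)} names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.feature_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("id").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(float), [str(i) for i in df.index])

    def to_libsvm(self, path: str | Path, labels: Sequence[str] | None = None) -> None:
        """Sparse LIBSVM-style text export; labels default to 0."""
        with open(path, "w") as fh:
            for row_i, row in enumerate(self.values):
                lab = labels[row_i] if labels is not None else 0
                cells = " ".join(
                    f"{j + 1}:{v:.10g}" for j, v in enumerate(row) if v != 0.0
                )
                fh.write(f"{lab} {cells}\n")


def enumerate_kmers(k: int) -> list[str]:
    """All 4^k words over {A,C,G,T} in lexicographic order (A<C<G<T)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return ["".join(p) for p in product(_ALPHABET, repeat=k)]


def feature_names(spec: KmerEncodingSpec) -> list[str]:
    """Deterministic column names: ``k<k>:<kmer>`` plus ``k<k>:lambda<j>``."""
    names: list[str] = []
    for k in spec.k_set:
        names.extend(f"k{k}:{w}" for w in enumerate_kmers(k))
        if spec.mode == "pseudo":
            names.extend(f"k{k}:lambda{j}" for j in range(1, spec.tier + 1))
    return names


def _window_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all k-windows and a validity mask (all-ACGT windows)."""
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    arr = _BASE_INDEX[np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    codes = np.where(windows < 0, 0, windows) @ powers
    return codes, valid


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Normalized k-mer frequency vector f of length 4^k.

    f_i = (count of valid windows equal to k-mer i) / (number of valid
    windows); windows containing non-ACGT characters are excluded from both
    numerator and denominator.
    """
    codes, valid = _window_codes(seq, k)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError(
            f"no valid (all-ACGT) window of size {k} in sequence of length {len(seq)}"
        )
    counts = np.bincount(codes[valid], minlength=4**k).astype(float)
    return counts / n_valid


def tier_correlation(seq: str, k: int, j: int) -> float:
    """j-th tier correlation rho_j >= 0 between windows j positions apart.

    rho_j is the average of [p(window_i) - p(window_{i+j})]^2 over all
    positions where both windows are valid, p(.) being the global normalized
    frequency of the k-mer occupying the window.  Requires 1 <= j < N - k.
    """
    n = len(seq)
    if j < 1 or j >= n - k:
        raise ValueError(f"tier j must satisfy 1 <= j < N - k = {n - k}, got {j}")
    freqs = kmer_frequencies(seq, k)
    codes, valid = _window_codes(seq, k)
    p = np.where(valid, freqs[codes], np.nan)
    left, right = p[:-j], p[j:]
    ok = ~np.isnan(left) & ~np.isnan(right)
    if not ok.any():
        raise ValueError(f"no valid window pair at tier j={j}")
    diff = left[ok] - right[ok]
    return float(np.mean(diff * diff))


def ckm_encode(seq: str, k_set: Iterable[int] = (1, 2, 3, 4)) -> np.ndarray:
    """Contiguous k-mer vector: concatenated frequency blocks, ascending k."""
    return np.concatenate([kmer_frequencies(seq, k) for k in k_set])


def pkm_encode(
    seq: str,
    k_set: Iterable[int] = (1, 2, 3, 4),
    d: int = 1,
    w: float = 0.1,
) -> np.ndarray:
    """Pseudo k-mer vector: per k, (f, w*rho) jointly renormalized.

    Each per-k block has 4^k + d entries summing to 1:
    v_x = f_x / D for the composition part and v_{4^k+j} = w*rho_j / D for
    the correlation part, with D = sum_i f_i + w * sum_j rho_j.
    """
    blocks = []
    for k in k_set:
        if d >= len(seq) - k:
            raise ValueError(
                f"tier d={d} requires sequence length > k + d = {k + d}"
            )
        f = kmer_frequencies(seq, k)
        rho = np.array([tier_correlation(seq, k, j) for j in range(1, d + 1)])
        denom = f.sum() + w * rho.sum()
        blocks.append(np.concatenate([f, w * rho]) / denom)
    return np.concatenate(blocks)


def _encode_one(seq: str, spec: KmerEncodingSpec) -> np.ndarray:
    if spec.mode == "contiguous":
        return ckm_encode(seq, spec.k_set)
    return pkm_encode(seq, spec.k_set, spec.tier, spec.weight)


def encode_dataset(
    data: Union[LabeledDataset, Sequence[SequenceRecord]],
    spec: KmerEncodingSpec = KmerEncodingSpec(),
    *,
    skip_invalid: bool = False,
) -> tuple[FeatureMatrix, list[str]]:
    """Encode every record into a FeatureMatrix (rows in dataset order).

    Returns the matrix plus the list of skipped ids.  Records failing the
    encoder preconditions abort the run with all offending ids reported,
    unless ``skip_invalid`` is set, in which case they are dropped.
    """
    records = data.records if isinstance(data, LabeledDataset) else list(data)
    names = feature_names(spec)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            rows.append(_encode_one(rec.residues, spec))
            ids.append(rec.id)
        except ValueError as exc:
            failures.append((rec.id, str(exc)))
    if failures and not skip_invalid:
        detail = "; ".join(f"{rid}: {msg}" for rid, msg in failures[:10])
        raise ValueError(f"{len(failures)} record(s) failed to encode: {detail}")
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(names, values, ids), [rid for rid, _ in failures]
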