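"""Synthetic labeled sequence sets from class-specific Markov composition profiles.

Class-discriminative signal in herbicide-target gene sequences is k-mer
compositional (mono- through tetra-nucleotide usage differs between
classes), so the generator controls exactly that axis: each class is a
Markov chain over {A,C,G,T} whose transition rows are a convex mixture

    class rows = (1 - delta) * base + delta * class-specific rows

of a shared base profile and per-class rows drawn symmetrically from the
simplex.  ``delta = 0`` makes every class identical (a null benchmark);
``delta`` near 1 gives strongly separated compositions.  The default order
is 2 so that tri- and tetra-mer features carry signal beyond mononucleotide
composition.

The default benchmark mirrors the shapes of the study datasets: a balanced
binary set of 120 resistant + 120 non-resistant sequences, a 7-class set of
{ACCase 36, ALS 37, EPSPS 29, GS 25, HPPD 18, PDS 18, PPO 20} = 183
sequences, and an independent set of 44 resistant (per-class {9,9,7,6,4,4,5})
plus 1324 non-resistant sequences.  Everything is deterministic given
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import LabeledDataset, SequenceRecord, write_fasta
from .two_stage import NON_RESISTANT, RESISTANT, RESISTANT_CLASSES

__all__ = [
    "SyntheticClassProfile",
    "make_profiles",
    "generate_sequences",
    "make_benchmark",
    "make_binary_pools",
    "write_benchmark",
    "DEFAULT_MULTI_SIZES",
    "DEFAULT_INDEPENDENT_RESISTANT",
]

_ALPHABET = "ACGT"

# per-class sizes of the 7-class training set and the independent resistant set
DEFAULT_MULTI_SIZES: dict[str, int] = {
    "ACCase": 36, "ALS": 37, "EPSPS": 29, "GS": 25, "HPPD": 18, "PDS": 18, "PPO": 20,
}
DEFAULT_INDEPENDENT_RESISTANT: dict[str, int] = {
    "ACCase": 9, "ALS": 9, "EPSPS": 7, "GS": 6, "HPPD": 4, "PDS": 4, "PPO": 5,
}


@dataclass(frozen=True)
class SyntheticClassProfile:
    """Markov-chain composition profile for one class.

    ``transitions`` is the 4^order x 4 row-stochastic matrix (order 0 gives a
    single row, i.e. i.i.d. composition); ``initial`` distributes the first
    max(order, 1) nucleotides over the 4^max(order,1) possible words.
    Lengths are drawn uniformly from ``length_range``.
    """

    name: str
    order: int
    transitions: np.ndarray
    initial: np.ndarray
    length_range: tuple[int, int] = (300, 900)

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError(f"Markov order must be 0, 1 or 2, got {self.order}")
        t = np.asarray(self.transitions, float)
        if t.shape != (4**self.order, 4):
            raise ValueError(
                f"transitions must be {4**self.order} x 4 for order {self.order}"
            )
        if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must be non-negative and sum to 1")
        init = np.asarray(self.initial, float)
        if init.shape != (4 ** max(self.order, 1),):
            raise ValueError(
                f"initial must have length {4 ** max(self.order, 1)}"
            )
        if (init < 0).any() or not np.isclose(init.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must be normalized")
        lo, hi = self.length_range
        if lo > hi or lo < 16:   # >= 4 * max encoder k guarantees encodability
            raise ValueError(f"invalid length range {self.length_range}")


def _base_transitions(order: int) -> np.ndarray:
    """Fixed, mildly AT-rich base profile shared by all classes."""
    row = np.array([0.29, 0.21, 0.22, 0.28])
    return np.tile(row, (4**order, 1))


def make_profiles(
    n_classes: int,
    separation: float,
    order: int = 2,
    seed: int = 0,
    *,
    names: Sequence[str] | None = None,
    length_range: tuple[int, int] = (300, 900),
) -> list[SyntheticClassProfile]:
    """Per-class profiles as a delta-mixture of a shared base and class rows.

    class rows = (1 - delta) * base + delta * class-specific rows, the latter
    sampled from a flat Dirichlet per row (symmetric across classes, seeded).
    delta = 0 makes all profiles identical; rows stay stochastic for any
    delta by convexity.
    """
    if not 0 <= separation <= 1:
        raise ValueError(f"separation delta must be in [0, 1], got {separation}")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if names is None:
        names = [f"class{i}" for i in range(n_classes)]
    if len(names) != n_classes:
        raise ValueError("names must match n_classes")
    rng = np.random.default_rng(seed)
    base = _base_transitions(order)
    n_states = 4 ** max(order, 1)
    profiles = []
    for name in names:
        specific = rng.dirichlet(np.ones(4), size=4**order)
        transitions = (1 - separation) * base + separation * specific
        initial_specific = rng.dirichlet(np.ones(n_states))
        initial = (1 - separation) * np.full(n_states, 1 / n_states) \
            + separation * initial_specific
        profiles.append(
            SyntheticClassProfile(name, order, transitions, initial, length_range)
        )
    return profiles


def generate_sequences(
    profile: SyntheticClassProfile, n: int, seed: int = 0
) -> list[SequenceRecord]:
    """Sample n sequences from the profile's Markov chain (deterministic ids)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = profile.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    order = profile.order
    n_init = max(order, 1)
    trans_cum = np.cumsum(profile.transitions, axis=1)
    init_cum = np.cumsum(profile.initial)
    records = []
    for i in range(n):
        length = int(lengths[i])
        word = int(np.searchsorted(init_cum, rng.random()))
        chars = []
        for pos in range(n_init - 1, -1, -1):
            chars.append(_ALPHABET[(word >> (2 * pos)) & 3])
        state = word if order > 0 else 0
        mask = 4**order - 1
        u = rng.random(length)   # pre-drawn uniforms, one per position
        for pos in range(n_init, length):
            row = trans_cum[state & mask if order > 0 else 0]
            nxt = int(np.searchsorted(row, u[pos]))
            chars.append(_ALPHABET[nxt])
            if order > 0:
                state = ((state << 2) | nxt) & mask
        records.append(
            SequenceRecord(f"{profile.name}_{i}", "", "".join(chars[:length]))
        )
    return records


def _benchmark_profiles(
    delta_binary: float,
    delta_multi: float,
    order: int,
    seed: int,
    length_range: tuple[int, int],
) -> tuple[list[SyntheticClassProfile], SyntheticClassProfile]:
    """Seven resistant class profiles plus the non-resistant profile.

    The resistant-vs-non-resistant axis is separated by ``delta_binary``
    (two delta-mixtures of the shared base), and the seven resistant classes
    are separated among themselves by ``delta_multi`` around the resistant
    centre.
    """
    rng = np.random.default_rng(seed)
    base = _base_transitions(order)
    n_states = 4 ** max(order, 1)
    res_rows = rng.dirichlet(np.ones(4), size=4**order)
    nonres_rows = rng.dirichlet(np.ones(4), size=4**order)
    res_centre = (1 - delta_binary) * base + delta_binary * res_rows
    nonres_trans = (1 - delta_binary) * base + delta_binary * nonres_rows
    uniform_init = np.full(n_states, 1 / n_states)
    nonres_profile = SyntheticClassProfile(
        NON_RESISTANT, order, nonres_trans, uniform_init, length_range
    )
    res_profiles = []
    for name in RESISTANT_CLASSES:
        specific = rng.dirichlet(np.ones(4), size=4**order)
        transitions = (1 - delta_multi) * res_centre + delta_multi * specific
        res_profiles.append(
            SyntheticClassProfile(name, order, transitions, uniform_init, length_range)
        )
    return res_profiles, nonres_profile


def make_binary_pools(
    delta_binary: float = 0.8,
    n_resistant: int = 122,
    n_non_resistant: int = 1444,
    order: int = 2,
    seed: int = 0,
    *,
    delta_multi: float = 0.8,
    length_range: tuple[int, int] = (300, 900),
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Class pools for bootstrap CV (defaults mirror the 122/1444 pool sizes).

    Resistant pool sequences are drawn round-robin across the seven class
    profiles; ids are globally unique.
    """
    res_profiles, nonres_profile = _benchmark_profiles(
        delta_binary, delta_multi, order, seed, length_range
    )
    per_class = [n_resistant // 7 + (1 if i < n_resistant % 7 else 0) for i in range(7)]
    resistant: list[SequenceRecord] = []
    for i, (profile, count) in enumerate(zip(res_profiles, per_class)):
        if count:
            resistant.extend(generate_sequences(profile, count, seed=seed + 1000 + i))
    non_resistant = generate_sequences(nonres_profile, n_non_resistant, seed=seed + 2000)
    return resistant, non_resistant


def make_benchmark(
    delta_binary: float = 0.8,
    delta_multi: float = 0.8,
    *,
    binary_per_class: int = 120,
    multi_sizes: dict[str, int] | None = None,
    independent_resistant: dict[str, int] | None = None,
    independent_non_resistant: int = 1324,
    order: int = 2,
    seed: int = 0,
    length_range: tuple[int, int] = (300, 900),
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """The three study-shaped datasets: binary, 7-class and 8-class independent.

    Returns (binary 120+120, multi 183 with the default per-class sizes,
    independent 44 resistant + 1324 non-resistant); all sizes configurable,
    all content reproducible from the seed.
    """
    if binary_per_class < 1 or independent_non_resistant < 0:
        raise ValueError("sizes must be positive")
    multi_sizes = dict(DEFAULT_MULTI_SIZES if multi_sizes is None else multi_sizes)
    independent_resistant = dict(
        DEFAULT_INDEPENDENT_RESISTANT
        if independent_resistant is None
        else independent_resistant
    )
    if any(n < 2 for n in multi_sizes.values()):
        raise ValueError("every 7-class size must be >= 2")
    res_profiles, nonres_profile = _benchmark_profiles(
        delta_binary, delta_multi, order, seed, length_range
    )
    by_name = {p.name: p for p in res_profiles}

    # binary set: resistant drawn round-robin over the 7 class profiles
    per_class = [
        binary_per_class // 7 + (1 if i < binary_per_class % 7 else 0)
        for i in range(7)
    ]
    bin_records: list[SequenceRecord] = []
    bin_labels: list[str] = []
    for i, (profile, count) in enumerate(zip(res_profiles, per_class)):
        if count == 0:
            continue
        for rec in generate_sequences(profile, count, seed=seed + 100 + i):
            bin_records.append(
                SequenceRecord(f"bin_{rec.id}", "", rec.residues)
            )
            bin_labels.append(RESISTANT)
    for rec in generate_sequences(nonres_profile, binary_per_class, seed=seed + 200):
        bin_records.append(SequenceRecord(f"bin_{rec.id}", "", rec.residues))
        bin_labels.append(NON_RESISTANT)
    binary = LabeledDataset(bin_records, bin_labels, frozenset({RESISTANT, NON_RESISTANT}))

    multi_records: list[SequenceRecord] = []
    multi_labels: list[str] = []
    for i, cls in enumerate(RESISTANT_CLASSES):
        for rec in generate_sequences(by_name[cls], multi_sizes[cls], seed=seed + 300 + i):
            multi_records.append(SequenceRecord(f"multi_{rec.id}", "", rec.residues))
            multi_labels.append(cls)
    multi = LabeledDataset(multi_records, multi_labels, frozenset(RESISTANT_CLASSES))

    ind_records: list[SequenceRecord] = []
    ind_labels: list[str] = []
    for i, cls in enumerate(RESISTANT_CLASSES):
        count = independent_resistant.get(cls, 0)
        if count == 0:
            continue
        for rec in generate_sequences(by_name[cls], count, seed=seed + 400 + i):
            ind_records.append(SequenceRecord(f"ind_{rec.id}", "", rec.residues))
            ind_labels.append(cls)
    if independent_non_resistant:
        for rec in generate_sequences(
            nonres_profile, independent_non_resistant, seed=seed + 500
        ):
            ind_records.append(SequenceRecord(f"ind_{rec.id}", "", rec.residues))
            ind_labels.append(NON_RESISTANT)
    independent = LabeledDataset(
        ind_records, ind_labels, frozenset(RESISTANT_CLASSES) | {NON_RESISTANT}
    )
    return binary, multi, independent


def write_benchmark(
    outdir: str | Path,
    delta_binary: float = 0.8,
    delta_multi: float = 0.8,
    seed: int = 0,
    **kwargs,
) -> dict[str, Path]:
    """Materialize the default benchmark as FASTA + TSV label files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets = dict(
        zip(
            ("binary", "multiclass", "independent"),
            make_benchmark(delta_binary, delta_multi, seed=seed, **kwargs),
        )
    )
    paths: dict[str, Path] = {}
    for name, ds in datasets.items():
        fasta = outdir / f"{name}.fasta"
        labels = outdir / f"{name}.labels.tsv"
        write_fasta(ds.records, fasta)
        with open(labels, "w") as fh:
            for rec, lab in zip(ds.records, ds.labels):
                fh.write(f"{rec.id}\t{lab}\n")
        paths[name] = fasta
        paths[f"{name}_labels"] = labels
    return paths
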