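"""Bag/instance data model, MUSK-style file I/O, synthetic bags, CV splits.

A *bag* is a labeled set of instance feature vectors — a molecule's
conformations in the MUSK benchmark, or one whole-slide image's patch
features.  Supervision is bag-level only: a bag is positive iff it contains
at least one "witness" instance drawn from the concept distribution.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "Bag",
    "MILDataset",
    "SyntheticConfig",
    "CVSplit",
    "read_musk",
    "write_musk",
    "generate_bags",
    "split_cv",
    "save_dataset",
    "load_dataset",
    "Standardizer",
]


@dataclass
class Bag:
    """One labeled set of instance feature vectors.

    ``instance_labels`` marks witness instances (1) when known — synthetic
    bags carry it; real data does not (bag-level supervision only).
    """

    bag_id: str
    instances: np.ndarray  # (n_i, d)
    label: int
    instance_labels: np.ndarray | None = None

    def __post_init__(self):
        self.instances = np.atleast_2d(np.asarray(self.instances, dtype=np.float64))
        if self.instances.shape[0] < 1:
            raise ValueError(f"bag {self.bag_id!r} has no instances")
        if self.label not in (0, 1):
            raise ValueError(f"bag {self.bag_id!r}: label must be 0 or 1")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]


@dataclass
class MILDataset:
    bags: list[Bag]
    feature_dim: int
    name: str = "dataset"

    def __post_init__(self):
        ids = [b.bag_id for b in self.bags]
        if len(set(ids)) != len(ids):
            raise ValueError("bag_ids must be unique")
        for b in self.bags:
            if b.instances.shape[1] != self.feature_dim:
                raise ValueError(
                    f"bag {b.bag_id!r} has feature dim {b.instances.shape[1]}, "
                    f"expected {self.feature_dim}"
                )

    def __len__(self) -> int:
        return len(self.bags)

    def __iter__(self) -> Iterator[Bag]:
        return iter(self.bags)

    def get(self, bag_id: str) -> Bag:
        for b in self.bags:
            if b.bag_id == bag_id:
                return b
        raise KeyError(bag_id)

    @property
    def bag_ids(self) -> list[str]:
        return [b.bag_id for b in self.bags]

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.bags], dtype=int)


@dataclass
class SyntheticConfig:
    """Generator settings for witness-structured MIL bags.

    Defaults give a well-separated two-population problem: background
    instances at the origin, witnesses offset by 2 per dimension
    (||concept − background|| = 8 against unit noise in 16 dimensions),
    with a fifth of the instances in each positive bag being witnesses and
    balanced bag labels.
    """

    n_bags: int = 200
    bag_size_range: tuple[int, int] = (6, 20)
    witness_rate: float = 0.2
    feature_dim: int = 16
    concept_mean: np.ndarray | None = None
    background_mean: np.ndarray | None = None
    noise_sd: float = 1.0
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")
        lo, hi = self.bag_size_range
        if lo < 1 or hi < lo:
            raise ValueError("bag_size_range must satisfy 1 <= min <= max")
        if not (0 < self.witness_rate <= 1):
            raise ValueError("witness_rate must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 <= self.positive_fraction <= 1):
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.concept_mean is None:
            self.concept_mean = np.full(self.feature_dim, 2.0)
        if self.background_mean is None:
            self.background_mean = np.zeros(self.feature_dim)
        self.concept_mean = np.asarray(self.concept_mean, dtype=np.float64)
        self.background_mean = np.asarray(self.background_mean, dtype=np.float64)
        if self.concept_mean.shape != (self.feature_dim,):
            raise ValueError("concept_mean length must equal feature_dim")
        if self.background_mean.shape != (self.feature_dim,):
            raise ValueError("background_mean length must equal feature_dim")


@dataclass
class CVSplit:
    fold_index: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/val/test ids must be pairwise disjoint")


# ----------------------------------------------------------------------
# MUSK-style tabular I/O
# ----------------------------------------------------------------------

def read_musk(path: str | Path) -> MILDataset:
    """Read a MUSK-style comma-separated file into a dataset.

    Layout: ``molecule_name, conformation_name, f_1, ..., f_d, class`` with
    one row per instance; rows sharing a molecule name form one bag.  The
    bag label is 1 if *any* of its rows is class-positive (the standard MIL
    convention for MUSK).  The feature dimension d is inferred from the
    first row.  Bags are ordered by first appearance.
    """
    path = Path(path)
    groups: dict[str, list[np.ndarray]] = {}
    row_labels: dict[str, list[int]] = {}
    d: int | None = None
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row:
                continue
            if len(row) < 4:
                raise ValueError(
                    f"{path.name}:{lineno}: expected molecule, conformation, "
                    f"features, class — got {len(row)} fields"
                )
            name = row[0]
            try:
                feats = np.array([float(v) for v in row[2:-1]])
                cls = float(row[-1])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric field ({exc})")
            if d is None:
                d = feats.size
            elif feats.size != d:
                raise ValueError(
                    f"{path.name}:{lineno}: feature count {feats.size} differs "
                    f"from inferred dimension {d}"
                )
            groups.setdefault(name, []).append(feats)
            row_labels.setdefault(name, []).append(int(cls > 0.5))
    if d is None:
        raise ValueError(f"{path.name}: empty file")
    bags = [
        Bag(bag_id=name, instances=np.vstack(rows),
            label=int(any(row_labels[name])))
        for name, rows in groups.items()
    ]
    return MILDataset(bags=bags, feature_dim=d, name=path.stem)


def write_musk(dataset: MILDataset, path: str | Path) -> None:
    """Write the canonical MUSK-style round-trip form (repr floats)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        for bag in dataset:
            for j, row in enumerate(bag.instances):
                writer.writerow(
                    [bag.bag_id, f"{bag.bag_id}_{j + 1}",
                     *(repr(float(v)) for v in row),
                     bag.label]
                )


# ----------------------------------------------------------------------
# Synthetic bags
# ----------------------------------------------------------------------

def generate_bags(config: SyntheticConfig) -> MILDataset:
    """Generate witness-structured bags from isotropic Gaussians.

    Positive bags: ``ceil(witness_rate * n_i)`` instances from
    N(concept_mean, noise_sd²·I), the rest from the background Gaussian.
    Negative bags are all-background.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_pos = int(round(config.positive_fraction * config.n_bags))
    labels = np.zeros(config.n_bags, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    lo, hi = config.bag_size_range
    bags = []
    for i in range(config.n_bags):
        n_i = int(rng.integers(lo, hi + 1))
        inst_labels = np.zeros(n_i, dtype=int)
        if labels[i] == 1:
            n_wit = math.ceil(config.witness_rate * n_i)
            inst_labels[:n_wit] = 1
            rng.shuffle(inst_labels)
        means = np.where(
            inst_labels[:, None] == 1, config.concept_mean, config.background_mean
        )
        X = means + config.noise_sd * rng.standard_normal((n_i, config.feature_dim))
        bags.append(
            Bag(bag_id=f"bag{i:04d}", instances=X, label=int(labels[i]),
                instance_labels=inst_labels)
        )
    return MILDataset(bags=bags, feature_dim=config.feature_dim, name="synthetic")


# ----------------------------------------------------------------------
# Cross-validation splits
# ----------------------------------------------------------------------

def split_cv(
    dataset: MILDataset,
    folds: int = 10,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> list[CVSplit]:
    """Repeated stratified shuffle-splits into train/val/test.

    Each fold is an *independent* stratified random split at the given
    fractions (not a rotation partition), reproducible from ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = np.array(dataset.bag_ids)
    y = dataset.labels
    n = len(ids)
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    if n_test < 1 or n_val < 1 or n - n_test - n_val < 1:
        raise ValueError(f"dataset of {n} bags is too small to split {fractions}")
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("stratified splitting needs >= 2 bags per class")
    splits = []
    for fold in range(folds):
        rest_ids, test_ids, rest_y, _ = train_test_split(
            ids, y, test_size=n_test, stratify=y, random_state=seed + fold
        )
        train_ids, val_ids = train_test_split(
            rest_ids, test_size=n_val, stratify=rest_y, random_state=seed + fold
        )
        splits.append(
            CVSplit(
                fold_index=fold,
                train_ids=list(train_ids),
                val_ids=list(val_ids),
                test_ids=list(test_ids),
            )
        )
    return splits


# ----------------------------------------------------------------------
# Serialization (bit-exact round trip)
# ----------------------------------------------------------------------

def save_dataset(dataset: MILDataset, path: str | Path) -> None:
    """Save to an ``.npz`` container: per-bag matrices + ids/labels arrays."""
    arrays = {
        "_ids": np.array(dataset.bag_ids),
        "_labels": dataset.labels,
        "_name": np.array(dataset.name),
    }
    for i, bag in enumerate(dataset):
        arrays[f"X_{i}"] = bag.instances
        if bag.instance_labels is not None:
            arrays[f"iy_{i}"] = bag.instance_labels
    np.savez(path, **arrays)


def load_dataset(path: str | Path) -> MILDataset:
    with np.load(path, allow_pickle=False) as z:
        ids = z["_ids"]
        labels = z["_labels"]
        name = str(z["_name"])
        bags = []
        for i, (bid, lab) in enumerate(zip(ids, labels)):
            iy = z[f"iy_{i}"] if f"iy_{i}" in z.files else None
            bags.append(
                Bag(bag_id=str(bid), instances=z[f"X_{i}"], label=int(lab),
                    instance_labels=iy)
            )
    return MILDataset(bags=bags, feature_dim=bags[0].instances.shape[1], name=name)


class Standardizer:
    """Per-dimension z-scoring fit on the training split only.

    The learned-adjacency kernel is distance-based and hence scale
    sensitive; standardizing instance features keeps one bandwidth
    meaningful across dimensions.
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, bags: Sequence[Bag]) -> "Standardizer":
        X = np.vstack([b.instances for b in bags])
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (X - self.mean_) / self.sd_
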