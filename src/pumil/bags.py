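"""Domain containers for multi-instance bags and positive-unlabeled scenarios.

A *bag* is a candidate modification site together with the reads that cover
it; an *instance* is one read's feature vector at that site.  A bag is
positive iff at least one of its reads is modified, which is the standard
multi-instance assumption.  In the positive-unlabeled (PU) setting only a
fraction of the truly positive bags carry a positive label (the *label
frequency*); everything else is unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# bag_label encoding used throughout and in the interchange TSV
POSITIVE = 1
NEGATIVE = 0
UNLABELED = -1

_LABEL_NAMES = {POSITIVE: "positive", NEGATIVE: "negative", UNLABELED: "unlabeled"}


@dataclass(frozen=True)
class InstanceFeature:
    """One read's feature vector at one candidate site."""

    instance_id: str
    features: np.ndarray
    hidden_label: int | None = None  # per-read truth, synthetic data only

    def __post_init__(self) -> None:
        arr = np.asarray(self.features, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"features must be 1-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite feature values in instance {self.instance_id!r}")
        object.__setattr__(self, "features", arr)


@dataclass
class SiteBag:
    """A candidate site with its covering reads and (PU) label state.

    ``hidden_bag_label`` is ground truth used only for synthetic data and
    evaluation; when present it must equal the OR of the hidden instance
    labels.
    """

    bag_id: str
    instances: list[InstanceFeature]
    bag_label: int = UNLABELED
    hidden_bag_label: int | None = None

    def __post_init__(self) -> None:
        if len(self.instances) < 1:
            raise ValueError(f"bag {self.bag_id!r} must contain at least one instance")
        if self.bag_label not in _LABEL_NAMES:
            raise ValueError(f"bag_label must be one of {sorted(_LABEL_NAMES)}")
        dims = {inst.features.shape[0] for inst in self.instances}
        if len(dims) != 1:
            raise ValueError(f"bag {self.bag_id!r} mixes feature dimensions {sorted(dims)}")
        hidden = [inst.hidden_label for inst in self.instances]
        if self.hidden_bag_label is not None and all(h is not None for h in hidden):
            expected = int(any(hidden))
            if self.hidden_bag_label != expected:
                raise ValueError(
                    f"bag {self.bag_id!r}: hidden_bag_label={self.hidden_bag_label} "
                    f"inconsistent with OR of instance labels ({expected})"
                )

    @property
    def size(self) -> int:
        return len(self.instances)

    @property
    def dim(self) -> int:
        return self.instances[0].features.shape[0]

    def feature_matrix(self) -> np.ndarray:
        """Stack instance features into a (k, D) array."""
        return np.stack([inst.features for inst in self.instances])


@dataclass
class PUBagDataset:
    """A collection of bags under a PU labeling scenario."""

    bags: list[SiteBag]
    label_frequency: float = 1.0
    fold_assignments: np.ndarray | None = None  # per-bag fold index

    def __len__(self) -> int:
        return len(self.bags)

    def labeled_positives(self) -> list[SiteBag]:
        return [b for b in self.bags if b.bag_label == POSITIVE]

    def unlabeled(self) -> list[SiteBag]:
        return [b for b in self.bags if b.bag_label == UNLABELED]

    def split_fold(self, fold: int) -> tuple["PUBagDataset", "PUBagDataset"]:
        """Return (train, held-out) datasets for one fold."""
        if self.fold_assignments is None:
            raise ValueError("dataset has no fold assignments; call stratified_folds first")
        mask = self.fold_assignments == fold
        train = [b for b, m in zip(self.bags, mask) if not m]
        test = [b for b, m in zip(self.bags, mask) if m]
        return (
            PUBagDataset(train, self.label_frequency),
            PUBagDataset(test, self.label_frequency),
        )


def make_pu_scenario(
    bags: Sequence[SiteBag], label_frequency: float, seed: int
) -> PUBagDataset:
    """Mask a fully-labeled bag collection into a PU scenario.

    Exactly ``round(label_frequency * n_positives)`` truly positive bags
    (chosen uniformly at random, deterministically under ``seed``) keep a
    positive label; every other bag becomes unlabeled.  Hidden labels are
    retained for evaluation only.
    """
    if not 0 < label_frequency <= 1:
        raise ValueError(f"label_frequency must be in (0, 1], got {label_frequency}")
    for bag in bags:
        if bag.hidden_bag_label is None:
            raise ValueError(f"bag {bag.bag_id!r} lacks hidden_bag_label")
    pos_idx = [i for i, b in enumerate(bags) if b.hidden_bag_label == 1]
    if not pos_idx:
        raise ValueError("cannot build PU scenario: no positive bags in input")
    n_label = int(round(label_frequency * len(pos_idx)))
    n_label = max(n_label, 1)  # LF > 0 guarantees at least one labeled positive
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(pos_idx, size=n_label, replace=False).tolist())
    out = []
    for i, bag in enumerate(bags):
        label = POSITIVE if i in chosen else UNLABELED
        out.append(replace(bag, bag_label=label, instances=list(bag.instances)))
    return PUBagDataset(out, label_frequency=label_frequency)


def stratified_folds(dataset: PUBagDataset, n_folds: int, seed: int) -> PUBagDataset:
    """Assign every bag to one of ``n_folds`` folds, stratified on bag_label.

    Per-fold class proportions are within one bag of the global proportions.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(dataset.bags), dtype=int)
    for label in sorted({b.bag_label for b in dataset.bags}):
        idx = np.array([i for i, b in enumerate(dataset.bags) if b.bag_label == label])
        if len(idx) < n_folds:
            raise ValueError(
                f"class {_LABEL_NAMES[label]!r} has {len(idx)} bags, "
                f"fewer than {n_folds} folds"
            )
        perm = rng.permutation(idx)
        for j, i in enumerate(perm):
            folds[i] = j % n_folds
    return PUBagDataset(list(dataset.bags), dataset.label_frequency, folds)


# ---------------------------------------------------------------------------
# Interchange format: long TSV, one row per read, plus a site-label TSV.


def write_bag_tsv(bags: Iterable[SiteBag], features_path: str | Path,
                  labels_path: str | Path | None = None) -> None:
    """Write bags in the long tab-delimited interchange format.

    ``features_path``: columns bag_id, instance_id, f_0..f_{D-1}.
    ``labels_path``: columns bag_id, label (1/0/-1), hidden_label (optional).
    """
    rows = []
    label_rows = []
    for bag in bags:
        for inst in bag.instances:
            rows.append([bag.bag_id, inst.instance_id, *inst.features.tolist()])
        label_rows.append(
            {
                "bag_id": bag.bag_id,
                "label": bag.bag_label,
                "hidden_label": "" if bag.hidden_bag_label is None else bag.hidden_bag_label,
            }
        )
    if not rows:
        raise ValueError("no bags to write")
    dim = len(rows[0]) - 2
    cols = ["bag_id", "instance_id"] + [f"f_{i}" for i in range(dim)]
    pd.DataFrame(rows, columns=cols).to_csv(features_path, sep="\t", index=False)
    if labels_path is not None:
        pd.DataFrame(label_rows).to_csv(labels_path, sep="\t", index=False)


def read_bag_tsv(features_path: str | Path,
                 labels_path: str | Path | None = None) -> list[SiteBag]:
    """Read bags from the long interchange format; inverse of write_bag_tsv."""
    df = pd.read_csv(features_path, sep="\t", dtype={"bag_id": str, "instance_id": str})
    fcols = [c for c in df.columns if c.startswith("f_")]
    fcols.sort(key=lambda c: int(c.split("_", 1)[1]))
    labels: dict[str, tuple[int, int | None]] = {}
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep="\t", dtype={"bag_id": str})
        for _, row in ldf.iterrows():
            hidden = row.get("hidden_label")
            hidden = None if pd.isna(hidden) or hidden == "" else int(hidden)
            labels[row["bag_id"]] = (int(row["label"]), hidden)
    bags = []
    for bag_id, group in df.groupby("bag_id", sort=False):
        insts = [
            InstanceFeature(row["instance_id"], row[fcols].to_numpy(dtype=float))
            for _, row in group.iterrows()
        ]
        label, hidden = labels.get(bag_id, (UNLABELED, None))
        bags.append(SiteBag(bag_id, insts, bag_label=label, hidden_bag_label=hidden))
    return bags
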