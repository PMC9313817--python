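"""Cross-validation folds, nested training subsets, and the experiment grid.

The study design: a held-out test set, the remaining ids split into k folds;
for each fold, training subsets of increasing size are sampled from the union
of the other folds so that each larger subset contains the smaller (nesting
isolates the effect of sample size from sample identity). Per (pretext, size)
cell the grid yields n_folds x n_subsample_chains x n_repeats runs.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np

PRETEXT_TASKS = ("random_init", "classification", "segmentation", "reconstruction", "jigsaw")

__all__ = ["ExperimentGrid", "RunDescriptor", "make_folds", "nested_subsets", "enumerate_runs", "derive_seed"]


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic sub-seed from a master seed and a coordinate tuple.

    Hash-based so that runs are reproducibly independent without a global
    counter; result is < 2**31.
    """
    key = repr((int(master_seed),) + tuple(parts)).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunDescriptor:
    pretext: str
    size: int
    fold: int
    chain: int
    repeat: int
    seed: int


@dataclass
class ExperimentGrid:
    """Full factorial experiment layout.

    Defaults mirror the study design: subset sizes 5..125, 4 folds, 2
    independent subsample chains per size and 2 training repeats per subset,
    i.e. 16 runs per (pretext, size) cell.
    """

    pretext_tasks: tuple[str, ...] = PRETEXT_TASKS
    subset_sizes: tuple[int, ...] = (5, 10, 25, 50, 75, 100, 125)
    n_folds: int = 4
    n_subsamples_per_size: int = 2
    n_repeats_per_subset: int = 2
    test_ids: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.pretext_tasks) - set(PRETEXT_TASKS)
        if unknown:
            raise ValueError(f"unknown pretext tasks: {sorted(unknown)}")
        if set(self.test_ids) & set(self.parent_ids):
            raise ValueError("test_ids and parent_ids must be disjoint")
        if len(set(self.subset_sizes)) != len(self.subset_sizes):
            raise ValueError("duplicate subset sizes")
        if list(self.subset_sizes) != sorted(self.subset_sizes):
            raise ValueError("subset_sizes must be increasing")
        if self.parent_ids:
            # largest subset must fit in parent minus one validation fold
            val_size = -(-len(self.parent_ids) // self.n_folds)  # ceil
            if max(self.subset_sizes) > len(self.parent_ids) - val_size:
                raise ValueError(
                    "max subset size exceeds parent size minus validation fold"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("pretext_tasks", "subset_sizes", "test_ids", "parent_ids"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentGrid":
        d = dict(d)
        for k in ("pretext_tasks", "subset_sizes", "test_ids", "parent_ids"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def make_folds(ids, k: int, seed: int) -> list[list[str]]:
    """Partition ids into k disjoint folds with sizes differing by at most 1."""
    ids = sorted(ids)
    if k <= 0:
        raise ValueError("k must be positive")
    if len(ids) < k:
        raise ValueError(f"cannot make {k} folds from {len(ids)} ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, idx in enumerate(perm):
        folds[i % k].append(ids[idx])
    return [sorted(f) for f in folds]


def nested_subsets(parent_ids, sizes, n_chains: int, seed: int) -> list[dict[int, list[str]]]:
    """Per chain, a size-indexed family of nested subsets of parent_ids.

    Within a chain, the subset at each size extends the previous one by
    exactly the size difference, so subset(s1) ⊂ subset(s2) for s1 < s2.
    Chains are drawn independently.
    """
    parent = sorted(parent_ids)
    sizes = list(sizes)
    if len(set(sizes)) != len(sizes):
        raise ValueError("duplicate sizes")
    if sizes != sorted(sizes):
        raise ValueError("sizes must be strictly increasing")
    if sizes and sizes[-1] > len(parent):
        raise ValueError("max size exceeds parent size")
    chains = []
    for chain in range(n_chains):
        rng = np.random.default_rng(derive_seed(seed, "chain", chain))
        order = [parent[i] for i in rng.permutation(len(parent))]
        chains.append({s: sorted(order[:s]) for s in sizes})
    return chains


def enumerate_runs(grid: ExperimentGrid) -> list[RunDescriptor]:
    """All run descriptors of the grid, each with a distinct deterministic seed."""
    runs = []
    for pretext in grid.pretext_tasks:
        for size in grid.subset_sizes:
            for fold in range(grid.n_folds):
                for chain in range(grid.n_subsamples_per_size):
                    for repeat in range(grid.n_repeats_per_subset):
                        seed = derive_seed(
                            grid.master_seed, pretext, size, fold, chain, repeat
                        )
                        runs.append(
                            RunDescriptor(pretext, size, fold, chain, repeat, seed)
                        )
    return runs
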