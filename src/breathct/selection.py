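"""Transfer-sample selection: Kennard-Stone and the four linkage schemes.

Transfer samples are the small set of measurements that tie the master and a
slave instrument together. *Standard* samples are the same breath observed on
both instruments back to back (matched by the shared sample id); *nonstandard*
samples are labeled slave measurements matched to the master picks by
proximity; *unlabeled* sets are chosen independently on each side by
Kennard-Stone. The class scheme restricts the candidates to both classes
(balanced) or to no-meal only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import feature_values

TWO_CLASS = "two_class"
ONE_CLASS = "one_class_no_meal"
SCHEMES = (TWO_CLASS, ONE_CLASS)


@dataclass
class TransferSet:
    """Row-aligned master/slave transfer matrices.

    Row i of ``Xm`` and ``Xs`` refer to the same transfer link. ``labels``
    holds per-row class labels (None for unlabeled sets).
    """

    Xm: np.ndarray
    Xs: np.ndarray
    master_ids: list
    slave_ids: list
    sample_type: str  # standard | nonstandard | unlabeled
    class_scheme: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Xm = np.asarray(self.Xm, dtype=float)
        self.Xs = np.asarray(self.Xs, dtype=float)
        if self.Xm.shape != self.Xs.shape:
            raise ValueError("master and slave transfer matrices must be row-aligned")
        if len(set(self.slave_ids)) != len(self.slave_ids):
            raise ValueError("a slave sample may appear only once in a transfer set")

    def __len__(self) -> int:
        return self.Xm.shape[0]


def kennard_stone(X: np.ndarray, m: int) -> np.ndarray:
    """Kennard-Stone max-min selection of ``m`` rows of ``X``.

    The first pick is the point farthest from the data mean; every subsequent
    pick maximizes its minimum Euclidean distance to the points already
    selected. Ties break toward the lowest row index, so the output is
    deterministic and prefix-stable (the first m' picks equal a run asked for
    only m').
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m must be in 1..{n}, got {m}")
    d0 = np.linalg.norm(X - X.mean(axis=0), axis=1)
    picks = [int(np.argmax(d0))]
    mind = np.linalg.norm(X - X[picks[0]], axis=1)
    for _ in range(1, m):
        mind[picks] = -np.inf
        nxt = int(np.argmax(mind))
        picks.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(X - X[nxt], axis=1))
    return np.asarray(picks, dtype=int)


def restrict_class(candidates: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Restrict candidate rows to the classes a scheme allows."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if scheme == ONE_CLASS:
        out = candidates[candidates["class"] == "no-meal"]
        if out.empty:
            raise ValueError("one-class scheme requested but no no-meal rows present")
        return out
    return candidates


def select_master_transfer(
    candidates: pd.DataFrame, m: int, scheme: str = TWO_CLASS
) -> pd.DataFrame:
    """Kennard-Stone pick of ``m`` master transfer rows under a class scheme.

    Two-class: KS runs separately within each class and the per-class picks
    are interleaved, which guarantees equal class representation. One-class:
    KS over the no-meal rows only.
    """
    candidates = restrict_class(candidates, scheme)
    if scheme == ONE_CLASS:
        idx = kennard_stone(feature_values(candidates), m)
        return candidates.iloc[idx]
    if m % 2:
        raise ValueError("two-class transfer sets need an even sample count")
    per_class = []
    for cls in ("meal", "no-meal"):
        rows = candidates[candidates["class"] == cls]
        if len(rows) < m // 2:
            raise ValueError(
                f"class {cls!r} has {len(rows)} candidates; need {m // 2}"
            )
        idx = kennard_stone(feature_values(rows), m // 2)
        per_class.append(rows.iloc[idx].reset_index(drop=True))
    interleaved = [
        per_class[cls].iloc[[i]] for i in range(m // 2) for cls in (0, 1)
    ]
    return pd.concat(interleaved, ignore_index=True)


def select_standard(
    master_transfer: pd.DataFrame,
    slave_data: pd.DataFrame,
    class_scheme: str = TWO_CLASS,
) -> TransferSet:
    """Standard transfer set: slave rows matched by shared sample id."""
    slave_by_id = slave_data.set_index("sample_id")
    missing = [sid for sid in master_transfer["sample_id"] if sid not in slave_by_id.index]
    if missing:
        raise ValueError(f"no slave measurement for sample id(s): {missing}")
    slave_rows = slave_by_id.loc[master_transfer["sample_id"]].reset_index()
    return TransferSet(
        Xm=feature_values(master_transfer),
        Xs=feature_values(slave_rows),
        master_ids=master_transfer["sample_id"].tolist(),
        slave_ids=slave_rows["sample_id"].tolist(),
        sample_type="standard",
        class_scheme=class_scheme,
        labels=slave_rows["class"].to_numpy(),
    )


def select_nonstandard(
    master_transfer: pd.DataFrame,
    slave_pool: pd.DataFrame,
    class_scheme: str = TWO_CLASS,
    match_within_class: bool = True,
) -> TransferSet:
    """Nonstandard transfer set: greedy nearest-neighbour matching.

    Processes the master picks in their Kennard-Stone order; each pick takes
    the closest not-yet-used row of the labeled slave pool (by default among
    rows of the same class, which preserves the equal class representation of
    two-class sets). Ties break toward the lowest pool row index.
    """
    if len(slave_pool) < len(master_transfer):
        raise ValueError(
            f"pool of {len(slave_pool)} cannot supply {len(master_transfer)} "
            "transfer samples without replacement"
        )
    pool_X = feature_values(slave_pool)
    pool_ids = slave_pool["sample_id"].tolist()
    pool_cls = slave_pool["class"].tolist()
    used = np.zeros(len(slave_pool), dtype=bool)
    slave_idx: list[int] = []
    Xm = feature_values(master_transfer)
    classes = master_transfer["class"].tolist()
    for i in range(len(master_transfer)):
        d = np.linalg.norm(pool_X - Xm[i], axis=1)
        allowed = ~used
        if match_within_class:
            allowed &= np.asarray([c == classes[i] for c in pool_cls])
        if not allowed.any():
            raise ValueError("slave pool exhausted during nonstandard matching")
        d = np.where(allowed, d, np.inf)
        j = int(np.argmin(d))
        used[j] = True
        slave_idx.append(j)
    slave_rows = slave_pool.iloc[slave_idx]
    return TransferSet(
        Xm=Xm,
        Xs=pool_X[slave_idx],
        master_ids=master_transfer["sample_id"].tolist(),
        slave_ids=[pool_ids[j] for j in slave_idx],
        sample_type="nonstandard",
        class_scheme=class_scheme,
        labels=slave_rows["class"].to_numpy(),
    )


def draw_pool(
    slave_data: pd.DataFrame,
    size: int,
    scheme: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Random labeled slave pool for nonstandard matching.

    Balanced across classes in the two-class scheme, no-meal only in the
    one-class scheme.
    """
    candidates = restrict_class(slave_data, scheme)
    if scheme == TWO_CLASS:
        halves = []
        for cls in ("meal", "no-meal"):
            rows = candidates[candidates["class"] == cls]
            take = size - size // 2 if cls == "meal" else size // 2
            if take > len(rows):
                raise ValueError(f"not enough {cls!r} rows for a pool of {size}")
            idx = rng.choice(len(rows), size=take, replace=False)
            halves.append(rows.iloc[np.sort(idx)])
        return pd.concat(halves, ignore_index=True)
    if size > len(candidates):
        raise ValueError(f"not enough rows for a pool of {size}")
    idx = rng.choice(len(candidates), size=size, replace=False)
    return candidates.iloc[np.sort(idx)].reset_index(drop=True)


def select_unlabeled(
    slave_data: pd.DataFrame, m: int, class_scheme: str = TWO_CLASS
) -> pd.DataFrame:
    """Kennard-Stone pick of ``m`` slave rows for unlabeled transfer methods."""
    candidates = restrict_class(slave_data, class_scheme)
    idx = kennard_stone(feature_values(candidates), m)
    return candidates.iloc[idx]
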