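"""Block-permutation schemes that bound a model's usable memory to n steps.

During training the dynamic features and the target are permuted *in unison*
by shuffling blocks of ``n + 1`` consecutive steps while preserving order
within each block.  Only the last element of each complete block enters the
loss: that position has exactly its ``n`` true antecedents, in original
order, immediately before it, so a sequence model trained this way can
exploit at most ``n`` steps of ordered history (it can still learn from the
marginal distribution of earlier values, which the permutation preserves).

``n = 0`` permutes every step independently (no-memory model M_0);
``n = FULL`` (None) leaves the series untouched (full-memory model M_full).
The first block starts at an offset drawn uniformly from ``{0, ..., n}`` so
that block boundaries vary between draws; leading/trailing fragments shorter
than ``n + 1`` take part in the shuffle but are fully loss-masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FULL", "PermutationScheme", "make_scheme", "apply_scheme",
           "MODEL_SET", "model_label", "memory_days"]

FULL = None  # sentinel for the unrestricted model

#: The model family of the study: memory bounds in steps and in days.
MODEL_SET: tuple = (FULL, 0, 1, 2, 3, 4, 5, 6)


def model_label(n) -> str:
    return "M_full" if n is FULL else f"M_{int(n)}"


def memory_days(n, step_days: int = 15):
    """Days of ordered history available to model M_n (None for M_full)."""
    return None if n is FULL else int(n) * step_days


@dataclass(frozen=True)
class PermutationScheme:
    """An index permutation and loss mask realizing memory bound ``n``."""

    n: int | None
    order: np.ndarray       # permuted original indices, length T
    loss_mask: np.ndarray   # per *permuted position*: contributes to the loss
    offset: int

    def __post_init__(self) -> None:
        T = self.order.shape[0]
        if self.loss_mask.shape != (T,):
            raise ValueError("order and loss_mask must have equal length")

    @property
    def T(self) -> int:
        return self.order.shape[0]

    def inverse(self) -> np.ndarray:
        inv = np.empty(self.T, dtype=int)
        inv[self.order] = np.arange(self.T)
        return inv


def make_scheme(T: int, n: int | None, rng: np.random.Generator
                ) -> PermutationScheme:
    """Draw a fresh block-permutation scheme for a length-``T`` sequence."""
    if n is FULL:
        return PermutationScheme(
            n=None, order=np.arange(T), loss_mask=np.ones(T, bool), offset=0)
    n = int(n)
    if n < 0:
        raise ValueError("memory bound must be >= 0 or FULL")
    if T < n + 1:
        raise ValueError(f"sequence length {T} < block size {n + 1}")
    size = n + 1
    offset = int(rng.integers(0, n + 1))
    starts = np.arange(offset, T - size + 1, size)
    blocks: list[np.ndarray] = []
    complete: list[bool] = []
    if offset > 0:
        blocks.append(np.arange(0, offset))
        complete.append(False)
    for s in starts:
        blocks.append(np.arange(s, s + size))
        complete.append(True)
    tail = offset + starts.size * size
    if tail < T:
        blocks.append(np.arange(tail, T))
        complete.append(False)
    perm = rng.permutation(len(blocks))
    order = np.concatenate([blocks[i] for i in perm])
    mask = np.zeros(T, dtype=bool)
    pos = 0
    for i in perm:
        ln = blocks[i].size
        if complete[i]:
            mask[pos + ln - 1] = True  # block-final: n in-order antecedents
        pos += ln
    return PermutationScheme(n=n, order=order, loss_mask=mask, offset=offset)


def apply_scheme(features: np.ndarray, target: np.ndarray,
                 scheme: PermutationScheme
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Reorder features and target along time by the same permutation.

    ``features`` may be (T, F) or (batch, T, F); ``target`` (T,) or
    (batch, T).  Static variables, being constant per step, are unaffected by
    construction.  Validation and prediction always use unpermuted series.
    """
    features = np.asarray(features)
    target = np.asarray(target)
    t_axis_f = 0 if features.ndim == 2 else 1
    t_axis_y = 0 if target.ndim == 1 else 1
    if features.shape[t_axis_f] != scheme.T or target.shape[t_axis_y] != scheme.T:
        raise ValueError(
            f"features/target length must equal scheme length {scheme.T}"
        )
    return (np.take(features, scheme.order, axis=t_axis_f),
            np.take(target, scheme.order, axis=t_axis_y))
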