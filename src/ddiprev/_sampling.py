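"""Vectorized weighted sampling primitives shared by the generator and null model."""

from __future__ import annotations

import numpy as np


def weighted_distinct(
    rng: np.random.Generator,
    weights: np.ndarray,
    sizes: np.ndarray,
) -> np.ndarray:
    """Sample, for each row r, ``sizes[r]`` distinct item indices from one pool.

    Uses the exponential-race construction (keys ~ Exp(1)/w, take the
    ``sizes[r]`` smallest), which is distributed exactly as successive
    weighted sampling without replacement but is fully vectorizable.

    Returns an int array of shape (n_rows, max(sizes)) padded with -1.
    Items with zero weight are never drawn; ``sizes`` is clipped to the
    number of positive-weight items.
    """
    weights = np.asarray(weights, dtype=float)
    sizes = np.asarray(sizes, dtype=np.int64)
    n = sizes.shape[0]
    n_avail = int((weights > 0).sum())
    sizes = np.minimum(sizes, n_avail)
    d_max = int(sizes.max()) if n else 0
    out = np.full((n, max(d_max, 1)), -1, dtype=np.int64)
    if n == 0 or d_max == 0:
        return out[:, :max(d_max, 0)] if d_max == 0 else out
    with np.errstate(divide="ignore"):
        inv_w = np.where(weights > 0, 1.0 / weights, np.inf)
    keys = rng.exponential(size=(n, weights.shape[0])) * inv_w[None, :]
    # Smallest d_max keys per row, then order within that small block.
    if d_max < keys.shape[1]:
        part = np.argpartition(keys, d_max - 1, axis=1)[:, :d_max]
    else:
        part = np.tile(np.arange(keys.shape[1]), (n, 1))
    block = np.take_along_axis(keys, part, axis=1)
    order = np.argsort(block, axis=1)
    ranked = np.take_along_axis(part, order, axis=1)
    col = np.arange(d_max)[None, :]
    out[:, :d_max] = np.where(col < sizes[:, None], ranked, -1)
    return out


def distinct_subsets(
    rng: np.random.Generator,
    n_options: np.ndarray,
    sizes: np.ndarray,
) -> np.ndarray:
    """Per row r, choose ``sizes[r]`` distinct integers uniformly from
    ``range(n_options[r])`` without replacement.

    Returns an int array (n_rows, max(sizes)) padded with -1.
    """
    n_options = np.asarray(n_options, dtype=np.int64)
    sizes = np.asarray(sizes, dtype=np.int64)
    sizes = np.minimum(sizes, n_options)
    n = sizes.shape[0]
    k_max = int(sizes.max()) if n else 0
    c_max = int(n_options.max()) if n else 0
    out = np.full((n, max(k_max, 1)), -1, dtype=np.int64)
    if n == 0 or k_max == 0:
        return out
    keys = rng.random((n, c_max))
    keys[np.arange(c_max)[None, :] >= n_options[:, None]] = np.inf
    if k_max < c_max:
        part = np.argpartition(keys, k_max - 1, axis=1)[:, :k_max]
    else:
        part = np.tile(np.arange(c_max), (n, 1))
    col = np.arange(part.shape[1])[None, :]
    out[:, : part.shape[1]] = np.where(col < sizes[:, None], part, -1)
    return out


def pair_code(lo: np.ndarray, hi: np.ndarray, n_items: int) -> np.ndarray:
    """Canonical integer code of an unordered item pair (lo < hi enforced)."""
    a = np.minimum(lo, hi).astype(np.int64)
    b = np.maximum(lo, hi).astype(np.int64)
    return a * np.int64(n_items) + b


def codes_in_sorted(codes: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    """Boolean membership of ``codes`` in a sorted reference array."""
    if sorted_ref.size == 0:
        return np.zeros(codes.shape, dtype=bool)
    idx = np.searchsorted(sorted_ref, codes)
    idx = np.minimum(idx, sorted_ref.size - 1)
    return sorted_ref[idx] == codes
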