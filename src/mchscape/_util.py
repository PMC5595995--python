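"""Shared numeric helpers (range expansion, smoothing, site keys)."""

from __future__ import annotations

import numpy as np

#: canonical base order used for all encodings
BASES = np.frombuffer(b"ACGT", dtype="S1")
BASE2CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    BASE2CODE[_b] = _i
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an uppercase DNA string as int8 codes (A=0,C=1,G=2,T=3; N/other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return BASE2CODE[raw]


def codes_to_seq(codes: np.ndarray) -> str:
    out = np.where(codes >= 0, BASES[np.clip(codes, 0, 3)], np.bytes_(b"N"))
    return out.tobytes().decode("ascii")


def expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten half-open index ranges [lo_i, hi_i) into (owner_index, flat_index).

    The standard trick for vectorised window queries: given per-window slice
    bounds into a sorted coordinate array, returns one row per (window, member).
    """
    counts = (hi - lo).astype(np.int64)
    counts = np.maximum(counts, 0)
    total = int(counts.sum())
    owner = np.repeat(np.arange(lo.size, dtype=np.int64), counts)
    if total == 0:
        return owner, np.empty(0, dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    flat = np.arange(total, dtype=np.int64) - np.repeat(starts, counts) + np.repeat(lo, counts)
    return owner, flat


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated (shorter) windows at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError("window larger than profile")
    x = np.asarray(x, dtype=float)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    c = np.concatenate(([0.0], np.cumsum(np.nan_to_num(x))))
    cn = np.concatenate(([0.0], np.cumsum(~np.isnan(x))))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, x.size)
    n = cn[hi] - cn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (c[hi] - c[lo]) / n
    out[n == 0] = np.nan
    return out


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals as disjoint sorted intervals."""
    if starts.size == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    running_max = np.maximum.accumulate(e)
    new_block = np.concatenate(([True], s[1:] > running_max[:-1]))
    block_id = np.cumsum(new_block) - 1
    out_s = s[new_block]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_block))
    # reduceat gives max end per block; combined with sorted starts this is the union
    del block_id
    return out_s.astype(np.int64), out_e.astype(np.int64)


def covered_length(
    query_starts: np.ndarray,
    query_ends: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> np.ndarray:
    """Base pairs of each half-open query interval covered by the union of (starts, ends)."""
    ms, me = merge_intervals(np.asarray(starts), np.asarray(ends))
    if ms.size == 0:
        return np.zeros(np.asarray(query_starts).size, dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(me - ms)))

    def _covered_before(x):
        x = np.asarray(x, dtype=np.int64)
        idx = np.searchsorted(ms, x, side="left")
        base = cum[idx]
        prev = idx - 1
        has_prev = prev >= 0
        overhang = np.zeros_like(base)
        pe = me[np.clip(prev, 0, None)]
        overhang[has_prev] = np.maximum(pe[has_prev] - x[has_prev], 0)
        overhang = np.minimum(overhang, (pe - ms[np.clip(prev, 0, None)]))
        return base - overhang

    return _covered_before(query_ends) - _covered_before(query_starts)


def site_key(chrom_codes: np.ndarray, pos: np.ndarray, strand_is_rev: np.ndarray) -> np.ndarray:
    """Pack (chrom, pos, strand) into a single sortable int64 key."""
    return (
        chrom_codes.astype(np.int64) * (1 << 33)
        + pos.astype(np.int64) * 2
        + strand_is_rev.astype(np.int64)
    )
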