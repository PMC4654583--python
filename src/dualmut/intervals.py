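"""Genomic interval containers and arithmetic.

Everything in the pipeline speaks 0-based half-open coordinates (BED
convention).  A :class:`FeatureTrack` is a named set of sorted intervals per
chromosome, either *binary* (presence/absence of a feature such as a histone
mark or a DNase site) or *valued* (one real number per interval, as for
recombination rate, methylation level or replication signal).

The primitives here — coverage of a window, length-weighted mean of a value
track over a window, membership of point positions — are the only interval
operations the downstream models need, and they are all expressed through
prefix sums over the sorted interval arrays so that batched queries are
vectorised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and union-merge possibly overlapping/adjacent intervals."""
    if len(starts) == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    # running maximum of ends; a new block starts where start > max(previous ends)
    run_max = np.maximum.accumulate(e)
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > run_max[:-1]
    idx = np.flatnonzero(new_block)
    ms = s[idx]
    me = np.empty(len(idx), dtype=np.int64)
    me[:-1] = run_max[idx[1:] - 1]
    me[-1] = run_max[-1]
    return ms, me


@dataclass
class _Chrom:
    """Sorted intervals on one chromosome with prefix sums for fast queries."""

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray | None = None
    # cumulative covered bp up to the end of interval i (inclusive)
    _cumlen: np.ndarray = field(init=False, repr=False)
    _cumw: np.ndarray | None = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        lens = self.ends - self.starts
        self._cumlen = np.concatenate([[0], np.cumsum(lens)])
        if self.values is not None:
            self._cumw = np.concatenate([[0.0], np.cumsum(self.values * lens)])

    def covered_before(self, x) -> np.ndarray:
        """Covered bp in [0, x) for scalar or array x."""
        x = np.asarray(x, dtype=np.int64)
        j = np.searchsorted(self.starts, x, side="right")  # intervals with start < x
        full = self._cumlen[np.maximum(j - 1, 0)]
        # partial part of interval j-1
        last_s = self.starts[np.maximum(j - 1, 0)]
        last_e = self.ends[np.maximum(j - 1, 0)]
        partial = np.clip(x - last_s, 0, last_e - last_s)
        out = np.where(j > 0, full + partial, 0)
        return out

    def weighted_before(self, x) -> np.ndarray:
        """Sum of value*covered-bp in [0, x)."""
        assert self._cumw is not None
        x = np.asarray(x, dtype=np.int64)
        j = np.searchsorted(self.starts, x, side="right")
        jm = np.maximum(j - 1, 0)
        full = self._cumw[jm]
        partial = np.clip(x - self.starts[jm], 0, self.ends[jm] - self.starts[jm]) * self.values[jm]
        return np.where(j > 0, full + partial, 0.0)

    def contains(self, pos) -> np.ndarray:
        """Boolean membership of point positions."""
        pos = np.asarray(pos, dtype=np.int64)
        j = np.searchsorted(self.starts, pos, side="right")
        jm = np.maximum(j - 1, 0)
        return (j > 0) & (pos < self.ends[jm])


class FeatureTrack:
    """A named interval set over the genome, binary or valued.

    Binary tracks are union-merged on construction; value tracks must be
    non-overlapping (a length-weighted mean over a self-overlap is undefined)
    and raise ``ValueError`` otherwise.
    """

    def __init__(
        self,
        name: str,
        intervals: Mapping[str, np.ndarray] | Iterable[tuple] | None = None,
        values: Mapping[str, np.ndarray] | None = None,
    ):
        self.name = name
        self._chroms: dict[str, _Chrom] = {}
        per_chrom: dict[str, list[list]] = {}
        if intervals is None:
            intervals = []
        if isinstance(intervals, Mapping):
            for chrom, arr in intervals.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                vals = None if values is None else np.asarray(values[chrom], dtype=float)
                self._add_chrom(chrom, arr[:, 0], arr[:, 1], vals)
        else:
            rows = list(intervals)
            has_val = any(len(r) > 3 for r in rows)
            for r in rows:
                per_chrom.setdefault(r[0], []).append(list(r[1:]))
            for chrom, items in per_chrom.items():
                a = np.array([it[:2] for it in items], dtype=np.int64)
                vals = np.array([it[2] for it in items], dtype=float) if has_val else None
                self._add_chrom(chrom, a[:, 0], a[:, 1], vals)

    def _add_chrom(self, chrom: str, starts, ends, values=None) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(starts >= ends):
            bad = int(np.flatnonzero(starts >= ends)[0])
            raise ValueError(
                f"track {self.name!r}, {chrom}: interval start >= end "
                f"({starts[bad]} >= {ends[bad]})"
            )
        if np.any(starts < 0):
            raise ValueError(f"track {self.name!r}, {chrom}: negative coordinate")
        if values is None:
            starts, ends = merge_intervals(starts, ends)
            self._chroms[chrom] = _Chrom(starts, ends)
        else:
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            values = np.asarray(values, dtype=float)[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(
                    f"value track {self.name!r}, {chrom}: overlapping intervals"
                )
            self._chroms[chrom] = _Chrom(starts, ends, values)

    # ---- introspection -------------------------------------------------

    @property
    def is_valued(self) -> bool:
        return any(c.values is not None for c in self._chroms.values())

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chroms)

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) interval array on a chromosome (empty if absent)."""
        c = self._chroms.get(chrom)
        if c is None:
            return np.empty((0, 2), dtype=np.int64)
        return np.column_stack([c.starts, c.ends])

    def interval_values(self, chrom: str) -> np.ndarray:
        c = self._chroms.get(chrom)
        if c is None or c.values is None:
            return np.empty(0)
        return c.values

    def iter_intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self._chroms:
            for s, e in self.intervals(chrom):
                yield chrom, int(s), int(e)

    def total_bp(self) -> int:
        return int(sum(c._cumlen[-1] for c in self._chroms.values()))

    def genome_mean(self) -> float:
        """Length-weighted mean value over all covered bp of a value track."""
        if not self.is_valued:
            raise ValueError(f"track {self.name!r} carries no values")
        tot = sum(c._cumlen[-1] for c in self._chroms.values())
        w = sum(c._cumw[-1] for c in self._chroms.values())
        return float(w / tot) if tot else float("nan")

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTrack):
            return NotImplemented
        if set(self._chroms) != set(other._chroms):
            return False
        for chrom, c in self._chroms.items():
            o = other._chroms[chrom]
            if not (np.array_equal(c.starts, o.starts) and np.array_equal(c.ends, o.ends)):
                return False
            if (c.values is None) != (o.values is None):
                return False
            if c.values is not None and not np.allclose(c.values, o.values):
                return False
        return True

    def __repr__(self) -> str:
        n = sum(len(c.starts) for c in self._chroms.values())
        kind = "value" if self.is_valued else "binary"
        return f"FeatureTrack({self.name!r}, {kind}, {n} intervals, {self.total_bp()} bp)"

    # ---- queries -------------------------------------------------------

    def coverage_before(self, chrom: str, x) -> np.ndarray:
        """Covered bp in [0, x) — the prefix function behind window queries."""
        c = self._chroms.get(chrom)
        if c is None or len(c.starts) == 0:
            return np.zeros_like(np.asarray(x, dtype=np.int64))
        return c.covered_before(x)

    def weighted_before(self, chrom: str, x) -> np.ndarray:
        c = self._chroms.get(chrom)
        if c is None or len(c.starts) == 0:
            return np.zeros(np.asarray(x).shape)
        return c.weighted_before(x)

    def contains(self, chrom: str, pos) -> np.ndarray:
        c = self._chroms.get(chrom)
        if c is None or len(c.starts) == 0:
            return np.zeros(np.asarray(pos).shape, dtype=bool)
        return c.contains(pos)

    def complement(self, genome) -> "FeatureTrack":
        """Uncovered intervals relative to a genome's chromosome lengths."""
        out: dict[str, np.ndarray] = {}
        for chrom, length in genome.chromosomes:
            iv = self.intervals(chrom)
            bounds = np.concatenate([[0], iv.ravel(), [length]])
            s, e = bounds[::2], bounds[1::2]
            keep = s < e
            out[chrom] = np.column_stack([s[keep], e[keep]])
        return FeatureTrack(f"not_{self.name}", out)


def coverage_in_window(track: FeatureTrack, chrom: str, start: int, end: int) -> int:
    """Base pairs of *track* inside the half-open window [start, end)."""
    if start > end:
        raise ValueError("window start > end")
    lo, hi = track.coverage_before(chrom, np.array([start, end]))
    return int(hi - lo)


def mean_value_in_window(
    track: FeatureTrack,
    chrom: str,
    start: int,
    end: int,
    missing_value: float | None = None,
) -> float:
    """Length-weighted mean of a value track over [start, end).

    Windows with zero covered bp return *missing_value* if given, otherwise
    the track's genome-wide length-weighted mean — mirroring mean imputation
    of unobserved methylation/recombination values.
    """
    if not track.is_valued:
        raise ValueError(f"track {track.name!r} is binary; use coverage_in_window")
    cov_lo, cov_hi = track.coverage_before(chrom, np.array([start, end]))
    cov = int(cov_hi - cov_lo)
    if cov == 0:
        return track.genome_mean() if missing_value is None else float(missing_value)
    w_lo, w_hi = track.weighted_before(chrom, np.array([start, end]))
    return float((w_hi - w_lo) / cov)


def splice_site_track(
    introns,
    donor_nt: int = 10,
    acceptor_nt: int = 50,
    name: str = "splice_site",
) -> FeatureTrack:
    """Strand-aware splice-site windows from intron intervals.

    For each intron the first *donor_nt* nucleotides on the 5' side and the
    last *acceptor_nt* on the 3' side are emitted, resolved by strand and
    clipped to the intron. *introns* is an iterable of
    ``(chrom, start, end, strand)`` rows (or a DataFrame with those columns).

    Introns shorter than donor_nt + acceptor_nt yield truncated, possibly
    overlapping windows (merged on construction) and a warning.
    """
    rows = []
    short = 0
    it = introns.itertuples(index=False) if hasattr(introns, "itertuples") else introns
    for chrom, start, end, strand in it:
        if strand not in ("+", "-"):
            raise ValueError(f"intron ({chrom}, {start}, {end}): strand must be '+' or '-'")
        length = end - start
        if length < donor_nt + acceptor_nt:
            short += 1
        if strand == "+":
            rows.append((chrom, start, min(start + donor_nt, end)))
            rows.append((chrom, max(end - acceptor_nt, start), end))
        else:
            rows.append((chrom, max(end - donor_nt, start), end))
            rows.append((chrom, start, min(start + acceptor_nt, end)))
    if short:
        warnings.warn(
            f"{short} intron(s) shorter than {donor_nt + acceptor_nt} nt: "
            "splice windows truncated"
        )
    return FeatureTrack(name, rows)
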