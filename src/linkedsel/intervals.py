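"""Genomic interval algebra: masks, value tracks, and B-quantile binning.

All coordinates are 0-based half-open (BED convention). An
:class:`IntervalTrack` stores a set of intervals, optionally carrying a
per-interval value (a background-selection coefficient ``B`` or a
recombination rate in cM/Mb). Tracks are the substrate for the neutral-site
mask (intersection of "include" filters minus the union of "exclude"
filters), for recombination-hotspot exclusion, and for per-base quantile
binning of the genome by ``B``.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "IntervalTrack",
    "MaskSet",
    "normalize_track",
    "build_neutral_mask",
    "hotspot_exclusion",
    "quantile_thresholds",
    "bin_membership",
    "disjoint_bins",
    "read_bed",
    "read_bedgraph",
]


class GenomeLayout(Mapping):
    """Contig name -> length (bp). The autosome universe for all tracks."""

    def __init__(self, lengths: Mapping[str, int]):
        self._lengths = {}
        for name, length in lengths.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
            if name in self._lengths:
                raise ValueError(f"duplicate contig name {name!r}")
            self._lengths[name] = length

    def __getitem__(self, name):
        return self._lengths[name]

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self):
        return len(self._lengths)

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def whole(self) -> "IntervalTrack":
        """The track covering every contig end to end."""
        return IntervalTrack(
            [(c, 0, n) for c, n in self._lengths.items()], layout=self
        )


@dataclass
class IntervalTrack:
    """A set of genomic intervals, optionally value-carrying.

    Parameters
    ----------
    intervals
        Iterable of ``(contig, start, end)`` or ``(contig, start, end, value)``.
    layout
        Optional :class:`GenomeLayout`; when given, intervals beyond a contig
        end are rejected.
    """

    intervals: Iterable = ()
    layout: GenomeLayout | None = None
    _data: dict = field(init=False, repr=False)

    def __post_init__(self):
        rows: dict[str, list] = {}
        has_value = None
        for iv in self.intervals:
            if len(iv) == 3:
                contig, start, end = iv
                value = np.nan
                this_has = False
            else:
                contig, start, end, value = iv
                this_has = True
            if has_value is None:
                has_value = this_has
            elif has_value != this_has:
                raise ValueError("mixed value-carrying and plain intervals")
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"empty interval ({contig},{start},{end})")
            if start < 0:
                raise ValueError(f"negative start ({contig},{start},{end})")
            if self.layout is not None:
                if contig not in self.layout:
                    raise ValueError(f"contig {contig!r} not in layout")
                if end > self.layout[contig]:
                    raise ValueError(
                        f"interval ({contig},{start},{end}) beyond contig end "
                        f"{self.layout[contig]}"
                    )
            rows.setdefault(contig, []).append((start, end, float(value)))
        self.has_values = bool(has_value)
        self._data = {}
        for contig, ivs in rows.items():
            ivs.sort()
            arr = np.asarray(ivs, dtype=float)
            self._data[contig] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        del self.intervals

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_data(cls, data, layout=None, has_values=False):
        t = cls([], layout=layout)
        t._data = data
        t.has_values = has_values
        return t

    def contigs(self):
        return sorted(self._data)

    def per_contig(self, contig):
        """(starts, ends, values) arrays for one contig (empty if absent)."""
        if contig in self._data:
            return self._data[contig]
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros(0)

    def to_list(self):
        out = []
        for contig in self.contigs():
            s, e, v = self._data[contig]
            for i in range(len(s)):
                if self.has_values:
                    out.append((contig, int(s[i]), int(e[i]), float(v[i])))
                else:
                    out.append((contig, int(s[i]), int(e[i])))
        return out

    @property
    def total_bp(self) -> int:
        """Covered base pairs after normalization."""
        n = 0
        for contig in self._data:
            s, e, _ = self._data[contig]
            ms, me = _merge(s, e)
            n += int((me - ms).sum())
        return n

    def lengths(self) -> np.ndarray:
        """Per-interval lengths in input (sorted) order, concatenated."""
        return np.concatenate(
            [self._data[c][1] - self._data[c][0] for c in self.contigs()]
        ) if self._data else np.zeros(0, dtype=np.int64)

    def values(self) -> np.ndarray:
        if not self.has_values:
            raise ValueError("track carries no values")
        return np.concatenate(
            [self._data[c][2] for c in self.contigs()]
        ) if self._data else np.zeros(0)

    def is_disjoint_sorted(self) -> bool:
        for contig in self._data:
            s, e, _ = self._data[contig]
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                return False
        return True

    def contains(self, contig, pos) -> np.ndarray:
        """Boolean membership for positions on one contig (vectorized)."""
        pos = np.asarray(pos)
        s, e, _ = self.per_contig(contig)
        if len(s) == 0:
            return np.zeros(pos.shape, dtype=bool)
        s, e = _merge(s, e)  # membership is insensitive to overlaps
        idx = np.searchsorted(s, pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < e[idx[ok]]
        return out

    def value_at(self, contig, pos) -> np.ndarray:
        """Per-position value lookup; NaN where uncovered."""
        if not self.has_values:
            raise ValueError("track carries no values")
        pos = np.asarray(pos)
        s, e, v = self.per_contig(contig)
        out = np.full(pos.shape, np.nan)
        if len(s) == 0:
            return out
        idx = np.searchsorted(s, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos.shape, dtype=bool)
        hit[ok] = pos[ok] < e[idx[ok]]
        out[hit] = v[idx[hit]]
        return out


def _merge(starts, ends):
    """Merge sorted, possibly overlapping/adjacent intervals."""
    if len(starts) == 0:
        return starts, ends
    keep_s = [starts[0]]
    keep_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= keep_e[-1]:
            keep_e[-1] = max(keep_e[-1], e)
        else:
            keep_s.append(s)
            keep_e.append(e)
    return np.asarray(keep_s, dtype=np.int64), np.asarray(keep_e, dtype=np.int64)


def _boolean_combine(tracks, mode):
    """Union or intersection of plain tracks via coverage counting."""
    contigs = set()
    for t in tracks:
        contigs.update(t._data)
    need = len(tracks)
    data = {}
    for contig in contigs:
        events = []
        for t in tracks:
            s, e, _ = t.per_contig(contig)
            ms, me = _merge(s, e)
            events.append(np.stack([ms, np.ones_like(ms)], axis=1))
            events.append(np.stack([me, -np.ones_like(me)], axis=1))
        ev = np.concatenate(events)
        order = np.lexsort((-ev[:, 1], ev[:, 0]))  # opens before closes at ties
        ev = ev[order]
        cov = np.cumsum(ev[:, 1])
        thresh = need if mode == "intersect" else 1
        inside = cov >= thresh
        # region between ev[i] and ev[i+1] is covered iff inside[i]
        starts = ev[:-1, 0][inside[:-1]]
        ends = ev[1:, 0][inside[:-1]]
        keep = starts < ends
        starts, ends = starts[keep], ends[keep]
        if len(starts):
            starts, ends = _merge(starts, ends)
            data[contig] = (starts, ends, np.full(len(starts), np.nan))
    return IntervalTrack._from_data(data)


def track_union(tracks) -> IntervalTrack:
    tracks = [t for t in tracks if t._data]
    if not tracks:
        return IntervalTrack([])
    return _boolean_combine(tracks, "union")


def track_intersect(tracks) -> IntervalTrack:
    tracks = list(tracks)
    if any(not t._data for t in tracks):
        return IntervalTrack([])
    return _boolean_combine(tracks, "intersect")


def track_subtract(a: IntervalTrack, b: IntervalTrack) -> IntervalTrack:
    """Positions in ``a`` but not in ``b``."""
    data = {}
    for contig in a._data:
        s, e, _ = a.per_contig(contig)
        s, e = _merge(s, e)
        bs, be, _ = b.per_contig(contig)
        bs, be = _merge(bs, be)
        out_s, out_e = [], []
        j = 0
        for ai, bi in zip(s, e):
            cur = ai
            while j < len(bs) and be[j] <= cur:
                j += 1
            k = j
            while k < len(bs) and bs[k] < bi:
                if bs[k] > cur:
                    out_s.append(cur)
                    out_e.append(min(bs[k], bi))
                cur = max(cur, be[k])
                if cur >= bi:
                    break
                k += 1
            if cur < bi:
                out_s.append(cur)
                out_e.append(bi)
        if out_s:
            data[contig] = (
                np.asarray(out_s, dtype=np.int64),
                np.asarray(out_e, dtype=np.int64),
                np.full(len(out_s), np.nan),
            )
    return IntervalTrack._from_data(data)


def normalize_track(track: IntervalTrack, layout: GenomeLayout | None = None) -> IntervalTrack:
    """Sort and merge overlapping/adjacent intervals (plain tracks only).

    Value-carrying tracks are validated (sorted, non-overlapping) but never
    merged, since adjacent intervals may carry distinct values.
    """
    layout = layout or track.layout
    if layout is not None:
        for contig in track._data:
            if contig not in layout:
                raise ValueError(f"contig {contig!r} not in layout")
            _, e, _ = track._data[contig]
            if e.max(initial=0) > layout[contig]:
                bad = int(e.max())
                raise ValueError(
                    f"interval end {bad} beyond contig {contig!r} end {layout[contig]}"
                )
    if track.has_values:
        if not track.is_disjoint_sorted():
            raise ValueError("value-carrying track has overlapping intervals")
        return track
    data = {}
    for contig in track._data:
        s, e, _ = track._data[contig]
        ms, me = _merge(s, e)
        data[contig] = (ms, me, np.full(len(ms), np.nan))
    out = IntervalTrack._from_data(data, layout=layout)
    return out


@dataclass
class MaskSet:
    """Named filter tracks, each tagged include or exclude.

    ``include`` tracks restrict the universe to their intersection;
    ``exclude`` tracks carve positions out. This is the container for the
    13-filter neutral-site scheme (accessibility, conservation, repeats,
    sweeps, ... consumed as BED inputs).
    """

    include: dict[str, IntervalTrack] = field(default_factory=dict)
    exclude: dict[str, IntervalTrack] = field(default_factory=dict)

    def names(self):
        return sorted(self.include) + sorted(self.exclude)


def build_neutral_mask(masks: MaskSet, layout: GenomeLayout) -> IntervalTrack:
    """Intersection of include tracks minus union of exclude tracks.

    An empty include set means the whole layout (every filter is then purely
    subtractive).
    """
    if masks.include:
        base = track_intersect(
            [normalize_track(t, layout) for t in masks.include.values()]
        )
    else:
        base = layout.whole()
    if masks.exclude:
        excl = track_union([normalize_track(t, layout) for t in masks.exclude.values()])
        base = track_subtract(base, excl)
    base.layout = layout
    return base


def hotspot_exclusion(
    rates: IntervalTrack | None,
    hotspots: IntervalTrack | None,
    flank: int = 1500,
    threshold: float = 10.0,
    max_span: int = 3000,
    layout: GenomeLayout | None = None,
    rate_mode: str = "interval",
) -> IntervalTrack:
    """Recombination-hotspot exclusion track.

    Removes (a) every position within ``flank`` bp of a position whose map
    rate is >= ``threshold`` cM/Mb and (b) a ``2*flank`` window centered on
    each annotated hotspot's midpoint — unless the hotspot itself is longer
    than ``max_span``, in which case the hotspot interval is excluded as-is.

    ``rate_mode`` selects whether the distance for rule (a) is measured from
    any base of the qualifying map interval (``"interval"``, default) or from
    its midpoint (``"midpoint"``).
    """
    pieces = []
    if rates is not None and rates._data:
        if not rates.has_values:
            raise ValueError("rates track must carry cM/Mb values")
        for contig in rates.contigs():
            s, e, v = rates.per_contig(contig)
            hot = v >= threshold
            if not hot.any():
                continue
            if rate_mode == "interval":
                lo = s[hot] - flank
                hi = e[hot] + flank
            elif rate_mode == "midpoint":
                mid = (s[hot] + e[hot]) // 2
                lo = mid - flank
                hi = mid + flank
            else:
                raise ValueError(f"unknown rate_mode {rate_mode!r}")
            for a, b in zip(lo, hi):
                pieces.append((contig, max(0, int(a)), int(b)))
    if hotspots is not None and hotspots._data:
        for contig in hotspots.contigs():
            s, e, _ = hotspots.per_contig(contig)
            span = e - s
            small = span <= max_span
            mid = (s + e) // 2
            for a, b, sm, m in zip(s, e, small, mid):
                if sm:
                    pieces.append((contig, max(0, int(m) - flank), int(m) + flank))
                else:
                    pieces.append((contig, int(a), int(b)))
    if layout is not None:
        pieces = [
            (c, s, min(e, layout[c])) for c, s, e in pieces if c in layout and s < layout[c]
        ]
    return normalize_track(IntervalTrack(pieces), layout)


def quantile_thresholds(bmap: IntervalTrack, q) -> np.ndarray:
    """Per-base (length-weighted) empirical quantiles of a value track.

    The ``q``-quantile is the smallest value ``B`` such that the fraction of
    covered bases with value <= ``B`` is at least ``q``. Monotone in ``q``.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if ((q <= 0) | (q >= 1)).any():
        raise ValueError("quantile fractions must lie strictly in (0,1)")
    vals = bmap.values()
    if len(vals) == 0:
        raise ValueError("empty value track")
    lens = bmap.lengths().astype(float)
    order = np.argsort(vals, kind="stable")
    v = vals[order]
    w = lens[order]
    cdf = np.cumsum(w) / w.sum()
    idx = np.searchsorted(cdf, q, side="left")
    idx = np.minimum(idx, len(v) - 1)
    return v[idx]


def bin_membership(
    bmap: IntervalTrack,
    low_quantiles=(0.01, 0.05, 0.10, 0.25),
    top_quantile: float = 0.01,
) -> dict[str, IntervalTrack]:
    """Nested low-B bins plus the top bin, as position sets.

    Returns tracks keyed ``"lowest_1pct"`` ... and ``"highest_1pct"``. The
    low bins are nested (not disjoint); positions lacking a B value are
    simply absent from the map and therefore excluded.
    """
    out = {}
    thr = quantile_thresholds(bmap, list(low_quantiles) + [1 - top_quantile])
    low_thr, top_thr = thr[:-1], thr[-1]
    for qf, t in zip(low_quantiles, low_thr):
        label = f"lowest_{_pct(qf)}"
        out[label] = _select_by_value(bmap, lambda v, t=t: v <= t)
    out[f"highest_{_pct(top_quantile)}"] = _select_by_value(bmap, lambda v: v >= top_thr)
    return out


def disjoint_bins(bmap: IntervalTrack, n_bins: int = 50):
    """Disjoint equal-occupancy bins of the per-base B distribution.

    Returns ``(tracks, bounds)`` where ``tracks`` is a list of ``n_bins``
    position-set tracks and ``bounds`` the ``(lo, hi)`` value bounds of each
    bin; the regression x-value for a bin is the mean of its bounds.
    Degenerate (constant) maps occupy a single bin.
    """
    vals = bmap.values()
    edges_q = np.arange(1, n_bins) / n_bins
    inner = quantile_thresholds(bmap, edges_q)
    lo_edge = float(vals.min())
    hi_edge = float(vals.max())
    edges = np.concatenate([[lo_edge], inner, [hi_edge]])
    tracks, bounds = [], []
    for k in range(n_bins):
        lo, hi = edges[k], edges[k + 1]
        if k == 0:
            sel = _select_by_value(bmap, lambda v: v <= hi)
        else:
            sel = _select_by_value(bmap, lambda v: (v > lo) & (v <= hi))
        tracks.append(sel)
        bounds.append((float(lo), float(hi)))
    return tracks, bounds


def _select_by_value(bmap: IntervalTrack, pred) -> IntervalTrack:
    data = {}
    for contig in bmap.contigs():
        s, e, v = bmap.per_contig(contig)
        keep = pred(v)
        if keep.any():
            ms, me = _merge(s[keep], e[keep])
            data[contig] = (ms, me, np.full(len(ms), np.nan))
    return IntervalTrack._from_data(data)


def _pct(f: float) -> str:
    p = 100 * f
    return f"{p:g}pct"


# -- plain-text IO ------------------------------------------------------------

def read_bed(path, layout: GenomeLayout | None = None) -> IntervalTrack:
    """Read a 3+ column BED file (extra columns ignored)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["contig", "start", "end"], dtype={0: str},
    )
    return IntervalTrack(
        list(df.itertuples(index=False, name=None)), layout=layout
    )


def read_bedgraph(path, layout: GenomeLayout | None = None) -> IntervalTrack:
    """Read a 4-column bedGraph (contig, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["contig", "start", "end", "value"],
        dtype={0: str},
    )
    return IntervalTrack(
        list(df.itertuples(index=False, name=None)), layout=layout
    )


def write_bed(track: IntervalTrack, path):
    with open(path, "w") as fh:
        for iv in track.to_list():
            if track.has_values:
                c, s, e, v = iv
                fh.write(f"{c}\t{s}\t{e}\t{v:.6g}\n")
            else:
                c, s, e = iv
                fh.write(f"{c}\t{s}\t{e}\n")
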