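"""Representative-frame selection from monitored distance distributions.

A representative snapshot is chosen by two criteria: every monitored
distance should fall in the most-populated ('modal') bin of its own
distribution, and among such frames the total hydrogen-bond length should
be smallest (shorter bonds ~ tighter binding).  Ring distances participate
in the modal-membership criterion only; the minimized total runs over
hydrogen bonds alone.

Two modes are provided: 'strict' (every series modal; error if no frame
qualifies), 'lexicographic' (maximize the number of modal series, then
minimize the total length) and 'auto' (strict with lexicographic fallback).
All ties break toward the lowest frame index, making selection fully
deterministic and invariant to the ordering of the monitored series.

Frame indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_stats import (DEFAULT_BIN_WIDTH, DEFAULT_FIRST_CENTER,
                               DEFAULT_N_BINS, HBondSeries, HistogramTable,
                               bin_hbond_series)

RING_FIRST_CENTER = 2.125
RING_N_BINS = 24


class SelectionError(ValueError):
    pass


def modal_interval(histogram: HistogramTable) -> tuple[float, float]:
    """Half-open [low, high) interval of the most-populated bin.

    Ties break toward the shorter-distance bin.  An all-zero histogram has
    no modal bin and is refused.
    """
    freq = np.asarray(histogram.frequencies)
    if not np.any(freq > 0):
        raise SelectionError(
            f"{histogram.bond_id}: all-zero histogram has no modal interval")
    k = int(np.argmax(freq))          # first maximum = shortest distance
    return histogram.bin_interval(k)


@dataclass
class SelectionReport:
    """Outcome of representative-frame selection (0-based frame index)."""

    chosen_frame: int
    total_hbond_length: np.ndarray        # per frame, Å
    modal_membership_count: np.ndarray    # per frame
    n_monitored: int
    mode_used: str
    criteria_config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chosen_frame": int(self.chosen_frame),
            "mode_used": self.mode_used,
            "n_monitored": self.n_monitored,
            "total_hbond_length": self.total_hbond_length.round(6).tolist(),
            "modal_membership_count":
                self.modal_membership_count.astype(int).tolist(),
            "criteria_config": self.criteria_config,
        }


def _in_interval(values: np.ndarray, interval) -> np.ndarray:
    lo, hi = interval
    return (values >= lo) & (values < hi)


def select_representative(hbond_series_list: list[HBondSeries],
                          ring_series: dict[str, np.ndarray] | None = None,
                          mode: str = "auto",
                          bin_width: float = DEFAULT_BIN_WIDTH,
                          first_center: float = DEFAULT_FIRST_CENTER,
                          n_bins: int = DEFAULT_N_BINS,
                          ring_first_center: float = RING_FIRST_CENTER,
                          ring_n_bins: int = RING_N_BINS) -> SelectionReport:
    """Choose the frame that best represents the monitored distributions."""
    if not hbond_series_list:
        raise SelectionError("at least one monitored H-bond series required")
    if mode not in ("strict", "lexicographic", "auto"):
        raise SelectionError(f"unknown mode {mode!r}")
    n_frames = hbond_series_list[0].n_frames
    for s in hbond_series_list:
        if s.n_frames != n_frames:
            raise SelectionError("monitored series differ in frame count")
    ring_series = dict(ring_series or {})

    total = np.zeros(n_frames)
    count = np.zeros(n_frames, dtype=int)
    intervals = {}
    for s in hbond_series_list:
        hist = bin_hbond_series(s, bin_width, first_center, n_bins)
        iv = modal_interval(hist)
        intervals[s.bond_id] = iv
        total += s.distances
        count += _in_interval(s.distances, iv)
    for rid, series in ring_series.items():
        series = np.asarray(series, dtype=float)
        if series.size != n_frames:
            raise SelectionError(f"ring series {rid!r} frame-count mismatch")
        hist = bin_hbond_series(HBondSeries(rid, series), bin_width,
                                ring_first_center, ring_n_bins)
        iv = modal_interval(hist)
        intervals[rid] = iv
        count += _in_interval(series, iv)

    n_monitored = len(hbond_series_list) + len(ring_series)
    strict_mask = count == n_monitored

    def best_of(mask: np.ndarray) -> int:
        idx = np.flatnonzero(mask)
        return int(idx[np.argmin(total[idx])])   # argmin: first = lowest index

    if mode in ("strict", "auto") and strict_mask.any():
        chosen, used = best_of(strict_mask), "strict"
    elif mode == "strict":
        raise SelectionError(
            "no frame satisfies every modal interval in strict mode")
    else:
        chosen, used = best_of(count == count.max()), "lexicographic"

    config = {"mode": mode, "bin_width": bin_width,
              "first_center": first_center, "n_bins": n_bins,
              "modal_intervals": {k: list(v) for k, v in intervals.items()}}
    return SelectionReport(chosen_frame=chosen, total_hbond_length=total,
                           modal_membership_count=count,
                           n_monitored=n_monitored, mode_used=used,
                           criteria_config=config)
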