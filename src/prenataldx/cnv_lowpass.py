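"""Genome-wide CNV calling from shallow-WGS 20 kb bin counts.

The procedure mirrors a batch-regularized read-depth pipeline:

1. **Batch normalization** — every sample in a sequencing batch is scaled to
   a common total count; the per-bin reference is the across-batch median of
   scaled counts, and each sample's signal is the log2 ratio to that
   reference. Bins whose reference falls below ``min_ref`` are masked.
2. **Smoothing** — a centered local linear regression (default window
   15 bins, truncated at chromosome edges) suppresses bin-level noise.
3. **First-order difference** — ``d_j = s_j − s_{j−1}`` on the smoothed
   series; away from copy-number change the difference is ~0, at a change it
   spikes.
4. **Breakpoints** — local extrema of ``|d|`` exceeding
   ``τ = max(k · 1.4826 · MAD(d), 0.1)`` become breakpoints ("the difference
   is still not zero"); the sign gives the direction.
5. **Calls** — consecutive opposite-direction breakpoints (down→up = loss,
   up→down = gain) bound candidate segments; a segment becomes a call when it
   spans ≥ ``min_bins`` bins and its mean linear ratio leaves
   [``loss_ratio``, ``gain_ratio``]. Chromosome ends and masked-bin gaps act
   as implicit breakpoints so terminal events remain callable.

Everything is deterministic for fixed inputs and parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinCountProfile",
    "BatchMatrix",
    "Breakpoint",
    "CnvCall",
    "BreakpointParams",
    "CallParams",
    "bin_reads",
    "normalize_batch",
    "detect_breakpoints",
    "assemble_cnv_calls",
    "call_sample",
    "profiles_from_frame",
    "frame_from_profiles",
]


@dataclass(frozen=True)
class BinCountProfile:
    """Per-chromosome 20 kb bin counts for one sample."""

    sample_id: str
    bin_size: int
    counts: Mapping[str, np.ndarray]  # chrom -> integer counts per bin

    def total(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))


@dataclass
class BatchMatrix:
    """Batch-normalized bin-count matrix with per-bin usability mask."""

    sample_ids: list[str]
    bins: pd.DataFrame  # columns chrom, start, end; one row per bin
    raw: np.ndarray  # bins x samples
    ratio: np.ndarray  # linear ratio to batch reference (NaN where masked)
    mask: np.ndarray  # True where the bin is usable

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in batch") from None

    def log2_ratio(self, sample_id: str) -> np.ndarray:
        r = self.ratio[:, self.sample_index(sample_id)]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(r)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return (self.bins["chrom"] == chrom).to_numpy()


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    bin_index: int  # index into the chromosome's usable-bin series
    magnitude: float  # thresholded difference value (signed)
    direction: str  # "up" | "down"


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    mean_ratio: float
    copy_number: int
    state: str  # "loss" | "gain"
    n_bins: int
    origin: str = "lowpass"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty call interval")


@dataclass(frozen=True)
class BreakpointParams:
    smooth_window: int = 15  # bins; centered local linear regression
    threshold_k: float = 5.0  # multiples of scaled MAD
    threshold_floor: float = 0.1  # absolute log2 floor for zero-noise input


@dataclass(frozen=True)
class CallParams:
    min_bins: int = 3
    loss_ratio: float = 0.75
    gain_ratio: float = 1.25
    max_copy_number: int = 6


def bin_reads(
    read_starts: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    bin_size: int,
    sample_id: str = "sample",
) -> BinCountProfile:
    """Count read starts per half-open bin ``[k·b, (k+1)·b)``.

    Positions must be sorted and within chromosome bounds; the total of the
    output equals the number of input reads.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_bins = math.ceil(length / bin_size)
        pos = np.asarray(read_starts.get(chrom, ()), dtype=np.int64)
        if pos.size:
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"read positions on {chrom} are not sorted")
            if pos[0] < 0 or pos[-1] >= length:
                raise ValueError(f"read position outside chromosome {chrom} bounds")
        counts[chrom] = np.bincount(pos // bin_size, minlength=n_bins).astype(np.int64)
    unknown = set(read_starts) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"reads on unknown chromosomes: {sorted(unknown)}")
    return BinCountProfile(sample_id=sample_id, bin_size=bin_size, counts=counts)


def normalize_batch(
    profiles: Sequence[BinCountProfile],
    min_ref: float = 10.0,
    min_batch: int = 8,
) -> BatchMatrix:
    """Scale samples to a common total and ratio them to the per-bin batch median.

    The reference is the across-batch *median* of scaled counts, robust to CNV
    carriers inside the batch; bins whose reference falls below ``min_ref``
    are masked out of all downstream arithmetic.
    """
    if len(profiles) < min_batch:
        raise ValueError(
            f"batch of {len(profiles)} samples is too small; "
            f"normalization needs at least {min_batch}"
        )
    first = profiles[0]
    chroms = list(first.counts)
    for p in profiles:
        if list(p.counts) != chroms or p.bin_size != first.bin_size:
            raise ValueError("profiles in a batch must share bin layout")
    raw_cols = []
    for p in profiles:
        raw_cols.append(np.concatenate([np.asarray(p.counts[c], float) for c in chroms]))
    raw = np.stack(raw_cols, axis=1)  # bins x samples
    bin_rows: list[tuple[str, int, int]] = []
    for c in chroms:
        n = len(first.counts[c])
        for k in range(n):
            bin_rows.append((c, k * first.bin_size, (k + 1) * first.bin_size))
    bins = pd.DataFrame(bin_rows, columns=["chrom", "start", "end"])

    totals = raw.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("a sample in the batch has zero total counts")
    target = float(np.median(totals))
    scaled = raw * (target / totals)
    ref = np.median(scaled, axis=1)
    mask = ref >= min_ref
    ratio = np.full_like(scaled, np.nan)
    ratio[mask] = scaled[mask] / ref[mask, None]
    logger.info(
        "normalized batch of %d samples: %d/%d bins usable",
        len(profiles),
        int(mask.sum()),
        mask.size,
    )
    return BatchMatrix(
        sample_ids=[p.sample_id for p in profiles],
        bins=bins,
        raw=raw,
        ratio=ratio,
        mask=mask,
    )


def _local_linear_smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered local linear regression with truncated edge windows.

    Closed form via sliding sums: the fit at index j over window
    [j-h, j+h] ∩ [0, n) evaluates the least-squares line at x = j.
    """
    n = y.size
    if n == 0 or window <= 1:
        return y.astype(float, copy=True)
    h = window // 2
    x = np.arange(n, dtype=float)
    ones = np.ones(n)

    def windowed_sum(v: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(v)))
        lo = np.clip(np.arange(n) - h, 0, n)
        hi = np.clip(np.arange(n) + h + 1, 0, n)
        return c[hi] - c[lo]

    s0 = windowed_sum(ones)
    s1 = windowed_sum(x)
    s2 = windowed_sum(x * x)
    sy = windowed_sum(y)
    sxy = windowed_sum(x * y)
    denom = s2 - s1 * s1 / s0
    ybar = sy / s0
    xbar = s1 / s0
    slope = np.where(denom > 1e-12, (sxy - s1 * sy / s0) / np.where(denom > 1e-12, denom, 1.0), 0.0)
    return ybar + slope * (x - xbar)


def _segment_runs(usable_idx: np.ndarray, max_gap: int = 1) -> list[np.ndarray]:
    """Split usable bin indices into runs broken by masked gaps > max_gap bins."""
    if usable_idx.size == 0:
        return []
    breaks = np.where(np.diff(usable_idx) > max_gap)[0]
    return np.split(usable_idx, breaks + 1)


def detect_breakpoints(
    matrix: BatchMatrix,
    sample_id: str,
    params: BreakpointParams = BreakpointParams(),
) -> list[Breakpoint]:
    """Smooth, difference and threshold one sample's log2-ratio series.

    Returns breakpoints per chromosome at local extrema of the first-order
    difference whose magnitude exceeds τ. ``bin_index`` refers to the global
    bin row in ``matrix.bins``; the difference at index j measures the change
    between bins j−1 and j, so a segment starting at a breakpoint includes
    bin j.
    """
    col = matrix.sample_index(sample_id)
    out: list[Breakpoint] = []
    for chrom in matrix.bins["chrom"].unique():
        in_chrom = matrix.chrom_slice(chrom)
        usable = in_chrom & matrix.mask
        idx = np.where(usable)[0]
        if idx.size < 2:
            logger.warning("chromosome %s has <2 usable bins; skipped", chrom)
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            series = np.log2(matrix.ratio[idx, col])
        series = np.where(np.isfinite(series), series, np.nanmin(series[np.isfinite(series)], initial=-6.0))
        smoothed = _local_linear_smooth(series, params.smooth_window)
        # scale the difference by the window: a copy step of height h smoothed
        # over W bins has per-bin difference ~h/W, so W*diff estimates the
        # step height itself and the log2-unit floor keeps its meaning
        w_eff = max(params.smooth_window, 1)
        d = w_eff * np.diff(smoothed)
        if d.size == 0:
            continue
        mad = float(np.median(np.abs(d - np.median(d))))
        tau = max(params.threshold_k * 1.4826 * mad, params.threshold_floor)
        absd = np.abs(d)
        over = absd > tau
        # a smoothed copy step yields a same-sign plateau of width ~W in d:
        # collapse each contiguous same-sign over-threshold run to its
        # |d|-weighted centroid, which sits at the true step for a symmetric
        # smoother
        j = 0
        while j < d.size:
            if not over[j]:
                j += 1
                continue
            sign = np.sign(d[j])
            k_end = j
            while k_end + 1 < d.size and over[k_end + 1] and np.sign(d[k_end + 1]) == sign:
                k_end += 1
            run = np.arange(j, k_end + 1)
            centroid = int(round(float(np.average(run, weights=absd[run]))))
            refined = _refine_breakpoint(
                series, centroid + 1, half_range=max(params.smooth_window // 2, 1)
            )
            out.append(
                Breakpoint(
                    chrom=chrom,
                    # change lands between idx[refined-1] and idx[refined]
                    bin_index=int(idx[refined]),
                    magnitude=float(d[centroid]),
                    direction="down" if sign < 0 else "up",
                )
            )
            j = k_end + 1
    return out


def _refine_breakpoint(series: np.ndarray, pos: int, half_range: int, flank: int = 4) -> int:
    """Snap a provisional change position to the raw-series edge.

    Searches ±half_range around ``pos`` for the split maximizing the absolute
    difference of flanking means — sharper than the smoothed statistic when
    the event is shorter than the smoothing window.
    """
    n = series.size
    best_pos, best_stat = pos, -np.inf
    candidates = sorted(
        range(max(1, pos - half_range), min(n, pos + half_range + 1)),
        key=lambda c: (abs(c - pos), c),
    )  # closest-first so ties keep the provisional position
    for c in candidates:
        left = series[max(0, c - flank) : c]
        right = series[c : c + flank]
        if left.size == 0 or right.size == 0:
            continue
        stat = abs(float(right.mean() - left.mean()))
        if stat > best_stat:
            best_stat, best_pos = stat, c
    return best_pos


def assemble_cnv_calls(
    breakpoints: Sequence[Breakpoint],
    matrix: BatchMatrix,
    sample_id: str,
    params: CallParams = CallParams(),
) -> list[CnvCall]:
    """Pair opposite-direction breakpoints into candidate segments and call.

    A loss needs a down-breakpoint on the left and an up-breakpoint on the
    right (gains the reverse); chromosome boundaries count as wildcards.
    Candidates shorter than ``min_bins`` or with mean linear ratio inside
    [loss_ratio, gain_ratio] are discarded.
    """
    col = matrix.sample_index(sample_id)
    calls: list[CnvCall] = []
    by_chrom: dict[str, list[Breakpoint]] = {}
    for bp in breakpoints:
        by_chrom.setdefault(bp.chrom, []).append(bp)
    for chrom in matrix.bins["chrom"].unique():
        in_chrom = matrix.chrom_slice(chrom)
        usable_idx = np.where(in_chrom & matrix.mask)[0]
        if usable_idx.size == 0:
            continue
        bps = sorted(by_chrom.get(chrom, []), key=lambda b: b.bin_index)
        # sentinel boundaries: chromosome start / end pair with anything
        cut_points: list[tuple[int, str | None]] = [(int(usable_idx[0]), None)]
        cut_points += [(bp.bin_index, bp.direction) for bp in bps]
        cut_points.append((int(usable_idx[-1]) + 1, None))
        for (left_idx, left_dir), (right_idx, right_dir) in zip(cut_points, cut_points[1:]):
            span = usable_idx[(usable_idx >= left_idx) & (usable_idx < right_idx)]
            # masked-bin gaps inside a candidate act as implicit breakpoints
            runs = _segment_runs(span, max_gap=2)
            for r, seg in enumerate(runs):
                run_left = left_dir if r == 0 else None
                run_right = right_dir if r == len(runs) - 1 else None
                call = _call_segment(
                    seg, matrix, col, sample_id, str(chrom), run_left, run_right, params
                )
                if call is not None:
                    calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def _call_segment(
    seg: np.ndarray,
    matrix: BatchMatrix,
    col: int,
    sample_id: str,
    chrom: str,
    left_dir: str | None,
    right_dir: str | None,
    params: CallParams,
) -> CnvCall | None:
    if seg.size >= params.min_bins:
        mean_ratio = float(np.nanmean(matrix.ratio[seg, col]))
        if params.loss_ratio <= mean_ratio <= params.gain_ratio:
            return None
        state = "loss" if mean_ratio < 1.0 else "gain"
        if state == "loss" and (left_dir == "up" or right_dir == "down"):
            return None
        if state == "gain" and (left_dir == "down" or right_dir == "up"):
            return None
        start = int(matrix.bins.iloc[seg[0]]["start"])
        end = int(matrix.bins.iloc[seg[-1]]["end"])
        copy_number = int(np.clip(round(2.0 * mean_ratio), 0, params.max_copy_number))
        return CnvCall(
            sample_id=sample_id,
            chrom=chrom,
            start=start,
            end=end,
            mean_ratio=mean_ratio,
            copy_number=copy_number,
            state=state,
            n_bins=int(seg.size),
        )
    return None


def call_sample(
    matrix: BatchMatrix,
    sample_id: str,
    bp_params: BreakpointParams = BreakpointParams(),
    call_params: CallParams = CallParams(),
) -> list[CnvCall]:
    """Breakpoint detection followed by call assembly for one sample."""
    bps = detect_breakpoints(matrix, sample_id, bp_params)
    return assemble_cnv_calls(bps, matrix, sample_id, call_params)


def profiles_from_frame(frame: pd.DataFrame, bin_size: int | None = None) -> list[BinCountProfile]:
    """Read per-sample profiles from a bincounts table (chrom, start, end, samples...)."""
    meta = ["chrom", "start", "end"]
    samples = [c for c in frame.columns if c not in meta]
    if bin_size is None:
        bin_size = int((frame["end"] - frame["start"]).max())
    out = []
    for s in samples:
        counts = {
            str(chrom): grp[s].to_numpy(dtype=np.int64)
            for chrom, grp in frame.groupby("chrom", sort=False)
        }
        out.append(BinCountProfile(sample_id=str(s), bin_size=bin_size, counts=counts))
    return out


def frame_from_profiles(profiles: Sequence[BinCountProfile]) -> pd.DataFrame:
    first = profiles[0]
    rows = []
    for chrom, counts in first.counts.items():
        for k in range(len(counts)):
            rows.append((chrom, k * first.bin_size, (k + 1) * first.bin_size))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    for p in profiles:
        frame[p.sample_id] = np.concatenate([np.asarray(p.counts[c]) for c in first.counts])
    return frame
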