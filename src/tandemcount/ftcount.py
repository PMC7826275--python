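"""Fourier-transform repeat-unit counter.

The counter compares a long read (Seq1, s_0..s_{n-1}) against phase-shifted,
wrapped periodic copies of a short known unit (Seq2, r_0..r_{m-1}):

* A conceptual n x n matrix M with a_{i,j} = r_{(i-j) mod m} is binarized
  against the read (M2), vertical runs of 1s in each column are relabeled with
  the run length (M3), values below a threshold X are zeroed (M4), and the
  row sums c_i form the match-run profile.
* The profile is smoothed with a (2L+1)-point moving average (copy-through at
  the edges), a dense region R is located, and the number of units in R is
  read off the discrete Fourier spectrum of the mean-subtracted profile over
  R, with documented degenerate fallbacks.

``literal_matrix_profile`` materializes the matrix and is the oracle;
``match_run_profile`` is the production equivalent that exploits the fact that
columns with equal j mod m are identical, weighting each distinct phase by its
column multiplicity, and is exactly equal to the oracle on any input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .io import ReadRecord, RepeatUnit, reverse_complement

_LITERAL_MAX_N = 2000

# ASCII code -> base index (A,C,G,T -> 0..3; everything else -> -1, never matches)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _encode_unit(seq: str) -> np.ndarray:
    codes = _encode(seq)
    if (codes < 0).any():
        raise ValueError("repeat unit must contain only A/C/G/T")
    return codes


@dataclass(frozen=True)
class DetectorParams:
    """Tunable constants of the detector.

    ``None`` values are resolved against the unit length m via
    :meth:`resolved`: L -> m // 20, gap_tolerance -> m, split_gap -> m // 4.
    """

    X: int = 12
    L: Optional[int] = None
    alpha: float = 0.1
    gap_tolerance: Optional[int] = None
    band_low: float = 0.5
    band_high: float = 1.5
    split_gap: Optional[int] = None
    min_prominence: float = 8.0

    def __post_init__(self) -> None:
        if self.X < 1:
            raise ValueError("X must be >= 1")
        if self.L is not None and self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not self.band_low < 1.0 < self.band_high:
            raise ValueError("band must satisfy band_low < 1 < band_high")

    def resolved(self, m: int) -> "DetectorParams":
        return replace(
            self,
            L=self.L if self.L is not None else max(1, m // 20),
            gap_tolerance=self.gap_tolerance if self.gap_tolerance is not None else m,
            split_gap=self.split_gap if self.split_gap is not None else max(1, m // 4),
        )


@dataclass
class MatchRunProfile:
    """Row-sum vector c of the thresholded run-length matrix M4."""

    c: np.ndarray
    n: int
    m: int
    X: int


@dataclass
class SmoothedProfile:
    """Moving-average profile v_ave; edges copied through unchanged."""

    v_ave: np.ndarray
    L: int


@dataclass(frozen=True)
class RepeatRegion:
    """Half-open profile interval containing the repeat array."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CopyCount:
    count: int
    peak_magnitude: float
    band_searched: tuple[int, int]
    method: str = "dft"
    read_id: str = ""
    orientation: str = "+"
    region: Optional[RepeatRegion] = None
    flags: tuple[str, ...] = ()


def literal_matrix_profile(seq1: str, seq2: str, X: int) -> MatchRunProfile:
    """Match-run profile by explicit construction of M, M2, M3 and M4.

    Column j of M holds the unit shifted down by j and wrapped, so
    a_{i,j} = r_{(i-j) mod m}. Oracle use only: n is capped at 2000 because
    the n x n matrix is materialized.
    """
    n, m = len(seq1), len(seq2)
    if m == 0:
        raise ValueError("seq2 must be nonempty")
    if n > _LITERAL_MAX_N:
        raise ValueError(
            f"literal_matrix_profile is capped at n <= {_LITERAL_MAX_N}; "
            "use match_run_profile for full-length reads"
        )
    if X < 1:
        raise ValueError("X must be >= 1")
    s = _encode(seq1)
    r = _encode_unit(seq2)
    i_idx = np.arange(n)
    unit_idx = (i_idx[:, None] - i_idx[None, :]) % m
    matrix = r[unit_idx]                                  # M
    m2 = (matrix == s[:, None]) & (s[:, None] >= 0)       # M2
    m3 = _run_values_per_column(m2)                       # M3
    m4 = np.where(m3 < X, 0, m3)                          # M4
    c = m4.sum(axis=1, dtype=np.int64)
    return MatchRunProfile(c=c, n=n, m=m, X=X)


def _run_values_per_column(mask: np.ndarray) -> np.ndarray:
    """Replace each vertical run of True of length k with the value k."""
    n, ncols = mask.shape
    padded = np.zeros((ncols, n + 1), dtype=bool)
    padded[:, :n] = mask.T
    flat = padded.ravel().astype(np.int8)
    diff = np.diff(np.concatenate(([np.int8(0)], flat)))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    lengths = ends - starts
    values = np.zeros(flat.size, dtype=np.int64)
    if lengths.size:
        offsets = np.repeat(np.cumsum(lengths) - lengths, lengths)
        positions = np.repeat(starts, lengths) + (np.arange(lengths.sum()) - offsets)
        values[positions] = np.repeat(lengths, lengths)
    return values.reshape(ncols, n + 1)[:, :n].T


def match_run_profile(seq1: str, seq2: str, X: int) -> MatchRunProfile:
    """Match-run profile for full-length reads; equals the literal oracle.

    Two exact reductions make this fast. First, columns j and j' of M are
    identical whenever j = j' (mod m), so each distinct phase p in [0, m) is
    processed once and weighted by its column multiplicity
    |{j < n : j mod m = p}|. Second, only runs of length >= X survive the
    thresholding, and every such run is a maximal extension of an exact
    X-mer match between the read and the cyclic unit, so runs are found by
    X-mer seeding instead of scanning all m x n cells.
    """
    n, m = len(seq1), len(seq2)
    if m == 0:
        raise ValueError("seq2 must be nonempty")
    if X < 1:
        raise ValueError("X must be >= 1")
    _encode_unit(seq2)  # validate alphabet even when no seeds are found
    c = np.zeros(n, dtype=np.int64)
    if n < X:
        return MatchRunProfile(c=c, n=n, m=m, X=X)

    # X-mers of the cyclic unit, one per offset u in [0, m)
    tiled = seq2 * ((X + m - 1) // m + 1)
    index: dict[str, list[int]] = {}
    for u in range(m):
        index.setdefault(tiled[u : u + X], []).append(u)

    phases: list[int] = []
    positions: list[int] = []
    for i in range(n - X + 1):
        offsets = index.get(seq1[i : i + X])
        if offsets:
            for u in offsets:
                phases.append((i - u) % m)
                positions.append(i)
    if not positions:
        return MatchRunProfile(c=c, n=n, m=m, X=X)

    p_arr = np.asarray(phases, dtype=np.int64)
    i_arr = np.asarray(positions, dtype=np.int64)
    order = np.lexsort((i_arr, p_arr))
    p_arr, i_arr = p_arr[order], i_arr[order]
    # a maximal run at phase p appears as consecutive seed positions i, i+1, ...
    is_start = np.empty(p_arr.size, dtype=bool)
    is_start[0] = True
    is_start[1:] = (p_arr[1:] != p_arr[:-1]) | (i_arr[1:] != i_arr[:-1] + 1)
    run_first = np.flatnonzero(is_start)
    run_last = np.append(run_first[1:], p_arr.size) - 1
    run_start = i_arr[run_first]
    run_len = i_arr[run_last] - run_start + X
    run_phase = p_arr[run_first]

    # columns j with j mod m = p all carry the same runs
    weights = np.array([len(range(p, n, m)) for p in range(m)], dtype=np.int64)
    contrib = weights[run_phase] * run_len
    delta = np.zeros(n + 1, dtype=np.int64)
    np.add.at(delta, run_start, contrib)
    np.add.at(delta, run_start + run_len, -contrib)
    return MatchRunProfile(c=np.cumsum(delta[:n]), n=n, m=m, X=X)


def smooth_profile(profile: MatchRunProfile, L: int) -> SmoothedProfile:
    """(2L+1)-point moving average; d_i = c_i outside [L, n-1-L]."""
    c = np.asarray(profile.c, dtype=float)
    n = c.size
    if L < 1:
        raise ValueError("L must be >= 1")
    if 2 * L + 1 > n:
        raise ValueError(f"smoothing window 2L+1={2 * L + 1} exceeds profile length {n}")
    kernel = np.full(2 * L + 1, 1.0 / (2 * L + 1))
    v = c.copy()
    v[L : n - L] = np.convolve(c, kernel, mode="valid")
    return SmoothedProfile(v_ave=v, L=L)


def find_repeat_region(
    smoothed: SmoothedProfile, params: DetectorParams
) -> Optional[RepeatRegion]:
    """Locate the dense region R of the smoothed profile.

    Positions with v_ave > alpha * max(v_ave) are marked; marked runs whose
    separating gaps are <= gap_tolerance are merged, and the longest merged
    run wins (leftmost on ties). Returns None when nothing is marked.
    """
    if params.gap_tolerance is None:
        raise ValueError("params.gap_tolerance unresolved; call params.resolved(m)")
    v = smoothed.v_ave
    vmax = v.max(initial=0.0)
    if vmax <= 0:
        return None
    runs = _true_runs(v > params.alpha * vmax)
    if not runs:
        return None
    merged = _merge_runs(runs, params.gap_tolerance)
    best = max(merged, key=lambda r: (r[1] - r[0], -r[0]))
    return RepeatRegion(best[0], best[1])


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    flat = mask.astype(np.int8)
    diff = np.diff(np.concatenate(([np.int8(0)], flat, [np.int8(0)])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    merged = [list(runs[0])]
    for start, end in runs[1:]:
        if start - merged[-1][1] <= max_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [tuple(r) for r in merged]


def count_repeats_dft(
    smoothed: SmoothedProfile,
    region: Optional[RepeatRegion],
    m: int,
    params: DetectorParams,
) -> CopyCount:
    """Count repeat units in region R from the profile spectrum.

    The region is first split at internal sub-threshold gaps at least
    ``split_gap`` long — such gaps arise from non-repeat insertions (a marker
    cassette) and must not be folded into the period estimate — and the
    per-block counts are summed. Per block: if the block is shorter than
    1.5 m it holds a single unit (one period has no usable fundamental);
    otherwise the DFT of the mean-subtracted profile is searched over the
    index band [band_low * |B|/m, band_high * |B|/m]. The peak index is the
    count when it is an interior local maximum at least ``min_prominence``
    times the band median; a flat or featureless spectrum falls back to
    round(|B|/m). All decisions scale-invariantly use ratios of magnitudes.
    """
    params = params.resolved(m)
    if region is None or len(region) == 0:
        return CopyCount(0, 0.0, (0, 0), method="dft", flags=("no_repeat",))
    if len(region) < 0.5 * m:
        # far narrower than one unit: a chance match blip, not a repeat
        return CopyCount(
            0, 0.0, (0, 0), method="dft", region=region,
            flags=("no_repeat", "region_too_short"),
        )
    if len(region) < 1.5 * m:
        return CopyCount(
            1, 0.0, (1, 1), method="dft", region=region, flags=("single_copy_rule",)
        )
    v = smoothed.v_ave
    threshold = 0.5 * params.alpha * v.max(initial=0.0)
    seg = v[region.start : region.end]
    blocks = _split_blocks(seg, threshold, params.split_gap, m)
    total = 0
    peak_mag = 0.0
    band_lo_all, band_hi_all = 0, 0
    widest_block = 0
    flags: list[str] = []
    for b0, b1 in blocks:
        blen = b1 - b0
        if blen < 1.5 * m:
            total += 1
            flags.append("single_copy_block")
            continue
        x = seg[b0:b1] - seg[b0:b1].mean()
        mags = np.abs(np.fft.rfft(x))
        center = blen / m
        lo = max(1, int(np.floor(params.band_low * center)))
        hi = min(mags.size - 1, int(np.ceil(params.band_high * center)))
        if hi <= lo:
            total += max(1, round(center))
            flags.append("band_degenerate")
            continue
        band = mags[lo : hi + 1]
        k_rel = int(np.argmax(band))
        k = lo + k_rel
        pk = float(band[k_rel])
        peak_mag = max(peak_mag, pk)
        if blen > widest_block:
            widest_block = blen
            band_lo_all, band_hi_all = lo, hi
        median = float(np.median(band))
        interior_peak = (
            0 < k_rel < band.size - 1
            and band[k_rel] > band[k_rel - 1]
            and band[k_rel] > band[k_rel + 1]
        )
        if median > 0 and interior_peak and pk >= params.min_prominence * median:
            total += k
        else:
            total += max(1, round(center))
            flags.append("flat_spectrum")
    if len(blocks) > 1:
        flags.append("split_region")
    return CopyCount(
        total,
        peak_mag,
        (band_lo_all, band_hi_all),
        method="dft",
        region=region,
        flags=tuple(dict.fromkeys(flags)),
    )


def _split_blocks(
    seg: np.ndarray, threshold: float, split_gap: int, m: int
) -> list[tuple[int, int]]:
    """Above-threshold runs of the region, merged across gaps < split_gap.

    Blocks shorter than m/2 are discarded as noise blips unless they are all
    there is.
    """
    runs = _true_runs(seg > threshold)
    if not runs:
        return [(0, seg.size)]
    merged = _merge_runs(runs, split_gap - 1)
    kept = [r for r in merged if r[1] - r[0] >= m // 2]
    return kept if kept else [max(merged, key=lambda r: r[1] - r[0])]


def count_read(
    read: ReadRecord, unit: RepeatUnit, params: DetectorParams = DetectorParams()
) -> CopyCount:
    """End-to-end count for one read: profile -> smooth -> region -> DFT.

    Both orientations of the unit are considered; a k-mer vote cheaply
    pre-selects the orientation and the full pipeline runs on both only when
    the vote is close, with the orientation of larger in-region profile mass
    (then larger count) reported. The result is invariant under
    reverse-complementing the read.
    """
    m = unit.length_m
    params = params.resolved(m)
    fwd_votes, rev_votes = _orientation_votes(read.sequence, unit.sequence)
    candidates: list[str] = []
    if fwd_votes == rev_votes == 0:
        candidates = ["+", "-"]
    elif fwd_votes >= 1.25 * rev_votes + 5:
        candidates = ["+"]
    elif rev_votes >= 1.25 * fwd_votes + 5:
        candidates = ["-"]
    else:
        candidates = ["+", "-"]

    best: Optional[tuple[float, int, str, CopyCount]] = None
    for orientation in candidates:
        unit_seq = unit.sequence if orientation == "+" else reverse_complement(unit.sequence)
        profile = match_run_profile(read.sequence, unit_seq, params.X)
        L = min(params.L, max(1, (profile.n - 1) // 2))
        if 2 * L + 1 > profile.n:
            smoothed = SmoothedProfile(profile.c.astype(float), 0)
        else:
            smoothed = smooth_profile(profile, L)
        region = find_repeat_region(smoothed, params)
        result = count_repeats_dft(smoothed, region, m, params)
        mass = float(smoothed.v_ave[region.start : region.end].sum()) if region else 0.0
        result.read_id = read.id
        result.orientation = orientation
        key = (mass, result.count, orientation)
        if best is None or key > best[:3]:
            best = (mass, result.count, orientation, result)
    assert best is not None
    result = best[3]
    if best[0] == 0.0:
        result.flags = tuple(dict.fromkeys(result.flags + ("no_repeat",)))
    return result


def _orientation_votes(read_seq: str, unit_seq: str, k: int = 13) -> tuple[int, int]:
    """Number of unit k-mers found verbatim in the read, per orientation."""
    if len(read_seq) < k or len(unit_seq) < k:
        return 0, 0
    read_kmers = {read_seq[i : i + k] for i in range(len(read_seq) - k + 1)}
    rc_unit = reverse_complement(unit_seq)
    fwd = sum(unit_seq[i : i + k] in read_kmers for i in range(len(unit_seq) - k + 1))
    rev = sum(rc_unit[i : i + k] in read_kmers for i in range(len(rc_unit) - k + 1))
    return fwd, rev
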