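"""Spanning-read selection by flank alignment.

A read spans the array iff both unique 1-kb flanks align to it on the same
strand in consistent order. Candidate placements come from exact k-mer seeds
clustered by diagonal; each cluster is scored with a banded edit-distance
alignment (edlib) of the chained flank stretch against the read window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib

from .io import FlankPair, ReadRecord, reverse_complement


@dataclass(frozen=True)
class SpanParams:
    k: int = 15
    min_identity: float = 0.75
    min_coverage: float = 0.5


@dataclass
class FlankHit:
    read_interval: tuple[int, int]
    flank: str               # "upstream" | "downstream"
    strand: str              # "+" | "-"
    identity: float
    flank_coverage: float
    flank_interval: tuple[int, int] = (0, 0)   # chained stretch of the flank


@dataclass
class SpanningCall:
    read_id: str
    spanning: bool
    orientation: str = "undetermined"   # "+" | "-" | "undetermined"
    array_interval: Optional[tuple[int, int]] = None
    flags: tuple[str, ...] = ()


def find_flank_hits(
    read: ReadRecord,
    flank: str,
    k: int = 15,
    min_identity: float = 0.75,
    min_coverage: float = 0.5,
    flank_label: str = "upstream",
) -> list[FlankHit]:
    """Seed-and-extend hits of one flank in a read, both strands.

    Exact k-mer seeds are clustered on near-constant diagonals; each cluster
    is rescored by edit-distance alignment and hits below the identity or
    coverage thresholds are dropped. Hits are sorted by read position.
    Zero hits is a valid result.
    """
    if k > len(flank):
        raise ValueError("seed length k exceeds flank length")
    hits: list[FlankHit] = []
    for strand in ("+", "-"):
        target_seq = read.sequence if strand == "+" else reverse_complement(read.sequence)
        for cluster in _seed_clusters(target_seq, flank, k, band=max(k, len(flank) // 5)):
            hit = _score_cluster(target_seq, flank, cluster, k, flank_label, strand)
            if hit is None:
                continue
            if hit.identity < min_identity or hit.flank_coverage < min_coverage:
                continue
            if strand == "-":
                n = len(read.sequence)
                a, b = hit.read_interval
                hit.read_interval = (n - b, n - a)
            hits.append(hit)
    hits = _dedupe_hits(hits)
    hits.sort(key=lambda h: h.read_interval)
    return hits


def _seed_clusters(target: str, flank: str, k: int, band: int) -> list[list[tuple[int, int]]]:
    """Cluster (target_pos, flank_pos) seed matches by diagonal."""
    index: dict[str, list[int]] = {}
    for pos in range(len(flank) - k + 1):
        index.setdefault(flank[pos : pos + k], []).append(pos)
    seeds: list[tuple[int, int]] = []
    for tp in range(len(target) - k + 1):
        for fp in index.get(target[tp : tp + k], ()):
            seeds.append((tp, fp))
    if not seeds:
        return []
    seeds.sort(key=lambda s: s[0] - s[1])
    clusters: list[list[tuple[int, int]]] = [[seeds[0]]]
    for seed in seeds[1:]:
        prev = clusters[-1][-1]
        if (seed[0] - seed[1]) - (prev[0] - prev[1]) <= band:
            clusters[-1].append(seed)
        else:
            clusters.append([seed])
    return clusters


def _score_cluster(
    target: str,
    flank: str,
    cluster: list[tuple[int, int]],
    k: int,
    flank_label: str,
    strand: str,
) -> Optional[FlankHit]:
    tps = [s[0] for s in cluster]
    fps = [s[1] for s in cluster]
    f0, f1 = min(fps), max(fps) + k
    coverage = (f1 - f0) / len(flank)
    pad = max(k, len(flank) // 5)
    t0 = max(0, min(tps) - pad)
    t1 = min(len(target), max(tps) + k + pad)
    query = flank[f0:f1]
    result = edlib.align(query, target[t0:t1], mode="HW", task="locations")
    if result["editDistance"] < 0 or not result["locations"]:
        return None
    loc_start, loc_end = result["locations"][0]
    identity = 1.0 - result["editDistance"] / len(query)
    return FlankHit(
        read_interval=(t0 + loc_start, t0 + loc_end + 1),
        flank=flank_label,
        strand=strand,
        identity=identity,
        flank_coverage=coverage,
        flank_interval=(f0, f1),
    )


def _dedupe_hits(hits: list[FlankHit]) -> list[FlankHit]:
    """Merge overlapping same-strand hits, keeping the best identity."""
    kept: list[FlankHit] = []
    for hit in sorted(hits, key=lambda h: (-h.identity, h.read_interval)):
        if any(
            h.strand == hit.strand and _overlaps(h.read_interval, hit.read_interval)
            for h in kept
        ):
            continue
        kept.append(hit)
    return kept


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_spanning(
    read: ReadRecord, flanks: FlankPair, params: SpanParams = SpanParams()
) -> SpanningCall:
    """Decide whether a read spans the whole array.

    Spanning requires an upstream and a downstream flank hit on the same
    strand with upstream before downstream in array orientation; the array
    interval lies between the inner flank edges. Each hit must also reach
    both ends of its flank, within an end tolerance that scales with the
    observed divergence (3 x (1 - identity) x flank length) — on error-free
    reads the tolerance is zero, so the call reduces to exact containment of
    both full flanks. If both strands offer a consistent pair the call is
    flagged undetermined. Equal-scoring hits are broken by leftmost read
    coordinate for determinism.
    """
    up_hits = find_flank_hits(
        read, flanks.upstream, params.k, params.min_identity, params.min_coverage, "upstream"
    )
    down_hits = find_flank_hits(
        read, flanks.downstream, params.k, params.min_identity, params.min_coverage, "downstream"
    )
    pairs: list[tuple[str, tuple[int, int]]] = []
    for strand in ("+", "-"):
        up = _best_hit(up_hits, strand)
        down = _best_hit(down_hits, strand)
        if up is None or down is None:
            continue
        if not (_covers_flank_ends(up, len(flanks.upstream))
                and _covers_flank_ends(down, len(flanks.downstream))):
            continue
        if strand == "+" and up.read_interval[1] <= down.read_interval[0]:
            pairs.append((strand, (up.read_interval[1], down.read_interval[0])))
        elif strand == "-" and down.read_interval[1] <= up.read_interval[0]:
            pairs.append((strand, (down.read_interval[1], up.read_interval[0])))
    if len(pairs) == 1:
        strand, interval = pairs[0]
        return SpanningCall(read.id, True, strand, interval)
    if len(pairs) > 1:
        return SpanningCall(read.id, False, "undetermined", None, flags=("ambiguous_pairs",))
    return SpanningCall(read.id, False, "undetermined", None)


def _best_hit(hits: list[FlankHit], strand: str) -> Optional[FlankHit]:
    candidates = [h for h in hits if h.strand == strand]
    if not candidates:
        return None
    return max(candidates, key=lambda h: (h.identity, -h.read_interval[0]))


def _covers_flank_ends(hit: FlankHit, flank_len: int) -> bool:
    """True when the chained stretch reaches both flank ends.

    The tolerance grows with observed divergence because seed survival decays
    near error clusters; at identity 1.0 it is zero, making the check exact.
    """
    tol = 3.0 * (1.0 - hit.identity) * flank_len
    f0, f1 = hit.flank_interval
    return f0 <= tol and (flank_len - f1) <= tol
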