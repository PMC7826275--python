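"""Synthetic tandem-array molecules and nanopore-like reads with ground truth.

The generator emulates the architecture of a budding-yeast macrosatellite such
as the CUP1 array: a ~2.0-kb unit iterated head-to-tail between unique 1-kb
flanks, optionally with a selection-marker cassette (URA3-style) inserted at a
unit boundary and with interstitial (partial-unit) deletions. Reads carry
uniform per-base substitution/insertion/deletion errors at rates caricaturing
an R9.4.1-era nanopore run. Every emitted read has a truth sidecar so each
downstream stage can be scored without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import (
    FlankPair,
    ReadRecord,
    RepeatUnit,
    reverse_complement,
    write_sequences,
    write_table,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_UNIT_LENGTH = 2000
DEFAULT_FLANK_LENGTH = 1000
DEFAULT_SUB_RATE = 0.03
DEFAULT_INS_RATE = 0.02
DEFAULT_DEL_RATE = 0.03


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform i.i.d. DNA string of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def random_unit(length: int, rng: np.random.Generator, id: str = "unit") -> RepeatUnit:
    return RepeatUnit(id, random_dna(length, rng))


def random_flanks(length: int, rng: np.random.Generator) -> FlankPair:
    return FlankPair(random_dna(length, rng), random_dna(length, rng))


@dataclass(frozen=True)
class ArraySpec:
    """Blueprint for one tandem-array molecule.

    ``cassette`` is (sequence, boundary_index): the cassette is inserted at the
    boundary between unit ``boundary_index - 1`` and unit ``boundary_index``
    (0 = before the first unit, copy_number = after the last).
    ``deletions`` are (unit_index, start_offset, end_offset) partial-unit
    removals in unit-local coordinates.
    """

    unit: RepeatUnit
    copy_number: int
    flanks: FlankPair
    cassette: Optional[tuple[str, int]] = None
    deletions: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.cassette is not None:
            seq, boundary = self.cassette
            if not seq:
                raise ValueError("cassette sequence must be nonempty")
            if not 0 <= boundary <= self.copy_number:
                raise ValueError(
                    f"cassette boundary {boundary} outside [0, {self.copy_number}]"
                )
        m = self.unit.length_m
        object.__setattr__(self, "deletions", tuple(self.deletions or ()))
        for unit_index, start, end in self.deletions:
            if unit_index >= self.copy_number:
                raise ValueError(
                    f"deletion references unit {unit_index} >= copy_number {self.copy_number}"
                )
            if not (0 <= start < end <= m):
                raise ValueError(f"deletion offsets ({start}, {end}) outside [0, {m}]")


@dataclass(frozen=True)
class ErrorModel:
    """Uniform per-base error process; rates are probabilities per template base."""

    sub_rate: float = DEFAULT_SUB_RATE
    ins_rate: float = DEFAULT_INS_RATE
    del_rate: float = DEFAULT_DEL_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must be in [0, 1]")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("sub_rate + ins_rate + del_rate must be < 1")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass
class ArrayTruth:
    """Ground-truth sidecar for one molecule or one read derived from it."""

    molecule_id: str
    copy_number: int
    cassette_boundary: Optional[int] = None
    deletion_count: int = 0
    strand: str = "+"
    is_spanning: bool = True


def build_array_molecule(spec: ArraySpec, molecule_id: str = "mol") -> tuple[str, ArrayTruth]:
    """Assemble upstream + k units (cassette, deletions applied) + downstream."""
    units = [spec.unit.sequence] * spec.copy_number
    for unit_index, start, end in spec.deletions:
        seq = units[unit_index]
        units[unit_index] = seq[:start] + seq[end:]
    if spec.cassette is not None:
        cassette_seq, boundary = spec.cassette
        body = "".join(units[:boundary]) + cassette_seq + "".join(units[boundary:])
        cassette_boundary: Optional[int] = boundary
    else:
        body = "".join(units)
        cassette_boundary = None
    sequence = spec.flanks.upstream + body + spec.flanks.downstream
    truth = ArrayTruth(
        molecule_id=molecule_id,
        copy_number=spec.copy_number,
        cassette_boundary=cassette_boundary,
        deletion_count=len(spec.deletions),
    )
    return sequence, truth


def apply_errors(sequence: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply per-base substitution/insertion/deletion errors.

    An insertion adds one uniform random base after the template base, so the
    expected output length is (1 + ins_rate - del_rate) x input length.
    """
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n = codes.size
    if n == 0 or model.total == 0.0:
        return sequence
    u = rng.random(n)
    is_sub = u < model.sub_rate
    is_ins = (u >= model.sub_rate) & (u < model.sub_rate + model.ins_rate)
    is_del = (u >= model.sub_rate + model.ins_rate) & (u < model.total)

    # substitution: shift to one of the three other bases (non-ACGT left as-is)
    base_idx = np.full(n, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        base_idx[codes == b] = i
    subbable = is_sub & (base_idx >= 0)
    shifts = rng.integers(1, 4, size=int(subbable.sum()))
    new_idx = (base_idx[subbable] + shifts) % 4
    codes[subbable] = _BASES[new_idx]

    counts = np.ones(n, dtype=np.int64)
    counts[is_del] = 0
    counts[is_ins] = 2
    out = np.repeat(codes, counts)
    # the inserted copy is the second of the pair; overwrite with a random base
    ends = np.cumsum(counts)
    ins_positions = ends[is_ins] - 1
    out[ins_positions] = _BASES[rng.integers(0, 4, size=ins_positions.size)]
    return out.tobytes().decode("ascii")


def simulate_read(
    molecule: str,
    truth: ArrayTruth,
    model: ErrorModel,
    window: Optional[tuple[int, int]] = None,
    rng: Optional[np.random.Generator] = None,
    strand: Optional[str] = None,
    read_id: Optional[str] = None,
) -> tuple[ReadRecord, ArrayTruth]:
    """Emit one read from a window of the molecule.

    The strand is drawn uniformly unless forced; "-" reads are
    reverse-complemented after the error process. ``is_spanning`` is true iff
    the window covers both full flanks, i.e. the whole molecule.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if window is None:
        window = (0, len(molecule))
    start, end = window
    if not (0 <= start < end <= len(molecule)):
        raise ValueError(f"window {window} outside molecule bounds [0, {len(molecule)}]")
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = apply_errors(molecule[start:end], model, rng)
    if strand == "-":
        seq = reverse_complement(seq)
    rid = read_id if read_id is not None else f"{truth.molecule_id}/{start}-{end}{strand}"
    phred = 40 if model.total == 0 else max(2, round(-10.0 * math.log10(model.total)))
    read = ReadRecord(rid, seq, [phred] * len(seq), source="simulated")
    read_truth = replace(
        truth,
        molecule_id=rid,
        strand=strand,
        is_spanning=(start == 0 and end == len(molecule)),
    )
    return read, read_truth


@dataclass(frozen=True)
class ReadLengthModel:
    """Log-normal read-length distribution, the usual shape of nanopore runs.

    Defaults give a median of ~12 kb with a long right tail. ``full=True``
    forces every window to be the whole molecule (all reads spanning).
    """

    mean_log: float = math.log(12_000.0)
    sigma_log: float = 0.8
    min_length: int = 500
    full: bool = False

    def sample(self, rng: np.random.Generator) -> int:
        if self.full:
            return np.iinfo(np.int64).max
        return max(self.min_length, int(round(rng.lognormal(self.mean_log, self.sigma_log))))


def simulate_population(
    specs: Sequence[tuple[ArraySpec, float]],
    n_reads: int,
    length_distribution: Optional[ReadLengthModel] = None,
    model: ErrorModel = ErrorModel(),
    out_prefix=None,
) -> tuple[list[ReadRecord], list[ArrayTruth]]:
    """Sample reads from a weighted mixture of array molecules.

    Windows are placed uniformly; a sampled length at least the molecule
    length yields a full (spanning) window. Deterministic under a fixed
    ``model.seed``. Writes ``<out_prefix>.fastq`` and ``<out_prefix>.truth.tsv``
    when ``out_prefix`` is given.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    weights = np.asarray([w for _, w in specs], dtype=float)
    if len(weights) == 0 or (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    if length_distribution is None:
        length_distribution = ReadLengthModel()
    rng = np.random.default_rng(model.seed)
    molecules = [
        build_array_molecule(spec, molecule_id=f"spec{i}")
        for i, (spec, _) in enumerate(specs)
    ]
    probs = weights / weights.sum()
    reads: list[ReadRecord] = []
    truths: list[ArrayTruth] = []
    choices = rng.choice(len(molecules), size=n_reads, p=probs)
    for i, which in enumerate(choices):
        molecule, mol_truth = molecules[which]
        rl = length_distribution.sample(rng)
        if rl >= len(molecule):
            window = (0, len(molecule))
        else:
            start = int(rng.integers(0, len(molecule) - rl + 1))
            window = (start, start + rl)
        read, truth = simulate_read(
            molecule, mol_truth, model, window=window, rng=rng, read_id=f"read{i:05d}"
        )
        reads.append(read)
        truths.append(truth)
    if out_prefix is not None:
        write_sequences(reads, f"{out_prefix}.fastq", format="fastq")
        write_table(
            [
                {
                    "read_id": t.molecule_id,
                    "copy_number": t.copy_number,
                    "cassette_boundary": "" if t.cassette_boundary is None else t.cassette_boundary,
                    "deletion_count": t.deletion_count,
                    "strand": t.strand,
                    "is_spanning": int(t.is_spanning),
                }
                for t in truths
            ],
            f"{out_prefix}.truth.tsv",
        )
    return reads, truths
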