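"""Barcoded sequencing of sorting cycles and read-processing.

Each sorting cycle's pool is tagged with a short (6-8 nt) DNA barcode and
sequenced as single-end reads of the form

    barcode + upstream_constant + variable_region + downstream_constant

truncated to the read length.  Processing mirrors a minimal, deterministic
amplicon pipeline: exact-prefix demultiplexing by cycle barcode, read
filtering (per-base quality floor, exact constant regions, variable-region
length within the design), variant counting, and per-cycle percentage
abundances.

The variable region is located by fixed offsets from the matched constant
flanks (no alignment): a read must start with the upstream constant and its
remainder must resume the downstream constant after one of the allowed
window lengths.  Indels therefore surface as constant-region mismatches,
which is the intended "errors in unintended positions" discard.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .library_design import (
    DNA_BASES,
    LibraryDesign,
    design_space_size,
    normalize_pool,
    variant_ids,
)

PHRED_OFFSET = 33
MAX_QUALITY = 40
DEFAULT_READ_LENGTH = 150
DEFAULT_MIN_QUALITY = 20

DISCARD_LOW_QUALITY = "low_quality"
DISCARD_CONSTANT_MISMATCH = "constant_mismatch"
DISCARD_LENGTH = "length"
DISCARD_REASONS = (DISCARD_LOW_QUALITY, DISCARD_CONSTANT_MISMATCH, DISCARD_LENGTH)


class ReadRecord(NamedTuple):
    """A single sequencing read (Sanger Phred+33 qualities)."""

    id: str
    sequence: str
    qualities: str

    @property
    def phred_scores(self) -> list[int]:
        return [ord(c) - PHRED_OFFSET for c in self.qualities]


class CycleBarcodeMap(dict):
    """Mapping of cycle label -> barcode (6-8 nt DNA).

    Barcodes must be unique; a pairwise Hamming distance below 2 between
    equal-length barcodes only triggers a warning, since matching is an
    exact-prefix policy either way.
    """

    def __init__(self, mapping: Mapping[str, str]):
        super().__init__({str(k): str(v).upper() for k, v in mapping.items()})
        self._validate()

    def _validate(self) -> None:
        seen: dict[str, str] = {}
        for cycle, barcode in self.items():
            if not 6 <= len(barcode) <= 8:
                raise ValueError(f"barcode for cycle {cycle!r} must be 6-8 nt")
            if any(b not in DNA_BASES for b in barcode):
                raise ValueError(f"barcode for cycle {cycle!r} is not ACGT DNA")
            if barcode in seen:
                raise ValueError(
                    f"barcode {barcode} assigned to both {seen[barcode]!r} and {cycle!r}"
                )
            seen[barcode] = cycle
        barcodes = list(self.values())
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1 :]:
                if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) < 2:
                    warnings.warn(
                        f"barcodes {a} and {b} are within Hamming distance 1; "
                        "a single sequencing error can cross-assign cycles",
                        stacklevel=2,
                    )

    @classmethod
    def from_tsv(cls, path) -> "CycleBarcodeMap":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(frame.iloc[:, 0], frame.iloc[:, 1])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"cycle": list(self.keys()), "barcode": list(self.values())}
        ).to_csv(path, sep="\t", index=False)


def default_barcode_map(n_cycles: int) -> CycleBarcodeMap:
    """Barcodes for cycles "0".."C-1" (mutual Hamming distance >= 2)."""
    stock = ["ACGTAC", "CTACGA", "GACTTG", "TGAGCT", "AGTCCA", "CAGATG", "GTCAGA", "TCGTAT"]
    if n_cycles > len(stock):
        raise ValueError(f"only {len(stock)} stock barcodes available")
    return CycleBarcodeMap({str(i): stock[i] for i in range(n_cycles)})


def _error_quality_char(per_base_error: float) -> str:
    if per_base_error <= 0:
        return chr(PHRED_OFFSET + MAX_QUALITY)
    q = int(round(-10.0 * math.log10(per_base_error)))
    return chr(PHRED_OFFSET + max(2, min(MAX_QUALITY, q)))


def simulate_reads(
    pools: Mapping[str, Mapping[str, float]],
    design: LibraryDesign,
    barcode_map: Mapping[str, str],
    depth: int,
    per_base_error: float = 0.0,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int | np.random.Generator | None = None,
) -> list[ReadRecord]:
    """Simulate ``depth`` reads per cycle from per-cycle pools.

    Variants are drawn multinomially in proportion to pool abundance;
    substitution errors are i.i.d. at ``per_base_error`` per base and the
    (uniform) base qualities are consistent with that rate.  Deterministic
    given the seed.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0.0 <= per_base_error < 1.0:
        raise ValueError("per_base_error must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    qchar = _error_quality_char(per_base_error)
    for cycle, pool in pools.items():
        if cycle not in barcode_map:
            raise KeyError(f"cycle {cycle!r} has no barcode")
        barcode = barcode_map[cycle]
        abund = normalize_pool(pool)
        ids = list(abund.keys())
        probs = np.asarray(list(abund.values()))
        if depth == 0:
            continue
        counts = rng.multinomial(depth, probs)
        templates = [
            (barcode + design.full_sequence(vid))[:read_length] for vid in ids
        ]
        serial = 0
        for template, count in zip(templates, counts):
            if count == 0:
                continue
            qualities = qchar * len(template)
            if per_base_error > 0:
                n_errors = rng.binomial(len(template), per_base_error, size=count)
            else:
                n_errors = np.zeros(count, dtype=int)
            for k in range(count):
                seq = template
                if n_errors[k] > 0:
                    positions = rng.choice(len(template), size=n_errors[k], replace=False)
                    chars = list(seq)
                    for pos in positions:
                        alternatives = DNA_BASES.replace(chars[pos], "")
                        chars[pos] = alternatives[rng.integers(3)]
                    seq = "".join(chars)
                reads.append(ReadRecord(f"{cycle}:{serial}", seq, qualities))
                serial += 1
    return reads


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    """Write reads as Sanger FASTQ (Phred+33)."""
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{read.qualities}\n")


def read_fastq(path) -> list[ReadRecord]:
    """Read a Sanger FASTQ file into ReadRecords (via Biopython)."""
    from Bio import SeqIO

    reads = []
    for record in SeqIO.parse(str(path), "fastq"):
        qualities = "".join(
            chr(PHRED_OFFSET + q) for q in record.letter_annotations["phred_quality"]
        )
        reads.append(ReadRecord(record.id, str(record.seq), qualities))
    return reads


@dataclass
class DemuxResult:
    """Per-cycle reads (barcode stripped) plus the unassigned tally."""

    by_cycle: dict[str, list[ReadRecord]]
    unassigned: int

    @property
    def assigned(self) -> int:
        return sum(len(reads) for reads in self.by_cycle.values())


def demultiplex(
    reads: Iterable[ReadRecord], barcode_map: Mapping[str, str]
) -> DemuxResult:
    """Assign reads to cycles by exact barcode-prefix match.

    Longest barcode wins if one barcode is a prefix of another; reads
    matching no barcode are tallied as unassigned (not an error).  The
    barcode is stripped from assigned reads.
    """
    lookup = {barcode: cycle for cycle, barcode in barcode_map.items()}
    lengths = sorted({len(b) for b in lookup}, reverse=True)
    by_cycle: dict[str, list[ReadRecord]] = {cycle: [] for cycle in barcode_map}
    unassigned = 0
    for read in reads:
        for length in lengths:
            cycle = lookup.get(read.sequence[:length])
            if cycle is not None:
                by_cycle[cycle].append(
                    ReadRecord(read.id, read.sequence[length:], read.qualities[length:])
                )
                break
        else:
            unassigned += 1
    return DemuxResult(by_cycle=by_cycle, unassigned=unassigned)


def locate_variable_region(sequence: str, design: LibraryDesign) -> tuple[str | None, str | None]:
    """Extract the variable region, or classify why the read fails.

    Returns ``(region, None)`` on success and ``(None, reason)`` on
    failure, where reason is ``constant_mismatch`` (flanks do not match
    the design exactly) or ``length`` (flanks match but the window
    length is not an allowed degenerate length).  The shortest window
    that resumes the downstream constant wins; with non-repetitive
    flanks the match is unique.
    """
    upstream = design.upstream_constant
    downstream = design.downstream_constant
    if not sequence.startswith(upstream):
        return None, DISCARD_CONSTANT_MISMATCH
    rest = sequence[len(upstream) :]
    scan_limit = min(len(rest), max(design.degenerate_lengths) + 6)
    for window in range(scan_limit + 1):
        tail = rest[window:]
        if tail == downstream[: len(tail)]:
            if window in design.degenerate_lengths:
                return rest[:window], None
            return None, DISCARD_LENGTH
    return None, DISCARD_CONSTANT_MISMATCH


@dataclass
class FilterResult:
    """Reads passing all filters plus per-reason discard counts."""

    passed: list[ReadRecord]
    discards: dict[str, int] = field(
        default_factory=lambda: {reason: 0 for reason in DISCARD_REASONS}
    )

    @property
    def n_discarded(self) -> int:
        return sum(self.discards.values())


def filter_reads(
    reads: Iterable[ReadRecord],
    design: LibraryDesign,
    min_q: int = DEFAULT_MIN_QUALITY,
) -> FilterResult:
    """Discard reads with low-quality bases or errors in unintended positions.

    A read is discarded if (a) any base quality is below ``min_q``,
    (b) the constant regions do not match the design exactly, or (c) the
    variable-region length is not an allowed degenerate length.  Reasons
    are tallied in that order of precedence.
    """
    result = FilterResult(passed=[])
    floor = chr(PHRED_OFFSET + min_q)
    for read in reads:
        if read.qualities and min(read.qualities) < floor:
            result.discards[DISCARD_LOW_QUALITY] += 1
            continue
        region, reason = locate_variable_region(read.sequence, design)
        if reason is not None:
            result.discards[reason] += 1
            continue
        result.passed.append(read)
    return result


@dataclass
class CountTable:
    """Variant x cycle read counts with per-cycle discard bookkeeping."""

    counts: pd.DataFrame
    discards: pd.DataFrame
    unassigned: int = 0

    @property
    def cycle_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        empty = pd.DataFrame(
            0, index=pd.Index(DISCARD_REASONS, name="reason"), columns=counts.columns
        )
        return cls(counts=counts, discards=empty)


def count_variants(
    passed_by_cycle: Mapping[str, Sequence[ReadRecord]],
    design: LibraryDesign,
    dense: bool | None = None,
    discards_by_cycle: Mapping[str, Mapping[str, int]] | None = None,
    unassigned: int = 0,
) -> CountTable:
    """Count reads per variant per cycle from filtered reads.

    With ``dense=True`` (the default for design spaces up to 10^5
    variants) every design-space variant is pre-registered as a row, so
    undetected variants appear with count 0; otherwise only observed
    variants become rows.
    """
    if dense is None:
        dense = design_space_size(design) <= 10**5
    cycles = list(passed_by_cycle.keys())
    counters: dict[str, Counter] = {}
    for cycle, reads in passed_by_cycle.items():
        counter: Counter = Counter()
        for read in reads:
            region, reason = locate_variable_region(read.sequence, design)
            if reason is None:
                counter[region] += 1
        counters[cycle] = counter
    if dense:
        index = variant_ids(design)
    else:
        observed = set().union(*(c.keys() for c in counters.values())) if counters else set()
        index = sorted(observed, key=lambda s: (len(s), s))
    counts = pd.DataFrame(
        {cycle: [counters[cycle].get(v, 0) for v in index] for cycle in cycles},
        index=pd.Index(index, name="variant_id"),
        dtype=int,
    )
    if discards_by_cycle is None:
        discards = pd.DataFrame(
            0, index=pd.Index(DISCARD_REASONS, name="reason"), columns=cycles
        )
    else:
        discards = pd.DataFrame(
            {
                cycle: [discards_by_cycle.get(cycle, {}).get(r, 0) for r in DISCARD_REASONS]
                for cycle in cycles
            },
            index=pd.Index(DISCARD_REASONS, name="reason"),
        )
    return CountTable(counts=counts, discards=discards, unassigned=unassigned)


def abundance_matrix(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Percentage abundance per cycle: ``100 * count / cycle total``."""
    frame = counts.counts if isinstance(counts, CountTable) else counts
    totals = frame.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"cycle {zero.index[0]!r} has zero total reads")
    return 100.0 * frame / totals


def process_reads(
    reads: Iterable[ReadRecord],
    design: LibraryDesign,
    barcode_map: Mapping[str, str],
    min_q: int = DEFAULT_MIN_QUALITY,
    dense: bool | None = None,
) -> CountTable:
    """Demultiplex, filter and count in one pass (convenience pipeline)."""
    demux = demultiplex(reads, barcode_map)
    passed: dict[str, list[ReadRecord]] = {}
    discards: dict[str, dict[str, int]] = {}
    for cycle, cycle_reads in demux.by_cycle.items():
        filtered = filter_reads(cycle_reads, design, min_q=min_q)
        passed[cycle] = filtered.passed
        discards[cycle] = filtered.discards
    return count_variants(
        passed, design, dense=dense, discards_by_cycle=discards, unassigned=demux.unassigned
    )
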