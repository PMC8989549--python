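"""Degenerate riboswitch library designs.

A screening library keeps fixed flanking sequences (promoter/tag upstream;
aptamer, ribosome binding site and reporter downstream) and fully randomizes
a short window between them.  Allowing several window lengths ``L`` gives a
design space of ``sum_L 4**L`` sequences — for example lengths {4,5,6} yield
5376 distinct variants and lengths {3,4,5,6} yield 5440.

Sequences are stored as DNA (T, not U); RNA is a display concern.  A variant
is identified by its variable-region sequence, which is unique across length
classes because the string length itself differs.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

DNA_BASES = "ACGT"

#: Refuse to materialize design spaces larger than this (desk-scale guard).
ENUMERATION_CAP = 10**7

# Minimal IUPAC degeneracy code for every non-empty subset of {A,C,G,T}.
IUPAC_FOR_SET: dict[frozenset[str], str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}
IUPAC_SETS: dict[str, frozenset[str]] = {c: s for s, c in IUPAC_FOR_SET.items()}


class InvalidDesignError(ValueError):
    """Raised when a library design violates its invariants."""


class EnumerationCapError(RuntimeError):
    """Raised when a design space is too large to materialize."""


@dataclass(frozen=True)
class LibraryDesign:
    """A degenerate library: constant flanks plus randomized-window lengths.

    Parameters
    ----------
    name
        Human-readable label.
    upstream_constant
        DNA immediately 5' of the randomized window (tag + promoter).
    degenerate_lengths
        Allowed lengths of the fully randomized window, e.g. ``{4, 5, 6}``.
    downstream_constant
        DNA immediately 3' of the window (aptamer + RBS + reporter context).
    """

    name: str
    upstream_constant: str
    degenerate_lengths: frozenset[int]
    downstream_constant: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "degenerate_lengths", frozenset(self.degenerate_lengths)
        )
        if not self.degenerate_lengths:
            raise InvalidDesignError("degenerate_lengths must be non-empty")
        for length in self.degenerate_lengths:
            if not isinstance(length, (int, np.integer)) or length < 0:
                raise InvalidDesignError(
                    f"degenerate length must be an integer >= 0, got {length!r}"
                )
        for label, seq in (
            ("upstream_constant", self.upstream_constant),
            ("downstream_constant", self.downstream_constant),
        ):
            if any(base not in DNA_BASES for base in seq):
                raise InvalidDesignError(f"{label} contains non-ACGT characters")

    def full_sequence(self, variable_region: str) -> str:
        """Concatenate the flanks around a variable region."""
        return self.upstream_constant + variable_region + self.downstream_constant


@dataclass(frozen=True)
class Variant:
    """One member of a design space, keyed by its variable-region sequence."""

    variant_id: str
    full_sequence: str


def design_space_size(design: LibraryDesign) -> int:
    """Number of distinct variants: ``sum_L 4**L`` over the allowed lengths."""
    return sum(4**length for length in design.degenerate_lengths)


def enumerate_design_space(
    design: LibraryDesign, cap: int = ENUMERATION_CAP
) -> Iterator[Variant]:
    """Yield every variant exactly once.

    Lengths ascend; within each length the variable regions are in
    lexicographic (A < C < G < T) order.
    """
    size = design_space_size(design)
    if size > cap:
        raise EnumerationCapError(
            f"design space has {size} variants, above the enumeration cap {cap}"
        )
    for length in sorted(design.degenerate_lengths):
        for bases in itertools.product(DNA_BASES, repeat=length):
            region = "".join(bases)
            yield Variant(region, design.full_sequence(region))


def variant_ids(design: LibraryDesign, cap: int = ENUMERATION_CAP) -> list[str]:
    """All variant ids in enumeration order."""
    return [v.variant_id for v in enumerate_design_space(design, cap=cap)]


def sample_library(
    design: LibraryDesign,
    n_templates: int,
    skew: float = 0.0,
    seed: int | np.random.Generator | None = None,
    cap: int = ENUMERATION_CAP,
) -> dict[str, int]:
    """Draw an initial template pool (variant -> template count).

    Counts are a multinomial draw of ``n_templates`` over the design space.
    ``skew`` models synthesis bias: per-variant weights are i.i.d.
    Gamma(shape=1/skew, mean 1); ``skew = 0`` gives an exactly uniform pool.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    if skew < 0:
        raise ValueError("skew must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = variant_ids(design, cap=cap)
    if skew == 0:
        weights = np.ones(len(ids))
    else:
        shape = 1.0 / skew
        weights = rng.gamma(shape, scale=1.0 / shape, size=len(ids))
    probs = weights / weights.sum()
    counts = rng.multinomial(n_templates, probs)
    return {vid: int(c) for vid, c in zip(ids, counts) if c > 0}


def normalize_pool(pool: Mapping[str, float]) -> dict[str, float]:
    """Rescale counts or weights to relative abundances summing to 1."""
    total = float(sum(pool.values()))
    if total <= 0:
        raise ValueError("pool has no mass")
    return {vid: float(c) / total for vid, c in pool.items() if c > 0}


def _base_set(char: str) -> frozenset[str]:
    char = char.upper().replace("U", "T")
    try:
        return IUPAC_SETS[char]
    except KeyError:
        raise ValueError(f"invalid nucleotide code {char!r}") from None


def consensus_sequence(variable_regions: Sequence[str]) -> str:
    """Minimal IUPAC consensus over equal-length sequences.

    Each position gets the smallest degeneracy code covering every base
    observed there; IUPAC codes in the input are expanded before the union.
    For example {"GCGT", "GTGT"} -> "GYGT" (rendered GYGU as RNA).
    """
    if not variable_regions:
        raise ValueError("need at least one sequence")
    length = len(variable_regions[0])
    if any(len(s) != length for s in variable_regions):
        raise ValueError("sequences must have equal lengths")
    out = []
    for position in range(length):
        observed: frozenset[str] = frozenset()
        for seq in variable_regions:
            observed |= _base_set(seq[position])
        out.append(IUPAC_FOR_SET[observed])
    return "".join(out)


def write_variants_fasta(variants: Iterable[Variant], path) -> None:
    """Write variants as FASTA with the variant id as the header."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(v.full_sequence), id=v.variant_id, description="")
        for v in variants
    ]
    seqio_write(records, str(path), "fasta")


def write_pool_tsv(pool: Mapping[str, float], path) -> None:
    """Write a pool as a two-column TSV (variant_id, count-or-abundance)."""
    import pandas as pd

    frame = pd.DataFrame(
        {"variant_id": list(pool.keys()), "count": list(pool.values())}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_pool_tsv(path) -> dict[str, float]:
    """Read a pool written by :func:`write_pool_tsv`."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["variant_id"].astype(str), frame["count"].astype(float)))


# --- Preset designs -------------------------------------------------------
#
# The flank sequences below are synthetic, representative stand-ins for a
# tag + T7 promoter upstream and an aptamer + RBS + split-GFP reporter
# context downstream; they carry the structural roles (fixed anchors for
# read parsing, realistic read lengths) rather than any published sequence.

UPSTREAM_TAG_T7 = "GCGGCCTAATACGACTCACTATAGGGAGA"
DOWNSTREAM_REPORTER = (
    "CTGGCAACGAATGGATCCGTTCGGACTGAAGTCGCT"  # aptamer stand-in
    "AAGGAGGTTAACATATG"  # RBS + start codon
    "CGTGACCACATGGTCCTTCATGAGTATGTAAATGCTGCTGGGATTACACAT"  # reporter ORF
    "CACCAGTCAGGTGGTCTGGT"  # 3' tag (beacon binding site)
)

#: Histamine ON-switch library: 4-6 randomized nt upstream of the aptamer
#: (5376 variants).
HISTAMINE_ON_DESIGN = LibraryDesign(
    name="HA-ON-N4_6",
    upstream_constant=UPSTREAM_TAG_T7,
    degenerate_lengths=frozenset({4, 5, 6}),
    downstream_constant=DOWNSTREAM_REPORTER,
)

#: Histamine OFF-switch library: 3-6 randomized nt (5440 variants).
HISTAMINE_OFF_DESIGN = LibraryDesign(
    name="HA-OFF-N3_6",
    upstream_constant=UPSTREAM_TAG_T7,
    degenerate_lengths=frozenset({3, 4, 5, 6}),
    downstream_constant=DOWNSTREAM_REPORTER,
)

#: Ciprofloxacin library: exactly 6 randomized nt (4096 variants).
CIPROFLOXACIN_DESIGN = LibraryDesign(
    name="CFX-N6",
    upstream_constant=UPSTREAM_TAG_T7,
    degenerate_lengths=frozenset({6}),
    downstream_constant=DOWNSTREAM_REPORTER,
)
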