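"""Read simulation, demultiplexing, filtering and counting."""

import numpy as np
import pytest

from ribodrop.seq_pipeline import (
    CycleBarcodeMap,
    ReadRecord,
    abundance_matrix,
    count_variants,
    default_barcode_map,
    demultiplex,
    filter_reads,
    locate_variable_region,
    process_reads,
    read_fastq,
    simulate_reads,
    write_fastq,
)


@pytest.fixture()
def barcodes():
    return default_barcode_map(2)


def uniform_pool(design):
    from ribodrop.library_design import variant_ids

    return {v: 1.0 for v in variant_ids(design)}


# ----------------------------------------------------------------- barcodes


def test_barcode_map_validation():
    with pytest.raises(ValueError):
        CycleBarcodeMap({"0": "ACG"})  # too short
    with pytest.raises(ValueError):
        CycleBarcodeMap({"0": "ACGTAN"})  # not DNA
    with pytest.raises(ValueError):
        CycleBarcodeMap({"0": "ACGTAC", "1": "ACGTAC"})  # duplicate
    with pytest.warns(UserWarning):
        CycleBarcodeMap({"0": "ACGTAC", "1": "ACGTAG"})  # Hamming 1


# ------------------------------------------------------------- simulation


def test_simulate_reads_depth_zero(tiny_design, barcodes):
    reads = simulate_reads({"0": uniform_pool(tiny_design)}, tiny_design, barcodes, 0)
    assert reads == []


def test_simulate_reads_missing_barcode(tiny_design):
    with pytest.raises(KeyError):
        simulate_reads(
            {"9": uniform_pool(tiny_design)}, tiny_design, default_barcode_map(1), 10
        )


def test_simulate_reads_deterministic(tiny_design, barcodes):
    pools = {"0": uniform_pool(tiny_design)}
    a = simulate_reads(pools, tiny_design, barcodes, 500, 0.01, seed=5)
    b = simulate_reads(pools, tiny_design, barcodes, 500, 0.01, seed=5)
    assert a == b


def test_simulate_reads_multinomial_proportions(tiny_design, barcodes):
    pool = {"AA": 0.9, "CC": 0.1}
    depth = 10_000
    reads = simulate_reads({"0": pool}, tiny_design, barcodes, depth, 0.0, seed=1)
    table = process_reads(reads, tiny_design, barcodes, dense=False)
    n_aa = table.counts.loc["AA", "0"]
    sigma = np.sqrt(depth * 0.9 * 0.1)
    assert abs(n_aa - 0.9 * depth) < 4 * sigma


# ------------------------------------------------------------------- demux


def test_demultiplex_partition(tiny_design, barcodes):
    pools = {c: uniform_pool(tiny_design) for c in barcodes}
    reads = simulate_reads(pools, tiny_design, barcodes, 300, 0.0, seed=2)
    stray = ReadRecord("x", "T" * 40, "I" * 40)
    result = demultiplex(reads + [stray], barcodes)
    assert result.unassigned == 1
    assert result.assigned + result.unassigned == len(reads) + 1


def test_demultiplex_is_exact_match(tiny_design, barcodes):
    barcode = barcodes["0"]
    mutated = "T" + barcode[1:] if barcode[0] != "T" else "A" + barcode[1:]
    read = ReadRecord("r", mutated + tiny_design.full_sequence("AA"), "I" * 40)
    result = demultiplex([read], barcodes)
    assert result.unassigned == 1 and result.assigned == 0


# ------------------------------------------------------------------ filter


def test_filter_passes_error_free_reads(tiny_design, barcodes):
    reads = simulate_reads(
        {"0": uniform_pool(tiny_design)}, tiny_design, barcodes, 500, 0.0, seed=3
    )
    demux = demultiplex(reads, barcodes)
    result = filter_reads(demux.by_cycle["0"], tiny_design)
    assert len(result.passed) == 500
    assert result.n_discarded == 0


def test_filter_discard_reasons(tiny_design):
    good = tiny_design.full_sequence("AC")
    ok = ReadRecord("ok", good, "I" * len(good))
    # substitution inside the upstream constant
    bad_const = "T" + good[1:] if good[0] != "T" else "A" + good[1:]
    const = ReadRecord("c", bad_const, "I" * len(good))
    # variable region of disallowed length 3
    bad_len_seq = tiny_design.full_sequence("ACG")
    length = ReadRecord("l", bad_len_seq, "I" * len(bad_len_seq))
    # one low-quality base
    lowq = ReadRecord("q", good, "I" * (len(good) - 1) + "#")
    result = filter_reads([ok, const, length, lowq], tiny_design, min_q=20)
    assert [r.id for r in result.passed] == ["ok"]
    assert result.discards == {
        "low_quality": 1,
        "constant_mismatch": 1,
        "length": 1,
    }


def test_filter_monotone_in_quality_threshold(tiny_design, rng):
    reads = []
    for i in range(200):
        seq = tiny_design.full_sequence("GT")
        quals = "".join(chr(33 + rng.integers(15, 41)) for _ in seq)
        reads.append(ReadRecord(str(i), seq, quals))
    passed = [
        len(filter_reads(reads, tiny_design, min_q=q).passed) for q in (0, 15, 25, 41)
    ]
    assert passed == sorted(passed, reverse=True)


def test_locate_variable_region(tiny_design):
    region, reason = locate_variable_region(tiny_design.full_sequence("GT"), tiny_design)
    assert (region, reason) == ("GT", None)
    region, reason = locate_variable_region(tiny_design.full_sequence("GTA"), tiny_design)
    assert region is None and reason == "length"


# ---------------------------------------------------------------- counting


def test_count_variants_dense_rows(tiny_design, barcodes):
    reads = [
        ReadRecord(str(i), tiny_design.full_sequence("AC"), "I" * 22) for i in range(10)
    ]
    table = count_variants({"0": reads}, tiny_design, dense=True)
    assert table.counts.loc["AC", "0"] == 10
    assert len(table.counts) == 20  # 4 + 16 variants pre-registered
    assert table.cycle_totals["0"] == 10


def test_abundance_matrix_percentages(tiny_design):
    reads_a = [ReadRecord(str(i), tiny_design.full_sequence("A"), "I" * 21) for i in range(75)]
    reads_b = [ReadRecord(str(i), tiny_design.full_sequence("C"), "I" * 21) for i in range(25)]
    table = count_variants({"0": reads_a + reads_b}, tiny_design, dense=False)
    ab = abundance_matrix(table)
    assert ab.loc["A", "0"] == pytest.approx(75.0)
    assert ab.loc["C", "0"] == pytest.approx(25.0)
    assert ab["0"].sum() == pytest.approx(100.0, abs=1e-6)


def test_abundance_matrix_zero_cycle_error(tiny_design):
    table = count_variants({"empty_cycle": []}, tiny_design, dense=True)
    with pytest.raises(ValueError, match="empty_cycle"):
        abundance_matrix(table)


def test_pipeline_recovers_pool_composition(tiny_design, barcodes):
    """End-to-end: error-free simulate -> demux -> filter -> count gives
    proportions equal to the pool within multinomial error (4 sigma)."""
    rng = np.random.default_rng(8)
    weights = rng.random(20)
    from ribodrop.library_design import variant_ids

    ids = variant_ids(tiny_design)
    pool = dict(zip(ids, weights / weights.sum()))
    depth = 100_000
    reads = simulate_reads({"0": pool}, tiny_design, barcodes, depth, 0.0, seed=4)
    table = process_reads(reads, tiny_design, barcodes)
    assert table.cycle_totals["0"] == depth
    for vid, p in pool.items():
        sigma = np.sqrt(depth * p * (1 - p))
        assert abs(table.counts.loc[vid, "0"] - depth * p) <= 4 * sigma + 1


# --------------------------------------------------------------------- io


def test_fastq_roundtrip(tiny_design, barcodes, tmp_path):
    reads = simulate_reads(
        {"0": uniform_pool(tiny_design)}, tiny_design, barcodes, 50, 0.02, seed=6
    )
    path = tmp_path / "reads.fastq"
    write_fastq(reads, path)
    back = read_fastq(path)
    assert back == reads
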