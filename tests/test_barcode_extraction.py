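"""Extraction/assignment unit tests against independent brute-force oracles."""

import gzip

import pytest

from promoscreen import (
    AMBIGUOUS,
    UNASSIGNED,
    AmpliconConfig,
    count_sample,
    extract_barcode,
    match_barcode,
)
from conftest import SMALL_BARCODES


# ---------------------------------------------------------------------------
# Independent oracles (pure-python, no shared code with the implementation)

def _oracle_extract(read, anchor5, anchor3, bc_len, max_mm):
    """Scan every offset for the best (fewest-mismatch, leftmost) anchor."""
    read = read.upper()
    best_off, best_mm = None, max_mm + 1
    for off in range(len(read) - len(anchor5) + 1):
        mm = sum(a != b for a, b in zip(read[off : off + len(anchor5)], anchor5))
        if mm < best_mm:
            best_off, best_mm = off, mm
    if best_off is None or best_mm > max_mm:
        return None
    start = best_off + len(anchor5)
    if start + bc_len > len(read):
        return None
    if anchor3:
        seg = read[start + bc_len : start + bc_len + len(anchor3)]
        if len(seg) < len(anchor3):
            return None
        if sum(a != b for a, b in zip(seg, anchor3)) > max_mm:
            return None
    return read[start : start + bc_len]


def _oracle_match(observed, barcode_of, max_mm):
    """Exhaustive Hamming scan over the whole map."""
    dists = {
        pid: sum(a != b for a, b in zip(observed, bc))
        for pid, bc in barcode_of.items()
    }
    dmin = min(dists.values())
    if dmin > max_mm:
        return UNASSIGNED
    winners = [pid for pid, d in dists.items() if d == dmin]
    return winners[0] if len(winners) == 1 else AMBIGUOUS


def _oracle_exact_substring(read, anchor5, anchor3, bc_len, barcode_of):
    """Naive zero-mismatch pipeline: find() + dict lookup."""
    read = read.upper()
    off = read.find(anchor5)
    if off == -1:
        return ("no_anchor", None)
    start = off + len(anchor5)
    if start + bc_len > len(read):
        return ("no_anchor", None)
    if anchor3 and read[start + bc_len : start + bc_len + len(anchor3)] != anchor3:
        return ("no_anchor", None)
    bc = read[start : start + bc_len]
    for pid, lib_bc in barcode_of.items():
        if bc == lib_bc:
            return ("assigned", pid)
    return (UNASSIGNED, None)


# ---------------------------------------------------------------------------

class TestExtractBarcode:
    def test_exact_anchors(self, amplicon):
        read = amplicon.anchor5 + "ACGTACGTACGTACG" + amplicon.anchor3 + "T" * 10
        assert extract_barcode(read, amplicon) == "ACGTACGTACGTACG"

    def test_anchor_absent(self, amplicon):
        assert extract_barcode("T" * 84, amplicon) is None

    def test_window_off_read_end(self, amplicon):
        read = "C" * 10 + amplicon.anchor5 + "ACGTA"  # barcode truncated
        assert extract_barcode(read, amplicon) is None

    def test_one_anchor_mismatch_tolerated(self, amplicon):
        a5 = "C" + amplicon.anchor5[1:]
        read = a5 + "ACGTACGTACGTACG" + amplicon.anchor3
        assert extract_barcode(read, amplicon) == "ACGTACGTACGTACG"
        strict = AmpliconConfig(
            anchor5=amplicon.anchor5, anchor3=amplicon.anchor3,
            max_anchor_mismatch=0,
        )
        assert extract_barcode(read, strict) is None

    def test_anchor3_enforced(self, amplicon):
        bad3 = "G" * len(amplicon.anchor3)
        read = amplicon.anchor5 + "ACGTACGTACGTACG" + bad3
        assert extract_barcode(read, amplicon) is None

    def test_revcomp_search(self, amplicon):
        from promoscreen.barcode_extraction import reverse_complement

        read = amplicon.anchor5 + "ACGTACGTACGTACG" + amplicon.anchor3 + "TTTT"
        rc = reverse_complement(read)
        assert extract_barcode(rc, amplicon) is None
        rc_cfg = AmpliconConfig(
            anchor5=amplicon.anchor5, anchor3=amplicon.anchor3, search_revcomp=True
        )
        assert extract_barcode(rc, rc_cfg) == "ACGTACGTACGTACG"

    def test_matches_exhaustive_offset_oracle_on_noisy_reads(self, amplicon):
        # 1000 simulated 84-nt reads at 1% per-base error
        import numpy as np

        rng = np.random.default_rng(2024)
        barcodes = list(SMALL_BARCODES.values())
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            bc = barcodes[rng.integers(len(barcodes))]
            prefix = "".join(bases[rng.integers(0, 4, 5)])
            read = (prefix + amplicon.anchor5 + bc + amplicon.anchor3).ljust(84, "T")
            arr = np.array(list(read))
            hit = rng.random(len(arr)) < 0.01
            arr[hit] = bases[rng.integers(0, 4, hit.sum())]
            noisy = "".join(arr)
            assert extract_barcode(noisy, amplicon) == _oracle_extract(
                noisy, amplicon.anchor5, amplicon.anchor3, 15,
                amplicon.max_anchor_mismatch,
            )


class TestMatchBarcode:
    def test_exact_match(self, small_map):
        assert match_barcode(SMALL_BARCODES["P2"], small_map, 0) == "P2"

    def test_unique_nearest_within_one(self, small_map):
        obs = "C" + SMALL_BARCODES["P1"][1:]
        assert match_barcode(obs, small_map, 1) == "P1"
        assert match_barcode(obs, small_map, 0) == UNASSIGNED

    def test_tie_is_ambiguous_verified_by_exhaustive_scan(self):
        from promoscreen import BarcodeMap, PromoterConstruct

        b1 = "AAAAAAAAAAAAAAA"
        b2 = "AAAAAAAAAAAAAAT"
        bc_map = BarcodeMap(
            [
                PromoterConstruct(promoter_id="X", barcode=b1),
                PromoterConstruct(promoter_id="Y", barcode=b2),
            ]
        )
        obs = "AAAAAAAAAAAAAAG"  # Hamming 1 from both
        assert match_barcode(obs, bc_map, 1) == AMBIGUOUS
        assert _oracle_match(obs, {"X": b1, "Y": b2}, 1) == AMBIGUOUS

    def test_length_mismatch_errors(self, small_map):
        with pytest.raises(ValueError, match="length"):
            match_barcode("ACGT", small_map, 1)

    def test_agrees_with_oracle_on_random_observations(self, small_map):
        import numpy as np

        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for max_mm in (0, 1, 2):
            for _ in range(300):
                obs = "".join(bases[rng.integers(0, 4, 15)])
                assert match_barcode(obs, small_map, max_mm) == _oracle_match(
                    obs, SMALL_BARCODES, max_mm
                )


def _write_fastq(path, reads, gz=False):
    opener = gzip.open if gz else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


class TestCountSample:
    def test_homogeneous_input(self, tmp_path, small_map, amplicon):
        read = amplicon.anchor5 + SMALL_BARCODES["P1"] + amplicon.anchor3 + "ACGT"
        path = tmp_path / "s.fastq"
        _write_fastq(path, [read] * 100)
        table = count_sample(path, small_map, amplicon, "s")
        assert table.counts == {"P1": 100, "P2": 0, "P3": 0, "P4": 0}
        assert table.reads_no_anchor == 0
        assert table.reads_seen == 100
        table.validate()

    def test_empty_fastq(self, tmp_path, small_map, amplicon):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        table = count_sample(path, small_map, amplicon, "e")
        assert table.reads_seen == 0 and table.total_assigned == 0

    def test_gzip_input_equivalent(self, tmp_path, small_map, amplicon):
        reads = [
            amplicon.anchor5 + SMALL_BARCODES[p] + amplicon.anchor3
            for p in ("P1", "P2", "P2", "P3")
        ]
        _write_fastq(tmp_path / "a.fastq", reads)
        _write_fastq(tmp_path / "a.fastq.gz", reads, gz=True)
        t1 = count_sample(tmp_path / "a.fastq", small_map, amplicon, "a")
        t2 = count_sample(tmp_path / "a.fastq.gz", small_map, amplicon, "a")
        assert t1.counts == t2.counts

    def test_truncated_fastq_names_record(self, tmp_path, small_map, amplicon):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n")
        with pytest.raises(ValueError, match="record 1"):
            count_sample(path, small_map, amplicon, "bad")

    def test_order_permutation_invariance(self, tmp_path, small_map, amplicon):
        import numpy as np

        reads = [
            amplicon.anchor5 + SMALL_BARCODES[p] + amplicon.anchor3
            for p in ("P1", "P1", "P2", "P3", "P4", "P4", "P4")
        ]
        _write_fastq(tmp_path / "f.fastq", reads)
        rng = np.random.default_rng(0)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        _write_fastq(tmp_path / "g.fastq", shuffled)
        a = count_sample(tmp_path / "f.fastq", small_map, amplicon, "f")
        b = count_sample(tmp_path / "g.fastq", small_map, amplicon, "g")
        assert a.counts == b.counts and a.qc_dict().items() >= {"reads_seen": 7}.items()

    def test_widening_bc_mismatch_never_loses_reads(self, tmp_path, small_map, amplicon):
        import numpy as np

        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        reads = []
        for _ in range(400):
            bc = list(SMALL_BARCODES.values())[rng.integers(4)]
            arr = np.array(list(amplicon.anchor5 + bc + amplicon.anchor3))
            hit = rng.random(len(arr)) < 0.05
            arr[hit] = bases[rng.integers(0, 4, hit.sum())]
            reads.append("".join(arr))
        path = tmp_path / "n.fastq"
        _write_fastq(path, reads)
        prev = -1
        for mm in (0, 1, 2, 3):
            cfg = AmpliconConfig(
                anchor5=amplicon.anchor5, anchor3=amplicon.anchor3, max_bc_mismatch=mm
            )
            t = count_sample(path, small_map, cfg, "n")
            usable = t.total_assigned + t.reads_bc_ambiguous
            assert usable >= prev
            prev = usable
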