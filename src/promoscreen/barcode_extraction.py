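"""Barcode extraction and counting from amplicon reads.

The assay amplifies the barcode region of the reporter cassette and
sequences it single-read (84 nt).  Each read therefore carries constant
amplicon sequence flanking the 15-nt barcode.  Extraction anchors on the
constant sequence immediately 5' of the barcode (optionally also the 3'
flank), allowing a bounded number of substitutions, and takes the
following fixed-length window as the observed barcode.  The observed
barcode is then assigned to the unique nearest library barcode within a
Hamming-distance limit; ties are "ambiguous", misses "unassigned".

Indels are not modeled: extraction is anchored and matching is
substitution-only, which is adequate for short fixed-length barcodes on
Illumina chemistry and is a documented limitation.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from .library_design import BarcodeMap

logger = logging.getLogger("promoscreen")

#: Sentinel outcomes of :func:`match_barcode`.
UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconConfig:
    """Amplicon layout and matching tolerances.

    The exact constant sequences flanking the barcode depend on the
    amplicon design and are required configuration.  ``anchor3`` may be
    empty when only the 5' flank is used.  ``search_revcomp`` enables a
    second pass on the reverse complement of reads that fail in the
    forward orientation; the single-read layout fixes the orientation, so
    it is off by default.
    """

    anchor5: str
    anchor3: str = ""
    bc_length: int = 15
    max_anchor_mismatch: int = 1
    max_bc_mismatch: int = 1
    search_revcomp: bool = False

    def __post_init__(self) -> None:
        if not self.anchor5:
            raise ValueError("anchor5 must be non-empty")
        if self.bc_length < 1:
            raise ValueError("bc_length must be >= 1")
        if self.max_anchor_mismatch < 0 or self.max_bc_mismatch < 0:
            raise ValueError("mismatch limits must be >= 0")
        object.__setattr__(self, "anchor5", self.anchor5.upper())
        object.__setattr__(self, "anchor3", self.anchor3.upper())


@dataclass
class BarcodeCountTable:
    """Per-sample promoter read counts with QC tallies.

    Conservation invariant: every read seen is accounted for exactly once —
    assigned to a promoter, failed anchor location, unassigned (no barcode
    within the mismatch limit) or ambiguous (tie between barcodes).
    """

    sample_id: str
    counts: dict[str, int]
    reads_seen: int = 0
    reads_no_anchor: int = 0
    reads_bc_unassigned: int = 0
    reads_bc_ambiguous: int = 0

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())

    def validate(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"{self.sample_id}: negative count")
        tallies = (self.reads_no_anchor, self.reads_bc_unassigned, self.reads_bc_ambiguous)
        if any(t < 0 for t in tallies):
            raise ValueError(f"{self.sample_id}: negative QC tally")
        if self.total_assigned + sum(tallies) != self.reads_seen:
            raise ValueError(
                f"{self.sample_id}: conservation violated: "
                f"{self.total_assigned} assigned + {sum(tallies)} failed != "
                f"{self.reads_seen} seen"
            )

    def qc_dict(self) -> dict[str, int]:
        return {
            "reads_seen": self.reads_seen,
            "reads_assigned": self.total_assigned,
            "reads_no_anchor": self.reads_no_anchor,
            "reads_bc_unassigned": self.reads_bc_unassigned,
            "reads_bc_ambiguous": self.reads_bc_ambiguous,
        }

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("promoter_id\tcount\n")
            for pid, c in self.counts.items():
                fh.write(f"{pid}\t{c}\n")

    def qc_to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"sample_id": self.sample_id, **self.qc_dict()}, fh, indent=2)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _best_anchor_offset(read: str, anchor: str, max_mismatch: int) -> int | None:
    """Leftmost offset with the fewest anchor mismatches, if within limit."""
    best_off: int | None = None
    best_mm = max_mismatch + 1
    for off in range(len(read) - len(anchor) + 1):
        mm = _mismatches(read[off : off + len(anchor)], anchor)
        if mm < best_mm:
            best_mm, best_off = mm, off
            if mm == 0:
                break
    return best_off if best_mm <= max_mismatch else None


def _extract_oriented(read: str, config: AmpliconConfig) -> str | None:
    off = _best_anchor_offset(read, config.anchor5, config.max_anchor_mismatch)
    if off is None:
        return None
    bc_start = off + len(config.anchor5)
    bc_end = bc_start + config.bc_length
    if bc_end > len(read):
        return None
    if config.anchor3:
        a3_end = bc_end + len(config.anchor3)
        if a3_end > len(read):
            return None
        if _mismatches(read[bc_end:a3_end], config.anchor3) > config.max_anchor_mismatch:
            return None
    return read[bc_start:bc_end]


def extract_barcode(read_sequence: str, config: AmpliconConfig) -> str | None:
    """Extract the barcode window from one read, or None on anchor failure.

    The 5' anchor is placed at its best-scoring (fewest-mismatch) offset,
    leftmost on ties; the barcode is the following ``bc_length`` bases.
    When ``anchor3`` is set it must follow the barcode immediately, within
    the same mismatch allowance.  Per-read failures are reported as None
    (tallied by :func:`count_sample`), never raised.
    """
    read = read_sequence.upper()
    bc = _extract_oriented(read, config)
    if bc is None and config.search_revcomp:
        bc = _extract_oriented(reverse_complement(read), config)
    return bc


def _encode_seqs(seqs: list[str], length: int) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), length
    )


def match_barcode(
    observed: str, bc_map: BarcodeMap, max_bc_mismatch: int
) -> str:
    """Assign an observed barcode to a promoter id, UNASSIGNED or AMBIGUOUS.

    Returns the promoter whose barcode is the unique nearest neighbour
    within ``max_bc_mismatch`` substitutions; AMBIGUOUS when two or more
    library barcodes tie at the minimal admissible distance.
    """
    observed = observed.upper()
    bc_len = len(bc_map.barcodes[0])
    if len(observed) != bc_len:
        raise ValueError(f"observed barcode length {len(observed)} != {bc_len}")
    best = max_bc_mismatch + 1
    best_id: str | None = None
    n_best = 0
    for entry in bc_map:
        d = _mismatches(observed, entry.barcode)
        if d < best:
            best, best_id, n_best = d, entry.promoter_id, 1
        elif d == best:
            n_best += 1
    if best > max_bc_mismatch:
        return UNASSIGNED
    return best_id if n_best == 1 else AMBIGUOUS


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ(.gz) file.

    Truncated or malformed records raise ``ValueError`` naming the index
    of the offending record.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = SeqIO.parse(fh, "fastq")
        idx = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ at record {idx}: {exc}") from exc
            yield str(rec.seq)
            idx += 1


def count_sample(
    fastq_path: str | Path,
    bc_map: BarcodeMap,
    config: AmpliconConfig,
    sample_id: str,
) -> BarcodeCountTable:
    """One pass over a FASTQ sample: extract, assign, tally.

    Extraction failures are counted as ``reads_no_anchor``; extracted
    barcodes are matched in a vectorized batch against the whole map.
    Every map promoter appears in the output counts (zero-filled), so
    downstream proportion tables share a common index.
    """
    table = BarcodeCountTable(
        sample_id=sample_id, counts={pid: 0 for pid in bc_map.promoter_ids}
    )
    observed: list[str] = []
    for seq in iter_fastq(fastq_path):
        table.reads_seen += 1
        bc = extract_barcode(seq, config)
        if bc is None:
            table.reads_no_anchor += 1
        else:
            observed.append(bc)
    if observed:
        lib = _encode_seqs(bc_map.barcodes, config.bc_length)
        pids = bc_map.promoter_ids
        chunk = 20_000
        for start in range(0, len(observed), chunk):
            obs = _encode_seqs(observed[start : start + chunk], config.bc_length)
            # (reads, barcodes) Hamming distances by broadcasting
            dist = (obs[:, None, :] != lib[None, :, :]).sum(axis=2)
            dmin = dist.min(axis=1)
            n_at_min = (dist == dmin[:, None]).sum(axis=1)
            argmin = dist.argmin(axis=1)
            for i in range(obs.shape[0]):
                if dmin[i] > config.max_bc_mismatch:
                    table.reads_bc_unassigned += 1
                elif n_at_min[i] > 1:
                    table.reads_bc_ambiguous += 1
                else:
                    table.counts[pids[argmin[i]]] += 1
    table.validate()
    return table
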