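"""Barcoded promoter-library data model.

A promoter library couples each promoter construct to a unique 15-nt DNA
barcode placed in the 3' UTR of a common reporter cassette, so that
sequencing the barcode region of a pooled sample reads out the relative
abundance of every construct at once.  This module holds the library
bookkeeping: the construct/barcode records, validated barcode maps
(TSV on disk), dose arithmetic for equimolar pooling, and a seeded
generator for fresh barcode sets with a minimum pairwise Hamming
distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("promoscreen")

BARCODE_LENGTH = 15
BARCODE_ALPHABET = frozenset("ACGT")


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_hamming(barcodes: Sequence[str]) -> int | None:
    """Minimum Hamming distance over all pairs; None for fewer than 2 codes."""
    if len(barcodes) < 2:
        return None
    arr = np.frombuffer("".join(barcodes).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(barcodes), -1)
    best = arr.shape[1]
    for i in range(len(barcodes) - 1):
        d = (arr[i + 1 :] != arr[i]).sum(axis=1).min()
        if d < best:
            best = int(d)
    return best


@dataclass(frozen=True)
class PromoterConstruct:
    """One barcoded promoter entry of the library.

    ``promoter_bp``/``stuffer_bp`` record the promoter and lacZ-stuffer
    lengths used to equalize construct sizes; they are optional metadata
    and not used in any computation here.
    """

    promoter_id: str
    barcode: str
    promoter_bp: int | None = None
    stuffer_bp: int | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.promoter_id:
            raise ValueError("promoter_id must be non-empty")
        bc = self.barcode.upper()
        object.__setattr__(self, "barcode", bc)
        if len(bc) != BARCODE_LENGTH:
            raise ValueError(
                f"barcode of {self.promoter_id!r} has length {len(bc)} != {BARCODE_LENGTH}"
            )
        bad = set(bc) - BARCODE_ALPHABET
        if bad:
            raise ValueError(
                f"barcode of {self.promoter_id!r} contains non-ACGT characters: {sorted(bad)}"
            )
        if self.promoter_bp is not None and self.promoter_bp <= 0:
            raise ValueError("promoter_bp must be positive")
        if self.stuffer_bp is not None and self.stuffer_bp < 0:
            raise ValueError("stuffer_bp must be non-negative")


class BarcodeMap:
    """Validated, ordered collection of :class:`PromoterConstruct`.

    Promoter ids and barcodes are each required to be unique; the minimum
    pairwise Hamming distance of the barcode set is recorded (reported, not
    enforced — the appropriate separation depends on the sequencing error
    rate and mismatch tolerance chosen downstream).
    """

    def __init__(self, entries: Iterable[PromoterConstruct]):
        self.entries: tuple[PromoterConstruct, ...] = tuple(entries)
        if not self.entries:
            raise ValueError("BarcodeMap requires at least one entry")
        seen_id: dict[str, PromoterConstruct] = {}
        seen_bc: dict[str, PromoterConstruct] = {}
        for e in self.entries:
            if e.promoter_id in seen_id:
                raise ValueError(f"duplicate promoter_id {e.promoter_id!r}")
            if e.barcode in seen_bc:
                raise ValueError(
                    f"duplicate barcode {e.barcode!r} shared by promoters "
                    f"{seen_bc[e.barcode].promoter_id!r} and {e.promoter_id!r}"
                )
            seen_id[e.promoter_id] = e
            seen_bc[e.barcode] = e
        self._by_id = seen_id
        self._by_barcode = seen_bc
        self.min_hamming: int | None = min_pairwise_hamming(self.barcodes)

    @property
    def promoter_ids(self) -> list[str]:
        return [e.promoter_id for e in self.entries]

    @property
    def barcodes(self) -> list[str]:
        return [e.barcode for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PromoterConstruct]:
        return iter(self.entries)

    def __getitem__(self, promoter_id: str) -> PromoterConstruct:
        return self._by_id[promoter_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BarcodeMap):
            return NotImplemented
        return self.entries == other.entries

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV (promoter_id, barcode, extra metadata columns)."""
        meta_keys: list[str] = []
        for e in self.entries:
            for k in e.metadata:
                if k not in meta_keys:
                    meta_keys.append(k)
        with open(path, "w") as fh:
            fh.write("\t".join(["promoter_id", "barcode", *meta_keys]) + "\n")
            for e in self.entries:
                row = [e.promoter_id, e.barcode]
                row += [str(e.metadata.get(k, "")) for k in meta_keys]
                fh.write("\t".join(row) + "\n")


def load_barcode_map(path: str | Path) -> BarcodeMap:
    """Load and validate a barcode map from TSV.

    Required header columns: ``promoter_id`` and ``barcode``; any extra
    columns are carried along as per-construct metadata.  Violations
    (wrong barcode length or alphabet, duplicates) raise ``ValueError``
    naming the offending line or entries.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty barcode map")
        header = header_line.rstrip("\n").split("\t")
        for col in ("promoter_id", "barcode"):
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        meta_cols = [c for c in header if c not in ("promoter_id", "barcode")]
        entries = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            row = dict(zip(header, fields))
            try:
                entries.append(
                    PromoterConstruct(
                        promoter_id=row["promoter_id"],
                        barcode=row["barcode"],
                        metadata={k: row[k] for k in meta_cols},
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    bc_map = BarcodeMap(entries)
    logger.info(
        "loaded barcode map %s: %d constructs, min pairwise Hamming distance %s",
        path,
        len(bc_map),
        bc_map.min_hamming,
    )
    return bc_map


@dataclass(frozen=True)
class PoolPlan:
    """Equimolar pooling arithmetic in vector genomes (VG)."""

    n_constructs: int
    dose_per_construct: float
    total_dose: float


def pool_dose(n_constructs: int, dose_per_construct: float) -> PoolPlan:
    """Total VG dose of an equimolar pool of ``n_constructs`` vectors."""
    if n_constructs <= 0:
        raise ValueError("n_constructs must be positive")
    if dose_per_construct <= 0:
        raise ValueError("dose_per_construct must be positive")
    return PoolPlan(
        n_constructs=n_constructs,
        dose_per_construct=dose_per_construct,
        total_dose=n_constructs * dose_per_construct,
    )


def generate_barcodes(
    n: int,
    length: int = BARCODE_LENGTH,
    min_hamming: int = 3,
    seed: int = 0,
    max_attempts: int = 1_000_000,
) -> list[str]:
    """Draw ``n`` distinct barcodes with pairwise Hamming distance >= ``min_hamming``.

    Seeded rejection sampling: candidates are drawn uniformly and kept when
    they clear the distance constraint against every accepted code.  Adequate
    for libraries up to a few hundred codes; raises when the constraint
    cannot be satisfied within ``max_attempts`` draws (e.g. by pigeonhole).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (1 <= min_hamming <= length):
        raise ValueError("require 1 <= min_hamming <= length")
    if n > 4**length:
        raise ValueError(f"cannot draw {n} distinct {length}-mers (only {4**length} exist)")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    accepted = np.empty((0, length), dtype=np.uint8)
    attempts = 0
    while accepted.shape[0] < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} barcodes of length {length} at distance >= "
                f"{min_hamming} within {max_attempts} draws; "
                "increase length or reduce n/min_hamming"
            )
        cand = bases[rng.integers(0, 4, size=length)]
        attempts += 1
        if accepted.shape[0] and int((accepted != cand).sum(axis=1).min()) < min_hamming:
            continue
        accepted = np.vstack([accepted, cand])
    return [bytes(row).decode("ascii") for row in accepted]


def barcode_map_from_codes(
    barcodes: Sequence[str], prefix: str = "P"
) -> BarcodeMap:
    """Build a map with auto-numbered promoter ids (P01, P02, ...)."""
    width = max(2, len(str(len(barcodes))))
    return BarcodeMap(
        PromoterConstruct(promoter_id=f"{prefix}{i + 1:0{width}d}", barcode=bc)
        for i, bc in enumerate(barcodes)
    )
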