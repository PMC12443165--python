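import pandas as pd
import pytest

from promoscreen import (
    AmpliconConfig,
    BarcodeCountTable,
    BarcodeMap,
    BulkExpression,
    PromoterConstruct,
    SampleSheet,
)

# Four hand-picked 15-mers, pairwise Hamming distance >= 8.
SMALL_BARCODES = {
    "P1": "AAAAACCCCCGGGGG",
    "P2": "CCCCCGGGGGTTTTT",
    "P3": "GGGGGTTTTTAAAAA",
    "P4": "TTTTTAAAAACCCCC",
}


@pytest.fixture
def small_map() -> BarcodeMap:
    return BarcodeMap(
        PromoterConstruct(promoter_id=pid, barcode=bc)
        for pid, bc in SMALL_BARCODES.items()
    )


@pytest.fixture
def amplicon() -> AmpliconConfig:
    return AmpliconConfig(
        anchor5="ATGGACGAGCTGTACAAGTA", anchor3="ACGGGTGGCATCCCT", bc_length=15
    )


def make_counts(sample_id: str, counts: dict[str, int], **qc) -> BarcodeCountTable:
    table = BarcodeCountTable(sample_id=sample_id, counts=dict(counts), **qc)
    if "reads_seen" not in qc:
        table.reads_seen = table.total_assigned
    table.validate()
    return table


@pytest.fixture
def worked_example():
    """Hand-computed 3-promoter x 2-tissue screen, one animal.

    All downstream values (R, E, S) were derived on paper from these
    counts and bulk-expression values; the expected numbers live in the
    tests that use this fixture.
    """
    counts = {
        "A1_liver_gDNA": make_counts("A1_liver_gDNA", {"P1": 50, "P2": 30, "P3": 20}),
        "A1_liver_cDNA": make_counts("A1_liver_cDNA", {"P1": 60, "P2": 20, "P3": 20}),
        "A1_heart_gDNA": make_counts("A1_heart_gDNA", {"P1": 25, "P2": 25, "P3": 50}),
        "A1_heart_cDNA": make_counts("A1_heart_cDNA", {"P1": 10, "P2": 40, "P3": 50}),
    }
    sheet = SampleSheet(
        pd.DataFrame(
            [
                {"sample_id": sid, "animal_id": "A1", "tissue": sid.split("_")[1],
                 "material": sid.split("_")[2]}
                for sid in counts
            ]
        )
    )
    bulk = BulkExpression.from_frame(
        pd.DataFrame(
            [
                {"animal_id": "A1", "tissue": "liver", "c_beta": 2.0},
                {"animal_id": "A1", "tissue": "heart", "c_beta": 0.5},
            ]
        )
    )
    return counts, sheet, bulk
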