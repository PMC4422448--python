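import sys
from pathlib import Path

import pytest

# make the oracles module importable as a plain module from any test
sys.path.insert(0, str(Path(__file__).parent))

from treetally import SegmentAlignment, SequenceSet, TaxonRecord


@pytest.fixture
def toy_sequences() -> SequenceSet:
    return SequenceSet(
        {
            "AgrTuAgp1": "MKVAELRRSTGLEHMKVAELRRST",
            "PheZuBph": "MKLAELKRSTGLDHMKLAELKRST",
            "SynSpCphA": "MRVAELRKSTGLEYMRVAELRKST",
            "AraThPhyA": "MKVSELRRATGLEHMKVSELRRAT",
        }
    )


@pytest.fixture
def toy_records() -> list[TaxonRecord]:
    return [
        TaxonRecord("AgrTuAgp1", "Agrobacterium tumefaciens", "alpha-proteobacteria",
                    "BphP", (1, 10), (15, 24)),
        TaxonRecord("PheZuBph", "Phenylobacterium zucineum", "alpha-proteobacteria",
                    "BphP", (1, 10), (15, 24)),
        TaxonRecord("SynSpCphA", "Synechocystis sp.", "cyanobacteria",
                    "CphA", (1, 10), (15, 24)),
        TaxonRecord("AraThPhyA", "Arabidopsis thaliana", "streptophyte",
                    "Phy", (1, 10), (15, 24)),
    ]


@pytest.fixture
def toy_alignment() -> SegmentAlignment:
    # 4 rows x 8 columns, hand-designed gap structure
    return SegmentAlignment(
        {
            "A": "MKV-AELR",
            "B": "MKL-AELR",
            "C": "MRV--ELR",
            "D": "M-VSADLR",
        }
    )
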