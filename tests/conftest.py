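import numpy as np
import pytest

from diapausemir import (
    ComparisonDesign,
    HairpinCatalog,
    HairpinEntry,
    Interval,
    SampleMeta,
)
from diapausemir.simulate import synthetic_catalog


@pytest.fixture
def tiny_catalog() -> HairpinCatalog:
    """Two hand-built hairpins with both arms annotated."""
    seq1 = ("ACGTACGTACGTACGTACGTAC"  # 5p arm, 1..22
            "GTTTGA"                   # loop
            "TTGCATTGCATTGCATTGCATT")  # 3p arm, 29..50
    seq2 = ("GGCCTTAAGGCCTTAAGGCCTT"
            "ACACAC"
            "CCGGAATTCCGGAATTCCGGAA")
    return HairpinCatalog(
        [
            HairpinEntry("mir-a", "fam-a", True, seq1,
                         Interval(1, 22), Interval(29, 50)),
            HairpinEntry("mir-b", "fam-b", False, seq2,
                         Interval(1, 22), Interval(29, 50)),
        ]
    )


@pytest.fixture
def random_catalog() -> HairpinCatalog:
    return synthetic_catalog(n_loci=12, seed=11)


@pytest.fixture
def study_metadata() -> list[SampleMeta]:
    """15 samples mirroring the study: 8 annual diapause, 7 non-annual."""
    rows = []
    spec = [
        ("Nothobranchius_furzeri", "africa_east", True, "diapause", 5),
        ("Austrofundulus_leohoignei", "south_america", True, "diapause", 2),
        ("Callopanchax_occidentalis", "africa_west", True, "diapause", 1),
        ("Aphyosemion_striatum", "africa_east", False, "normal_development", 4),
        ("Rivulus_cylindraceus", "south_america", False, "normal_development", 1),
        ("Epiplatys_dageti", "africa_west", False, "normal_development", 1),
        ("Aplocheilus_lineatus", "india", False, "normal_development", 1),
    ]
    for species, clade, annual, status, n in spec:
        for r in range(1, n + 1):
            rows.append(
                SampleMeta(f"{species}_{r}", species, clade, annual, status, r)
            )
    return rows


@pytest.fixture
def simulated_design() -> ComparisonDesign:
    return ComparisonDesign(
        "simulated",
        [f"annual_{i+1}" for i in range(8)],
        [f"nonannual_{i+1}" for i in range(7)],
    )


def metadata_for_design(design: ComparisonDesign) -> list[SampleMeta]:
    meta = []
    for s in sorted(design.group_a):
        meta.append(SampleMeta(s, "Annual_sp", "africa_east", True, "diapause", 1))
    for s in sorted(design.group_b):
        meta.append(
            SampleMeta(s, "Nonannual_sp", "africa_east", False, "normal_development", 1)
        )
    return meta
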