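import numpy as np
import pytest

import apol1hap as ah


@pytest.fixture(scope="session")
def panel():
    return ah.default_panel()


@pytest.fixture(scope="session")
def founders(panel):
    return ah.build_default_founders(panel)


@pytest.fixture(scope="session")
def cohort(panel):
    """Default simulated cohort, seed 7, noise-free."""
    return ah.simulate_population(ah.SimConfig(seed=7))


@pytest.fixture(scope="session")
def records(cohort):
    hm, _ = cohort
    return ah.tally_unique(hm)


def make_matrix(panel, rows, sample_prefix="S"):
    """Build a HaplotypeMatrix from a list of (hapA, hapB) binary tuples."""
    alleles = np.array(rows, dtype=np.uint8)
    ids = [f"{sample_prefix}{i}" for i in range(len(rows))]
    return ah.HaplotypeMatrix(panel=panel, sample_ids=ids, alleles=alleles)


def write_panel_tsv(path, rows):
    """rows: (variant_id, chrom, pos, pos_alt_build, ref, alt, class, role)"""
    header = "variant_id\tchrom\tpos\tpos_alt_build\tref\talt\tclass\trole"
    lines = [header] + ["\t".join(str(x) for x in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def mini_panel():
    """Three plain SNPs without role tags, for I/O-level tests."""
    return ah.VariantPanel([
        ah.PanelVariant("v1", "chr22", 100, "A", "G", "intronic"),
        ah.PanelVariant("v2", "chr22", 200, "C", "T", "intronic"),
        ah.PanelVariant("v3", "chr22", 300, "G", "A", "exonic"),
    ])
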