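import numpy as np
import pandas as pd
import pytest

from devmeth import (ProbeManifest, SampleSheet, SimulationDesign,
                     simulate_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-scale simulated study (5,000 probes, 50 samples, seed 1)."""
    return simulate_dataset(SimulationDesign(seed=1))


@pytest.fixture(scope="session")
def null_dataset():
    """Same design with zero planted genotype effects."""
    return simulate_dataset(
        SimulationDesign(n_isolated_dmps=0, n_dmr_blocks=0, seed=2))


@pytest.fixture
def tiny_manifest():
    tab = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "pos": [100, 250, 500],
        "genes": [("GeneA",), ("GeneA", "GeneB"), ()],
        "feature": ["promoter", "gene_body", "intergenic"],
        "biotype": ["protein_coding", "protein_coding", "NA"],
        "flagged": [False, False, False],
        "mfg_change_flagged": [False, False, False],
        "autosomal": [True, True, True],
    }, index=pd.Index(["cg01", "cg02", "cg03"], name="probe_id"))
    return ProbeManifest(tab)


def balanced_sample_sheet(n_per_cell=5, n_chips=2, neuronal=None, seed=0):
    """Helper: genotype x age factorial sheet with alternating chips."""
    from devmeth.types import AGE_LABELS
    rng = np.random.default_rng(seed)
    rows = []
    for gt in ("WT", "HET"):
        for age in AGE_LABELS:
            for rep in range(n_per_cell):
                rows.append((f"{gt}_{age}_{rep}", gt, age,
                             f"chip{rep % n_chips + 1}"))
    t = pd.DataFrame(rows, columns=["sample_id", "genotype", "age_label",
                                    "chip_id"]).set_index("sample_id")
    sheet = SampleSheet(t)
    if neuronal == "random":
        sheet.table["neuronal_prop"] = rng.uniform(0.3, 0.7, len(t))
    elif neuronal is not None:
        sheet.table["neuronal_prop"] = neuronal
    return sheet
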