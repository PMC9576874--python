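import numpy as np
import pytest

from telomethyl import simulate
from telomethyl.datamodel import (
    CpGRecord,
    GenomicPosition,
    PhenotypeVector,
    SNPRecord,
    StudyDataset,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-sample default-shaped cohort with ground truth."""
    cfg = simulate.default_simulation_config(seed=11, n_samples=150)
    ds, truth, extras = simulate.simulate_study(cfg)
    return cfg, ds, truth, extras


@pytest.fixture()
def two_feature_dataset():
    """Factory: covariate-free dataset with one SNP and one cis CpG."""

    def make(dosage, m, tl):
        dosage = np.asarray(dosage, dtype=float)
        n = len(dosage)
        snp = SNPRecord.from_dosages(
            "rs1", GenomicPosition("chr1", 1_000_000), "A", "G", dosage)
        cpg = CpGRecord("cg00000001", GenomicPosition("chr1", 1_015_000),
                        np.asarray(m, dtype=float))
        return StudyDataset([snp], [cpg], None,
                            PhenotypeVector(np.asarray(tl, dtype=float)),
                            [f"S{i}" for i in range(n)])

    return make
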