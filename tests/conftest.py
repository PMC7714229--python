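import numpy as np
import pytest
from hypothesis import settings

import gpsel as g

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_K():
    """3-accession relationship matrix of the D-score worked example."""
    return np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.1], [0.5, 0.1, 1.0]])


@pytest.fixture(scope="session")
def panel():
    """Structured synthetic panel: 200 near-inbred accessions, 2 x 250 SNPs, h2=0.5."""
    cfg = g.SynthConfig(
        n_accessions=200, n_chromosomes=2, snps_per_chromosome=250,
        h2=0.5, het_rate=0.02, missing_rate=0.02, n_qtl=50, seed=3,
    )
    m_raw, gm = g.make_founders(cfg)
    m = g.impute_missing_as_major(m_raw)
    pheno, truth = g.make_phenotype(m, cfg)
    return {"cfg": cfg, "m_raw": m_raw, "m": m, "gm": gm, "pheno": pheno,
            "truth": truth}


@pytest.fixture(scope="session")
def panel_fit(panel):
    model = g.GBLUP.from_dataframe(panel["pheno"], panel["m"], "trait")
    return model.fit()


@pytest.fixture()
def toy_files(tmp_path):
    """Hand-written 3-accession x 4-SNP genotype + map fixture on disk."""
    geno = tmp_path / "geno.tsv"
    geno.write_text(
        "accession\ts1\ts2\ts3\ts4\n"
        "a1\t1\t0\t-1\t1\n"
        "a2\t1\tNA\t1\t-1\n"
        "a3\t-1\t1\t0\t1\n"
    )
    mp = tmp_path / "snps.map"
    mp.write_text(
        "1\ts1\t0.0\t100\n"
        "1\ts2\t0.5\t500\n"
        "1\ts3\t2.0\t25000\n"
        "2\ts4\t0.0\t900\n"
    )
    return geno, mp
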