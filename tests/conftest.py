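import numpy as np
import pytest

from dgrscout.dataset import Dataset
from dgrscout.model import Contig, DgrSystem, GeneFeature, ImmuneCatalog, PfamHit


def make_gene(gid, contig, start, end, strand="+", pfams=(), vr=False):
    return GeneFeature(
        gene_id=gid,
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        pfam_hits=[PfamHit(p, 1e-10) for p in pfams],
        contains_vr=vr,
    )


@pytest.fixture
def toy_dataset():
    """One 40 kbp linear contig: RT at [5000,6000), VR host at [8000,9000),
    an accessory nearby, and a distant decoy."""
    contigs = {"c1": Contig("c1", 40_000)}
    features = [
        make_gene("rt1", "c1", 5_000, 6_000, "+", ["PF00078"]),
        make_gene("tgt1", "c1", 8_000, 9_000, "+", ["PF01833"]),
        make_gene("acc1", "c1", 9_200, 9_800, "-", ["PF05635"]),
        make_gene("far1", "c1", 30_000, 31_000, "+", ["PF99999"]),
    ]
    systems = [
        DgrSystem(
            contig_id="c1",
            system_id="s1",
            rt_gene_id="rt1",
            vr_intervals=[(8_100, 8_200, "tgt1")],
            tr_interval=(6_100, 6_200),
        )
    ]
    return Dataset.assemble(contigs, features, systems)


@pytest.fixture(scope="session")
def recovery_sim():
    """200-contig simulation with near-certain immune co-localization."""
    from dgrscout.simulate import SimConfig, simulate_dataset

    return simulate_dataset(
        SimConfig(n_contigs=200, seed=7, with_sequences=False,
                  p_immune_colocalization=0.95)
    )


@pytest.fixture(scope="session")
def recovery_icity(recovery_sim):
    from dgrscout.icity import run_icity

    return run_icity(recovery_sim.dataset, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def immune_catalog():
    return ImmuneCatalog(["PF01797", "PF13455"])
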