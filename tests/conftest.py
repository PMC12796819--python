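import numpy as np
import pandas as pd
import pytest

import lfqminer as L
from lfqminer.synthetic import (
    AnnotationPlan,
    PlantedEffect,
    SimulationSpec,
    simulate_gene_annotations,
    simulate_protein_groups,
)

TINY_PG = """Protein IDs\tMajority protein IDs\tGene names\tLFQ intensity MS01\tLFQ intensity MS02\tLFQ intensity MS03\tLFQ intensity MS04\tReverse\tPotential contaminant\tOnly identified by site
P00001\tP00001\tHmgcs2\t1000000\t2000000\t1500000\t1800000\t\t\t
P00002\tP00002\tPklr\t0\t500000\t600000\t700000\t\t\t
P00003\tP00003\tPklr\t300000\t400000\t350000\t0\t\t\t
P00004\tP00004\t\t100000\t110000\t120000\t130000\t\t\t
REV__P9\tREV__P9\tJunk\t50000\t60000\t70000\t80000\t+\t\t
CON__P8\tCON__P8\tKrt1\t90000\t95000\t99000\t91000\t\t+\t
"""

TINY_DESIGN = """label\tcondition\treplicate\torder
MS01\tCtrl\t1\t1
MS02\tCtrl\t2\t2
MS03\tTrt\t1\t3
MS04\tTrt\t2\t4
"""


@pytest.fixture
def tiny_pg_file(tmp_path):
    p = tmp_path / "proteinGroups.txt"
    p.write_text(TINY_PG)
    return str(p)


@pytest.fixture
def tiny_design_file(tmp_path):
    p = tmp_path / "design.tsv"
    p.write_text(TINY_DESIGN)
    return str(p)


def make_sim(seed=11, n_proteins=600, n_de=60, effect=2.0, **kwargs):
    spec = SimulationSpec(seed=seed, n_proteins=n_proteins, **kwargs)
    h = n_de // 2
    treated = [c for c in spec.conditions if c.endswith("LDT409")] or [spec.conditions[-1]]
    spec.planted = [
        PlantedEffect(tuple(range(h)), {c: effect for c in treated}),
        PlantedEffect(tuple(range(h, n_de)), {c: -effect for c in treated}),
    ]
    spec.__post_init__()
    return spec, simulate_protein_groups(spec)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Simulated 4-condition study written to disk, parsed and preprocessed."""
    outdir = str(tmp_path_factory.mktemp("sim"))
    spec, sim = make_sim()
    paths = sim.write(outdir)
    table = L.parse_protein_groups(paths["protein_groups"])
    design = L.parse_design(paths["design"], table)
    clean = L.remove_flagged_rows(table)
    ds_raw = L.ExpressionDataset.from_table(clean, design)
    ds_filt = L.filter_missing(ds_raw, 0)
    ds = L.impute_left_censored(L.log2_transform(ds_filt), seed=101)
    return {
        "spec": spec,
        "sim": sim,
        "paths": paths,
        "table": table,
        "design": design,
        "ds_raw": ds_raw,
        "ds_filt": ds_filt,
        "ds": ds,
    }


@pytest.fixture(scope="session")
def contrast_results(sim_bundle):
    return L.fit_all_contrasts(sim_bundle["ds"])


@pytest.fixture(scope="session")
def annotation_bundle(sim_bundle):
    plan = AnnotationPlan()
    gene_sets, consensome = simulate_gene_annotations(
        sim_bundle["sim"], plan, seed=5
    )
    return {"plan": plan, "gene_sets": gene_sets, "consensome": consensome}
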