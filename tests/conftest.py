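from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from svdriver.model import BreakpointEnd, BreakpointJunction, GeneRecord, GenomicInterval
from svdriver.ontology import Ontology
from svdriver.pipeline import run_cohort
from svdriver.simulate import SimulationConfig, load_cohort, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def build_ontology(parents: dict[str, list[str]], annotations=None) -> Ontology:
    """Ontology from a child -> parents mapping (and optional annotations)."""
    g = nx.DiGraph()
    g.add_nodes_from(parents)
    for child, ps in parents.items():
        for p in ps:
            g.add_edge(child, p)
    onto = Ontology(g)
    if annotations is not None:
        onto.set_annotations(annotations)
    return onto


def make_junction(jid, chrom_a, pos_a, chrom_b, pos_b, sv_type="BND",
                  orient_a="tail", orient_b="head", patient=""):
    return BreakpointJunction(
        jid,
        BreakpointEnd(chrom_a, pos_a, orient_a),
        BreakpointEnd(chrom_b, pos_b, orient_b),
        sv_type,
        patient,
    )


def make_gene(symbol, chrom, start, end, strand="+", **kw):
    return GeneRecord(
        symbol=symbol,
        refseq_id=kw.pop("refseq_id", f"NM_{abs(hash(symbol)) % 10_000:05d}"),
        interval=GenomicInterval(chrom, start, end, strand),
        **kw,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One 8-patient simulated cohort, generated once and loaded back
    through the standard readers."""
    out = tmp_path_factory.mktemp("cohort")
    cohort = simulate_cohort(SimulationConfig(seed=3, n_patients=8), out)
    genes, ontology, bundle, patients = load_cohort(out)
    return {
        "cohort": cohort,
        "genes": genes,
        "ontology": ontology,
        "bundle": bundle,
        "patients": patients,
    }


@pytest.fixture(scope="session")
def small_cohort_results(small_cohort):
    calls, summaries, summary = run_cohort(
        small_cohort["patients"],
        small_cohort["genes"],
        small_cohort["ontology"],
        small_cohort["bundle"],
    )
    return {"calls": calls, "summaries": summaries, "summary": summary}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
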