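"""Shared fixtures: one synthetic world, simulated and processed once.

The expensive chain (genome -> planted hairpins -> library -> filtering ->
mapping -> classification -> candidate evaluation) is session-scoped; the
tests and the acceptance suite all read from the same seeded world.
"""

from __future__ import annotations

import pytest

from fruitmir import annotate, novel, preprocess
from fruitmir import simulate as sim

SEED = 1


@pytest.fixture(scope="session")
def spec():
    return sim.SimulationSpec(seed=SEED)


@pytest.fixture(scope="session")
def world(spec):
    """Genome with planted hairpins, annotation, truth and known-miRNA db."""
    genome0, features = sim.generate_genome(spec)
    genome, truth = sim.plant_hairpins(genome0, spec, features)
    known_db = sim.make_known_mirna_db(
        SEED, spec.n_known_mirnas,
        avoid=[h.mature_seq for h in truth.planted_hairpins],
    )
    return {
        "genome": genome, "features": features, "truth": truth,
        "known_db": known_db,
    }


@pytest.fixture(scope="session")
def library(spec, world):
    reads, sidecar = sim.simulate_srna_library(
        world["truth"], spec, world["genome"], world["features"],
        world["known_db"],
    )
    return {"reads": reads, "sidecar": sidecar}


@pytest.fixture(scope="session")
def processed(library):
    clean, summary = preprocess.filter_reads(
        library["reads"], sim.ADAPTER3, sim.ADAPTER5
    )
    tags = preprocess.collapse_tags(clean)
    return {"clean": clean, "summary": summary, "tags": tags}


@pytest.fixture(scope="session")
def annotated(world, processed):
    hits = annotate.map_tags(processed["tags"], world["genome"])
    assignment, summary = annotate.classify_tags(
        processed["tags"], hits, world["features"], world["known_db"]
    )
    return {"hits": hits, "assignment": assignment, "summary": summary}


@pytest.fixture(scope="session")
def novel_inputs(processed, annotated):
    unannot = annotate.unannotated_tags(processed["tags"], annotated["assignment"])
    useqs = {t.sequence for t in unannot}
    uhits = [h for h in annotated["hits"] if h.tag_sequence in useqs]
    return {"tags": unannot, "hits": uhits}


@pytest.fixture(scope="session")
def evaluated_candidates(world, novel_inputs):
    """One scored candidate per unannotated read locus (default criteria)."""
    return novel.evaluate_candidates(
        world["genome"], novel_inputs["tags"], novel_inputs["hits"]
    )


@pytest.fixture(scope="session")
def predictions(world, novel_inputs):
    return novel.predict_novel(
        world["genome"], novel_inputs["tags"], novel_inputs["hits"]
    )
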