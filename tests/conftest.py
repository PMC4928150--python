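"""Shared fixtures: toy resources built in code, plus a small synthetic kinome."""

import dataclasses

import pytest

from kinvar import (
    AnnotationBundle,
    Dataset,
    OntologyGraph,
    VariantRecord,
    generate,
)
from kinvar.synthetic import preset


@pytest.fixture
def diamond_ontology() -> OntologyGraph:
    """D -> {B, C}, B -> A, C -> A: the classic multiple-inheritance diamond."""
    return OntologyGraph(
        terms={"A", "B", "C", "D"},
        parents={"B": {"A"}, "C": {"A"}, "D": {"B", "C"}},
        namespace={t: "molecular_function" for t in "ABCD"},
    )


@pytest.fixture
def toy_bundle() -> AnnotationBundle:
    bundle = AnnotationBundle()
    bundle.kinase_group["P1"] = "TK"
    bundle.kinase_group["P2"] = "CAMK"
    bundle.go_direct["P1"] = {"D"}
    bundle.domains["P1"] = [("Pkinase", 30, 290)]
    bundle.sites[("P1", 100)] = {"act_site"}
    bundle.sift[("P1", 100, "A", "V")] = 0.02
    return bundle


def _toy_variants(protein: str, n_disease: int, n_neutral: int, start: int = 1) -> list:
    """Distinct labelled substitutions on one protein at consecutive positions."""
    out = []
    pos = start
    for _ in range(n_disease):
        out.append(VariantRecord(protein, pos, "A", "V", "disease"))
        pos += 1
    for _ in range(n_neutral):
        out.append(VariantRecord(protein, pos, "A", "V", "neutral"))
        pos += 1
    return out


@pytest.fixture
def group_toy():
    """10 disease + 20 neutral variants; group TK holds 4 disease, 2 neutral.

    The TK log-odds then reduces to log2((4/10)/(2/20)) = 2.0.
    """
    bundle = AnnotationBundle()
    bundle.kinase_group["PTK"] = "TK"
    bundle.kinase_group["POT"] = "OTHER"
    variants = _toy_variants("PTK", 4, 2) + _toy_variants("POT", 6, 18)
    return Dataset(variants), bundle


@pytest.fixture(scope="session")
def small_strong():
    """A reduced strong-signal kinome: quick enough for per-test CV runs."""
    cfg = dataclasses.replace(
        preset("strong"), n_proteins=120, n_variants=900, seed=7
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def full_strong():
    """The shipped 'strong' study conditions at full size (seed 11)."""
    return generate(preset("strong", seed=11))
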