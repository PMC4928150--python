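"""Self-contained synthetic kinome generator.

Produces a complete, internally consistent stand-in for the real training
resources — a GO-like ontology DAG, protein group/domain/site annotations,
per-substitution conservation scores and a labelled variant table — with
configurable class-conditional signal, so that the whole pipeline is
exercisable without any download.

The generator emulates the statistical structure of the real data:

* pathogenic variants concentrate in a subset of kinase groups and in
  proteins carrying particular "risk" GO terms (class-skewed group and term
  log-odds);
* pathogenic variants fall inside annotated domains more often than neutral
  ones;
* conservation (SIFT-like) scores of pathogenic variants are shifted toward
  0 while neutral scores spread over [0, 1];
* functionally annotated residues (site categories) are hit more often by
  pathogenic variants.

It makes no attempt to mimic real kinase sequences, real GO identifiers or
real UniProt accessions; identifiers are synthetic throughout.

Default dimensions mirror the real training compendium: 459 proteins in 15
groups, ~3689 variants with a ~27.7 % pathogenic fraction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._exceptions import ConfigurationError
from .io import (
    SITE_CATEGORIES,
    AnnotationBundle,
    Dataset,
    VariantRecord,
    write_annotations,
    write_variants,
)
from .ontology import OntologyGraph, write_ontology

AA = sorted("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic kinome.

    Effect sizes are odds multipliers applied when allocating pathogenic
    variants to proteins: a protein in a risk group is ``group_enrichment_odds``
    times more likely to receive a pathogenic variant than a background
    protein, and likewise for risk GO terms.  ``domain_enrichment_odds``
    tilts pathogenic positions into domain intervals.  ``sift_shift`` is the
    gap between the mean conservation score of neutral (~0.5) and pathogenic
    variants.  ``site_hit_prob`` gives the per-class probability that a
    variant's residue carries a functional-site annotation.
    """

    n_proteins: int = 459
    n_groups: int = 15
    n_go_terms: int = 120
    dag_parent_prob: float = 0.3
    n_domains: int = 30
    domain_length_range: tuple[int, int] = (50, 300)
    protein_length_range: tuple[int, int] = (320, 1200)
    n_variants: int = 3689
    disease_fraction: float = 1021 / 3689
    group_enrichment_odds: float = 1.0
    domain_enrichment_odds: float = 1.0
    go_enrichment_odds: float = 1.0
    sift_shift: float = 0.0
    site_hit_prob: tuple[float, float] = (0.03, 0.03)  # (disease, neutral)
    missing_sift_prob: float = 0.10
    n_risk_groups: int = 3
    n_risk_terms: int = 8
    go_risk_protein_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.dag_parent_prob,
            self.missing_sift_prob,
            self.go_risk_protein_prob,
            *self.site_hit_prob,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if min(self.group_enrichment_odds, self.domain_enrichment_odds, self.go_enrichment_odds) <= 0:
            raise ConfigurationError("enrichment odds must be > 0")
        if self.n_variants < 10:
            raise ConfigurationError("n_variants must be >= 10")
        if not 0.0 < self.disease_fraction < 1.0:
            raise ConfigurationError("disease_fraction must lie in (0, 1)")
        if self.domain_length_range[1] >= self.protein_length_range[0]:
            raise ConfigurationError("domains must fit inside the shortest protein")
        if not 0.0 <= self.sift_shift <= 0.45:
            raise ConfigurationError("sift_shift must lie in [0, 0.45]")


#: Shipped study conditions: "strong" plants a clear multi-channel signal
#: (for end-to-end recovery checks); "null" removes every class-conditional
#: difference (false-positive control).
PRESETS: dict[str, GeneratorConfig] = {
    "strong": GeneratorConfig(
        group_enrichment_odds=8.0,
        domain_enrichment_odds=4.0,
        go_enrichment_odds=8.0,
        sift_shift=0.30,
        site_hit_prob=(0.12, 0.02),
    ),
    "null": GeneratorConfig(),
}


def preset(name: str, seed: int | None = None) -> GeneratorConfig:
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return cfg


def _beta_params(mean: float, concentration: float = 4.0) -> tuple[float, float]:
    mean = min(max(mean, 0.02), 0.98)
    return mean * concentration, (1 - mean) * concentration


def generate(
    config: GeneratorConfig,
) -> tuple[Dataset, AnnotationBundle, OntologyGraph, dict]:
    """Build the full synthetic kinome; byte-reproducible from ``config``.

    Returns the labelled variant dataset, the annotation bundle, the
    ontology graph and a ground-truth record naming the planted risk
    groups/terms and echoing the configuration.
    """
    rng = np.random.default_rng(config.seed)

    # --- ontology: random DAG over terms T0001.. in topological order
    terms = [f"T{i:04d}" for i in range(config.n_go_terms)]
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    ns_names = ("molecular_function", "biological_process", "cellular_component")
    for i, term in enumerate(terms):
        namespace[term] = ns_names[i % 3]
        if i == 0:
            continue
        # one parent per term, a second with probability dag_parent_prob
        n_parents = 1 + int(rng.random() < config.dag_parent_prob)
        chosen = rng.choice(i, size=min(n_parents, i), replace=False)
        parents[term] = {terms[j] for j in chosen}
    graph = OntologyGraph(terms=set(terms), parents=parents, namespace=namespace)

    # --- proteins, groups, domains, GO annotation
    proteins = [f"KIN{i:04d}" for i in range(config.n_proteins)]
    groups = [f"G{g:02d}" for g in range(config.n_groups)]
    risk_groups = set(rng.choice(groups, size=min(config.n_risk_groups, len(groups)), replace=False))
    risk_terms = set(rng.choice(terms[config.n_go_terms // 3 :], size=config.n_risk_terms, replace=False))
    background_terms = [t for t in terms if t not in risk_terms]

    domain_ids = [f"D{j:02d}" for j in range(config.n_domains)]

    bundle = AnnotationBundle()
    lengths: dict[str, int] = {}
    go_risk_flag: dict[str, bool] = {}
    for p in proteins:
        bundle.kinase_group[p] = groups[int(rng.integers(len(groups)))]
        lengths[p] = int(rng.integers(*config.protein_length_range))

        n_dom = int(rng.integers(1, 4))
        doms = []
        for _ in range(n_dom):
            dom = domain_ids[int(rng.integers(len(domain_ids)))]
            length = int(rng.integers(*config.domain_length_range))
            start = int(rng.integers(1, lengths[p] - length + 1))
            doms.append((dom, start, start + length - 1))
        bundle.domains[p] = doms

        go_risk_flag[p] = bool(rng.random() < config.go_risk_protein_prob)
        n_terms = int(rng.integers(3, 9))
        direct = set(rng.choice(background_terms, size=n_terms, replace=False).tolist())
        if go_risk_flag[p]:
            n_risk = int(rng.integers(2, min(5, len(risk_terms)) + 1))
            direct |= set(rng.choice(sorted(risk_terms), size=n_risk, replace=False).tolist())
        bundle.go_direct[p] = direct

    # --- per-protein pathogenic-allocation weight from the planted odds
    weights = np.array(
        [
            (config.group_enrichment_odds if bundle.kinase_group[p] in risk_groups else 1.0)
            * (config.go_enrichment_odds if go_risk_flag[p] else 1.0)
            for p in proteins
        ]
    )
    weights = weights / weights.sum()
    uniform = np.full(len(proteins), 1.0 / len(proteins))

    n_disease = int(rng.binomial(config.n_variants, config.disease_fraction))
    n_neutral = config.n_variants - n_disease

    p_in_domain = {
        "disease": config.domain_enrichment_odds / (config.domain_enrichment_odds + 1.0),
        "neutral": 0.5,
    }
    sift_mean = {"disease": 0.5 - config.sift_shift, "neutral": 0.5}
    site_prob = {"disease": config.site_hit_prob[0], "neutral": config.site_hit_prob[1]}

    seen: set[tuple[str, int, str, str]] = set()
    records: list[VariantRecord] = []
    for label, count, alloc in (
        ("disease", n_disease, weights),
        ("neutral", n_neutral, uniform),
    ):
        made = 0
        while made < count:
            p = proteins[int(rng.choice(len(proteins), p=alloc))]
            length = lengths[p]
            doms = bundle.domains[p]
            if doms and rng.random() < p_in_domain[label]:
                dom, start, end = doms[int(rng.integers(len(doms)))]
                pos = int(rng.integers(start, end + 1))
            else:
                pos = int(rng.integers(1, length + 1))
            wt, mut = rng.choice(AA, size=2, replace=False)
            key = (p, pos, str(wt), str(mut))
            if key in seen:
                continue
            seen.add(key)
            records.append(VariantRecord(p, pos, str(wt), str(mut), label))
            made += 1

            a, b = _beta_params(sift_mean[label])
            if rng.random() >= config.missing_sift_prob:
                bundle.sift[key] = float(np.round(rng.beta(a, b), 6))
            if rng.random() < site_prob[label]:
                cat = SITE_CATEGORIES[int(rng.integers(len(SITE_CATEGORIES)))]
                bundle.sites.setdefault((p, pos), set()).add(cat)

    order = rng.permutation(len(records))
    dataset = Dataset(
        [records[i] for i in order],
        provenance={"source": "synthetic", "config": dataclasses.asdict(config)},
    )

    ground_truth = {
        "risk_groups": sorted(risk_groups),
        "risk_terms": sorted(risk_terms),
        "n_disease": n_disease,
        "n_neutral": n_neutral,
        "config": dataclasses.asdict(config),
    }
    return dataset, bundle, graph, ground_truth


def write_fixture(directory: str | Path, config: GeneratorConfig) -> dict[str, Path]:
    """Generate and serialize a complete fixture directory.

    Writes ``variants.tsv``, the five annotation TSVs, ``ontology.obo`` and
    ``ground_truth.json`` in the canonical dialects.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset, bundle, graph, truth = generate(config)

    paths = write_annotations(bundle, directory)
    paths["variants"] = directory / "variants.tsv"
    write_variants(dataset, paths["variants"])
    paths["ontology"] = directory / "ontology.obo"
    write_ontology(graph, paths["ontology"])
    paths["ground_truth"] = directory / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
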