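"""Log-odds annotation features and the 25-element variant feature vector.

The classifier describes each substitution at three levels:

* **protein level** — the log2 odds ratio of disease vs neutral variant
  frequency for the protein's kinase group, and the sum of such ratios over
  every GO term annotating the protein (direct terms plus all ontology
  ancestors, ``sum_go_lor``);
* **domain level** — the sum of log-odds ratios over the domains whose
  intervals cover the variant position (``sum_pfam_lor``);
* **residue level** — the wild-type and mutant residues, the differences in
  hydrophobicity, volume, C-beta branching and formal charge they induce,
  the precomputed SIFT score, and binary flags for residue-level functional
  annotation (twelve UniProt site categories, Phospho.ELM phosphosites,
  FireDB functional residues, plus ``any_uniprot`` — the OR of the twelve
  UniProt flags).

Each per-category log-odds ratio is

    lor(c) = log2( ((d_c + xi) / D) / ((n_c + xi) / N) )

with d_c, n_c the disease/neutral variant counts in category c, D, N the
class totals, and pseudocount xi (default 1e-20) keeping the ratio finite
when one class count is zero.  With xi this small, a category observed only
with disease variants yields |lor| of order 60-70; these extremes are kept
as-is, faithful to the formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import ValidationError
from .io import (
    UNIPROT_SITE_CATEGORIES,
    AnnotationBundle,
    Dataset,
    VariantRecord,
)
from .ontology import OntologyGraph
from .scales import DEFAULT_SCALES, AminoAcidScales

DEFAULT_XI = 1e-20

#: Fixed, versioned order of the 25 semantic features.
FEATURE_ORDER: tuple[str, ...] = (
    "sum_go_lor",
    "sift_score",
    "kinase_group_lor",
    "sum_pfam_lor",
    "wt_aa",
    "mut_aa",
    "delta_hydrophobicity",
    "delta_volume",
    "delta_cbeta",
    "delta_charge",
    "firedb",
    "any_uniprot",
    "phosphoelm",
) + UNIPROT_SITE_CATEGORIES

FEATURE_ORDER_VERSION = "kinvar-25-v1"

CATEGORICAL_FEATURES = ("wt_aa", "mut_aa")


def log_odds(d: int, n: int, D: int, N: int, xi: float = DEFAULT_XI) -> float:
    """log2 odds ratio of disease vs neutral frequency with pseudocount."""
    if D < 1 or N < 1:
        raise ValidationError(f"class totals must be >= 1, got D={D}, N={N}")
    if not 0 <= d <= D or not 0 <= n <= N:
        raise ValidationError(f"counts out of range: d={d}/{D}, n={n}/{N}")
    if xi <= 0:
        raise ValidationError(f"pseudocount must be > 0, got {xi}")
    return math.log2(((d + xi) / D) / ((n + xi) / N))


@dataclass
class LogOddsTable:
    """Per-category log2 odds ratios with the counts they were built from.

    ``contributors`` records the variant keys whose labels entered any count,
    which lets cross-validation prove that no held-out variant leaked into a
    training-fold table.
    """

    kind: str  # "group" | "go" | "pfam"
    lor: dict[str, float]
    disease_counts: dict[str, int]
    neutral_counts: dict[str, int]
    disease_total: int
    neutral_total: int
    pseudocount: float = DEFAULT_XI
    contributors: set[tuple[str, int, str, str]] = field(default_factory=set)

    def get(self, category: str) -> float | None:
        return self.lor.get(category)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, self.lor[c], self.disease_counts.get(c, 0), self.neutral_counts.get(c, 0))
            for c in sorted(self.lor)
        ]
        return pd.DataFrame(rows, columns=["category", "lor", "disease_count", "neutral_count"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _variant_categories(
    kind: str,
    variant: VariantRecord,
    ann: AnnotationBundle,
    graph: OntologyGraph | None,
    go_cache: dict[str, frozenset[str]] | None = None,
) -> Iterable[str]:
    """Categories of ``kind`` that the variant counts toward / sums over."""
    if kind == "group":
        group = ann.group_of(variant.protein_id)
        return (group,) if group is not None else ()
    if kind == "go":
        if graph is None:
            raise ValidationError("GO table requires an ontology graph")
        if go_cache is not None and variant.protein_id in go_cache:
            return go_cache[variant.protein_id]
        expanded = graph.with_ancestors(ann.go_terms(variant.protein_id))
        if go_cache is not None:
            go_cache[variant.protein_id] = expanded
        return expanded
    if kind == "pfam":
        return ann.domains_at(variant.protein_id, variant.position)
    raise ValidationError(f"unknown log-odds table kind {kind!r}")


def build_lor_table(
    kind: str,
    data: Dataset,
    ann: AnnotationBundle,
    graph: OntologyGraph | None = None,
    xi: float = DEFAULT_XI,
) -> LogOddsTable:
    """Count disease/neutral variants per category and build the table.

    ``data`` must contain only disease/neutral labels.  A category with zero
    variants of both classes never enters the table (no evidence).  For
    ``kind="go"``, each protein's direct term set is first expanded with all
    ontology ancestors, so a variant increments every term up to the roots.
    """
    disease_counts: dict[str, int] = {}
    neutral_counts: dict[str, int] = {}
    contributors: set[tuple[str, int, str, str]] = set()
    D = N = 0
    go_cache: dict[str, frozenset[str]] = {}
    for v in data:
        if v.label == "disease":
            D += 1
            counts = disease_counts
        elif v.label == "neutral":
            N += 1
            counts = neutral_counts
        else:
            raise ValidationError(
                "log-odds tables are built from classified variants only; "
                f"got label {v.label!r} for {v.protein_id}:{v.position}"
            )
        cats = _variant_categories(kind, v, ann, graph, go_cache)
        if cats:
            contributors.add(v.key)
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
    if D < 1 or N < 1:
        raise ValidationError(
            f"both classes required to build a log-odds table (disease={D}, neutral={N})"
        )
    lor = {
        c: log_odds(disease_counts.get(c, 0), neutral_counts.get(c, 0), D, N, xi)
        for c in set(disease_counts) | set(neutral_counts)
    }
    return LogOddsTable(
        kind=kind,
        lor=lor,
        disease_counts=disease_counts,
        neutral_counts=neutral_counts,
        disease_total=D,
        neutral_total=N,
        pseudocount=xi,
        contributors=contributors,
    )


def sum_lor(table: LogOddsTable, categories: Iterable[str]) -> float:
    """Sum of stored log-odds over ``categories``; unseen categories add 0."""
    return float(sum(table.lor.get(c, 0.0) for c in categories))


def biochemical_deltas(
    wt: str, mut: str, scales: AminoAcidScales = DEFAULT_SCALES
) -> tuple[float, float, int, int]:
    """(delta_volume, delta_hydrophobicity, delta_cbeta, delta_charge), mutant minus wild-type."""
    for aa in (wt, mut):
        if aa not in scales.hydrophobicity:
            raise ValidationError(f"non-canonical residue {aa!r}")
    return (
        scales.volume[mut] - scales.volume[wt],
        scales.hydrophobicity[mut] - scales.hydrophobicity[wt],
        scales.cbeta_branching[mut] - scales.cbeta_branching[wt],
        scales.formal_charge[mut] - scales.formal_charge[wt],
    )


def featurize(
    variant: VariantRecord,
    ann: AnnotationBundle,
    graph: OntologyGraph,
    tables: dict[str, LogOddsTable],
    scales: AminoAcidScales = DEFAULT_SCALES,
    go_cache: dict[str, frozenset[str]] | None = None,
) -> dict:
    """The 25 semantic features for one variant, as an ordered mapping.

    ``tables`` maps ``{"group", "go", "pfam"}`` to fitted log-odds tables.
    A missing SIFT score is emitted as NaN; the classifier imputes it with
    its training-split median.  A protein absent from every annotation
    resource still yields a vector, with zero/empty defaults.
    """
    dvol, dhyd, dcb, dchg = biochemical_deltas(variant.wt_aa, variant.mut_aa, scales)

    group = ann.group_of(variant.protein_id)
    group_lor = tables["group"].lor.get(group, 0.0) if group is not None else 0.0
    go_terms = _variant_categories("go", variant, ann, graph, go_cache)
    go_sum = sum_lor(tables["go"], go_terms)
    pfam_sum = sum_lor(tables["pfam"], ann.domains_at(variant.protein_id, variant.position))

    sites = ann.sites_at(variant.protein_id, variant.position)
    uniprot_flags = {c: int(c in sites) for c in UNIPROT_SITE_CATEGORIES}
    sift = ann.sift_of(variant.key)

    row = {
        "sum_go_lor": go_sum,
        "sift_score": float("nan") if sift is None else float(sift),
        "kinase_group_lor": group_lor,
        "sum_pfam_lor": pfam_sum,
        "wt_aa": variant.wt_aa,
        "mut_aa": variant.mut_aa,
        "delta_hydrophobicity": dhyd,
        "delta_volume": dvol,
        "delta_cbeta": dcb,
        "delta_charge": dchg,
        "firedb": int("firedb" in sites),
        "any_uniprot": int(any(uniprot_flags.values())),
        "phosphoelm": int("phosphoelm" in sites),
        **uniprot_flags,
    }
    return {name: row[name] for name in FEATURE_ORDER}


class VariantFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from variant records to the 25-feature semantic matrix.

    ``fit`` builds the three log-odds tables (kinase group, ancestor-expanded
    GO terms, covering domains) from the *training* variants and their
    labels; ``transform`` evaluates any variant against those fitted tables.
    Categories never seen during fit contribute 0, so prediction is total.

    Parameters
    ----------
    annotations, ontology : resources the features are computed from.
    scales : amino-acid property scales (defaults to the published ones).
    xi : pseudocount for the log-odds ratios.
    """

    def __init__(
        self,
        annotations: AnnotationBundle | None = None,
        ontology: OntologyGraph | None = None,
        scales: AminoAcidScales = DEFAULT_SCALES,
        xi: float = DEFAULT_XI,
    ):
        self.annotations = annotations
        self.ontology = ontology
        self.scales = scales
        self.xi = xi

    @staticmethod
    def _as_dataset(X) -> Dataset:
        if isinstance(X, Dataset):
            return X
        if isinstance(X, pd.DataFrame):
            return Dataset(
                [
                    VariantRecord(
                        str(r.protein_id), int(r.position), str(r.wt_aa), str(r.mut_aa),
                        str(getattr(r, "label", "unclassified")),
                    )
                    for r in X.itertuples(index=False)
                ]
            )
        return Dataset(list(X))

    def fit(self, X, y=None):
        if self.annotations is None or self.ontology is None:
            raise ValidationError("VariantFeaturizer requires annotations and ontology")
        data = self._as_dataset(X)
        if y is not None:
            labelled = [
                VariantRecord(v.protein_id, v.position, v.wt_aa, v.mut_aa, str(label))
                for v, label in zip(data.variants, y, strict=True)
            ]
            data = Dataset(labelled)
        self.tables_ = {
            kind: build_lor_table(kind, data, self.annotations, self.ontology, self.xi)
            for kind in ("group", "go", "pfam")
        }
        self.feature_order_ = list(FEATURE_ORDER)
        self.feature_order_version_ = FEATURE_ORDER_VERSION
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "tables_"):
            raise ValidationError("VariantFeaturizer is not fitted")
        data = self._as_dataset(X)
        go_cache: dict[str, frozenset[str]] = {}
        rows = [
            featurize(v, self.annotations, self.ontology, self.tables_, self.scales, go_cache)
            for v in data
        ]
        index = X.index if isinstance(X, pd.DataFrame) else None
        frame = pd.DataFrame(rows, columns=list(FEATURE_ORDER), index=index)
        return frame


def write_feature_matrix(
    features: pd.DataFrame, dataset: Dataset, path: str | Path
) -> None:
    """Feature matrix TSV: variant key columns followed by the 25 features."""
    keys = dataset.to_frame()[["protein_id", "position", "wt_aa", "mut_aa"]]
    out = pd.concat([keys.reset_index(drop=True), features.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def has_signal_columns(frame: pd.DataFrame) -> bool:
    """True when the frame carries exactly the 25 semantic features in order."""
    return list(frame.columns) == list(FEATURE_ORDER)
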