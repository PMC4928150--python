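"""Readers, writers and validation for variant tables and annotation resources.

All tabular resources use plain tab-separated text with a header row:

* variants:    ``protein_id  position  wt_aa  mut_aa  label``
* GO table:    ``protein_id  term_id``
* group table: ``protein_id  group``
* domains:     ``protein_id  domain_id  start  end`` (1-based, inclusive)
* sites:       ``protein_id  position  category``
* SIFT scores: ``protein_id  position  wt_aa  mut_aa  score``

Coordinates are 1-based UniProt residue numbering throughout.  Only the 20
canonical amino acids are accepted; ambiguity/selenocysteine codes (B, Z, X,
U) are rejected at parse time because the physicochemical scales and the
classifier features are defined only for the canonical residues.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._exceptions import ParseError, ValidationError
from .ontology import OntologyGraph

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

LABELS = ("disease", "neutral", "unclassified")

#: Closed vocabulary of residue-level site categories: the twelve UniProt
#: feature categories plus phosphorylation sites (Phospho.ELM) and
#: catalytic/ligand-binding residues (FireDB).
UNIPROT_SITE_CATEGORIES = (
    "act_site",
    "binding",
    "carbohyd",
    "metal",
    "np_bind",
    "disulfid",
    "mod_res",
    "repeat",
    "signal",
    "transmem",
    "zn_fing",
    "site",
)
SITE_CATEGORIES = UNIPROT_SITE_CATEGORIES + ("phosphoelm", "firedb")

VARIANT_COLUMNS = ("protein_id", "position", "wt_aa", "mut_aa", "label")

# Label precedence when duplicate variant rows disagree: a pathogenic record
# wins outright; a classified (neutral) record beats an unclassified one.
_LABEL_RANK = {"disease": 0, "neutral": 1, "unclassified": 2}


@dataclass(frozen=True)
class VariantRecord:
    """One amino-acid substitution in a protein, optionally labelled."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    label: str = "unclassified"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in CANONICAL_AA:
                raise ValidationError(f"non-canonical amino acid code {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValidationError(
                f"synonymous record {self.protein_id}:{self.position}{self.wt_aa}"
            )
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")


@dataclass
class Dataset:
    """A deduplicated collection of variant records with provenance."""

    variants: list[VariantRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def proteins(self) -> set[str]:
        return {v.protein_id for v in self.variants}

    def labelled(self) -> "Dataset":
        """Subset with only disease/neutral records (training material)."""
        kept = [v for v in self.variants if v.label != "unclassified"]
        return Dataset(kept, dict(self.provenance, subset="labelled"))

    def subset(self, proteins: Iterable[str]) -> "Dataset":
        wanted = set(proteins)
        kept = [v for v in self.variants if v.protein_id in wanted]
        return Dataset(kept, dict(self.provenance, subset="by-protein"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.protein_id, v.position, v.wt_aa, v.mut_aa, v.label) for v in self.variants],
            columns=list(VARIANT_COLUMNS),
        )

    def class_counts(self) -> tuple[int, int]:
        """(disease, neutral) counts among labelled records."""
        d = sum(1 for v in self.variants if v.label == "disease")
        n = sum(1 for v in self.variants if v.label == "neutral")
        return d, n


@dataclass
class AnnotationBundle:
    """Per-protein and per-residue annotation resources.

    Lookups for proteins or residues absent from a resource return empty
    values rather than raising: missing annotation is ordinary, not an error.
    """

    kinase_group: dict[str, str] = field(default_factory=dict)
    go_direct: dict[str, set[str]] = field(default_factory=dict)
    domains: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    sites: dict[tuple[str, int], set[str]] = field(default_factory=dict)
    sift: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def group_of(self, protein_id: str) -> str | None:
        return self.kinase_group.get(protein_id)

    def go_terms(self, protein_id: str) -> set[str]:
        return self.go_direct.get(protein_id, set())

    def domains_of(self, protein_id: str) -> list[tuple[str, int, int]]:
        return self.domains.get(protein_id, [])

    def domains_at(self, protein_id: str, position: int) -> set[str]:
        """Domain ids whose 1-based inclusive interval covers ``position``."""
        return {
            dom for dom, start, end in self.domains.get(protein_id, [])
            if start <= position <= end
        }

    def sites_at(self, protein_id: str, position: int) -> set[str]:
        return self.sites.get((protein_id, position), set())

    def sift_of(self, key: tuple[str, int, str, str]) -> float | None:
        return self.sift.get(key)


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_tsv(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df[list(columns)]


def _parse_int(value: str, path: Path, line: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{line}: {what} {value!r} is not an integer") from None


def read_variants(path: str | Path, dialect: str = "canonical") -> Dataset:
    """Read and deduplicate a variant table.

    Duplicate ``(protein_id, position, wt_aa, mut_aa)`` keys collapse to one
    record.  When duplicate labels conflict, a pathogenic instance is kept if
    present; otherwise a classified (neutral) label beats unclassified;
    otherwise the first-seen label stands.  Every collapse is logged in the
    returned provenance.
    """
    if dialect != "canonical":
        raise ValidationError(f"unknown variant dialect {dialect!r}")
    path = Path(path)
    df = _read_tsv(path, VARIANT_COLUMNS)

    order: list[tuple] = []
    best: dict[tuple, VariantRecord] = {}
    dedup_log: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pos = _parse_int(row.position, path, i, "position")
        try:
            rec = VariantRecord(row.protein_id, pos, row.wt_aa, row.mut_aa, row.label)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{i}: {exc}") from None
        if rec.key not in best:
            best[rec.key] = rec
            order.append(rec.key)
        else:
            prev = best[rec.key]
            if _LABEL_RANK[rec.label] < _LABEL_RANK[prev.label]:
                best[rec.key] = rec
                dedup_log.append(
                    f"{rec.protein_id}:{rec.position}{rec.wt_aa}>{rec.mut_aa}: "
                    f"kept {rec.label!r} over {prev.label!r}"
                )
            else:
                dedup_log.append(
                    f"{rec.protein_id}:{rec.position}{rec.wt_aa}>{rec.mut_aa}: "
                    f"kept {prev.label!r}, dropped {rec.label!r}"
                )
    provenance = {
        "source": str(path),
        "sha256": _file_digest(path),
        "rows_read": len(df),
        "dedup": dedup_log,
    }
    return Dataset([best[k] for k in order], provenance)


def write_variants(dataset: Dataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def read_annotations(
    paths: dict[str, str | Path],
    ontology: OntologyGraph | None = None,
) -> AnnotationBundle:
    """Assemble an :class:`AnnotationBundle` from per-resource TSV files.

    ``paths`` maps resource names (``groups``, ``go``, ``domains``, ``sites``,
    ``sift``) to file paths; any resource may be omitted.  GO terms absent
    from ``ontology`` (when given) are rejected so that downstream ancestor
    expansion is total.
    """
    bundle = AnnotationBundle()

    if "groups" in paths:
        df = _read_tsv(paths["groups"], ("protein_id", "group"))
        for row in df.itertuples(index=False):
            bundle.kinase_group[row.protein_id] = row.group

    if "go" in paths:
        p = Path(paths["go"])
        df = _read_tsv(p, ("protein_id", "term_id"))
        for i, row in enumerate(df.itertuples(index=False), start=2):
            if ontology is not None and row.term_id not in ontology.terms:
                raise ValidationError(f"{p}:{i}: term {row.term_id!r} not in ontology")
            bundle.go_direct.setdefault(row.protein_id, set()).add(row.term_id)

    if "domains" in paths:
        p = Path(paths["domains"])
        df = _read_tsv(p, ("protein_id", "domain_id", "start", "end"))
        for i, row in enumerate(df.itertuples(index=False), start=2):
            start = _parse_int(row.start, p, i, "start")
            end = _parse_int(row.end, p, i, "end")
            if not (1 <= start <= end):
                raise ValidationError(f"{p}:{i}: bad interval [{start}, {end}]")
            bundle.domains.setdefault(row.protein_id, []).append((row.domain_id, start, end))

    if "sites" in paths:
        p = Path(paths["sites"])
        df = _read_tsv(p, ("protein_id", "position", "category"))
        for i, row in enumerate(df.itertuples(index=False), start=2):
            pos = _parse_int(row.position, p, i, "position")
            if row.category not in SITE_CATEGORIES:
                raise ValidationError(f"{p}:{i}: unknown site category {row.category!r}")
            bundle.sites.setdefault((row.protein_id, pos), set()).add(row.category)

    if "sift" in paths:
        p = Path(paths["sift"])
        df = _read_tsv(p, ("protein_id", "position", "wt_aa", "mut_aa", "score"))
        for i, row in enumerate(df.itertuples(index=False), start=2):
            pos = _parse_int(row.position, p, i, "position")
            try:
                score = float(row.score)
            except ValueError:
                raise ParseError(f"{p}:{i}: score {row.score!r} is not a number") from None
            if not (0.0 <= score <= 1.0):
                raise ValidationError(f"{p}:{i}: sift score {score} outside [0, 1]")
            bundle.sift[(row.protein_id, pos, row.wt_aa, row.mut_aa)] = score

    return bundle


def write_annotations(bundle: AnnotationBundle, directory: str | Path) -> dict[str, Path]:
    """Serialize a bundle back to the canonical TSV dialects (round-trip aid)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["groups"] = directory / "groups.tsv"
    pd.DataFrame(
        sorted(bundle.kinase_group.items()), columns=["protein_id", "group"]
    ).to_csv(paths["groups"], sep="\t", index=False)

    paths["go"] = directory / "go.tsv"
    rows = [(p, t) for p, terms in sorted(bundle.go_direct.items()) for t in sorted(terms)]
    pd.DataFrame(rows, columns=["protein_id", "term_id"]).to_csv(
        paths["go"], sep="\t", index=False
    )

    paths["domains"] = directory / "domains.tsv"
    rows = [
        (p, d, s, e)
        for p, doms in sorted(bundle.domains.items())
        for d, s, e in sorted(doms)
    ]
    pd.DataFrame(rows, columns=["protein_id", "domain_id", "start", "end"]).to_csv(
        paths["domains"], sep="\t", index=False
    )

    paths["sites"] = directory / "sites.tsv"
    rows = [
        (p, pos, c)
        for (p, pos), cats in sorted(bundle.sites.items())
        for c in sorted(cats)
    ]
    pd.DataFrame(rows, columns=["protein_id", "position", "category"]).to_csv(
        paths["sites"], sep="\t", index=False
    )

    paths["sift"] = directory / "sift.tsv"
    rows = [
        (p, pos, wt, mut, format(score, ".6g"))
        for (p, pos, wt, mut), score in sorted(bundle.sift.items())
    ]
    pd.DataFrame(rows, columns=["protein_id", "position", "wt_aa", "mut_aa", "score"]).to_csv(
        paths["sift"], sep="\t", index=False
    )

    return paths
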