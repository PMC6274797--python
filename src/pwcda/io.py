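"""Plain-text I/O: association tables, annotation catalogs, scores and ROC points.

File formats
------------
Association file
    Delimited text with columns ``circRNA_id, disease_id[, species]``.
    Lines starting with ``#`` are comments. Identifiers are normalized by
    trimming surrounding whitespace and case-folding, so ``"C1 "`` and
    ``"c1"`` name the same entity; no alias resolution beyond that is
    attempted. Entity order is first-appearance order, which makes every
    derived matrix reproducible without sorting assumptions.

Annotation file
    Delimited text with columns ``entity_id, term_id`` (GO terms for
    circRNAs, disease-gene annotation ids for diseases). Repeated lines
    collapse into a set.

The binary association matrix ``M`` has diseases as rows and circRNAs as
columns: ``M[i, j] = 1`` iff disease *i* and circRNA *j* form a verified
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A delimited input line could not be parsed."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def normalize_id(raw: str) -> str:
    """Canonical form of an identifier: trimmed and case-folded."""
    return raw.strip().casefold()


@dataclass(frozen=True)
class AssociationRecord:
    """One raw association line: circRNA, disease and optional species tag."""

    circ_id: str
    disease_id: str
    species: str | None = None


@dataclass
class AssociationTable:
    """Verified circRNA-disease pairs with stable entity orderings.

    ``pairs`` holds ``(disease_index, circ_index)`` tuples indexing into
    ``disease_ids`` and ``circ_ids`` respectively.
    """

    circ_ids: list[str]
    disease_ids: list[str]
    pairs: set[tuple[int, int]]

    def __post_init__(self):
        if len(set(self.circ_ids)) != len(self.circ_ids):
            raise ValueError("duplicate circRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        for i, j in self.pairs:
            if not (0 <= i < len(self.disease_ids) and 0 <= j < len(self.circ_ids)):
                raise ValueError(f"pair index ({i}, {j}) out of range")

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_ids(self) -> set[tuple[str, str]]:
        """Pairs as ``(disease_id, circ_id)`` identifier tuples."""
        return {(self.disease_ids[i], self.circ_ids[j]) for i, j in self.pairs}

    @classmethod
    def from_records(cls, records: Iterable[AssociationRecord]) -> "AssociationTable":
        circ_ids: list[str] = []
        disease_ids: list[str] = []
        circ_index: dict[str, int] = {}
        dis_index: dict[str, int] = {}
        pairs: set[tuple[int, int]] = set()
        for rec in records:
            c = normalize_id(rec.circ_id)
            d = normalize_id(rec.disease_id)
            if c not in circ_index:
                circ_index[c] = len(circ_ids)
                circ_ids.append(c)
            if d not in dis_index:
                dis_index[d] = len(disease_ids)
                disease_ids.append(d)
            pairs.add((dis_index[d], circ_index[c]))
        return cls(circ_ids=circ_ids, disease_ids=disease_ids, pairs=pairs)


@dataclass
class AssociationMatrix:
    """Binary disease × circRNA matrix derived from an :class:`AssociationTable`."""

    values: np.ndarray
    row_ids: list[str]  # diseases
    col_ids: list[str]  # circRNAs

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix must be binary")


@dataclass
class AnnotationCatalog:
    """Entity id → finite set of annotation-term ids (possibly empty)."""

    entity_ids: list[str]
    term_sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids in catalog")

    def terms(self, entity_id: str) -> frozenset[str]:
        """Term set for an entity; entities never mentioned get the empty set."""
        return self.term_sets.get(normalize_id(entity_id), frozenset())


#: recognised first-column header names (a header row is optional on input)
_HEADER_FIRST_FIELDS = {"circrna_id", "entity_id", "disease_id"}


def _iter_lines(path, delimiter: str, min_fields: int):
    path = Path(path)
    any_data = False
    first_data_line = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if first_data_line and normalize_id(fields[0]) in _HEADER_FIRST_FIELDS:
                first_data_line = False
                continue
            first_data_line = False
            if len(fields) < min_fields or any(f == "" for f in fields[:min_fields]):
                raise ParseError(
                    path, lineno, f"expected at least {min_fields} non-empty fields, got {fields!r}"
                )
            any_data = True
            yield lineno, fields
    if not any_data:
        raise ParseError(path, 0, "file contains no data lines")


def read_association_records(path, delimiter: str = ",") -> list[AssociationRecord]:
    """Read raw association lines, keeping the optional species column."""
    records = []
    for _lineno, fields in _iter_lines(path, delimiter, 2):
        species = fields[2] if len(fields) >= 3 and fields[2] else None
        records.append(AssociationRecord(fields[0], fields[1], species))
    return records


def read_association_table(path, delimiter: str = ",") -> AssociationTable:
    """Read a delimited association file into an :class:`AssociationTable`.

    Duplicate lines (after id normalization) collapse to a single pair; id
    ordering is first-appearance order.
    """
    return AssociationTable.from_records(read_association_records(path, delimiter))


def filter_by_species(
    records: Sequence[AssociationRecord], species: str
) -> AssociationTable:
    """Keep only records whose species tag matches (case-insensitively).

    Raises if any record lacks a species column (skip filtering instead) or
    if no record survives (downstream stages need at least one pair).
    """
    if any(rec.species is None for rec in records):
        raise ValueError(
            "species column absent from one or more records; skip species filtering"
        )
    wanted = normalize_id(species)
    kept = [rec for rec in records if normalize_id(rec.species) == wanted]
    if not kept:
        raise ValueError(f"no records with species {species!r}; table would be empty")
    return AssociationTable.from_records(kept)


def build_association_matrix(table: AssociationTable) -> AssociationMatrix:
    """Binary matrix M, diseases × circRNAs, M[i, j] = 1 iff (i, j) is a pair."""
    if table.n_pairs == 0:
        raise ValueError("association table has no pairs")
    m = np.zeros((table.n_diseases, table.n_circ), dtype=float)
    for i, j in table.pairs:
        m[i, j] = 1.0
    return AssociationMatrix(m, list(table.disease_ids), list(table.circ_ids))


def read_annotation_catalog(path, delimiter: str = ",") -> AnnotationCatalog:
    """Read a two-column ``entity_id, term_id`` file, grouping terms per entity."""
    entity_ids: list[str] = []
    sets: dict[str, set[str]] = {}
    try:
        lines = list(_iter_lines(path, delimiter, 2))
    except ParseError as err:
        if err.lineno == 0:  # empty catalog is valid: everything falls back to GIP
            return AnnotationCatalog(entity_ids=[], term_sets={})
        raise
    for _lineno, fields in lines:
        ent = normalize_id(fields[0])
        if ent not in sets:
            sets[ent] = set()
            entity_ids.append(ent)
        sets[ent].add(fields[1].strip())
    return AnnotationCatalog(
        entity_ids=entity_ids, term_sets={k: frozenset(v) for k, v in sets.items()}
    )


def write_association_table(path, table: AssociationTable, delimiter: str = ",") -> None:
    with Path(path).open("w") as fh:
        fh.write(delimiter.join(["circRNA_id", "disease_id"]) + "\n")
        for i, j in sorted(table.pairs):
            fh.write(delimiter.join([table.circ_ids[j], table.disease_ids[i]]) + "\n")


def write_annotation_catalog(path, catalog: AnnotationCatalog, delimiter: str = ",") -> None:
    with Path(path).open("w") as fh:
        fh.write(delimiter.join(["entity_id", "term_id"]) + "\n")
        for ent in catalog.entity_ids:
            for term in sorted(catalog.term_sets.get(ent, frozenset())):
                fh.write(delimiter.join([ent, term]) + "\n")


def write_score_matrix(path, scores) -> None:
    """Write a score matrix (header = circRNA ids, first column = disease id).

    ``scores`` is any object with ``values`` (diseases × circRNAs),
    ``disease_ids`` and ``circ_ids`` attributes.
    """
    df = pd.DataFrame(scores.values, index=scores.disease_ids, columns=scores.circ_ids)
    df.to_csv(path, index_label="disease_id")


def read_score_matrix(path) -> pd.DataFrame:
    """Read a score matrix written by :func:`write_score_matrix`."""
    return pd.read_csv(path, index_col="disease_id", float_precision="round_trip")


def write_roc_points(path, roc) -> None:
    """Write ROC sweep points as ``threshold, FPR, TPR`` rows."""
    df = pd.DataFrame(
        {"threshold": roc.thresholds, "FPR": roc.fpr, "TPR": roc.tpr}
    )
    df.to_csv(path, index=False)


def ranked_predictions(scores, known_pairs: set[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Rank all (disease, circRNA) pairs by descending score.

    Ties break by ``(disease_id, circRNA_id)`` lexicographic order so output
    is deterministic. ``known_pairs`` (as ``(disease_id, circ_id)`` tuples)
    flags already-verified associations in an extra column.
    """
    rows = []
    for i, d in enumerate(scores.disease_ids):
        for j, c in enumerate(scores.circ_ids):
            rows.append((d, c, float(scores.values[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    df = pd.DataFrame(rows, columns=["disease_id", "circRNA_id", "score"])
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    if known_pairs is not None:
        df["known"] = [
            (d, c) in known_pairs for d, c in zip(df["disease_id"], df["circRNA_id"])
        ]
    return df


def write_ranked_predictions(path, scores, known_pairs=None) -> None:
    ranked_predictions(scores, known_pairs).to_csv(
        path, index=False)
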