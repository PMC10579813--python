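"""Reading, cleaning, standardizing and vectorizing clinical symptom records.

A record is a set of symptom terms plus a set of syndrome labels. This module
turns delimited-text record files into the design matrix ``X`` (binary or
TF-IDF) and the binary label matrix ``Y`` consumed by the selection and
cascade stages, and writes every tabular artifact back out as plain text.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.preprocessing import normalize

logger = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "Record",
    "RecordSet",
    "SynonymDictionary",
    "FeatureSpace",
    "LabelMatrix",
    "read_records",
    "write_records",
    "read_synonyms",
    "clean_and_merge",
    "standardize",
    "vectorize",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class Dialect:
    """Layout of a delimited record file.

    ``field_sep`` separates columns, ``term_sep`` separates terms inside a
    cell. With ``has_id`` the first column carries the record id; otherwise
    ids ``r000001, r000002, ...`` are assigned by line order.
    """

    field_sep: str = "\t"
    term_sep: str = "|"
    has_header: bool = False
    has_id: bool = False


@dataclass(frozen=True)
class Record:
    record_id: str
    symptoms: frozenset[str]
    labels: frozenset[str]


@dataclass
class RecordSet:
    records: list[Record]

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordSet):
            return NotImplemented
        return self.records == other.records


@dataclass
class SynonymDictionary:
    """Maps variant symptom spellings to their standard term.

    The mapping must be idempotent: one application is final. Chains such as
    ``{a: b, b: c}`` are accepted with a warning; ``a`` still maps to ``b``
    only (apply-once semantics).
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        chained = [v for v in self.mapping.values() if v in self.mapping and self.mapping[v] != v]
        if chained:
            warnings.warn(
                f"synonym dictionary is not idempotent; {len(chained)} standard "
                f"terms are themselves remapped (e.g. {chained[0]!r}); "
                "terms are mapped once only",
                stacklevel=2,
            )

    def apply(self, term: str) -> str:
        return self.mapping.get(term, term)


@dataclass
class FeatureSpace:
    """Design matrix with its term index and per-feature value ranges."""

    X: np.ndarray
    feature_names: list[str]
    feature_min: np.ndarray
    feature_max: np.ndarray

    def __post_init__(self) -> None:
        n, f = self.X.shape
        if len(self.feature_names) != f:
            raise ValueError("feature_names length does not match X")
        if np.any(self.feature_min > self.feature_max):
            raise ValueError("feature_min exceeds feature_max")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class LabelMatrix:
    """Binary label matrix with label names and empirical priors P(C)."""

    Y: np.ndarray
    label_names: list[str]
    priors: np.ndarray

    def __post_init__(self) -> None:
        if len(self.label_names) != self.Y.shape[1]:
            raise ValueError("label_names length does not match Y")
        if np.any((self.priors <= 0) | (self.priors > 1)):
            raise ValueError("label priors must lie in (0, 1]")

    @property
    def n_labels(self) -> int:
        return self.Y.shape[1]


def _split_cell(cell: str, sep: str) -> frozenset[str]:
    return frozenset(t.strip() for t in cell.split(sep) if t.strip())


def read_records(path: str | Path, dialect: Dialect = Dialect()) -> RecordSet:
    """Parse a delimited record file verbatim — no cleaning is applied here.

    Rows with empty symptom or label cells are retained (removal belongs to
    :func:`clean_and_merge`). Malformed rows raise with their line number.
    """
    path = Path(path)
    expected = 3 if dialect.has_id else 2
    records: list[Record] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.field_sep)
        for lineno, row in enumerate(reader, start=1):
            if dialect.has_header and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != expected:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected} fields, got {len(row)}"
                )
            if dialect.has_id:
                rid, sym_cell, lab_cell = row
            else:
                rid = f"r{lineno:06d}"
                sym_cell, lab_cell = row
            records.append(
                Record(rid, _split_cell(sym_cell, dialect.term_sep), _split_cell(lab_cell, dialect.term_sep))
            )
    return RecordSet(records)


def write_records(rs: RecordSet, path: str | Path, dialect: Dialect = Dialect(has_id=True)) -> None:
    """Write records as delimited text; terms are sorted for determinism."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.field_sep, lineterminator="\n")
        if dialect.has_header:
            cols = ["record_id"] if dialect.has_id else []
            writer.writerow(cols + ["symptoms", "labels"])
        for r in rs.records:
            cells = [
                dialect.term_sep.join(sorted(r.symptoms)),
                dialect.term_sep.join(sorted(r.labels)),
            ]
            if dialect.has_id:
                cells.insert(0, r.record_id)
            writer.writerow(cells)


def read_synonyms(path: str | Path, field_sep: str = "\t") -> SynonymDictionary:
    """Read a two-column variant -> standard term dictionary."""
    mapping: dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=field_sep), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
            mapping[row[0].strip()] = row[1].strip()
    return SynonymDictionary(mapping)


def clean_and_merge(rs: RecordSet) -> RecordSet:
    """Drop records missing symptoms or labels; merge identical presentations.

    Records whose symptom sets are identical are collapsed into a single
    record carrying the union of their label sets (this is how single-label
    duplicates become one multi-label record). The surviving record keeps the
    first-seen id. Idempotent.
    """
    kept = [r for r in rs.records if r.symptoms and r.labels]
    n_dropped = len(rs.records) - len(kept)
    merged: dict[frozenset[str], Record] = {}
    for r in kept:
        prev = merged.get(r.symptoms)
        if prev is None:
            merged[r.symptoms] = r
        else:
            merged[r.symptoms] = Record(prev.record_id, prev.symptoms, prev.labels | r.labels)
    out = list(merged.values())
    logger.info(
        "clean_and_merge: dropped %d incomplete records, merged %d duplicates, %d remain",
        n_dropped,
        len(kept) - len(out),
        len(out),
    )
    if not out:
        raise ValueError("no records remain after cleaning")
    return RecordSet(out)


def standardize(rs: RecordSet, syn: SynonymDictionary) -> RecordSet:
    """Map every symptom term through the synonym dictionary (applied once)."""
    unmapped: set[str] = set()
    records = []
    for r in rs.records:
        mapped = set()
        for t in r.symptoms:
            if t not in syn.mapping:
                unmapped.add(t)
            mapped.add(syn.apply(t))
        records.append(Record(r.record_id, frozenset(mapped), r.labels))
    if syn.mapping:
        logger.info("standardize: %d distinct terms had no dictionary entry", len(unmapped))
    return RecordSet(records)


def vectorize(rs: RecordSet, scheme: str = "tfidf") -> tuple[FeatureSpace, LabelMatrix]:
    """Build the design matrix X and label matrix Y from cleaned records.

    ``binary`` gives a 0/1 presence matrix. ``tfidf`` weights presence by the
    smoothed inverse document frequency ``ln((1+n)/(1+df)) + 1`` and
    L2-normalizes each row. Terms and labels are column-ordered by sorted
    name; every retained column occurs in at least one record.
    """
    if scheme not in ("tfidf", "binary"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if not rs.records:
        raise ValueError("empty record set")
    for r in rs.records:
        if not r.symptoms or not r.labels:
            raise ValueError(f"record {r.record_id} is not cleaned (empty symptoms or labels)")

    terms = sorted(set().union(*(r.symptoms for r in rs.records)))
    labels = sorted(set().union(*(r.labels for r in rs.records)))
    t_idx = {t: i for i, t in enumerate(terms)}
    l_idx = {l: i for i, l in enumerate(labels)}

    n = len(rs.records)
    X = np.zeros((n, len(terms)))
    Y = np.zeros((n, len(labels)), dtype=np.int8)
    for i, r in enumerate(rs.records):
        for t in r.symptoms:
            X[i, t_idx[t]] = 1.0
        for l in r.labels:
            Y[i, l_idx[l]] = 1

    if scheme == "tfidf":
        df = X.sum(axis=0)
        idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
        X = normalize(X * idf, norm="l2", axis=1)

    fs = FeatureSpace(X, terms, X.min(axis=0), X.max(axis=0))
    lm = LabelMatrix(Y, labels, Y.mean(axis=0))
    return fs, lm


def write_matrix(M: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Write a matrix as sparse text triplets (row, col, value) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows, cols = np.nonzero(M)
    with path.open("w", encoding="utf-8") as fh:
        for i, j in zip(rows, cols):
            fh.write(f"{i}\t{j}\t{M[i, j]:.12g}\n")
    sidecar = {"shape": list(M.shape), "nnz": int(len(rows))}
    sidecar.update(meta or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    M = np.zeros(tuple(sidecar["shape"]))
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            i, j, v = line.split("\t")
            M[int(i), int(j)] = float(v)
    return M


def write_name_index(names: Sequence[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{i}\t{n}\n" for i, n in enumerate(names)), encoding="utf-8")
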