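"""Data model and I/O for primary-study 2x2 tables and meta-analysis corpora.

A corpus is stored as long-format delimited text (comma default, tab
accepted), one row per primary study, with either raw counts::

    meta_id, study_id, tp, fp, fn, tn

or accuracy fractions plus group sizes, from which counts are
reconstructed::

    meta_id, study_id, n_diseased, n_nondiseased, sensitivity, specificity

An optional ``label`` column carries a free-text description per
meta-analysis.  Lines starting with ``#`` are comments; a leading
``# provenance: ...`` line is captured into :attr:`Corpus.provenance`.
"""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass, field

from .exceptions import CorpusFormatError, CorpusValidationError

__all__ = [
    "StudyTable",
    "MetaAnalysis",
    "Corpus",
    "reconstruct_table",
    "read_corpus",
    "write_corpus",
]

COUNT_COLUMNS = ("tp", "fp", "fn", "tn")
FRACTION_COLUMNS = ("n_diseased", "n_nondiseased", "sensitivity", "specificity")


@dataclass(frozen=True)
class StudyTable:
    """One primary study's 2x2 contingency table.

    Parameters
    ----------
    study_id : str
        Label unique within its meta-analysis.
    tp, fp, fn, tn : int
        True positive, false positive, false negative and true negative
        counts.  All must be non-negative, and each disease group must
        contain at least one participant.
    """

    study_id: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in COUNT_COLUMNS:
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise CorpusValidationError(
                    f"study {self.study_id!r}: {name} must be an integer, got {value!r}"
                )
            if value < 0:
                raise CorpusValidationError(
                    f"study {self.study_id!r}: {name} must be non-negative, got {value}"
                )
        if self.n_diseased < 1:
            raise CorpusValidationError(
                f"study {self.study_id!r}: tp + fn must be >= 1"
            )
        if self.n_nondiseased < 1:
            raise CorpusValidationError(
                f"study {self.study_id!r}: fp + tn must be >= 1"
            )

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn

    @property
    def n_total(self) -> int:
        return self.n_diseased + self.n_nondiseased

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_diseased

    @property
    def specificity(self) -> float:
        return self.tn / self.n_nondiseased


@dataclass(frozen=True)
class MetaAnalysis:
    """An identified, ordered collection of primary studies."""

    meta_id: str
    studies: tuple[StudyTable, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        if len(self.studies) < 1:
            raise CorpusValidationError(
                f"meta-analysis {self.meta_id!r} must contain at least one study"
            )
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(
                f"meta-analysis {self.meta_id!r}: duplicate study_id values {dup}"
            )

    @property
    def k(self) -> int:
        return len(self.studies)


@dataclass(frozen=True)
class Corpus:
    """A collection of meta-analyses with a provenance note."""

    metas: tuple[MetaAnalysis, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "metas", tuple(self.metas))
        ids = [m.meta_id for m in self.metas]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(f"duplicate meta_id values {dup}")

    def __len__(self) -> int:
        return len(self.metas)

    def __iter__(self):
        return iter(self.metas)

    def get(self, meta_id: str) -> MetaAnalysis:
        for m in self.metas:
            if m.meta_id == meta_id:
                return m
        raise KeyError(meta_id)


def _round_half_even(x: float) -> int:
    # Snap values within 1e-9 of an exact half so that e.g. 0.45 * 10,
    # which is not representable in binary, still rounds like 4.5.
    nearest_half = math.floor(x) + 0.5
    if abs(x - nearest_half) < 1e-9:
        x = nearest_half
    return int(round(x))


def reconstruct_table(
    n_diseased: int,
    n_nondiseased: int,
    sensitivity: float,
    specificity: float,
    study_id: str = "",
) -> StudyTable:
    """Rebuild a 2x2 table from group sizes and accuracy fractions.

    tp = round(sensitivity * n_diseased) and tn = round(specificity *
    n_nondiseased), using round-half-to-even; the remaining cells are
    the group complements.
    """
    if n_diseased < 1 or n_nondiseased < 1:
        raise CorpusValidationError(
            f"study {study_id!r}: group sizes must be >= 1, "
            f"got ({n_diseased}, {n_nondiseased})"
        )
    for name, frac in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= frac <= 1.0):
            raise CorpusValidationError(
                f"study {study_id!r}: {name} must be in [0, 1], got {frac}"
            )
    tp = _round_half_even(sensitivity * n_diseased)
    tn = _round_half_even(specificity * n_nondiseased)
    return StudyTable(
        study_id=study_id,
        tp=tp,
        fn=n_diseased - tp,
        tn=tn,
        fp=n_nondiseased - tn,
    )


def _resolve_columns(header: list[str], columns: dict[str, str] | None):
    """Map canonical column names onto the file header.

    Returns (mode, mapping) where mode is 'counts' or 'fractions'.
    """
    mapping = {name: name for name in
               ("meta_id", "study_id", "label") + COUNT_COLUMNS + FRACTION_COLUMNS}
    if columns:
        mapping.update(columns)
    present = set(header)
    for required in ("meta_id", "study_id"):
        if mapping[required] not in present:
            raise CorpusFormatError(
                f"missing required column {mapping[required]!r}; header is {header}"
            )
    has_counts = all(mapping[c] in present for c in COUNT_COLUMNS)
    has_fracs = all(mapping[c] in present for c in FRACTION_COLUMNS)
    if has_counts:
        return "counts", mapping
    if has_fracs:
        return "fractions", mapping
    raise CorpusFormatError(
        "need either count columns "
        f"{[mapping[c] for c in COUNT_COLUMNS]} or fraction columns "
        f"{[mapping[c] for c in FRACTION_COLUMNS]}; header is {header}"
    )


def _parse_int(row: dict, col: str, lineno: int) -> int:
    raw = row.get(col, "")
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise CorpusValidationError(
            f"line {lineno}: column {col!r} must be an integer, got {raw!r}"
        ) from None
    return value


def _parse_float(row: dict, col: str, lineno: int) -> float:
    raw = row.get(col, "")
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise CorpusValidationError(
            f"line {lineno}: column {col!r} must be a number, got {raw!r}"
        ) from None


def read_corpus(path: str | os.PathLike, columns: dict[str, str] | None = None) -> Corpus:
    """Read a corpus from delimited text (comma or tab separated).

    ``columns`` optionally remaps canonical column names to the names
    used in the file, e.g. ``{"tp": "true_pos"}``.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()

    provenance = ""
    lines = text.splitlines()
    data_lines: list[tuple[int, str]] = []  # (1-based lineno, content)
    for i, line in enumerate(lines, start=1):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("provenance:"):
                provenance = stripped.split(":", 1)[1].strip()
            continue
        if line.strip():
            data_lines.append((i, line))
    if not data_lines:
        raise CorpusFormatError(f"{path}: no header line found")

    header_lineno, header_line = data_lines[0]
    delimiter = "\t" if "\t" in header_line else ","
    reader = csv.DictReader(
        io.StringIO("\n".join(l for _, l in data_lines)), delimiter=delimiter
    )
    header = [h.strip() for h in (reader.fieldnames or [])]
    mode, mapping = _resolve_columns(header, columns)

    metas: dict[str, list[StudyTable]] = {}
    labels: dict[str, str] = {}
    order: list[str] = []
    for offset, row in enumerate(reader):
        lineno = data_lines[offset + 1][0]
        meta_id = (row.get(mapping["meta_id"]) or "").strip()
        study_id = (row.get(mapping["study_id"]) or "").strip()
        if not meta_id or not study_id:
            raise CorpusValidationError(
                f"line {lineno}: meta_id and study_id must be non-empty"
            )
        try:
            if mode == "counts":
                table = StudyTable(
                    study_id=study_id,
                    tp=_parse_int(row, mapping["tp"], lineno),
                    fp=_parse_int(row, mapping["fp"], lineno),
                    fn=_parse_int(row, mapping["fn"], lineno),
                    tn=_parse_int(row, mapping["tn"], lineno),
                )
            else:
                table = reconstruct_table(
                    n_diseased=_parse_int(row, mapping["n_diseased"], lineno),
                    n_nondiseased=_parse_int(row, mapping["n_nondiseased"], lineno),
                    sensitivity=_parse_float(row, mapping["sensitivity"], lineno),
                    specificity=_parse_float(row, mapping["specificity"], lineno),
                    study_id=study_id,
                )
        except CorpusValidationError as exc:
            raise CorpusValidationError(f"line {lineno}: {exc}") from None
        if meta_id not in metas:
            metas[meta_id] = []
            order.append(meta_id)
        metas[meta_id].append(table)
        label = (row.get(mapping["label"]) or "").strip()
        if label:
            labels[meta_id] = label

    return Corpus(
        metas=tuple(
            MetaAnalysis(meta_id=m, studies=tuple(metas[m]), label=labels.get(m, ""))
            for m in order
        ),
        provenance=provenance,
    )


def write_corpus(corpus: Corpus, path: str | os.PathLike) -> None:
    """Write a corpus in the canonical counts-mode CSV format.

    ``read_corpus(write_corpus(c))`` reproduces ``c`` exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if corpus.provenance:
            fh.write(f"# provenance: {corpus.provenance}\n")
        writer = csv.writer(fh)
        writer.writerow(["meta_id", "study_id", "tp", "fp", "fn", "tn", "label"])
        for meta in corpus:
            for s in meta.studies:
                writer.writerow(
                    [meta.meta_id, s.study_id, s.tp, s.fp, s.fn, s.tn, meta.label]
                )
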