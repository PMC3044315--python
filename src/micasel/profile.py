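"""Expression-matrix container and delimited-text I/O.

The canonical in-memory orientation is samples-by-genes: a profile with *p*
biological samples measured on *n* genes is a ``p x n`` matrix whose rows are
samples.  Files on disk may be oriented either way; the reader transposes
genes-by-samples input into the canonical form.  Gene order is significant for
everything downstream (the wavelet transform runs along the gene axis), so the
loader never re-sorts genes unless explicitly asked to.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError, FormatError, LabelError, ParseError

logger = logging.getLogger(__name__)

_DELIMITERS = ("\t", ",")


def _sniff_delimiter(header_line: str) -> str:
    # tab wins over comma so gene descriptions containing commas survive
    for d in _DELIMITERS:
        if d in header_line:
            return d
    return "\t"


@dataclass
class ExpressionProfile:
    """A ``p x n`` sample-by-gene expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (p, n)
        Expression intensities (unitless after preprocessing).
    sample_ids : list of str, length p
    gene_ids : list of str, length n
    labels : ndarray of shape (p,), optional
        Two-class labels in {+1, -1}; +1 is the positive ("cancer") class.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        p, n = self.values.shape
        if p == 0 or n == 0:
            raise FormatError("profile must have at least one sample and one gene")
        if len(self.sample_ids) != p:
            raise FormatError(
                f"{len(self.sample_ids)} sample ids for {p} rows")
        if len(self.gene_ids) != n:
            raise FormatError(f"{len(self.gene_ids)} gene ids for {n} columns")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}",
                row=int(bad[0]), column=int(bad[1]))
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (p,):
                raise LabelError(f"labels have shape {self.labels.shape}, expected ({p},)")
            if not np.all(np.isin(self.labels, (-1, 1))):
                raise LabelError("labels must contain only +1 and -1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "ExpressionProfile":
        """Row (sample) subset, preserving gene order."""
        indices = np.asarray(indices)
        return ExpressionProfile(
            values=self.values[indices].copy(),
            sample_ids=[self.sample_ids[i] for i in indices],
            gene_ids=list(self.gene_ids),
            labels=None if self.labels is None else self.labels[indices].copy(),
        )

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise LabelError("this operation requires a labelled profile")
        if len(np.unique(self.labels)) < 2:
            raise LabelError("training requires both +1 and -1 labels")
        return self.labels


def read_profile(path, orientation: str = "samples-by-genes",
                 label_path=None, sort_genes: bool = False) -> ExpressionProfile:
    """Read a delimited expression matrix (and optional label file).

    The file must have one header row of column ids and one leading column of
    row ids.  ``orientation`` says what the file's rows are; the returned
    profile is always samples-by-genes.
    """
    if orientation not in ("samples-by-genes", "genes-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        col_ids = [c.strip() for c in header[1:]]
        if not col_ids:
            raise FormatError(f"{path}: header row has no column ids")
        row_ids: list[str] = []
        rows: list[np.ndarray] = []
        width = len(header)
        for lineno, fields in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue  # blank trailing line
            if len(fields) != width:
                raise FormatError(
                    f"{path}: data row {lineno} has {len(fields) - 1} fields, "
                    f"expected {width - 1}")
            row_ids.append(fields[0].strip())
            try:
                rows.append(np.array(fields[1:], dtype=float))
            except ValueError:
                for j, cell in enumerate(fields[1:]):
                    try:
                        float(cell)
                    except ValueError:
                        raise ParseError(
                            f"{path}: non-numeric cell {cell!r} at data row "
                            f"{lineno} (id {fields[0]!r}), column {col_ids[j]!r}",
                            row=lineno, column=col_ids[j]) from None
                raise
    if not rows:
        raise FormatError(f"{path}: no data rows")
    values = np.vstack(rows)

    if orientation == "genes-by-samples":
        values = values.T
        sample_ids, gene_ids = col_ids, row_ids
    else:
        sample_ids, gene_ids = row_ids, col_ids

    labels = None
    if label_path is not None:
        mapping = read_labels(label_path)
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise LabelError(
                f"{label_path}: no label for sample(s) {missing[:5]}")
        labels = np.array([mapping[s] for s in sample_ids], dtype=int)

    prof = ExpressionProfile(values, sample_ids, gene_ids, labels)
    if sort_genes:
        order = np.argsort(np.asarray(prof.gene_ids, dtype=object))
        prof = ExpressionProfile(prof.values[:, order],
                                 prof.sample_ids,
                                 [prof.gene_ids[i] for i in order],
                                 prof.labels)
    return prof


def read_labels(path) -> dict[str, int]:
    """Read a two-column (sample_id, label) file into a mapping."""
    mapping: dict[str, int] = {}
    with open(path, newline="") as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first)
        lines = [first] + fh.readlines()
    for lineno, fields in enumerate(csv.reader(lines, delimiter=delim), start=1):
        if not fields or (len(fields) == 1 and not fields[0].strip()):
            continue
        if len(fields) != 2:
            raise LabelError(f"{path}: line {lineno} must have exactly two fields")
        sid, raw = fields[0].strip(), fields[1].strip()
        if lineno == 1 and raw.lstrip("+-") and not raw.lstrip("+-").isdigit():
            continue  # optional header line
        try:
            lab = int(raw)
        except ValueError:
            raise LabelError(f"{path}: line {lineno}: label {raw!r} is not an integer")
        if lab not in (-1, 1):
            raise LabelError(f"{path}: line {lineno}: label must be +1 or -1, got {lab}")
        mapping[sid] = lab
    return mapping


def write_profile(profile: ExpressionProfile, path, label_path=None,
                  delimiter: str = "\t", fmt: str = "%.10g") -> None:
    """Write a profile (and optionally its labels) as delimited text."""
    with open(path, "w", newline="") as fh:
        fh.write("sample_id" + delimiter + delimiter.join(profile.gene_ids) + "\n")
        for i, sid in enumerate(profile.sample_ids):
            fh.write(sid + delimiter
                     + delimiter.join(fmt % v for v in profile.values[i]) + "\n")
    if label_path is not None:
        if profile.labels is None:
            raise LabelError("profile has no labels to write")
        with open(label_path, "w", newline="") as fh:
            for sid, lab in zip(profile.sample_ids, profile.labels):
                fh.write(f"{sid}{delimiter}{'+1' if lab > 0 else '-1'}\n")


def log2_transform(profile: ExpressionProfile, offset: float = 0.0) -> ExpressionProfile:
    """Return a copy with every entry x replaced by log2(x + offset)."""
    if offset < 0:
        raise DomainError("offset must be nonnegative")
    shifted = profile.values + offset
    if np.any(shifted <= 0):
        bad = np.argwhere(shifted <= 0)
        coords = [(profile.sample_ids[i], profile.gene_ids[j]) for i, j in bad[:5]]
        raise DomainError(
            f"log2 undefined for {len(bad)} entries with value + offset <= 0, "
            f"first offenders (sample, gene): {coords}")
    return replace(profile, values=np.log2(shifted))
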