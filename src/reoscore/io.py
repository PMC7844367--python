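"""File formats and probe-to-gene collapsing.

Formats (all plain text):

* expression matrix — TSV/CSV, header row of sample ids, first column gene
  ids, cells numeric or ``NA`` for missing;
* probe map — two-column TSV ``probe_id<TAB>gene_id``, one row per
  (probe, gene) assignment, multi-mapping expressed as repeated probe rows;
* signature — TSV with header ``gene_a  gene_b  cancer_direction``,
  direction in {greater, less}, pairs stored with gene_a < gene_b;
* pathway sets — GMT (name, description, member genes per line).

Parsing is locale-independent (decimal point only) and validated row by
row so errors carry the offending id or line number.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .matrix import ExpressionMatrix
from .pairs import DIRECTIONS, DirectedGenePair, ReversalSignature

MISSING_TOKEN = "NA"

_DELIMS = {"tsv": "\t", "csv": ","}


def _delimiter(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'") from None


def read_expression_matrix(
    path: str | Path, dialect: str = "tsv", cohort_label: str = ""
) -> ExpressionMatrix:
    """Read a gene-by-sample matrix.

    Hard errors: duplicate gene id (named), ragged row (line number),
    non-numeric cell other than ``NA`` (line number and content).
    """
    delim = _delimiter(dialect)
    path = Path(path)
    genes: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        samples = [s.strip() for s in header[1:]]
        if len(samples) != len(set(samples)):
            raise ValidationError(f"{path}: duplicate sample id in header")
        width = len(header)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise ValidationError(
                    f"{path}: line {lineno}: expected {width} fields, found {len(row)}"
                )
            gene = row[0].strip()
            if gene in seen:
                raise ValidationError(f"{path}: duplicate gene id {gene!r}")
            seen.add(gene)
            genes.append(gene)
            vals = np.empty(len(samples))
            for j, cell in enumerate(row[1:]):
                cell = cell.strip()
                if cell == MISSING_TOKEN:
                    vals[j] = np.nan
                else:
                    try:
                        vals[j] = float(cell)
                    except ValueError:
                        raise ValidationError(
                            f"{path}: line {lineno}: non-numeric cell {cell!r}"
                        ) from None
            rows.append(vals)
    if not genes:
        raise ValidationError(f"{path}: no gene rows")
    data = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
    return ExpressionMatrix(data, cohort_label=cohort_label or path.stem)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    delim = _delimiter(dialect)
    matrix.data.to_csv(path, sep=delim, na_rep=MISSING_TOKEN, index_label="gene_id")


@dataclass
class ProbeGeneMap:
    """Probe-to-gene assignments; a probe may map to 0, 1 or several genes."""

    mapping: dict[str, tuple[str, ...]]

    def unique_probes(self) -> dict[str, str]:
        """Probes mapping to exactly one gene (the only ones that survive
        collapsing)."""
        return {p: gs[0] for p, gs in self.mapping.items() if len(gs) == 1}


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    path = Path(path)
    mapping: dict[str, list[str]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 2 fields, found {len(row)}"
                )
            probe, gene = row[0].strip(), row[1].strip()
            mapping.setdefault(probe, [])
            if gene:
                mapping[probe].append(gene)
    return ProbeGeneMap({p: tuple(dict.fromkeys(gs)) for p, gs in mapping.items()})


def collapse_probes(probe_matrix: ExpressionMatrix, probe_map: ProbeGeneMap) -> ExpressionMatrix:
    """Collapse a probe-by-sample matrix to gene level.

    Probes mapping to zero or multiple genes are discarded; a gene's value
    per sample is the arithmetic mean (on the provided scale) over its
    surviving probes. Probes absent from the map are treated as unmapped
    and discarded. Missing probe values are ignored in the mean; a gene
    whose surviving probes are all missing in a sample stays missing there.
    """
    unique = probe_map.unique_probes()
    surviving = [p for p in probe_matrix.gene_ids if p in unique]
    if not surviving:
        raise ComputationError("no probe maps uniquely to a gene; empty collapse")
    sub = probe_matrix.data.loc[surviving]
    gene_of = pd.Series([unique[p] for p in surviving], index=sub.index)
    collapsed = sub.groupby(gene_of).mean()  # skips NaN per cell
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, cohort_label=probe_matrix.cohort_label)


def read_signature(path: str | Path) -> ReversalSignature:
    path = Path(path)
    entries: list[DirectedGenePair] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty signature file") from None
        if [h.strip() for h in header[:3]] != ["gene_a", "gene_b", "cancer_direction"]:
            raise ValidationError(
                f"{path}: expected header 'gene_a\\tgene_b\\tcancer_direction'"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 3 fields, found {len(row)}"
                )
            a, b, direction = row[0].strip(), row[1].strip(), row[2].strip()
            if a == b:
                raise ValidationError(f"{path}: line {lineno}: pair with identical genes {a!r}")
            if direction not in DIRECTIONS:
                raise ValidationError(
                    f"{path}: line {lineno}: unknown direction {direction!r}; "
                    f"accepted tokens: {', '.join(DIRECTIONS)}"
                )
            entries.append(DirectedGenePair(a, b, direction))
    return ReversalSignature(entries).sorted()


def write_signature(signature: ReversalSignature, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "cancer_direction"])
        for p in signature.sorted():
            writer.writerow([p.gene_a, p.gene_b, p.direction])


def read_gmt(path: str | Path) -> list[tuple[str, set[str]]]:
    """Read gene sets in GMT format: name, description, member genes."""
    path = Path(path)
    sets: list[tuple[str, set[str]]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT rows need name, description and >=1 gene"
                )
            name = fields[0].strip()
            if name in seen:
                raise ValidationError(f"{path}: duplicate gene-set name {name!r}")
            seen.add(name)
            genes = {g.strip() for g in fields[2:] if g.strip()}
            sets.append((name, genes))
    if not sets:
        raise ValidationError(f"{path}: no gene sets")
    return sets


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not genes:
        raise ValidationError(f"{path}: no genes")
    return list(dict.fromkeys(genes))


def read_groups(path: str | Path) -> pd.Series:
    """Groups file: TSV ``sample_id<TAB>group_label``; returns Series."""
    path = Path(path)
    ids: list[str] = []
    labels: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 2 fields, found {len(row)}"
                )
            ids.append(row[0].strip())
            labels.append(row[1].strip())
    if not ids:
        raise ValidationError(f"{path}: no samples")
    if len(ids) != len(set(ids)):
        raise ValidationError(f"{path}: duplicate sample id")
    return pd.Series(labels, index=ids, name="group")
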