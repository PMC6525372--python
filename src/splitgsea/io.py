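"""Readers and writers for GCT, CLS, GMT and result TSV files.

Gene identifiers are matched case-sensitively between gene-set and
expression files; silent case-folding hides identifier-scheme mismatches.
Every output file carries a comment header (seed, statistic, permutation
count, software version) sufficient to reproduce the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _fail(path, line_no, message):
    raise ParseError(f"{path}:{line_no}: {message}")


# ----------------------------------------------------------------------
# expression matrices
# ----------------------------------------------------------------------

def read_expression(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a genes x samples expression matrix (GCT ``#1.2`` or plain TSV).

    Returns a DataFrame indexed by gene id with sample-id columns.  The
    format is inferred from the extension unless ``fmt`` is given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    fmt = fmt.lower()
    if fmt == "gct":
        return _read_gct(path)
    if fmt == "tsv":
        return _read_expression_tsv(path)
    raise ValueError(f"unknown expression format {fmt!r}")


def _validate_matrix(df: pd.DataFrame, path, body_start: int) -> pd.DataFrame:
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        first = df.index.get_loc(dup[0])
        row = first.start if isinstance(first, slice) else np.flatnonzero(first)[0]
        _fail(path, body_start + int(row), f"duplicate gene id {dup[0]!r}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(bad | df[col].isna())[0])
            _fail(
                path,
                body_start + row,
                f"non-numeric or missing value in column {col!r} "
                f"for gene {df.index[row]!r}",
            )
        df[col] = numeric
    return df.astype(float)


def _read_gct(path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].strip().startswith("#1.2"):
        _fail(path, 1, "expected GCT version line '#1.2'")
    try:
        n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        _fail(path, 2, "expected tab-separated dimensions '<n_genes>\\t<n_samples>'")
    body = pd.read_csv(StringIO("\n".join(lines[2:])), sep="\t", dtype=str)
    if body.shape[1] != n_samples + 2:
        _fail(
            path,
            3,
            f"header has {body.shape[1] - 2} sample columns, "
            f"dimension line promised {n_samples}",
        )
    if body.shape[0] != n_genes:
        _fail(
            path,
            2,
            f"found {body.shape[0]} gene rows, dimension line promised {n_genes}",
        )
    df = body.set_index(body.columns[0]).drop(columns=[body.columns[1]])
    df.index.name = "Name"
    return _validate_matrix(df, path, body_start=4)


def _read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    return _validate_matrix(df, path, body_start=2)


def write_gct(df_or_dataset, path, descriptions=None) -> None:
    """Write a genes x samples matrix as GCT ``#1.2``."""
    if isinstance(df_or_dataset, ExpressionDataset):
        ds = df_or_dataset
        df = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids)
    else:
        df = df_or_dataset
    n_genes, n_samples = df.shape
    desc = descriptions if descriptions is not None else ["na"] * n_genes
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_genes}\t{n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, d, row in zip(df.index, desc, df.to_numpy()):
            fh.write(f"{gene}\t{d}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def read_phenotype(path, fmt: str | None = None):
    """Read per-sample binary labels (CLS categorical dialect or 2-col TSV).

    Returns ``(labels, classes)``; ``classes`` is the ordered pair fixed by
    file order, whose first element is the positive direction.
    """
    path = Path(path)
    if fmt is None:
        fmt = "cls" if path.suffix.lower() == ".cls" else "tsv"
    fmt = fmt.lower()
    if fmt == "cls":
        return _read_cls(path)
    if fmt == "tsv":
        return _read_phenotype_tsv(path)
    raise ValueError(f"unknown phenotype format {fmt!r}")


def _read_cls(path):
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if len(lines) < 3:
        _fail(path, 1, "CLS file needs 3 lines (counts, '# classes', labels)")
    head = lines[0].split()
    if len(head) < 3:
        _fail(path, 1, "expected '<n_samples> <n_classes> 1'")
    n_samples, n_classes = int(head[0]), int(head[1])
    if n_classes != 2:
        _fail(path, 1, f"expected exactly 2 classes, file declares {n_classes}")
    class_line = lines[1].split()
    if class_line[0] != "#":
        _fail(path, 2, "expected class-name line starting with '#'")
    classes = class_line[1:]
    if len(classes) != 2:
        _fail(path, 2, f"expected 2 class names, found {len(classes)}")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        _fail(path, 3, f"{len(tokens)} labels for {n_samples} declared samples")
    if set(tokens) <= set(classes):
        labels = tokens
    elif set(tokens) <= {"0", "1"}:
        labels = [classes[int(t)] for t in tokens]
    else:
        _fail(path, 3, f"labels must be class names {classes} or indices 0/1")
    if len(set(labels)) != 2:
        _fail(path, 3, "only one phenotype class present")
    return np.array(labels), tuple(classes)


def _read_phenotype_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
    if df.shape[1] != 2:
        _fail(path, 1, "phenotype TSV needs two columns: sample_id, label")
    labels = df.iloc[:, 1].to_numpy()
    seen = list(dict.fromkeys(labels.tolist()))
    if len(seen) != 2:
        _fail(path, 1, f"expected exactly 2 classes, found {len(seen)}")
    return labels, tuple(seen)


def write_cls(labels, classes, path) -> None:
    labels = list(labels)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write("# " + " ".join(map(str, classes)) + "\n")
        fh.write(" ".join(map(str, labels)) + "\n")


# ----------------------------------------------------------------------
# gene sets
# ----------------------------------------------------------------------

def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (name, description, members...)."""
    collection = GeneSetCollection()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            _fail(path, line_no, "GMT line needs name, description and >= 1 member")
        name, _desc, *members = fields
        members = [m for m in members if m]
        if not members:
            _fail(path, line_no, f"gene set {name!r} has no members")
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            logger.warning(
                "%s:%d: gene set %s: %d duplicate member id(s) removed",
                path,
                line_no,
                name,
                len(members) - len(unique),
            )
        try:
            collection.add(GeneSet(name, unique))
        except ValueError as exc:
            _fail(path, line_no, str(exc))
    return collection


def write_gene_sets(collection: GeneSetCollection, path, descriptions=None) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            desc = (descriptions or {}).get(gs.name, "na")
            fh.write("\t".join([gs.name, desc, *sorted(gs.members)]) + "\n")


# ----------------------------------------------------------------------
# results and run configuration
# ----------------------------------------------------------------------

def load_dataset(expression_path, phenotype_path) -> ExpressionDataset:
    """Read matrix + labels into an :class:`ExpressionDataset`."""
    expr = read_expression(expression_path)
    labels, classes = read_phenotype(phenotype_path)
    if len(labels) != expr.shape[1]:
        raise ParseError(
            f"{phenotype_path}: {len(labels)} labels for "
            f"{expr.shape[1]} expression columns"
        )
    return ExpressionDataset(
        gene_ids=[str(g) for g in expr.index],
        values=expr.to_numpy(),
        sample_ids=[str(s) for s in expr.columns],
        phenotype=labels,
        classes=classes,
    )


def results_header(**meta) -> str:
    """Comment header recording everything needed to reproduce a run."""
    from . import __version__

    lines = [f"# splitgsea {__version__}"]
    lines.append(
        "# direction: positive statistic = enrichment toward the first "
        "phenotype class"
    )
    for key, value in meta.items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_results(df: pd.DataFrame, path, **meta) -> None:
    with open(path, "w") as fh:
        fh.write(results_header(**meta))
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class RunConfig:
    """Validated configuration for a CLI run (flags win over config files)."""

    expression: str | None = None
    phenotype: str | None = None
    gene_sets: str | None = None
    statistic: str = "es"
    n_splits: int = 25
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    alternative: str = "sign-matched"
    out_dir: str = "."
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extras = {k: v for k, v in raw.items() if k not in known}
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(extras=extras, **kwargs)

    def validate_paths(self) -> None:
        for attr in ("expression", "phenotype", "gene_sets"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{attr} file not found: {value}")
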