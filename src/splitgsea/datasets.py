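"""In-memory containers: expression matrices with binary phenotypes, gene sets.

The expression container is deliberately simple: a genes x samples float
matrix plus identifiers and a two-class phenotype.  The first phenotype class
is the "positive" direction — a positive gene-phenotype correlation means
higher expression in that class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class DegeneratePhenotypeError(ValueError):
    """Raised when a phenotype does not have two classes with >= 2 samples."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression values with per-sample binary phenotype.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    values
        Numeric matrix, shape ``(n_genes, n_samples)``; no missing values.
    sample_ids
        Unique sample identifiers, one per matrix column.
    phenotype
        Per-sample class labels; exactly two distinct labels, each with at
        least two samples.
    classes
        Ordered pair of class labels; first class is the positive direction.
        Defaults to first-appearance order of ``phenotype``.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    phenotype: np.ndarray
    classes: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.phenotype = np.asarray(self.phenotype)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if len(self.phenotype) != n_samples:
            raise ValueError("phenotype length does not match sample count")
        if self.classes is None:
            _, first = np.unique(self.phenotype, return_index=True)
            order = np.argsort(first)
            self.classes = tuple(np.unique(self.phenotype)[order])
        else:
            self.classes = tuple(self.classes)
        observed = set(np.unique(self.phenotype).tolist())
        if observed != set(self.classes) or len(self.classes) != 2:
            raise DegeneratePhenotypeError(
                f"expected exactly two phenotype classes {self.classes!r}, "
                f"observed {sorted(map(str, observed))}"
            )
        for cls in self.classes:
            if int((self.phenotype == cls).sum()) < 2:
                raise DegeneratePhenotypeError(
                    f"phenotype class {cls!r} has fewer than 2 samples"
                )

    # -- basic geometry ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def positive_mask(self) -> np.ndarray:
        """Boolean mask of samples in the first (positive-direction) class."""
        return self.phenotype == self.classes[0]

    def class_sizes(self) -> tuple[int, int]:
        pos = self.positive_mask
        return int(pos.sum()), int((~pos).sum())

    # -- restriction -------------------------------------------------------
    def subset_samples(self, which) -> "ExpressionDataset":
        """Restrict to a subset of samples (ids, indices, or boolean mask)."""
        which = np.asarray(which)
        if which.dtype == bool:
            idx = np.flatnonzero(which)
        elif which.dtype.kind in "iu":
            idx = which
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in which.tolist()])
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            values=self.values[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            phenotype=self.phenotype[idx],
            classes=self.classes,
        )

    def with_phenotype(self, phenotype: Sequence) -> "ExpressionDataset":
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            values=self.values,
            sample_ids=self.sample_ids,
            phenotype=np.asarray(phenotype),
            classes=self.classes,
        )

    def swap_classes(self) -> "ExpressionDataset":
        """Exchange the positive/negative phenotype direction."""
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            values=self.values,
            sample_ids=self.sample_ids,
            phenotype=self.phenotype,
            classes=(self.classes[1], self.classes[0]),
        )

    def gene_indexer(self) -> Mapping[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass(frozen=True)
class GeneSet:
    """A named subset of gene identifiers."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def member_mask(self, dataset: ExpressionDataset) -> np.ndarray:
        """Boolean mask over dataset genes; validates the intersection.

        Members absent from the dataset are dropped (with a logged count);
        the remaining intersection must be a non-empty proper subset.
        """
        mask = np.fromiter(
            (g in self.members for g in dataset.gene_ids),
            dtype=bool,
            count=dataset.n_genes,
        )
        n_hit = int(mask.sum())
        n_dropped = len(self.members) - n_hit
        if n_dropped:
            logger.info(
                "gene set %s: %d member(s) absent from the dataset were dropped",
                self.name,
                n_dropped,
            )
        if n_hit == 0:
            raise ValueError(
                f"gene set {self.name!r} shares no genes with the dataset"
            )
        if n_hit >= dataset.n_genes:
            raise ValueError(
                f"gene set {self.name!r} covers every dataset gene; "
                "the complement is empty"
            )
        return mask


class GeneSetCollection:
    """Ordered collection of uniquely named gene sets (GMT semantics)."""

    def __init__(self, gene_sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for gs in gene_sets:
            self.add(gs)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls(GeneSet(name, members) for name, members in mapping.items())
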