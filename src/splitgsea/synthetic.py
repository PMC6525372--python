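"""Synthetic benchmark generator: 600-gene block-structured Gaussian data.

Datasets are drawn from a multivariate normal with unit variances.  Genes
come in ten independent blocks differing in the between-phenotype mean shift
``dmu`` (class A mean is ``+dmu/2``, class B ``-dmu/2``; only the difference
matters to rank statistics) and in the within-block correlation ``rho``:

====== ===== ============ =====================================
block  size  dmu          rho
====== ===== ============ =====================================
i      420   0            0
ii     20    0.5          0
iii    20    0.25         0
iv     20    0.1          0
v      20    0.5          0.6
vi     20    0.25         0.6
vii    20    0.1          0.6
viii   20    +0.5 / -0.5  0.6 within each 10-gene subgroup,
             (10 each)    -0.6 between the subgroups
ix     20    +0.5 / -0.5  0
x      20    0            0.6
====== ===== ============ =====================================

On top of the blocks sit 21 twenty-gene benchmark sets named ``a``-``u``
that mix association strengths, correlation structures and up/down balance;
``a`` and ``j`` are negative controls with no phenotype association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._random import as_generator
from .datasets import ExpressionDataset, GeneSet, GeneSetCollection

N_GENES = 600
DEFAULT_N_PER_CLASS = 25
BLOCK_IDS = ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix", "x")


@dataclass(frozen=True)
class BlockSpec:
    """One block of exchangeable genes in the synthetic covariance model."""

    block_id: str
    size: int
    dmu: np.ndarray          # per-gene mean difference (A minus B)
    correlation: np.ndarray  # size x size correlation matrix

    def __post_init__(self):
        object.__setattr__(self, "dmu", np.asarray(self.dmu, float))
        object.__setattr__(self, "correlation", np.asarray(self.correlation, float))
        c = self.correlation
        if c.shape != (self.size, self.size):
            raise ValueError("correlation shape does not match block size")
        if not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        # positive definiteness: factorization must succeed
        np.linalg.cholesky(c)


def _equicorrelated(size: int, rho: float) -> np.ndarray:
    c = np.full((size, size), rho)
    np.fill_diagonal(c, 1.0)
    return c


def build_blocks() -> list[BlockSpec]:
    """The ten covariance blocks, totalling 600 genes."""
    blocks = [
        BlockSpec("i", 420, np.zeros(420), np.eye(420)),
        BlockSpec("ii", 20, np.full(20, 0.5), np.eye(20)),
        BlockSpec("iii", 20, np.full(20, 0.25), np.eye(20)),
        BlockSpec("iv", 20, np.full(20, 0.1), np.eye(20)),
        BlockSpec("v", 20, np.full(20, 0.5), _equicorrelated(20, 0.6)),
        BlockSpec("vi", 20, np.full(20, 0.25), _equicorrelated(20, 0.6)),
        BlockSpec("vii", 20, np.full(20, 0.1), _equicorrelated(20, 0.6)),
    ]
    # block viii: two anti-correlated 10-gene subgroups with opposite shifts
    c8 = np.empty((20, 20))
    c8[:10, :10] = _equicorrelated(10, 0.6)
    c8[10:, 10:] = _equicorrelated(10, 0.6)
    c8[:10, 10:] = -0.6
    c8[10:, :10] = -0.6
    np.fill_diagonal(c8, 1.0)
    dmu8 = np.concatenate([np.full(10, 0.5), np.full(10, -0.5)])
    blocks.append(BlockSpec("viii", 20, dmu8, c8))
    blocks.append(BlockSpec("ix", 20, dmu8.copy(), np.eye(20)))
    blocks.append(BlockSpec("x", 20, np.zeros(20), _equicorrelated(20, 0.6)))
    assert sum(b.size for b in blocks) == N_GENES
    return blocks


def block_offsets(blocks=None) -> dict[str, int]:
    """Start index of each block in the concatenated 600-gene layout."""
    blocks = blocks or build_blocks()
    offsets, pos = {}, 0
    for b in blocks:
        offsets[b.block_id] = pos
        pos += b.size
    return offsets


@dataclass(frozen=True)
class SyntheticCatalogue:
    """The block layout plus the 21 benchmark gene sets (as index lists)."""

    blocks: list[BlockSpec]
    sets: dict[str, list[int]]
    controls: tuple = ("a", "j")

    def gene_ids(self) -> list[str]:
        ids = []
        for b in self.blocks:
            ids.extend(f"{b.block_id}_{k:03d}" for k in range(b.size))
        return ids

    def collection(self) -> GeneSetCollection:
        ids = self.gene_ids()
        return GeneSetCollection(
            GeneSet(name, [ids[i] for i in idx]) for name, idx in self.sets.items()
        )

    def dmu(self) -> np.ndarray:
        return np.concatenate([b.dmu for b in self.blocks])


def gene_set_catalogue() -> SyntheticCatalogue:
    """Build the 21 benchmark sets ``a``-``u``.

    Partial draws from a block take its lowest-index genes; where a block
    subgroup is named (up- or down-shifted halves of viii/ix) the draw comes
    from that subgroup.  Multi-block counts that the composition list leaves
    open are fixed as: ``m`` = 7/7/6 from (ii)/(iii)/(iv); ``n`` = 7/7/6 from
    (v)/(vi)/(vii); ``o`` = 4/4/3/3/3/3 from (ii)-(vii); ``u`` = the first
    gene of each of (ii)-(x) plus the second gene of (ii), (iii) and (iv).
    """
    blocks = build_blocks()
    off = block_offsets(blocks)

    def take(block: str, count: int, start: int = 0) -> list[int]:
        return list(range(off[block] + start, off[block] + start + count))

    up8 = lambda n: take("viii", n)           # dmu = +0.5 subgroup
    down8 = lambda n: take("viii", n, 10)     # dmu = -0.5 subgroup
    up9 = lambda n: take("ix", n)
    down9 = lambda n: take("ix", n, 10)

    sets: dict[str, list[int]] = {
        "a": take("i", 20),
        "b": take("ii", 20),
        "c": take("iii", 20),
        "d": take("iv", 20),
        "e": take("v", 20),
        "f": take("vi", 20),
        "g": take("vii", 20),
        "h": take("viii", 20),
        "i": take("ix", 20),
        "j": take("x", 20),
        "k": take("ii", 10) + take("v", 10),
        "l": take("ii", 10) + up8(5) + down8(5),
        "m": take("ii", 7) + take("iii", 7) + take("iv", 6),
        "n": take("v", 7) + take("vi", 7) + take("vii", 6),
        "o": take("ii", 4) + take("iii", 4) + take("iv", 3)
        + take("v", 3) + take("vi", 3) + take("vii", 3),
        "p": up9(10) + down8(5) + up8(5),
        "q": take("ii", 10) + up8(5) + down8(5),
        "r": take("ii", 3) + up9(10) + down9(7),
        "s": take("i", 10) + take("ii", 10),
        "t": take("i", 10) + take("v", 10),
        "u": take("i", 8)
        + [off[b] for b in ("ii", "iii", "iv", "v", "vi", "vii", "viii", "ix", "x")]
        + [off[b] + 1 for b in ("ii", "iii", "iv")],
    }
    for name, idx in sets.items():
        assert len(idx) == 20, name
        assert len(set(idx)) == 20, name
    return SyntheticCatalogue(blocks=blocks, sets=sets)


def simulate_dataset(
    n_per_class: int = DEFAULT_N_PER_CLASS,
    random_state=None,
    catalogue: SyntheticCatalogue | None = None,
) -> ExpressionDataset:
    """Draw one synthetic dataset (default 25 samples per phenotype class).

    Class A gene means are ``+dmu/2`` and class B ``-dmu/2``; unit variances
    and the block correlation structure throughout.  Deterministic given the
    random state.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    rng = as_generator(random_state)
    cat = catalogue or gene_set_catalogue()
    n = 2 * n_per_class
    parts = []
    for b in cat.blocks:
        z = rng.standard_normal((n, b.size))
        if not np.allclose(b.correlation, np.eye(b.size)):
            z = z @ np.linalg.cholesky(b.correlation).T
        shift = np.where(np.arange(n) < n_per_class, 0.5, -0.5)[:, None] * b.dmu
        parts.append((z + shift).T)
    values = np.concatenate(parts, axis=0)
    phenotype = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    sample_ids = [f"A{k:03d}" for k in range(n_per_class)] + [
        f"B{k:03d}" for k in range(n_per_class)
    ]
    return ExpressionDataset(
        gene_ids=cat.gene_ids(),
        values=values,
        sample_ids=sample_ids,
        phenotype=phenotype,
        classes=("A", "B"),
    )
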