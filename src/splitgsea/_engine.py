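"""Vectorized permutation engine.

Phenotype permutation only relabels samples, so per-gene expression ranks
never change.  The engine precomputes, once per dataset,

* the genes x samples mid-rank matrix (full-cohort correlations become one
  matrix product per batch of permutations), and
* a genes x samples x samples pairwise comparison tensor
  ``C[g, i, j] = [x_gi > x_gj] + 0.5 [x_gi = x_gj]`` (zero diagonal), from
  which the Mann-Whitney U of any sample subgroup pair is a bilinear form —
  this is what makes split statistics affordable, since within-half ranks
  cannot be read off the full-cohort ranks.

All aggregation is exact: U values are sums of half-integers and are
represented exactly in float32.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @njit(cache=False)
    def _pairwise_u_kernel(cmp, a_idx, a_cnt, b_idx, b_cnt, out):
        n_genes = cmp.shape[0]
        n_cols = a_idx.shape[0]
        for g in range(n_genes):
            cg = cmp[g]
            for k in range(n_cols):
                acc = 0.0
                for x in range(a_cnt[k]):
                    row = cg[a_idx[k, x]]
                    for y in range(b_cnt[k]):
                        acc += row[b_idx[k, y]]
                out[g, k] = acc


def _masks_to_indices(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column True positions of a (n, K) mask, padded to the max count."""
    counts = mask.sum(axis=0).astype(np.int64)
    width = int(counts.max()) if counts.size else 0
    order = np.argsort(~mask, axis=0, kind="stable")[:width]  # True rows first
    return np.ascontiguousarray(order.T.astype(np.int32)), counts


class RankEngine:
    """Shared-rank evaluator for one expression matrix (genes x samples)."""

    # refuse to build the comparison tensor above ~1.2 GB
    MAX_CMP_BYTES = 1.2e9

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        self.n_genes, self.n_samples = self.values.shape
        self.ranks = rankdata(self.values, axis=1)
        self._cmp: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def cmp(self) -> np.ndarray | None:
        """Lazy pairwise comparison tensor, or None if it would be too big."""
        if self._cmp is None:
            nbytes = 4.0 * self.n_genes * self.n_samples**2
            if nbytes > self.MAX_CMP_BYTES:
                return None
            x = self.values
            out = np.empty((self.n_genes, self.n_samples, self.n_samples), np.float32)
            for g0 in range(0, self.n_genes, 256):
                g1 = min(self.n_genes, g0 + 256)
                xi = x[g0:g1, :, None]
                xj = x[g0:g1, None, :]
                out[g0:g1] = (xi > xj) + 0.5 * (xi == xj)
            idx = np.arange(self.n_samples)
            out[:, idx, idx] = 0.0
            self._cmp = out
        return self._cmp

    # ------------------------------------------------------------------
    def correlations_labeled(self, pos_mask: np.ndarray) -> np.ndarray:
        """Scaled MW correlations for full-cohort label columns.

        ``pos_mask``: boolean (n_samples, K); each column marks the positive
        class.  Returns (n_genes, K) float64.
        """
        pos = pos_mask.astype(float)
        n_a = pos.sum(axis=0)
        n_b = self.n_samples - n_a
        ranksum = self.ranks @ pos
        u = ranksum - n_a * (n_a + 1) / 2.0
        return 2.0 * u / (n_a * n_b) - 1.0

    def correlations_within(
        self, a_mask: np.ndarray, b_mask: np.ndarray
    ) -> np.ndarray:
        """Scaled MW correlations restricted to subgroup columns.

        ``a_mask``/``b_mask``: boolean (n_samples, K); column k compares
        samples in ``a_mask[:, k]`` against ``b_mask[:, k]`` (disjoint).
        """
        n_a = a_mask.sum(axis=0).astype(float)
        n_b = b_mask.sum(axis=0).astype(float)
        if np.any(n_a < 1) or np.any(n_b < 1):
            raise ValueError("a subgroup lost one phenotype class entirely")
        cmp = self.cmp
        if cmp is None:
            u = self._u_within_slow(a_mask, b_mask)
        elif _HAVE_NUMBA:
            a_idx, a_cnt = _masks_to_indices(a_mask)
            b_idx, b_cnt = _masks_to_indices(b_mask)
            u = np.empty((self.n_genes, a_mask.shape[1]), np.float32)
            _pairwise_u_kernel(cmp, a_idx, a_cnt, b_idx, b_cnt, u)
            u = u.astype(float)
        else:
            u = self._u_within_gemm(a_mask, b_mask)
        return 2.0 * u / (n_a * n_b) - 1.0

    def _u_within_gemm(self, a_mask: np.ndarray, b_mask: np.ndarray) -> np.ndarray:
        cmp = self._cmp
        n = self.n_samples
        flat = cmp.reshape(self.n_genes * n, n)
        k_total = a_mask.shape[1]
        u = np.empty((self.n_genes, k_total), float)
        chunk = max(1, int(2.4e8 // (8 * self.n_genes * n)))
        b_f = b_mask.astype(np.float32)
        a_f = a_mask.astype(np.float32)
        for s in range(0, k_total, chunk):
            e = min(k_total, s + chunk)
            t = (flat @ b_f[:, s:e]).reshape(self.n_genes, n, e - s)
            u[:, s:e] = np.einsum("gik,ik->gk", t, a_f[:, s:e])
        return u

    def mean_diff(self, a_mask: np.ndarray, b_mask: np.ndarray) -> np.ndarray:
        """Between-group mean expression difference per column (ranking
        tie-break; negates exactly when the groups are exchanged)."""
        n_a = a_mask.sum(axis=0).astype(float)
        n_b = b_mask.sum(axis=0).astype(float)
        weights = a_mask / n_a - b_mask / n_b
        return self.values @ weights

    def _u_within_slow(self, a_mask: np.ndarray, b_mask: np.ndarray) -> np.ndarray:
        """Per-column rank recomputation; used when the tensor is too large."""
        k_total = a_mask.shape[1]
        u = np.empty((self.n_genes, k_total), float)
        for k in range(k_total):
            sub = a_mask[:, k] | b_mask[:, k]
            ranks = rankdata(self.values[:, sub], axis=1)
            in_a = a_mask[sub, k]
            n_a = int(in_a.sum())
            u[:, k] = ranks[:, in_a].sum(axis=1) - n_a * (n_a + 1) / 2.0
        return u


def enrichment_scores(
    correlations: np.ndarray,
    member_masks: np.ndarray,
    weight_exponent: float = 1.0,
    tie_break: np.ndarray | None = None,
    chunk: int = 4096,
) -> np.ndarray:
    """Vectorized running-sum ES for many correlation columns and gene sets.

    Parameters
    ----------
    correlations
        (n_genes, K) per-column scaled correlations.
    member_masks
        (n_sets, n_genes) boolean membership matrix.
    tie_break
        Optional (n_genes, K) secondary ordering key (between-class mean
        difference), descending, applied within correlation ties.
    Returns
    -------
    (n_sets, K) signed enrichment scores.
    """
    member_masks = np.atleast_2d(member_masks)
    n_sets = member_masks.shape[0]
    n_genes, k_total = correlations.shape
    set_sizes = member_masks.sum(axis=1)
    out = np.empty((n_sets, k_total), float)
    for s0 in range(0, k_total, chunk):
        s1 = min(k_total, s0 + chunk)
        rc = correlations[:, s0:s1]
        if tie_break is None:
            order = np.argsort(-rc, axis=0, kind="stable")
        else:
            order = np.lexsort((-tie_break[:, s0:s1], -rc), axis=0)
        r_sorted = np.take_along_axis(rc, order, axis=0)
        if weight_exponent == 1.0:
            weights = np.abs(r_sorted)
        else:
            weights = np.abs(r_sorted) ** weight_exponent
        cols = np.arange(s1 - s0)
        for si in range(n_sets):
            hit = member_masks[si][order]
            n_r = np.where(hit, weights, 0.0).sum(axis=0)
            if np.any(n_r == 0.0):
                raise ValueError(
                    "a permutation yielded zero correlation for every gene-set "
                    "member (N_R = 0); the running sum is undefined"
                )
            miss = 1.0 / (n_genes - set_sizes[si])
            steps = np.where(hit, weights / n_r, -miss)
            running = np.cumsum(steps, axis=0)
            idx = np.argmax(np.abs(running), axis=0)
            out[si, s0:s1] = running[idx, cols]
    return out


# ----------------------------------------------------------------------
# mask generation: label permutations and stratified half-splits
# ----------------------------------------------------------------------

def permutation_masks(
    pos_mask: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Column-wise random relabelings preserving the positive-class size."""
    n = pos_mask.shape[0]
    n_a = int(pos_mask.sum())
    order = np.argsort(rng.random((n, n_perm)), axis=0)
    out = np.zeros((n, n_perm), dtype=bool)
    np.put_along_axis(out, order[:n_a], True, axis=0)
    return out


def split_half_masks(
    pos_cols: np.ndarray, n_splits: int, rng: np.random.Generator
) -> np.ndarray:
    """Stratified half-split masks for each label column.

    ``pos_cols``: boolean (n_samples, K) positive-class columns.  Each column
    is split ``n_splits`` times into halves S1/S2, stratified by its own
    labels; odd class counts are balanced so ``|S1|`` and ``|S2|`` differ by
    at most one (one random draw decides which side gets the extra).

    Returns a boolean S1 mask of shape (n_samples, K * n_splits); S2 is the
    complement.  Column ``k * n_splits + m`` is split m of label column k.
    """
    n, k_labels = pos_cols.shape
    k_total = k_labels * n_splits
    pos = np.repeat(pos_cols, n_splits, axis=1)
    neg = ~pos
    n_a = pos.sum(axis=0)
    n_b = n - n_a

    draw = rng.integers(0, 2, size=k_total)
    a_odd = n_a % 2 == 1
    b_odd = n_b % 2 == 1
    both_odd = a_odd & b_odd
    # counts of each class placed in S1; when both classes are odd the two
    # extras go to opposite halves so |S1| = |S2|
    n1_a = n_a // 2 + np.where(a_odd, draw, 0)
    n1_b = np.where(both_odd, n // 2 - n1_a, n_b // 2 + b_odd * draw)

    prio = rng.random((n, k_total))
    key_a = np.where(pos, prio, 2.0)
    key_b = np.where(neg, prio, 2.0)
    order_a = np.argsort(key_a, axis=0)
    order_b = np.argsort(key_b, axis=0)
    t = np.arange(n)[:, None]
    s1 = np.zeros((n, k_total), dtype=bool)
    pick_a = np.zeros_like(s1)
    np.put_along_axis(pick_a, order_a, t < n1_a, axis=0)
    pick_b = np.zeros_like(s1)
    np.put_along_axis(pick_b, order_b, t < n1_b, axis=0)
    s1 = pick_a | pick_b
    return s1
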