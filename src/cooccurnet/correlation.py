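"""Pairwise rank association between taxa: concordance counting, the
(C-D)/(C+D) statistic, permutation null distributions and FDR control.

The association statistic is built from the concordant/discordant pair
counts of two abundance vectors observed over the same samples.  With no
ties, (C-D)/(C+D) equals Kendall's tau; with ties — guaranteed in
zero-inflated abundance data — it is the Goodman-Kruskal gamma, which
ignores tied pairs.  Both the printed form (``gamma_paper``, the default)
and the tie-corrected ``tau_b`` are offered, and every output records which
was used.

Significance comes from a permutation null: one vector is permuted against
the other and the statistic recomputed.  For n <= 8 samples all n!
permutations are enumerated exactly (the study's own group sizes: 6-8
mice); larger n uses seeded Monte Carlo sampling.  Two-sided p-values only.
Q-values are Benjamini-Hochberg, computed over exactly one network's family
of pairs (one group x sample type x rank), never pooled across networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_abundance import AbundanceTable

__all__ = [
    "ConcordanceCounts",
    "PairAssociation",
    "PairwiseResult",
    "DegeneratePairError",
    "SampleSizeTooLargeError",
    "concordance_counts",
    "association_statistic",
    "exact_p_value",
    "monte_carlo_p_value",
    "permutation_p_value",
    "bh_fdr",
    "pairwise_associations",
    "write_associations",
    "read_associations",
]

METHODS = ("gamma_paper", "tau_b")

DEFAULT_MAX_EXACT_N = 8
DEFAULT_N_PERMUTATIONS = 999


class DegeneratePairError(ValueError):
    """All sample pairs are tied (C + D == 0); the statistic is undefined."""


class SampleSizeTooLargeError(ValueError):
    """n exceeds the exact-enumeration bound; use Monte Carlo instead."""


@dataclass(frozen=True)
class ConcordanceCounts:
    """Pair-concordance partition of the n(n-1)/2 sample index pairs.

    C: concordant; D: discordant; Tx: tied in x only; Ty: tied in y only;
    Txy: tied in both.  C + D + Tx + Ty + Txy == n(n-1)/2.
    """

    C: int
    D: int
    Tx: int
    Ty: int
    Txy: int
    n: int

    def __post_init__(self) -> None:
        total = self.n * (self.n - 1) // 2
        parts = (self.C, self.D, self.Tx, self.Ty, self.Txy)
        if any(v < 0 for v in parts):
            raise ValueError("concordance counts must be non-negative")
        if sum(parts) != total:
            raise ValueError(
                f"counts sum to {sum(parts)}, expected n(n-1)/2 = {total}"
            )


@dataclass(frozen=True)
class PairAssociation:
    """One unordered taxon pair's association within a single FDR family."""

    taxon_i: str
    taxon_j: str
    counts: ConcordanceCounts
    tau: float
    method: str
    p_value: float
    q_value: float

    @property
    def sign(self) -> str:
        if self.tau > 0:
            return "co_occurrence"
        if self.tau < 0:
            return "co_exclusion"
        return "none"


@dataclass(frozen=True)
class PairwiseResult:
    """All pairwise associations of one network family plus the excluded
    degenerate pairs (taxon_i, taxon_j, reason)."""

    associations: list[PairAssociation]
    degenerate: list[tuple[str, str, str]]
    method: str
    n: int


def _as_vector(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _pair_signs(x: np.ndarray) -> np.ndarray:
    """Signs of x[j] - x[i] over all index pairs i < j, as int8."""
    iu, ju = np.triu_indices(len(x), k=1)
    return np.sign(x[ju] - x[iu]).astype(np.int8)


def concordance_counts(x: Sequence[float], y: Sequence[float]) -> ConcordanceCounts:
    """Classify every sample index pair as concordant, discordant or tied.

    Vectorised over all n(n-1)/2 pairs; equivalent to the naive double loop
    comparing (x[i], x[j]) and (y[i], y[j]) orderings.
    """
    xv, yv = _as_vector(x, "x"), _as_vector(y, "y")
    if len(xv) != len(yv):
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    dx = _pair_signs(xv)
    dy = _pair_signs(yv)
    prod = dx.astype(np.int64) * dy
    C = int((prod > 0).sum())
    D = int((prod < 0).sum())
    Txy = int(((dx == 0) & (dy == 0)).sum())
    Tx = int(((dx == 0) & (dy != 0)).sum())
    Ty = int(((dx != 0) & (dy == 0)).sum())
    return ConcordanceCounts(C=C, D=D, Tx=Tx, Ty=Ty, Txy=Txy, n=n)


def association_statistic(counts: ConcordanceCounts, method: str = "gamma_paper") -> float:
    """Evaluate the rank-association statistic from concordance counts.

    ``gamma_paper`` is (C-D)/(C+D): tied pairs are ignored, so the value
    reaches +-1 for any fully concordant/discordant untied subset.
    ``tau_b`` is (C-D)/sqrt((C+D+Tx)(C+D+Ty)), the tie-corrected form.
    Both lie in [-1, 1] by construction; nothing is clamped numerically.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    cd = counts.C + counts.D
    if cd == 0:
        raise DegeneratePairError(
            "all sample pairs tied (C + D == 0); pair is non-assessable"
        )
    num = counts.C - counts.D
    if method == "gamma_paper":
        return num / cd
    denom = np.sqrt(float(cd + counts.Tx) * float(cd + counts.Ty))
    return num / denom


@lru_cache(maxsize=None)
def _all_permutations(n: int) -> np.ndarray:
    """All n! index permutations as an (n!, n) int8 array (n <= 8)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _null_counts_ge(
    dx: np.ndarray, y: np.ndarray, perms: np.ndarray, method: str
) -> tuple[int, int]:
    """Count permutations whose |statistic| >= the observed |statistic|.

    Returns (count, total).  All comparisons are exact integer arithmetic:
    for gamma, |num_p| * den_obs >= |num_obs| * den_p (a degenerate
    permutation has num_p = den_p = 0 and therefore always counts,
    conservatively); for tau_b the tie-structure denominators are invariant
    under permutation of y, so only |num| is compared.
    """
    n = y.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    Y = y[perms]  # (m, n)
    dy = np.sign(Y[:, ju] - Y[:, iu]).astype(np.int8)  # (m, npairs)
    dx64 = dx.astype(np.int64)
    num = dy @ dx64  # C - D per permutation
    obs_num = int(dx64 @ _pair_signs(y).astype(np.int64))
    if method == "tau_b":
        count = int((np.abs(num) >= abs(obs_num)).sum())
    else:
        absdx = np.abs(dx64)
        den = np.abs(dy) @ absdx  # C + D per permutation
        obs_den = int(absdx @ np.abs(_pair_signs(y)).astype(np.int64))
        count = int((np.abs(num) * obs_den >= abs(obs_num) * den).sum())
    return count, perms.shape[0]


def _check_pair(x: Sequence[float], y: Sequence[float], method: str) -> tuple:
    xv, yv = _as_vector(x, "x"), _as_vector(y, "y")
    if len(xv) != len(yv):
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if len(xv) < 3:
        raise ValueError(f"need at least 3 samples, got {len(xv)}")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    counts = concordance_counts(xv, yv)
    if counts.C + counts.D == 0:
        raise DegeneratePairError(
            "all sample pairs tied (C + D == 0); no p-value is defined"
        )
    return xv, yv, counts


def exact_p_value(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "gamma_paper",
    *,
    max_exact_n: int = DEFAULT_MAX_EXACT_N,
) -> float:
    """Two-sided exact permutation p-value by full n! enumeration.

    p is the proportion of all n! permutations of y whose |statistic| is at
    least the observed |statistic| (the observed/identity permutation is one
    of them, so p >= 1/n!).  Permutations for which every pair is tied count
    toward the numerator, conservatively.
    """
    xv, yv, _ = _check_pair(x, y, method)
    n = len(xv)
    if n > max_exact_n:
        raise SampleSizeTooLargeError(
            f"n = {n} exceeds max_exact_n = {max_exact_n}; "
            "use monte_carlo_p_value"
        )
    perms = _all_permutations(n)
    dx = _pair_signs(xv)
    count, total = _null_counts_ge(dx, yv, perms, method)
    return count / total


def monte_carlo_p_value(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "gamma_paper",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> float:
    """Two-sided Monte-Carlo permutation p-value with add-one correction.

    p = (1 + #{sampled |stat| >= observed |stat|}) / (1 + n_permutations);
    deterministic for a given seed.
    """
    if n_permutations < 999:
        raise ValueError("n_permutations must be at least 999")
    xv, yv, _ = _check_pair(x, y, method)
    rng = np.random.default_rng(seed)
    n = len(xv)
    perms = np.tile(np.arange(n), (n_permutations, 1))
    perms = rng.permuted(perms, axis=1)
    dx = _pair_signs(xv)
    count, total = _null_counts_ge(dx, yv, perms, method)
    return (1 + count) / (1 + total)


def permutation_p_value(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "gamma_paper",
    *,
    max_exact_n: int = DEFAULT_MAX_EXACT_N,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> tuple[float, str]:
    """Exact enumeration when n <= max_exact_n, else Monte Carlo.

    Returns (p_value, null_kind) where null_kind is ``"exact"`` or
    ``"monte_carlo"`` so callers can record which null was used.
    """
    try:
        return (
            exact_p_value(x, y, method, max_exact_n=max_exact_n),
            "exact",
        )
    except SampleSizeTooLargeError:
        return (
            monte_carlo_p_value(x, y, method, n_permutations, seed),
            "monte_carlo",
        )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending-sorted p's,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_associations(
    table: AbundanceTable,
    method: str = "gamma_paper",
    *,
    max_exact_n: int = DEFAULT_MAX_EXACT_N,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> PairwiseResult:
    """All unordered taxon-pair associations of one network family.

    The table must hold the samples of exactly one group x sample type x
    rank cell (>= 3 samples, >= 2 taxa); q-values are BH-adjusted over
    exactly this family.  Degenerate pairs (all sample pairs tied, e.g. two
    taxa absent from every sample of the group) are excluded from the family
    and reported separately with a reason.
    """
    if table.n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {table.n_samples}")
    if table.n_taxa < 2:
        raise ValueError(f"need >= 2 taxa, got {table.n_taxa}")
    matrix = table.data.to_numpy(dtype=float)
    taxa = table.taxon_ids
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    seed_seq = np.random.SeedSequence(seed)
    pair_seeds = [
        int(child.generate_state(1)[0] % (2**31))
        for child in seed_seq.spawn(len(pairs))
    ]
    kept: list[tuple[str, str, ConcordanceCounts, float, float]] = []
    degenerate: list[tuple[str, str, str]] = []
    for (i, j), pair_seed in zip(pairs, pair_seeds):
        x, y = matrix[:, i], matrix[:, j]
        counts = concordance_counts(x, y)
        if counts.C + counts.D == 0:
            degenerate.append(
                (taxa[i], taxa[j], "all sample pairs tied (C + D == 0)")
            )
            continue
        tau = association_statistic(counts, method)
        p, _ = permutation_p_value(
            x,
            y,
            method,
            max_exact_n=max_exact_n,
            n_permutations=n_permutations,
            seed=pair_seed,
        )
        kept.append((taxa[i], taxa[j], counts, tau, p))
    if not kept:
        raise ValueError("fewer than 2 non-degenerate taxa: no assessable pair")
    q_values = bh_fdr([rec[4] for rec in kept])
    associations = [
        PairAssociation(
            taxon_i=ti,
            taxon_j=tj,
            counts=counts,
            tau=tau,
            method=method,
            p_value=p,
            q_value=float(q),
        )
        for (ti, tj, counts, tau, p), q in zip(kept, q_values)
    ]
    return PairwiseResult(
        associations=associations,
        degenerate=degenerate,
        method=method,
        n=table.n_samples,
    )


_ASSOC_COLUMNS = [
    "taxon_i", "taxon_j", "n", "C", "D", "Tx", "Ty", "Txy",
    "tau", "method", "p_value", "q_value", "sign",
]


def write_associations(result: PairwiseResult, path: str | Path) -> None:
    """Write the long-format association TSV (one row per assessed pair)."""
    rows = [
        {
            "taxon_i": a.taxon_i,
            "taxon_j": a.taxon_j,
            "n": a.counts.n,
            "C": a.counts.C,
            "D": a.counts.D,
            "Tx": a.counts.Tx,
            "Ty": a.counts.Ty,
            "Txy": a.counts.Txy,
            "tau": a.tau,
            "method": a.method,
            "p_value": a.p_value,
            "q_value": a.q_value,
            "sign": a.sign,
        }
        for a in result.associations
    ]
    pd.DataFrame(rows, columns=_ASSOC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_associations(path: str | Path) -> list[PairAssociation]:
    """Read an association TSV written by :func:`write_associations`."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon_i": str, "taxon_j": str})
    out = []
    for row in df.itertuples(index=False):
        counts = ConcordanceCounts(
            C=int(row.C), D=int(row.D), Tx=int(row.Tx), Ty=int(row.Ty),
            Txy=int(row.Txy), n=int(row.n),
        )
        out.append(
            PairAssociation(
                taxon_i=row.taxon_i,
                taxon_j=row.taxon_j,
                counts=counts,
                tau=float(row.tau),
                method=str(row.method),
                p_value=float(row.p_value),
                q_value=float(row.q_value),
            )
        )
    return out
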