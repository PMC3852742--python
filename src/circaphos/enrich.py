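"""Monte Carlo permutation tests for kinase-target enrichment.

Two statistics: the overlap count between the differential site set and the
predicted-target set (null: redraw the differential set uniformly from the
detected universe without replacement, which is exactly hypergeometric), and
the difference in mean fold change between predicted targets and the rest
(null: permute the predicted labels over sites). All p-values use the add-one
rule p = (exceedances + 1) / (draws + 1), so p is never zero and the smallest
reportable value at n draws is 1/(n+1).

``hypergeometric_tail`` gives the exact null tail for the count statistic by
direct summation of binomial-coefficient ratios; it exists to cross-check the
Monte Carlo route and is never used to produce it.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Hashable, Iterable, Mapping

import numpy as np

_CHUNK = 10_000


@dataclass(frozen=True)
class EnrichmentResult:
    statistic_name: str
    observed: float
    n_permutations: int
    n_as_extreme: int
    p_value: float
    tail: str
    seed: int


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    N objects, K of them flagged, n drawn without replacement. Computed as a
    ratio of exact integer binomial sums, then converted to float.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not 0 <= k <= min(K, n):
        if k > min(K, n):
            return 0.0
        raise ValueError("k must be >= 0")
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return num / comb(N, n)


def _random_subsets_overlap(
    rng: np.random.Generator, flags: np.ndarray, n_draw: int, n_perm: int
) -> np.ndarray:
    """Overlap counts between ``n_perm`` uniform random n_draw-subsets of the
    universe and the flagged elements. Subsets are materialized explicitly
    (random-key order statistics), chunked to bound memory."""
    N = len(flags)
    counts = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(_CHUNK, n_perm - done)
        keys = rng.random((m, N))
        idx = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw] if n_draw > 0 else None
        if n_draw == 0:
            counts[done : done + m] = 0
        else:
            counts[done : done + m] = flags[idx].sum(axis=1)
        done += m
    return counts


def overrepresentation_test(
    differential_ids: set,
    predicted_flags: Mapping[Hashable, bool],
    universe: Iterable[Hashable],
    n_perm: int = 100_000,
    seed: int | None = None,
    tail: str = "greater",
) -> EnrichmentResult:
    """Monte Carlo test for over-/under-representation of predicted targets
    among differential sites.

    observed = |differential ∩ predicted|; null draws |differential| site ids
    from the detected universe without replacement.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible permutation tests")
    universe = sorted(universe)
    if not universe:
        raise ValueError("universe of detected sites must be non-empty")
    if not set(differential_ids) <= set(universe):
        raise ValueError("differential_ids must be a subset of the universe")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in {"greater", "less", "two-sided"}:
        raise ValueError(f"unknown tail {tail!r}")

    flags = np.array([bool(predicted_flags.get(u, False)) for u in universe])
    n_draw = len(differential_ids)
    observed = sum(1 for s in differential_ids if predicted_flags.get(s, False))

    rng = np.random.default_rng(seed)
    null = _random_subsets_overlap(rng, flags, n_draw, n_perm)

    ge = int(np.sum(null >= observed))
    le = int(np.sum(null <= observed))
    if tail == "greater":
        n_extreme, p = ge, (ge + 1) / (n_perm + 1)
    elif tail == "less":
        n_extreme, p = le, (le + 1) / (n_perm + 1)
    else:
        p_g = (ge + 1) / (n_perm + 1)
        p_l = (le + 1) / (n_perm + 1)
        n_extreme = min(ge, le)
        p = min(1.0, 2 * min(p_g, p_l))
    return EnrichmentResult("count_overlap", float(observed), n_perm, n_extreme, p, tail, seed)


def foldchange_shift_test(
    fold_changes: Mapping[Hashable, float],
    predicted_flags: Mapping[Hashable, bool],
    n_perm: int = 100_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Two-sided permutation test for a mean fold-change shift of predicted
    targets relative to the remaining sites.

    observed = mean(FC | predicted) - mean(FC | rest); null permutes the
    predicted labels over sites.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible permutation tests")
    sites = sorted(fold_changes)
    values = np.array([fold_changes[s] for s in sites], dtype=float)
    flags = np.array([bool(predicted_flags.get(s, False)) for s in sites])
    K = int(flags.sum())
    if K == 0 or K == len(sites):
        raise ValueError("need at least one predicted and one non-predicted site")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    observed = float(values[flags].mean() - values[~flags].mean())
    total = values.sum()
    N = len(values)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(_CHUNK, n_perm - done)
        keys = rng.random((m, N))
        idx = np.argpartition(keys, K - 1, axis=1)[:, :K]
        sel = values[idx].sum(axis=1)
        null[done : done + m] = sel / K - (total - sel) / (N - K)
        done += m

    n_extreme = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p = (n_extreme + 1) / (n_perm + 1)
    return EnrichmentResult("mean_fc_diff", observed, n_perm, n_extreme, p, "two-sided", seed)


def result_to_dict(res: EnrichmentResult) -> dict:
    return {
        "statistic": res.statistic_name,
        "observed": res.observed,
        "n_permutations": res.n_permutations,
        "n_as_extreme": res.n_as_extreme,
        "p_value": res.p_value,
        "tail": res.tail,
        "seed": res.seed,
    }
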