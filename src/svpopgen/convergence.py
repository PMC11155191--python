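"""Cross-species shared-ortholog counting and the permutation test for
excess convergent gene-use (molecular parallelism)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class OrthologMap:
    """One-to-one ortholog pairs between two species' gene symbols.

    Pairs reusing a gene id on either side are dropped (first occurrence
    wins); the number dropped is recorded.
    """

    a_to_b: dict[str, str] = field(default_factory=dict)
    n_dropped: int = 0

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "OrthologMap":
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        a_to_b: dict[str, str] = {}
        dropped = 0
        for a, b in pairs:
            if a in seen_a or b in seen_b:
                dropped += 1
                continue
            seen_a.add(a)
            seen_b.add(b)
            a_to_b[a] = b
        return cls(a_to_b=a_to_b, n_dropped=dropped)

    def __len__(self) -> int:
        return len(self.a_to_b)


def shared_orthologs(
    genes_a: set[str] | list[str],
    genes_b: set[str] | list[str],
    orthologs: OrthologMap,
) -> tuple[list[str], int]:
    """Species-A genes whose ortholog is in the species-B set.

    Returns the sorted shared list and the number of A genes with no entry in
    the map (unmapped; reported, not an error).  The shared count is symmetric
    under swapping A and B (with the map inverted).
    """
    if len(orthologs) == 0:
        raise ValueError("empty ortholog map")
    genes_b = set(genes_b)
    shared, unmapped = [], 0
    for a in set(genes_a):
        b = orthologs.a_to_b.get(a)
        if b is None:
            unmapped += 1
        elif b in genes_b:
            shared.append(a)
    return sorted(shared), unmapped


@dataclass
class ConvergenceResult:
    k_obs: int
    n_a: int
    n_b: int
    universe: int
    n_perm: int
    p_value: float
    expected: float  # hypergeometric expectation nA*nB/U
    null_mean: float
    null_counts: np.ndarray
    seed: int | None

    def summary(self) -> dict:
        return {
            "k_obs": self.k_obs,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "universe": self.universe,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "expected": self.expected,
            "null_mean": self.null_mean,
            "seed": self.seed,
        }


def convergence_permutation_test(
    n_a: int,
    n_b: int,
    universe: int,
    k_obs: int,
    n_perm: int = 1000,
    seed: int | None = None,
    smoothing: bool = False,
) -> ConvergenceResult:
    """Upper-tail permutation P for the shared-ortholog count.

    The universe is the set of ortholog pairs eligible for selection in both
    species (an explicit, consequential choice — see the expectation it
    implies).  Each replicate draws uniform gene sets of sizes ``n_a`` and
    ``n_b`` from the universe and counts pairs hit on both sides, so the null
    count is hypergeometric with mean ``n_a*n_b/universe``.
    ``P = #{k_perm >= k_obs} / B`` (optionally (k+1)/(B+1) smoothed).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    if n_a > universe or n_b > universe:
        raise ValueError("gene-set sizes exceed the universe")
    if k_obs > min(n_a, n_b):
        raise ValueError("observed shared count exceeds the smaller gene set")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        a = rng.choice(universe, size=n_a, replace=False)
        b_mask = np.zeros(universe, dtype=bool)
        b_mask[rng.choice(universe, size=n_b, replace=False)] = True
        counts[i] = int(b_mask[a].sum())
    k_exceed = int((counts >= k_obs).sum())
    p = (k_exceed + 1) / (n_perm + 1) if smoothing else k_exceed / n_perm
    return ConvergenceResult(
        k_obs=k_obs,
        n_a=n_a,
        n_b=n_b,
        universe=universe,
        n_perm=n_perm,
        p_value=float(p),
        expected=n_a * n_b / universe,
        null_mean=float(counts.mean()),
        null_counts=counts,
        seed=seed,
    )


def parallelism_percentage(n_shared: int, n_candidates: int) -> float:
    """Shared (convergent) genes as a percentage of one species' candidates."""
    if n_candidates <= 0:
        raise ValueError("candidate count must be positive")
    if n_shared > n_candidates:
        raise ValueError("shared count exceeds candidate count")
    return 100.0 * n_shared / n_candidates
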