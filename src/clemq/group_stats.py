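"""Group comparisons across granule age pools.

Three procedures mirror the study's statistics track:

* a classical one-way fixed-effects ANOVA across the age groups;
* a sequential post-hoc grouping procedure — pairwise t-tests among the
  youngest groups, pooling the indistinguishable ones into a single large
  group, then comparing that pooled group against each older group;
* a Beta-Binomial comparison of MGB co-occurrence counts, reporting the
  posterior probability that the per-cell rate in one age class exceeds
  the other (a re-specification of the original, unpublished Bayesian
  analysis).

t-tests default to Welch's unequal-variance variant; p-values are raw,
with Bonferroni correction available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AgeGroupSample",
    "PosthocResult",
    "BayesCountResult",
    "one_way_anova",
    "sequential_posthoc",
    "bayes_count_compare",
]


@dataclass(frozen=True)
class AgeGroupSample:
    """Per-replicate measurements for one granule age group."""

    age_label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError(f"group {self.age_label!r} is empty")

    @property
    def n(self) -> int:
        return len(self.values)


def one_way_anova(groups: list[AgeGroupSample]) -> tuple[float, float]:
    """Classical one-way fixed-effects F test with (k-1, N-k) df."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.age_label!r} has fewer than two values")
    if all(np.ptp(g.values) == 0 for g in groups) and len({g.values[0] for g in groups}) == 1:
        raise ValueError("all values identical; ANOVA is degenerate")
    f, p = stats.f_oneway(*[np.asarray(g.values) for g in groups])
    return float(f), float(p)


@dataclass
class PosthocResult:
    """Outcome of the sequential pooling procedure."""

    pooled_labels: list[str]
    remaining_labels: list[str]
    pooling_pvalues: dict[tuple[str, str], float]
    final_pvalues: dict[str, float]
    alpha: float


def _ttest(a, b, equal_var: bool) -> float:
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def sequential_posthoc(
    groups: list[AgeGroupSample],
    alpha: float = 0.05,
    equal_var: bool = False,
    bonferroni: bool = False,
) -> PosthocResult:
    """Pool age-indistinguishable young groups, then test against old ones.

    Groups must be ordered young to old.  Starting from the youngest, each
    next group is tested pairwise against every group already in the pool;
    if no test is significant at ``alpha`` it joins the pool, otherwise
    pooling stops.  The pooled values are then tested against each
    remaining group and all p-values reported (raw by default;
    ``bonferroni`` scales the final p-values by their count).
    """
    if len(groups) < 3:
        raise ValueError("sequential post-hoc needs at least three ordered groups")
    pool = [groups[0]]
    pooling_p: dict[tuple[str, str], float] = {}
    idx = 1
    while idx < len(groups) - 1:
        cand = groups[idx]
        ps = {}
        for g in pool:
            ps[(g.age_label, cand.age_label)] = _ttest(g.values, cand.values, equal_var)
        pooling_p.update(ps)
        if any(p < alpha for p in ps.values()):
            break
        pool.append(cand)
        idx += 1
    remaining = groups[idx:]
    pooled_values = np.concatenate([np.asarray(g.values) for g in pool])
    final_p: dict[str, float] = {}
    for g in remaining:
        p = _ttest(pooled_values, g.values, equal_var)
        if bonferroni:
            p = min(1.0, p * len(remaining))
        final_p[g.age_label] = p
    return PosthocResult(
        pooled_labels=[g.age_label for g in pool],
        remaining_labels=[g.age_label for g in remaining],
        pooling_pvalues=pooling_p,
        final_pvalues=final_p,
        alpha=alpha,
    )


@dataclass(frozen=True)
class BayesCountResult:
    """Posterior comparison of two binomial rates under Beta(1,1) priors."""

    prob_b_greater: float
    ci_low: float  # 95% credible interval for p_b - p_a
    ci_high: float
    posterior_a: tuple[float, float]  # Beta parameters
    posterior_b: tuple[float, float]


def _one_sided_mass(post_b, post_a, grid: np.ndarray, weights: np.ndarray) -> float:
    # integral of pdf_b(q) * cdf_a(q) dq = P(p_b > p_a) on a shared grid
    return float(np.sum(weights * post_b.pdf(grid) * post_a.cdf(grid)))


def bayes_count_compare(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
    n_grid: int = 4001,
    n_mc: int = 200_000,
    seed: int = 0,
    method: str = "grid",
) -> BayesCountResult:
    """P(rate_b > rate_a) from independent Beta-Binomial posteriors.

    ``counts_* = (successes, trials)``.  Posteriors are Beta(1+s, 1+f).
    The one-sided probability is computed by quadrature of
    ``pdf_b * cdf_a`` on a shared grid, normalized against its mirror so
    that the comparison and its reverse sum to one by construction
    (``method='mc'`` uses seeded Monte-Carlo draws instead).  The 95%
    credible interval for ``p_b - p_a`` always comes from seeded posterior
    sampling.
    """
    for name, (s, t) in (("a", counts_a), ("b", counts_b)):
        if not 0 <= s <= t:
            raise ValueError(f"counts_{name}: need 0 <= successes <= trials, got {s}/{t}")
    sa, ta = counts_a
    sb, tb = counts_b
    post_a = stats.beta(1 + sa, 1 + ta - sa)
    post_b = stats.beta(1 + sb, 1 + tb - sb)
    rng = np.random.default_rng(seed)
    draws_a = post_a.rvs(n_mc, random_state=rng)
    draws_b = post_b.rvs(n_mc, random_state=rng)
    if method == "grid":
        # midpoint rule on (0, 1); shared grid keeps the mirror symmetric
        grid = (np.arange(n_grid) + 0.5) / n_grid
        w = np.full(n_grid, 1.0 / n_grid)
        fwd = _one_sided_mass(post_b, post_a, grid, w)
        rev = _one_sided_mass(post_a, post_b, grid, w)
        prob = fwd / (fwd + rev)
    elif method == "mc":
        prob = float(np.mean(draws_b > draws_a))
    else:
        raise ValueError(f"unknown method {method!r}")
    diff = draws_b - draws_a
    lo, hi = np.quantile(diff, [0.025, 0.975])
    return BayesCountResult(
        prob_b_greater=prob,
        ci_low=float(lo),
        ci_high=float(hi),
        posterior_a=(1 + sa, 1 + ta - sa),
        posterior_b=(1 + sb, 1 + tb - sb),
    )
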