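"""Association between network states and propagation types.

The question is whether the functional network state during a spike event
is independent of how that spike propagated.  With both variables
categorical (3 network states x 3 wave types in the reference analysis),
the tools are the Pearson chi-squared test on the contingency table
(df = (r-1)(c-1) = 4 for 3x3) and Cramér's V
``sqrt(chi2 / (n (min(r, c) - 1)))`` as the effect size.

Because k-means type labels depend on the random seed, the test is also
run repeatedly — one k-means re-clustering of the delay features per run —
yielding distributions of chi-squared and V.  Chance level comes from a
label-permutation null (network-state labels shuffled per run, preserving
both marginals), and a one-sided Wilcoxon rank-sum test compares the
observed V distribution against that null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "AssociationResult",
    "RepeatedAssociation",
    "contingency",
    "chi_squared",
    "cramers_v",
    "associate",
    "repeated_association",
]


def contingency(states: np.ndarray, types: np.ndarray) -> np.ndarray:
    """Cross-tabulate two equal-length label vectors into an r x c table.

    Rows follow the sorted unique states, columns the sorted unique types.
    """
    states = np.asarray(states)
    types = np.asarray(types)
    if states.shape != types.shape or states.ndim != 1:
        raise ValueError("states and types must be equal-length 1-D vectors")
    s_levels, s_idx = np.unique(states, return_inverse=True)
    t_levels, t_idx = np.unique(types, return_inverse=True)
    table = np.zeros((s_levels.size, t_levels.size), dtype=int)
    np.add.at(table, (s_idx, t_idx), 1)
    return table


def chi_squared(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a contingency table.

    Zero-marginal rows/columns are dropped (with a warning) before the df
    computation; an expected count below 5 warns but does not fail.  No
    continuity correction is applied (it is a 2x2-only adjustment).
    Returns ``(chi2, df, p_value)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-marginal rows/columns before the test",
                      UserWarning)
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need >= 2 rows and columns with positive marginals")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if np.any(expected < 5):
        warnings.warn("expected count below 5; chi-squared approximation may "
                      "be poor", UserWarning)
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    """Cramér's V = sqrt(chi2 / (n (min(r, c) - 1))), in [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if min(r, c) < 2:
        raise ValueError("V needs at least 2 levels on each margin")
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


@dataclass
class AssociationResult:
    """One chi-squared association test plus its effect size."""

    table: np.ndarray
    chi2: float
    df: int
    p_value: float
    cramers_v: float
    n: int


def associate(states: np.ndarray, types: np.ndarray) -> AssociationResult:
    """Contingency + chi-squared + Cramér's V in one call."""
    table = contingency(states, types)
    chi2, df, p = chi_squared(table)
    n = int(table.sum())
    v = cramers_v(chi2, n, *table.shape)
    return AssociationResult(table=table, chi2=chi2, df=df, p_value=p,
                             cramers_v=v, n=n)


@dataclass
class RepeatedAssociation:
    """Distributions over repeated seeded re-clusterings of the wave types.

    ``v_samples`` are the observed Cramér's V per run; ``null_v_samples``
    the V of the same types against permuted network states;
    ``rank_sum_p`` the one-sided Wilcoxon rank-sum p-value that the
    observed V exceed chance.
    """

    runs: int
    chi2_samples: np.ndarray
    v_samples: np.ndarray
    null_v_samples: np.ndarray
    rank_sum_p: float
    n_reseeded: int = 0


def repeated_association(projected_features: np.ndarray,
                         network_states: np.ndarray, k: int = 3,
                         runs: int = 1000, base_seed: int = 0
                         ) -> RepeatedAssociation:
    """Re-cluster the wave types ``runs`` times and test association each time.

    Per run ``r``: a single k-means initialization seeded ``base_seed + r``
    labels the projected delay features (one init per run — the run-to-run
    variability of k-means is the quantity being integrated over); the
    chi-squared statistic and Cramér's V against the *fixed* network states
    are recorded; and a null V is drawn by permuting the network-state
    labels with the same run seed.  A degenerate run (empty cluster) is
    re-seeded and counted.
    """
    X = np.asarray(projected_features, dtype=float)
    states = np.asarray(network_states)
    if X.shape[0] != states.size:
        raise ValueError("one network state per event required")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    chi2_s = np.empty(runs)
    v_s = np.empty(runs)
    v_null = np.empty(runs)
    n = states.size
    n_reseeded = 0
    for run in range(runs):
        seed = int(base_seed) + run
        for attempt in range(100):
            km = KMeans(n_clusters=k, n_init=1, random_state=seed + attempt * runs)
            types = km.fit_predict(X)
            if np.unique(types).size == k:
                break
            n_reseeded += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            chi2, _df, _p = chi_squared(contingency(states, types))
            v_s[run] = cramers_v(chi2, n, np.unique(states).size, k)
            chi2_s[run] = chi2
            rng = np.random.default_rng(seed)
            perm = rng.permutation(states)
            chi2_0, _, _ = chi_squared(contingency(perm, types))
            v_null[run] = cramers_v(chi2_0, n, np.unique(perm).size, k)
    p = float(stats.ranksums(v_s, v_null, alternative="greater").pvalue)
    return RepeatedAssociation(runs=runs, chi2_samples=chi2_s, v_samples=v_s,
                               null_v_samples=v_null, rank_sum_p=p,
                               n_reseeded=n_reseeded)
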