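"""Cohort-description statistics for a three-stage case-control design.

Categorical covariates are compared across CN/MCI/AD with Pearson's
chi-square on the r x c contingency table (no continuity correction — the
convention that reproduces standard staged-cohort tables). Continuous
measures are gated by a per-group Shapiro-Wilk normality test: normal
variables go to Hotelling's T2 (multivariate) or its univariate special
case, non-normal ones to Kruskal-Wallis with pairwise Mann-Whitney U tests
under a Bonferroni factor of 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMetadata, GROUPS


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    low_expected_warning: bool  # any expected cell < 5


def chi_square_independence(counts) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts are row x column marginals over the total; p comes from
    the chi-square upper tail with (r-1)(c-1) degrees of freedom. No Yates
    correction. A table with any expected count below 5 is still tested but
    flagged.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=1) == 0) or np.any(obs.sum(axis=0) == 0):
        raise ValueError("zero marginal row/column")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    low = bool(np.any(expected < 5))
    if low:
        warnings.warn("some expected counts < 5; chi-square approximation is weak")
    return ContingencyResult(observed=obs, expected=expected, chi2=float(chi2),
                             df=int(df), p_value=float(p),
                             low_expected_warning=low)


@dataclass
class GroupComparisonResult:
    variable: str
    overall_test: str  # "kruskal-wallis" or "hotelling-t2"
    overall_p: float
    pairwise_p: dict[str, float]       # "CN-MCI" etc. -> raw two-sided p
    bonferroni_flags: dict[str, bool]  # raw p < 0.05 / n_pairs


def kruskal_then_pairwise(values_by_group: dict[str, np.ndarray],
                          variable: str = "") -> GroupComparisonResult:
    """Kruskal-Wallis omnibus test followed by all pairwise Mann-Whitney U
    tests; pairwise significance flags use a Bonferroni divisor equal to
    the number of pairs (3 for three groups)."""
    groups = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) and \
            len(np.unique(arrays[0])) == 1:
        overall_p = 1.0  # all values identical: no evidence of any difference
    else:
        try:
            overall_p = float(stats.kruskal(*arrays).pvalue)
        except ValueError:  # all numbers identical across groups
            overall_p = 1.0
    pairs = list(combinations(range(len(groups)), 2))
    pairwise: dict[str, float] = {}
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        if np.array_equal(np.sort(a), np.sort(b)) and len(np.unique(a)) == 1:
            p = 1.0
        else:
            pooled = np.concatenate([a, b])
            exact = a.size <= 8 and b.size <= 8 and len(np.unique(pooled)) == pooled.size
            p = float(stats.mannwhitneyu(
                a, b, alternative="two-sided",
                method="exact" if exact else "asymptotic",
                use_continuity=True).pvalue)
        pairwise[f"{groups[i]}-{groups[j]}"] = p
    alpha = 0.05 / len(pairs)
    flags = {k: v < alpha for k, v in pairwise.items()}
    return GroupComparisonResult(variable=variable,
                                 overall_test="kruskal-wallis",
                                 overall_p=overall_p, pairwise_p=pairwise,
                                 bonferroni_flags=flags)


def hotelling_t2(group_a, group_b) -> tuple[float, float, float]:
    """Two-sample Hotelling's T2 on low-dimensional observations.

    T2 = (n1 n2 / (n1 + n2)) d' S_pooled^-1 d with d the mean difference;
    the F transform uses (dim, n1 + n2 - dim - 1) degrees of freedom. In
    one dimension T2 equals the squared pooled-variance t statistic.
    """
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    n1, dim = A.shape
    n2, dim2 = B.shape
    if dim != dim2:
        raise ValueError("dimension mismatch between groups")
    if n1 + n2 - 2 <= dim:
        raise ValueError("combined n - 2 must exceed the dimension")
    d = A.mean(axis=0) - B.mean(axis=0)
    S = (((n1 - 1) * np.cov(A, rowvar=False, ddof=1).reshape(dim, dim)
          + (n2 - 1) * np.cov(B, rowvar=False, ddof=1).reshape(dim, dim))
         / (n1 + n2 - 2))
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular pooled covariance; reduce the dimension (use scores "
            "or a covariate subset)"
        ) from None
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    f_stat = t2 * (n1 + n2 - dim - 1) / (dim * (n1 + n2 - 2))
    p = float(stats.f.sf(f_stat, dim, n1 + n2 - dim - 1))
    return t2, float(f_stat), p


def normality_gate(values_by_group: dict[str, np.ndarray],
                   alpha: float = 0.05) -> str:
    """Route a variable to parametric or rank-based testing.

    Shapiro-Wilk per group at the given alpha; "normal" only when every
    group passes. Groups with n < 3 or constant values route to
    "non-normal" with a warning (the test is undefined there).
    """
    for g, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3 or len(np.unique(v)) == 1:
            warnings.warn(f"group {g}: too few or constant values; treating as non-normal")
            return "non-normal"
        if stats.shapiro(v).pvalue < alpha:
            return "non-normal"
    return "normal"


def _fmt_median(vals: np.ndarray) -> str:
    q25, med, q75 = np.percentile(vals, [25, 50, 75])
    return f"{med:g} ({q25:g}, {q75:g})"


def cohort_table(metadata: SampleMetadata,
                 categorical: list[str] | None = None,
                 continuous: list[str] | None = None) -> pd.DataFrame:
    """A staged-cohort description table: per-group summaries with an
    overall p per covariate and pairwise Bonferroni significance letters.

    Categorical covariates get level counts and a chi-square p; continuous
    ones get median (P25, P75) and the normality-gated omnibus p with
    pairwise flags (a = AD vs CN, b = MCI vs CN, c = AD vs MCI).
    """
    bio = metadata.table.loc[metadata.biological_ids]
    covars = [c for c in bio.columns if c not in ("group", "is_qc")]
    if categorical is None:
        categorical = [c for c in covars if not pd.api.types.is_numeric_dtype(bio[c])]
    if continuous is None:
        continuous = [c for c in covars if pd.api.types.is_numeric_dtype(bio[c])]
    letter = {"CN-AD": "a", "CN-MCI": "b", "MCI-AD": "c"}
    rows = []
    for var in categorical:
        levels = sorted(bio[var].dropna().unique())
        counts = np.array([[int(((bio["group"] == g) & (bio[var] == lv)).sum())
                            for lv in levels] for g in GROUPS])
        res = chi_square_independence(counts)
        row = {"variable": f"{var} ({'/'.join(map(str, levels))})",
               "test": "chi-square", "p": res.p_value, "flags": ""}
        for g in GROUPS:
            sub = bio[bio["group"] == g]
            row[g] = "/".join(str(int((sub[var] == lv).sum())) for lv in levels)
        rows.append(row)
    for var in continuous:
        by_group = {g: bio.loc[bio["group"] == g, var].dropna().to_numpy(dtype=float)
                    for g in GROUPS}
        gate = normality_gate(by_group)
        if gate == "normal":
            pair_p = {}
            for a, b in combinations(GROUPS, 2):
                t2, f_stat, p = hotelling_t2(by_group[a][:, None], by_group[b][:, None])
                pair_p[f"{a}-{b}"] = p
            overall_p = float(stats.f_oneway(*by_group.values()).pvalue)
            flags = {k: v < 0.05 / 3 for k, v in pair_p.items()}
            test = "anova+t2"
        else:
            res = kruskal_then_pairwise(by_group, var)
            overall_p, flags, test = res.overall_p, res.bonferroni_flags, res.overall_test
        row = {"variable": var, "test": test, "p": overall_p,
               "flags": "".join(letter[k] for k, v in sorted(flags.items()) if v)}
        for g in GROUPS:
            row[g] = _fmt_median(by_group[g])
        rows.append(row)
    cols = ["variable"] + list(GROUPS) + ["test", "p", "flags"]
    return pd.DataFrame(rows)[cols]
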