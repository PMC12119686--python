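"""Nonparametric association battery for the epitope matrix and covariates.

Continuous variables are compared between groups with two-sided
Mann-Whitney U tests (exact null for small tie-free samples, normal
approximation with tie correction otherwise); correlations use Spearman's
rank coefficient; binary-by-binary contingencies use Fisher's exact test
(the standard exact treatment of a 2x2 table with small cells); paired
comparisons use the Wilcoxon signed-rank test, and multiple paired
conditions the Friedman test followed by Dunn's all-pairs z comparisons
with Bonferroni adjustment.

No multiplicity correction is applied across an association table by
default; a Benjamini-Hochberg switch is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .epitope_caller import SubjectEpitopeMatrix
from .serology import SubjectRecord, percentile_cutoff, records_to_frame

ALPHA = 0.05
EXACT_MAX_N = 12


class DataError(ValueError):
    pass


class SpecificationError(KeyError):
    pass


@dataclass
class GroupComparison:
    variable: str
    group_labels: tuple[str, str]
    summaries: dict[str, tuple[float, tuple[float, float]]]  # median, (q1, q3)
    statistic: float
    p_value: float
    test: str
    note: str = ""


def _summary(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Median and IQR by the nearest-rank convention used for serology cutoffs."""
    med = percentile_cutoff(values, 50) if values.size >= 2 else float(values[0])
    if values.size >= 2:
        q1, q3 = percentile_cutoff(values, 25), percentile_cutoff(values, 75)
    else:
        q1 = q3 = float(values[0])
    return med, (q1, q3)


def compare_groups_continuous(
    values: Sequence[float],
    group_flags: Sequence[bool],
    variable: str = "",
    group_labels: tuple[str, str] = ("group0", "group1"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U between the two groups defined by ``group_flags``.

    Uses the exact null distribution when the smaller group has at most 12
    observations and there are no ties; otherwise the normal approximation
    with tie correction (no continuity correction, so that symmetric inputs
    give p = 1).
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(group_flags, dtype=bool)
    x, y = values[~flags], values[flags]
    if x.size == 0 or y.size == 0:
        raise DataError(f"{variable or 'comparison'}: a group is empty")
    ties = np.unique(values).size < values.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MAX_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return GroupComparison(
        variable=variable,
        group_labels=group_labels,
        summaries={
            group_labels[0]: _summary(x),
            group_labels[1]: _summary(y),
        },
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        test=f"Mann-Whitney U ({method})",
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rank correlation with tie-aware ranks; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("correlate needs paired vectors of length >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def exact_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Fisher's exact two-sided test on a 2x2 table.

    Returns the sample odds ratio (with a 0.5 continuity correction applied
    to every cell when any cell is zero) and the point-probability-method
    two-sided p-value.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise DataError(f"need a 2x2 table of non-negative counts, got {t!r}")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return float(odds_ratio), float(p)


def paired_compare(
    before: Sequence[float], after: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test; zero differences are dropped."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size or before.size == 0:
        raise DataError("paired_compare needs equal-length non-empty vectors")
    diffs = after - before
    nonzero = diffs[diffs != 0]
    note = ""
    if nonzero.size == 0:
        note = "all paired differences are zero; p = 1 by convention"
        warnings.warn(note, stacklevel=2)
        stat, p = 0.0, 1.0
    else:
        if nonzero.size < 6:
            note = f"only {nonzero.size} non-zero pair(s); test has little power"
            warnings.warn(note, stacklevel=2)
        res = stats.wilcoxon(
            before, after, zero_method="wilcox", alternative="two-sided",
            method="exact" if nonzero.size <= EXACT_MAX_N else "auto",
        )
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        variable=variable,
        group_labels=("before", "after"),
        summaries={"before": _summary(before), "after": _summary(after)},
        statistic=stat,
        p_value=p,
        test="Wilcoxon signed-rank",
        note=note,
    )


def _friedman(ranks: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square with tie correction, valid for any k >= 2.

    Computed from within-subject ranks directly (scipy's implementation
    requires k >= 3; k = 2 reduces to a sign-test ordering).
    """
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction over within-subject tie groups
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, 1.0
    chi2 /= correction
    return float(chi2), float(stats.chi2.sf(chi2, k - 1))


def multi_paired_compare(
    condition_matrix: pd.DataFrame | np.ndarray,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> tuple[GroupComparison, pd.DataFrame]:
    """Friedman omnibus over k conditions x n subjects, then Dunn's pairwise z.

    ``condition_matrix`` has one row per subject, one column per condition.
    Dunn's z uses within-subject mean ranks and a Bonferroni adjustment over
    the tested pairs (all pairs when ``pairs`` is None).
    """
    data = np.asarray(condition_matrix, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise DataError("need an n x k matrix with k >= 2 conditions")
    n, k = data.shape
    names = (
        list(condition_matrix.columns)
        if isinstance(condition_matrix, pd.DataFrame)
        else [f"cond{j}" for j in range(k)]
    )
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    if np.allclose(data, data[:, [0]]):
        warnings.warn("all conditions identical; Friedman p = 1 by convention")
        chi2, p = 0.0, 1.0
    else:
        chi2, p = _friedman(ranks)
    omnibus = GroupComparison(
        variable="omnibus",
        group_labels=(names[0], names[-1]),
        summaries={names[j]: _summary(data[:, j]) for j in range(k)},
        statistic=float(chi2),
        p_value=float(p),
        test="Friedman",
    )
    if pairs is None:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    m = len(pairs)
    for i, j in pairs:
        z = (mean_ranks[j] - mean_ranks[i]) / se
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append((names[i], names[j], z, p_raw, min(1.0, p_raw * m)))
    dunn = pd.DataFrame(
        rows, columns=["condition_a", "condition_b", "z", "p_raw", "p_adjusted"]
    )
    return omnibus, dunn


# ---------------------------------------------------------------------------
# association tables


@dataclass
class AssociationTable:
    rows: pd.DataFrame
    note: str = "no multiplicity correction across rows"


def _resolve_variable(
    name: str,
    matrix: SubjectEpitopeMatrix,
    records_df: pd.DataFrame,
) -> tuple[pd.Series, str]:
    """Return (series indexed by subject, kind in {'binary','continuous'})."""
    if name == "group":
        return (matrix.groups == "SLE").astype(bool), "binary"
    if name == "any_epitope_positive":
        return (matrix.per_subject_totals > 0), "binary"
    if name == "n_epitopes":
        return matrix.per_subject_totals.astype(float), "continuous"
    if name in matrix.positivity.columns:
        return matrix.positivity[name].astype(bool), "binary"
    if name in records_df.columns:
        col = records_df[name]
        if col.dtype == bool:
            return col, "binary"
        return col.astype(float), "continuous"
    raise SpecificationError(f"unknown variable {name!r}")


def build_association_table(
    matrix: SubjectEpitopeMatrix,
    records: Iterable[SubjectRecord],
    spec: Sequence[tuple[str, str, str]],
    alpha: float = ALPHA,
    bh_correction: bool = False,
) -> AssociationTable:
    """Run the declared (lhs, rhs, test) associations.

    ``test`` may be ``"auto"`` (binary x binary -> Fisher exact, binary x
    continuous -> Mann-Whitney, continuous x continuous -> Spearman) or one
    of ``"fisher"``, ``"mannwhitney"``, ``"spearman"`` explicitly.  Rows
    with a constant variable are emitted with p = NA and a degenerate-test
    note.
    """
    records_df = records_to_frame(records)
    rows = []
    for lhs, rhs, test in spec:
        ls, lkind = _resolve_variable(lhs, matrix, records_df)
        rs, rkind = _resolve_variable(rhs, matrix, records_df)
        common = ls.index.intersection(rs.index)
        ls, rs = ls.loc[common], rs.loc[common]
        if rkind == "continuous" or lkind == "continuous":
            keep = ~(pd.isna(ls) | pd.isna(rs))
            ls, rs = ls[keep], rs[keep]
        if test == "auto":
            test = {
                ("binary", "binary"): "fisher",
                ("binary", "continuous"): "mannwhitney",
                ("continuous", "binary"): "mannwhitney",
                ("continuous", "continuous"): "spearman",
            }[(lkind, rkind)]
        note = ""
        effect: float = float("nan")
        stat: float = float("nan")
        p: float = float("nan")
        degenerate = (lkind == "binary" and ls.nunique() < 2) or (
            rkind == "binary" and rs.nunique() < 2
        )
        if degenerate:
            note = "degenerate: constant variable"
            warnings.warn(f"{lhs} vs {rhs}: {note}", stacklevel=2)
        elif test == "fisher":
            table = pd.crosstab(ls, rs).reindex(
                index=[False, True], columns=[False, True], fill_value=0
            )
            effect, p = exact_2x2(table.to_numpy())
            stat = float(table.to_numpy()[1, 1])
        elif test == "mannwhitney":
            flags, vals = (ls, rs) if lkind == "binary" else (rs, ls)
            cmp = compare_groups_continuous(
                vals.to_numpy(), flags.to_numpy(), variable=f"{lhs} vs {rhs}"
            )
            med0 = cmp.summaries[cmp.group_labels[0]][0]
            med1 = cmp.summaries[cmp.group_labels[1]][0]
            effect = med1 - med0
            stat, p = cmp.statistic, cmp.p_value
        elif test == "spearman":
            effect, p = correlate(ls.to_numpy(), rs.to_numpy())
            stat = effect
        else:
            raise SpecificationError(f"unknown test {test!r}")
        rows.append((lhs, rhs, test, effect, stat, p, note))
    df = pd.DataFrame(
        rows, columns=["lhs", "rhs", "test", "effect", "statistic", "p_value", "note"]
    )
    if bh_correction:
        valid = df["p_value"].notna()
        p = df.loc[valid, "p_value"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        df.loc[valid, "p_adjusted"] = adj
        df["significant"] = df.get("p_adjusted", df["p_value"]) < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    return AssociationTable(rows=df)


def write_association_table(table: AssociationTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
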