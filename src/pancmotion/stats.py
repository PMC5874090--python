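"""Friedman tests with Conover post-hoc homogeneous groups.

The Friedman test is the nonparametric repeated-measures comparison of
k treatments observed in b blocks: values are mid-ranked within each
block and the tie-corrected chi-square statistic

    T1 = (k - 1) * sum_j (R_j - b(k+1)/2)^2 / (A1 - C1)

is referred to chi-square with k - 1 degrees of freedom, where R_j are
treatment rank sums, A1 the sum of squared ranks and C1 = b k (k+1)^2/4.
An exact permutation p-value (enumeration of all within-block orderings)
is available for small designs.

The post-hoc step is the rank analogue of Fisher's protected least
significant difference as proposed by Conover: pairwise statistics

    t_ij = |R_i - R_j| / sqrt( 2 b (A1 - C1) / ((b-1)(k-1))
                               * (1 - T1 / (b (k-1))) )

are referred to Student's t with (b-1)(k-1) degrees of freedom, run only
when the omnibus test is significant.  Because every pair shares one
critical difference, the non-significant pairs of treatments sorted by
rank sum form intervals, and homogeneous groups are rendered as maximal
such intervals, each carrying one symbol -- treatments sharing a symbol
are statistically indistinguishable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Symbols used in rendered homogeneous-group tables.
GROUP_SYMBOLS = ("X", "•", "|", "+", "#", "~")


@dataclass
class BlockDesign:
    """Complete-block matrix of values: rows are blocks, columns treatments."""

    values: np.ndarray  # (b, k)
    block_labels: list[str] | None = None
    treatment_labels: list[str] | None = None
    comparison: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be a blocks x treatments matrix")
        b, k = self.values.shape
        if k < 2 or b < 2:
            raise ValueError("need at least 2 treatments and 2 blocks")
        if np.isnan(self.values).any():
            raise ValueError("design contains missing cells; drop incomplete blocks")
        if self.treatment_labels is None:
            self.treatment_labels = [f"T{j + 1}" for j in range(k)]
        if self.block_labels is None:
            self.block_labels = [f"B{i + 1}" for i in range(b)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FriedmanResult:
    statistic: float
    dof: int
    p_value: float
    rank_sums: np.ndarray
    method: str = "chisq"


@dataclass
class PosthocResult:
    friedman: FriedmanResult
    rank_sums: np.ndarray
    pairwise_p: np.ndarray  # (k, k), symmetric, unit diagonal
    groups: list[set[int]]  # per treatment, indices of the group(s) it belongs to
    treatment_labels: list[str]
    alpha: float
    n_groups: int


def _block_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, values)  # mid-ranks for ties


def _friedman_statistic(values: np.ndarray) -> tuple[float, np.ndarray, float, float]:
    """Tie-corrected statistic, rank sums, A1 and C1 for a (b, k) table."""
    b, k = values.shape
    ranks = _block_ranks(values)
    rank_sums = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = b * k * (k + 1) ** 2 / 4.0
    ss = float(((rank_sums - b * (k + 1) / 2.0) ** 2).sum())
    if a1 == c1:  # every block fully tied
        return 0.0, rank_sums, a1, c1
    return (k - 1) * ss / (a1 - c1), rank_sums, a1, c1


def friedman(design: BlockDesign, method: str = "chisq") -> FriedmanResult:
    """Friedman test on a complete block design.

    ``method="chisq"`` uses the chi-square reference distribution with
    k - 1 dof; ``method="exact"`` computes the permutation p-value by
    exhaustive enumeration of all (k!)^b within-block orderings (small
    designs only).
    """
    b, k = design.shape
    stat, rank_sums, _, _ = _friedman_statistic(design.values)
    dof = k - 1
    if method == "chisq":
        p = 1.0 if stat == 0.0 else float(sps.chi2.sf(stat, dof))
        return FriedmanResult(stat, dof, p, rank_sums, "chisq")
    if method != "exact":
        raise ValueError("method must be 'chisq' or 'exact'")
    n_perm = math.factorial(k) ** b
    if n_perm > 2_000_000:
        raise ValueError(
            f"exact enumeration needs {n_perm} permutations; use method='chisq'"
        )
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    base_ranks = _block_ranks(design.values)
    for combo in itertools.product(perms, repeat=b):
        table = np.stack([base_ranks[i, list(pi)] for i, pi in enumerate(combo)])
        rs = table.sum(axis=0)
        a1 = float((table**2).sum())
        c1 = b * k * (k + 1) ** 2 / 4.0
        ss = float(((rs - b * (k + 1) / 2.0) ** 2).sum())
        s = 0.0 if a1 == c1 else (k - 1) * ss / (a1 - c1)
        total += 1
        if s >= stat - 1e-12:
            count += 1
    return FriedmanResult(stat, dof, count / total, rank_sums, "exact")


def conover_posthoc(design: BlockDesign, alpha: float = 0.05) -> PosthocResult:
    """Conover's all-pairs rank comparison after a Friedman test.

    Two-sided p-values from the Student-t reference with (b-1)(k-1)
    degrees of freedom; homogeneous groups are maximal intervals of
    treatments (sorted by rank sum) whose members are pairwise
    non-significant at ``alpha``.  A design with zero rank variance
    (all blocks fully tied) returns a single all-inclusive group.
    """
    b, k = design.shape
    omnibus = friedman(design)
    stat, rank_sums, a1, c1 = _friedman_statistic(design.values)
    dof = (b - 1) * (k - 1)
    pairwise = np.ones((k, k))
    if a1 == c1:
        warnings.warn(
            "degenerate design (zero rank variance); single homogeneous group",
            stacklevel=2,
        )
        return PosthocResult(
            omnibus, rank_sums, pairwise, [{0} for _ in range(k)],
            list(design.treatment_labels), alpha, 1,
        )
    protect = 1.0 - stat / (b * (k - 1))
    denom2 = 2.0 * b * (a1 - c1) / dof * protect
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(rank_sums[i] - rank_sums[j])
            if denom2 <= 0:  # treatment effect exhausts all rank variance
                p = 1.0 if diff == 0 else 0.0
            else:
                t = diff / np.sqrt(denom2)
                p = float(2.0 * sps.t.sf(t, dof))
            pairwise[i, j] = pairwise[j, i] = p
    groups = _homogeneous_groups(rank_sums, pairwise, alpha)
    n_groups = len({g for gs in groups for g in gs})
    return PosthocResult(
        omnibus, rank_sums, pairwise, groups,
        list(design.treatment_labels), alpha, n_groups,
    )


def _homogeneous_groups(
    rank_sums: np.ndarray, pairwise_p: np.ndarray, alpha: float
) -> list[set[int]]:
    """Maximal-interval lettering of treatments sorted by rank sum.

    A pair is homogeneous when its p-value >= alpha.  With one shared
    critical difference, homogeneity of a sorted interval's endpoints
    implies homogeneity of all inner pairs, so maximal homogeneous sets
    are intervals in rank-sum order.
    """
    k = len(rank_sums)
    order = np.argsort(rank_sums, kind="stable")
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            pairwise_p[order[a], order[j + 1]] >= alpha for a in range(i, j + 1)
        ):
            j += 1
        intervals.append((i, j))
    # keep maximal intervals only
    maximal = [
        (i, j)
        for (i, j) in intervals
        if not any((a <= i and j <= c) and (a, c) != (i, j) for a, c in intervals)
    ]
    maximal = sorted(set(maximal))
    groups: list[set[int]] = [set() for _ in range(k)]
    for g, (i, j) in enumerate(maximal):
        for pos in range(i, j + 1):
            groups[order[pos]].add(g)
    return groups


@dataclass
class ComparisonResult:
    """One Friedman + (protected) Conover run for a dataset and direction."""

    dataset: str
    direction: str
    comparison: str
    design: BlockDesign | None
    friedman: FriedmanResult | None
    posthoc: PosthocResult | None
    n_blocks_dropped: int
    testable: bool
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.testable and self.friedman.p_value < 0.05)


def _pivot_design(
    df: pd.DataFrame,
    treatment_col: str | list[str],
    block_cols: list[str],
    value_col: str,
    comparison: str,
) -> tuple[BlockDesign | None, int, str]:
    """Build a complete-block design from long records; drop incomplete blocks."""
    pivot = df.pivot_table(
        index=block_cols, columns=treatment_col, values=value_col, aggfunc="mean"
    )
    complete = pivot.dropna(axis=0)
    dropped = len(pivot) - len(complete)
    if complete.shape[0] < 2 or complete.shape[1] < 2:
        return None, dropped, "fewer than 2 complete blocks or 2 treatments"
    design = BlockDesign(
        complete.to_numpy(float),
        block_labels=[str(i) for i in complete.index],
        treatment_labels=[str(c) for c in complete.columns],
        comparison=comparison,
    )
    return design, dropped, ""


DIRECTIONS = ("LL", "AP", "SI", "3D")


def _direction_column(direction: str) -> str:
    return "D3D" if direction == "3D" else direction


def build_comparison_suite(
    records: pd.DataFrame,
    alpha: float = 0.05,
    datasets: list[str] | None = None,
    pooled: bool = True,
) -> list[ComparisonResult]:
    """Run the three setup comparisons per dataset and motion direction.

    For each dataset and direction in (LL, AP, SI, 3D), three complete
    block designs are assembled from the non-reference-phase displacement
    records (signed values for LL/AP/SI, magnitudes for 3D):

    * ``prone_vs_supine`` -- treatments are the 2 positions, blocks are
      device x phase cells (whole pancreas only);
    * ``devices`` -- treatments are the immobilization devices, blocks
      position x phase (whole pancreas only);
    * ``structures`` -- treatments pancreas/head/body/tail, blocks
      position x device x phase.

    With ``pooled=True`` an additional ``"all"`` dataset is analysed with
    the dataset id folded into the blocks.  Incomplete blocks (e.g. a
    missing position/device acquisition) are dropped and counted.  The
    Conover post-hoc runs only when the omnibus Friedman p < alpha.
    """
    data = records[~records["is_reference"]].copy()
    if datasets is None:
        datasets = sorted(data["dataset"].unique())
    runs: list[tuple[str, pd.DataFrame, list[str]]] = [
        (str(d), data[data["dataset"] == d], []) for d in datasets
    ]
    if pooled and len(datasets) > 1:
        runs.append(("all", data, ["dataset"]))

    specs = [
        ("prone_vs_supine", "position", ["device", "phase"], True),
        ("devices", "device", ["position", "phase"], True),
        ("structures", "structure", ["position", "device", "phase"], False),
    ]
    results: list[ComparisonResult] = []
    for ds_name, df, extra_blocks in runs:
        for direction in DIRECTIONS:
            col = _direction_column(direction)
            for comparison, treat, blocks, pancreas_only in specs:
                sub = df[df["structure"] == "pancreas"] if pancreas_only else df
                design, dropped, note = _pivot_design(
                    sub, treat, extra_blocks + blocks, col, comparison
                )
                if design is None:
                    results.append(
                        ComparisonResult(
                            ds_name, direction, comparison, None, None, None,
                            dropped, False, note,
                        )
                    )
                    continue
                fr = friedman(design)
                post = conover_posthoc(design, alpha) if fr.p_value < alpha else None
                results.append(
                    ComparisonResult(
                        ds_name, direction, comparison, design, fr, post,
                        dropped, True,
                    )
                )
    return results


#: Row order of the rendered symbol table (position, device, structure rows).
TABLE_ROWS = (
    ("prone_vs_supine", "prone"),
    ("devices", "vacuum"),
    ("devices", "mask"),
    ("devices", "compressor"),
    ("structures", "pancreas"),
    ("structures", "head"),
    ("structures", "body"),
    ("structures", "tail"),
)


def render_symbol_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Render homogeneous-group symbols as a setup-comparison grid.

    Rows are the compared treatments (prone/supine as a single row, the
    three devices, the four structures); columns are (dataset, direction)
    pairs.  A blank cell means no significant difference in that
    comparison; otherwise each treatment shows the symbol(s) of its
    homogeneous group(s) -- rows sharing a symbol are indistinguishable.
    """
    by_key = {(r.dataset, r.direction, r.comparison): r for r in results}
    datasets = sorted({r.dataset for r in results}, key=lambda d: (d == "all", d))
    cols = [(d, direction) for d in datasets for direction in DIRECTIONS]
    table = pd.DataFrame(
        "", index=[f"{c}:{t}" for c, t in TABLE_ROWS],
        columns=pd.MultiIndex.from_tuples(cols, names=["dataset", "direction"]),
    )
    for (ds, direction) in cols:
        for comparison in ("prone_vs_supine", "devices", "structures"):
            res = by_key.get((ds, direction, comparison))
            if res is None or not res.testable or res.posthoc is None:
                continue
            post = res.posthoc
            if post.n_groups <= 1:
                continue
            for t_idx, label in enumerate(post.treatment_labels):
                symbols = "".join(
                    GROUP_SYMBOLS[g % len(GROUP_SYMBOLS)]
                    for g in sorted(post.groups[t_idx])
                )
                if comparison == "prone_vs_supine":
                    # a 2-treatment split is rendered as a single mark
                    table.loc["prone_vs_supine:prone", (ds, direction)] = (
                        GROUP_SYMBOLS[0]
                    )
                else:
                    row = f"{comparison}:{label}"
                    if row in table.index:
                        table.loc[row, (ds, direction)] = symbols
    return table
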