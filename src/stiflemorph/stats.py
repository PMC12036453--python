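"""Nonparametric statistical battery for the morphometry tables.

Covers assumption gating (Shapiro-Wilk, Bartlett), Kruskal-Wallis with
pairwise post hoc tests, aligned-rank-transform (ART) two-way factorial
omnibus tests, rank-sum comparisons, Bland-Altman agreement, two-way
absolute-agreement single-measure ICC, Bonferroni correction, and the
mean +/- SD summary table builder.

Conventions: midranks everywhere, tie corrections applied to H and to the
rank-sum normal approximation, alpha = 0.05, ART alignment via cell means
(balanced designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class PosthocRow:
    pair: tuple[str, str]
    statistic: float
    p: float
    adjusted_p: float


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple[int, ...]
    p_value: float
    adjusted_p: float | None = None
    posthoc: list[PosthocRow] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "posthoc": [
                {
                    "pair": list(r.pair),
                    "statistic": r.statistic,
                    "p": r.p,
                    "adjusted_p": r.adjusted_p,
                }
                for r in self.posthoc
            ],
        }


@dataclass
class AgreementResult:
    icc: float  # NaN when not applicable / undefined
    bias: float
    loa_low: float
    loa_high: float
    slope: float = float("nan")  # differences-vs-means proportional-bias probe
    means: np.ndarray | None = None
    diffs: np.ndarray | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "slope": self.slope,
            "note": self.note,
        }


@dataclass
class AssumptionGate:
    shapiro_p: list[float]
    bartlett_p: float
    nonparametric: bool


# ---------------------------------------------------------------------------
# Assumption gating


def gate_assumptions(groups: list[np.ndarray]) -> AssumptionGate:
    """Shapiro-Wilk per group and Bartlett across groups; flags the
    nonparametric route when any p < 0.05."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if len(g) < 3:
            raise ValueError(f"group {i}: need >= 3 values for normality testing")
        if np.ptp(g) == 0:
            raise ValueError(f"group {i}: constant values, normality undefined")
    shapiro_p = [float(sps.shapiro(g).pvalue) for g in arrs]
    bartlett_p = float(sps.bartlett(*arrs).pvalue)
    nonpar = any(p < ALPHA for p in shapiro_p) or bartlett_p < ALPHA
    return AssumptionGate(shapiro_p, bartlett_p, nonpar)


# ---------------------------------------------------------------------------
# Rank-based omnibus and pairwise tests


def kruskal_wallis(groups: list[np.ndarray]) -> StatResult:
    """Tie-corrected Kruskal-Wallis H with the chi-square approximation."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    total_n = sum(len(g) for g in arrs)
    if total_n < 5:
        raise ValueError("need total n >= 5")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return StatResult("kruskal_wallis", 0.0, (len(arrs) - 1,), 1.0)
    h, p = sps.kruskal(*arrs)
    return StatResult("kruskal_wallis", float(h), (len(arrs) - 1,), float(p))


def ranksum(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-sided Wilcoxon rank-sum (statistic = rank sum of the first sample).

    Exact null distribution when the combined sample size is <= 20 and there
    are no ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        w = n1 * (n1 + n2 + 1) / 2.0
        return StatResult("ranksum", w, (n1, n2), 1.0)
    method = "exact" if (n1 + n2 <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + n1 * (n1 + 1) / 2.0  # U1 -> Wilcoxon W
    p = float(res.pvalue)
    if res.statistic == n1 * n2 / 2.0:
        p = 1.0
    return StatResult("ranksum", w, (n1, n2), min(p, 1.0))


def bonferroni(p_values: list[float] | np.ndarray, m: int) -> np.ndarray:
    """min(1, p * m), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if m < len(p):
        raise ValueError(f"m = {m} is smaller than the number of p-values ({len(p)})")
    return np.minimum(1.0, p * m)


def posthoc_pairwise(
    groups: list[np.ndarray],
    method: str = "ranksum_bonferroni",
    labels: list[str] | None = None,
) -> list[PosthocRow]:
    """All pairwise comparisons between groups.

    ``ranksum_bonferroni`` (default): two-sample rank-sum per pair with a
    Bonferroni factor equal to the number of pairs. ``tukey_on_ranks``:
    Tukey HSD applied to the global midranks of the pooled data.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    pairs = list(combinations(range(k), 2))

    if method == "ranksum_bonferroni":
        rows = []
        raw = []
        for i, j in pairs:
            r = ranksum(arrs[i], arrs[j])
            raw.append((i, j, r.statistic, r.p_value))
        adj = bonferroni([p for *_, p in raw], len(pairs))
        for (i, j, stat, p), ap in zip(raw, adj):
            rows.append(PosthocRow((labels[i], labels[j]), stat, p, float(ap)))
        return rows

    if method == "tukey_on_ranks":
        pooled = np.concatenate(arrs)
        ranks = sps.rankdata(pooled)  # midranks
        split = np.cumsum([len(g) for g in arrs])[:-1]
        rank_groups = np.split(ranks, split)
        res = sps.tukey_hsd(*rank_groups)
        rows = []
        for i, j in pairs:
            stat = float(np.mean(rank_groups[i]) - np.mean(rank_groups[j]))
            p = float(res.pvalue[i, j])
            rows.append(PosthocRow((labels[i], labels[j]), stat, p, p))
        return rows

    raise ValueError(f"unknown posthoc method {method!r}")


# ---------------------------------------------------------------------------
# Aligned rank transform two-way factorial ANOVA


def _balanced_twoway_anova_on(
    y: np.ndarray, ai: np.ndarray, bi: np.ndarray, na: int, nb: int
) -> dict[str, tuple[float, tuple[int, int], float]]:
    """F statistics of a balanced two-way factorial ANOVA (all three effects)."""
    n_tot = len(y)
    grand = y.mean()
    cell_mean = np.zeros((na, nb))
    cell_n = np.zeros((na, nb), dtype=int)
    for a in range(na):
        for b in range(nb):
            sel = (ai == a) & (bi == b)
            cell_n[a, b] = sel.sum()
            cell_mean[a, b] = y[sel].mean()
    n_cell = cell_n[0, 0]
    row_mean = cell_mean.mean(axis=1)
    col_mean = cell_mean.mean(axis=0)
    ss_a = n_cell * nb * float(((row_mean - grand) ** 2).sum())
    ss_b = n_cell * na * float(((col_mean - grand) ** 2).sum())
    inter = cell_mean - row_mean[:, None] - col_mean[None, :] + grand
    ss_ab = n_cell * float((inter**2).sum())
    resid = y - cell_mean[ai, bi]
    ss_e = float((resid**2).sum())
    df_e = n_tot - na * nb
    ms_e = ss_e / df_e
    out = {}
    for name, ss, df in (
        ("A", ss_a, na - 1),
        ("B", ss_b, nb - 1),
        ("A:B", ss_ab, (na - 1) * (nb - 1)),
    ):
        f = (ss / df) / ms_e if ms_e > 0 else float("inf")
        p = float(sps.f.sf(f, df, df_e)) if np.isfinite(f) else 0.0
        out[name] = (float(f), (df, df_e), p)
    return out


def art_anova(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    response: str = "value",
) -> dict[str, StatResult]:
    """Aligned-rank-transform two-way factorial omnibus tests.

    For each effect (A, B, A x B) the responses are aligned by subtracting
    every cell-mean-estimated effect except the one under test, midranked,
    and passed through a standard two-way factorial ANOVA on the ranks; only
    the F for the aligned-for effect is reported. The aligned responses for
    every effect must sum to zero (internal correctness check), which
    requires a balanced, fully crossed design.
    """
    df = table.dropna(subset=[response])
    a_levels = sorted(df[factor_a].unique())
    b_levels = sorted(df[factor_b].unique())
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise ValueError("each factor needs >= 2 levels")
    ai = df[factor_a].map({l: i for i, l in enumerate(a_levels)}).to_numpy()
    bi = df[factor_b].map({l: i for i, l in enumerate(b_levels)}).to_numpy()
    y = df[response].to_numpy(dtype=float)

    cell_n = np.zeros((na, nb), dtype=int)
    np.add.at(cell_n, (ai, bi), 1)
    for a in range(na):
        for b in range(nb):
            if cell_n[a, b] == 0:
                raise ValueError(
                    f"empty cell ({factor_a}={a_levels[a]}, {factor_b}={b_levels[b]})"
                )
            if cell_n[a, b] < 2:
                raise ValueError(
                    f"cell ({a_levels[a]}, {b_levels[b]}) has < 2 observations"
                )
    if np.ptp(cell_n) != 0:
        raise ValueError(
            "art_anova requires a balanced design (equal cell sizes); "
            f"got cell counts {cell_n.tolist()}"
        )

    cell_mean = np.zeros((na, nb))
    for a in range(na):
        for b in range(nb):
            cell_mean[a, b] = y[(ai == a) & (bi == b)].mean()
    grand = cell_mean.mean()
    a_eff = cell_mean.mean(axis=1) - grand
    b_eff = cell_mean.mean(axis=0) - grand
    ab_eff = cell_mean - cell_mean.mean(axis=1)[:, None] - cell_mean.mean(axis=0)[None, :] + grand
    resid = y - cell_mean[ai, bi]

    aligned = {
        factor_a: resid + a_eff[ai],
        factor_b: resid + b_eff[bi],
        f"{factor_a}:{factor_b}": resid + ab_eff[ai, bi],
    }
    effect_key = {factor_a: "A", factor_b: "B", f"{factor_a}:{factor_b}": "A:B"}

    scale = max(float(np.abs(y).max()), 1.0)
    results: dict[str, StatResult] = {}
    for name, vals in aligned.items():
        if abs(float(vals.sum())) > 1e-9 * scale * len(vals):
            raise RuntimeError(
                f"ART internal check failed: aligned responses for {name} "
                f"sum to {vals.sum():.3e}, not 0"
            )
        ranks = sps.rankdata(vals)
        anova = _balanced_twoway_anova_on(ranks, ai, bi, na, nb)
        f, dfs, p = anova[effect_key[name]]
        results[name] = StatResult(f"art_anova[{name}]", f, dfs, p)
    return results


# ---------------------------------------------------------------------------
# Agreement statistics


def bland_altman(pairs: np.ndarray) -> AgreementResult:
    """Bias and 1.96-SD limits of agreement of paired measurements, plus the
    slope of differences vs means as a proportional-bias probe."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (m1, m2) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if np.ptp(means) > 0:
        slope = float(np.polyfit(means, diffs, 1)[0])
    else:
        slope = 0.0
    return AgreementResult(
        icc=float("nan"),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        slope=slope,
        means=means,
        diffs=diffs,
    )


def icc_agreement(rater_a: np.ndarray, rater_b: np.ndarray) -> AgreementResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC
    (ICC(A,1)) from the two-way mean squares, with k = 2 raters."""
    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired observations")
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    ba = bland_altman(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.ptp(row_means) == 0 or denom == 0:
        return AgreementResult(
            icc=float("nan"),
            bias=ba.bias,
            loa_low=ba.loa_low,
            loa_high=ba.loa_high,
            slope=ba.slope,
            note="undefined: zero between-subject variance",
        )
    icc = (msr - mse) / denom
    return AgreementResult(
        icc=float(icc),
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        slope=ba.slope,
        means=ba.means,
        diffs=ba.diffs,
    )


# ---------------------------------------------------------------------------
# Long table and summary


LONG_COLUMNS = ("specimen_id", "species", "tissue", "region", "measure", "value")


def validate_long_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"long table missing columns: {missing}")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("long table contains non-finite values")
    keys = table[["specimen_id", "tissue", "region", "measure"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].to_dict()
        raise ValueError(f"duplicate (specimen, tissue, region, measure) key: {dup}")
    return table


def build_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per (species, tissue, region, measure): n, mean, SD (n-1), CV%, and a
    formatted mean +/- SD string. Single-observation groups get a missing SD."""
    validate_long_table(table)
    rows = []
    grouped = table.groupby(["species", "tissue", "region", "measure"], dropna=False)
    for (species, tissue, region, measure), grp in grouped:
        vals = grp["value"].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        cv = 100.0 * sd / mean if (len(vals) > 1 and mean != 0) else float("nan")
        fmt = f"{mean:.3g} ± {sd:.3g}" if np.isfinite(sd) else f"{mean:.3g}"
        rows.append(
            dict(
                species=species,
                tissue=tissue,
                region=region,
                measure=measure,
                n=len(vals),
                mean=mean,
                sd=sd,
                cv_pct=cv,
                mean_sd=fmt,
            )
        )
    return pd.DataFrame(rows)
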