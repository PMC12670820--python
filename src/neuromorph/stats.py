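"""Cohort statistics: normality-gated group comparisons and pain correlations.

The analysis stage mirrors a small-cohort clinical workflow: distributions
are screened with a Lilliefors-style Kolmogorov-Smirnov normality test
(parameters estimated from the sample); groups that pass on both sides are
compared with an independent-samples t-test, anything else — including
degenerate, zero-variance groups such as "unorganized tissue in control
nerves" — falls back to a two-sided Mann-Whitney U with tie correction
(exact enumeration for pooled n <= 12, normal approximation beyond).
Associations with the NRS pain score use tie-corrected Spearman rank
correlation (two-sided p from the t approximation on n-2 df, optionally a
seeded Monte-Carlo permutation p).  Raw p-values are reported; a
Benjamini-Hochberg column can be added on request.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .io import CohortRecord
from .morphometry import TissueComposition

__all__ = [
    "StatResult",
    "StatsConfig",
    "AnalysisReport",
    "test_normality",
    "compare_groups",
    "spearman_correlation",
    "run_full_analysis",
    "significance_stars",
    "compositions_to_frame",
]

_EXACT_MW_MAX_N = 12
ALPHA_NORMALITY = 0.05

#: tissue variables compared between groups (relative and absolute)
_COMPARED_CLASSES = (
    "unorganized_nervous",
    "organized_nervous",
    "connective",
    "adipose",
)


@dataclass(frozen=True)
class StatResult:
    """One test outcome, schema-stable for the JSON report."""

    variable: str
    comparison: str
    test_name: str
    statistic: float
    p_value: float
    n: dict[str, int]
    effect_direction: str = ""
    note: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass(frozen=True)
class StatsConfig:
    """Options for the analysis stage."""

    welch: bool = False
    bh_adjust: bool = False
    spearman_permutations: int | None = None
    seed: int = 0


@dataclass
class AnalysisReport:
    """Every comparison and correlation of the analysis stage."""

    group_comparisons: list[StatResult]
    pain_correlations: list[StatResult]
    exploratory: list[StatResult]
    config: dict
    bh_adjusted: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return dict(
            group_comparisons=[r.to_dict() for r in self.group_comparisons],
            pain_correlations=[r.to_dict() for r in self.pain_correlations],
            exploratory=[r.to_dict() for r in self.exploratory],
            config=self.config,
            bh_adjusted=self.bh_adjusted,
        )

    def find(self, variable: str, comparison: str) -> StatResult:
        for r in (
            self.group_comparisons + self.pain_correlations + self.exploratory
        ):
            if r.variable == variable and r.comparison == comparison:
                return r
        raise KeyError(f"no result for {variable!r} / {comparison!r}")


# ---------------------------------------------------------------------------
# Primitive tests
# ---------------------------------------------------------------------------

def test_normality(values, variable: str = "") -> StatResult:
    """Lilliefors KS test of normality (mean/SD estimated from the data).

    Requires n >= 4 and non-constant input; "normal" means p > 0.05.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"{variable or 'input'}: need n >= 4 for normality test")
    if np.ptp(x) == 0:
        raise ValueError(f"{variable or 'input'}: degenerate: zero variance")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return StatResult(
        variable=variable,
        comparison="normality",
        test_name="ks_normality",
        statistic=float(stat),
        p_value=float(p),
        n={"n": int(x.size)},
        note="normal" if p > ALPHA_NORMALITY else "non-normal",
    )


def _is_degenerate(x: np.ndarray) -> bool:
    return x.size < 4 or np.ptp(x) == 0


def _mannwhitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (handles ties)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n = a.size, pooled.size
    offset = n_a * (n_a + 1) / 2.0
    u_obs = ranks[:n_a].sum() - offset
    mu = a.size * b.size / 2.0
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for comb in itertools.combinations(range(n), n_a):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if abs(u - mu) >= dev_obs - 1e-9:
            count += 1
    return float(u_obs), count / total


def compare_groups(
    a,
    b,
    force_nonparametric: bool = False,
    welch: bool = False,
    variable: str = "",
    comparison: str = "",
    n_labels: tuple[str, str] = ("a", "b"),
) -> StatResult:
    """Compare two independent samples, auto-selecting the test.

    Mann-Whitney U (two-sided, tie-corrected; exact enumeration when the
    pooled size is <= 12) when forced, when either group is degenerate
    (constant or too small to assess normality), or when either group fails
    the Lilliefors screen; otherwise an independent-samples t-test
    (Student's by default, Welch's on request).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"{variable or 'input'}: need n >= 2 in each group")

    nonparametric = force_nonparametric
    note = ""
    if not nonparametric:
        if _is_degenerate(a) or _is_degenerate(b):
            nonparametric = True
            note = "degenerate or small group; routed to Mann-Whitney"
        else:
            normal = all(
                test_normality(x).p_value > ALPHA_NORMALITY for x in (a, b)
            )
            if not normal:
                nonparametric = True
                note = "normality rejected; routed to Mann-Whitney"

    direction = (
        "a>b" if np.median(a) > np.median(b)
        else "a<b" if np.median(a) < np.median(b) else "a=b"
    )
    if nonparametric:
        if a.size + b.size <= _EXACT_MW_MAX_N:
            stat, p = _mannwhitney_exact(a, b)
            method = "mann_whitney_u"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
            method = "mann_whitney_u"
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
        method = "t_independent"
        direction = (
            "a>b" if a.mean() > b.mean()
            else "a<b" if a.mean() < b.mean() else "a=b"
        )
    return StatResult(
        variable=variable,
        comparison=comparison,
        test_name=method,
        statistic=stat,
        p_value=min(1.0, float(p)),
        n={n_labels[0]: int(a.size), n_labels[1]: int(b.size)},
        effect_direction=direction,
        note=note,
    )


def spearman_correlation(
    x,
    y,
    variable: str = "",
    comparison: str = "",
    n_permutations: int | None = None,
    seed: int = 0,
) -> StatResult:
    """Tie-corrected Spearman rho with a two-sided p-value.

    The default p uses the t approximation on n-2 degrees of freedom;
    ``n_permutations`` switches to a seeded Monte-Carlo permutation p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError(f"{variable or 'input'}: need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"{variable or 'input'}: constant input")
    rho, p = sps.spearmanr(x, y)
    note = "t-approximation"
    if n_permutations:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E]))
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx_c = rx - rx.mean()
        denom_x = np.sqrt((rx_c**2).sum())
        hits = 0
        for _ in range(int(n_permutations)):
            perm = rng.permutation(ry)
            perm_c = perm - perm.mean()
            r = (rx_c @ perm_c) / (denom_x * np.sqrt((perm_c**2).sum()))
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = (hits + 1) / (int(n_permutations) + 1)
        note = f"permutation ({n_permutations} draws)"
    direction = "positive" if rho > 0 else "negative" if rho < 0 else "none"
    return StatResult(
        variable=variable,
        comparison=comparison,
        test_name="spearman",
        statistic=float(rho),
        p_value=min(1.0, float(p)),
        n={"n": int(x.size)},
        effect_direction=direction,
        note=note,
    )


def significance_stars(p: float) -> str:
    """Figure annotation: '**' for p < 0.01, '*' for p < 0.05, else ''."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

def compositions_to_frame(
    compositions: list[TissueComposition], records: list[CohortRecord]
) -> pd.DataFrame:
    """Join compositions with clinical metadata into one tidy table."""
    by_id = {c.sample_id: c for c in compositions}
    missing = [r.sample_id for r in records if r.sample_id not in by_id]
    if missing:
        raise ValueError(f"missing composition for sample(s): {missing}")
    rows = []
    for rec in records:
        comp = by_id[rec.sample_id]
        row = dict(
            sample_id=rec.sample_id,
            group=rec.group,
            nrs=rec.nrs,
            age=rec.age,
            sex=rec.sex,
            deviation_index=comp.deviation_index,
        )
        for cls, v in comp.relative_area.items():
            row[f"rel_{cls}"] = v
        for cls, v in comp.absolute_area_mm2.items():
            row[f"abs_{cls}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _safe_spearman(df, xcol, ycol, variable, comparison, config) -> StatResult:
    sub = df[[xcol, ycol]].dropna()
    try:
        return spearman_correlation(
            sub[xcol], sub[ycol],
            variable=variable, comparison=comparison,
            n_permutations=config.spearman_permutations, seed=config.seed,
        )
    except ValueError as exc:
        return StatResult(
            variable=variable, comparison=comparison, test_name="spearman",
            statistic=float("nan"), p_value=float("nan"),
            n={"n": int(len(sub))}, note=f"not computable: {exc}",
        )


def run_full_analysis(
    compositions: list[TissueComposition],
    records: list[CohortRecord],
    config: StatsConfig = StatsConfig(),
) -> AnalysisReport:
    """Run every comparison of the analysis stage over one cohort.

    (i) control vs pooled neuromas, relative and absolute areas of the four
    solid tissue classes; (ii) painful vs non-painful neuromas likewise;
    (iii) Spearman vs NRS among neuroma samples for relative unorganized,
    relative organized and the deviation index (samples with an undefined
    index excluded); (iv) exploratory age-vs-NRS Spearman and NRS-by-sex
    Mann-Whitney.  Raw p-values; optional Benjamini-Hochberg column.
    """
    df = compositions_to_frame(compositions, records)
    is_neuroma = df["group"].isin(["nonpainful_neuroma", "painful_neuroma"])
    comparisons: list[StatResult] = []

    def split_compare(mask_a, mask_b, comparison, labels):
        for prefix, kind in (("rel", "relative"), ("abs", "absolute")):
            for cls in _COMPARED_CLASSES:
                col = f"{prefix}_{cls}"
                comparisons.append(
                    compare_groups(
                        df.loc[mask_a, col], df.loc[mask_b, col],
                        welch=config.welch,
                        variable=f"{kind}_{cls}",
                        comparison=comparison,
                        n_labels=labels,
                    )
                )

    split_compare(
        df["group"] == "control", is_neuroma,
        "control_vs_neuroma", ("control", "neuroma"),
    )
    split_compare(
        df["group"] == "painful_neuroma", df["group"] == "nonpainful_neuroma",
        "painful_vs_nonpainful", ("painful", "nonpainful"),
    )

    neuroma = df[is_neuroma]
    correlations = [
        _safe_spearman(
            neuroma, col, "nrs", variable, "vs_nrs", config
        )
        for variable, col in (
            ("relative_unorganized_nervous", "rel_unorganized_nervous"),
            ("relative_organized_nervous", "rel_organized_nervous"),
            ("deviation_index", "deviation_index"),
        )
    ]

    exploratory = [
        _safe_spearman(df, "age", "nrs", "age", "vs_nrs", config)
    ]
    nrs_m = df.loc[df["sex"] == "male", "nrs"]
    nrs_f = df.loc[df["sex"] == "female", "nrs"]
    if nrs_m.size >= 2 and nrs_f.size >= 2:
        exploratory.append(
            compare_groups(
                nrs_m, nrs_f, force_nonparametric=True,
                variable="nrs", comparison="by_sex",
                n_labels=("male", "female"),
            )
        )

    bh = None
    if config.bh_adjust:
        all_res = comparisons + correlations
        ps = [r.p_value for r in all_res if math.isfinite(r.p_value)]
        keys = [
            f"{r.variable}|{r.comparison}"
            for r in all_res
            if math.isfinite(r.p_value)
        ]
        if ps:
            adj = multipletests(ps, method="fdr_bh")[1]
            bh = dict(zip(keys, map(float, adj)))

    return AnalysisReport(
        group_comparisons=comparisons,
        pain_correlations=correlations,
        exploratory=exploratory,
        config=dict(
            welch=config.welch,
            bh_adjust=config.bh_adjust,
            spearman_permutations=config.spearman_permutations,
            seed=config.seed,
        ),
        bh_adjusted=bh,
    )
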