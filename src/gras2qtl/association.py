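"""Marker-genotype class summaries and Tukey-Kramer comparisons.

The Tukey-Kramer statistic for groups i and j is

    q_ij = |mean_i - mean_j| / sqrt((MSW / 2) * (1/n_i + 1/n_j))

with MSW the pooled within-group variance, referred to the studentized-range
distribution with K groups and N - K error degrees of freedom.  Because the
statistic depends on the data only through (n, mean, sd) per group, the test
accepts either raw observations or printed summary triplets, and the two
entry points agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataFormatError


@dataclass
class GroupStats:
    """Size, mean, and sample standard deviation (n-1 denominator) of one class."""

    n: int
    mean: float
    sd: float


@dataclass
class ClassSummary:
    """Per-genotype-class trait summary with all pairwise contrasts."""

    marker: str
    classes: pd.DataFrame  # index: class label; columns n, mean, sd
    contrasts: pd.DataFrame  # columns: class_a, class_b, diff, q, p_adj, stars
    degenerate: bool = False

    @property
    def n_total(self) -> int:
        return int(self.classes["n"].sum())


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _as_stats(groups) -> list[GroupStats]:
    out = []
    for g in groups:
        if isinstance(g, GroupStats):
            out.append(g)
        elif isinstance(g, (tuple, list)) and len(g) == 3:
            out.append(GroupStats(int(g[0]), float(g[1]), float(g[2])))
        else:
            arr = np.asarray(g, dtype=float)
            arr = arr[np.isfinite(arr)]
            if len(arr) < 1:
                raise DataFormatError("empty group passed to tukey_kramer")
            sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan")
            out.append(GroupStats(len(arr), float(arr.mean()), sd))
    return out


def tukey_kramer(groups, labels: list[str] | None = None) -> pd.DataFrame:
    """All-pairs Tukey-Kramer comparisons.

    ``groups`` is either a list of raw observation arrays or a list of
    ``(n, mean, sd)`` triplets / :class:`GroupStats`; both give identical
    results for matched inputs.  Requires >= 2 groups with n >= 2 each.
    Returns one row per pair with the mean difference (b - a), q statistic,
    adjusted P, and significance stars.  With zero pooled variance the P is
    NaN for equal means and 0 for unequal (degenerate case).
    """
    gs = _as_stats(groups)
    if len(gs) < 2:
        raise DataFormatError("tukey_kramer needs at least 2 groups")
    if any(g.n < 2 for g in gs):
        raise DataFormatError("every group needs n >= 2")
    labels = labels or [f"g{i + 1}" for i in range(len(gs))]
    K = len(gs)
    N = sum(g.n for g in gs)
    msw = sum((g.n - 1) * g.sd**2 for g in gs) / (N - K)
    rows = []
    for i, j in combinations(range(K), 2):
        gi, gj = gs[i], gs[j]
        diff = gj.mean - gi.mean
        if msw <= 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else float("nan")
        else:
            se = np.sqrt((msw / 2.0) * (1.0 / gi.n + 1.0 / gj.n))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, K, N - K))
        rows.append((labels[i], labels[j], diff, q, p, _stars(p)))
    return pd.DataFrame(
        rows, columns=["class_a", "class_b", "diff", "q", "p_adj", "stars"]
    )


def class_summary(
    genotypes: pd.Series,
    phenotype: pd.Series,
    marker: str = "marker",
    classes: tuple[str, ...] = ("A", "H", "B"),
) -> ClassSummary:
    """Per-genotype-class n / mean / sd and Tukey-Kramer contrasts.

    ``genotypes`` holds codes per individual; individuals with missing
    genotype or phenotype are excluded.  Contrasts involving a class with
    n < 2 are reported as NaN.
    """
    common = genotypes.index.intersection(phenotype.index)
    g = genotypes.loc[common]
    y = phenotype.loc[common].astype(float)
    ok = (g.isin(classes)) & np.isfinite(y)
    g, y = g[ok], y[ok]
    stats_rows = {}
    raw = {}
    for c in classes:
        vals = y[g == c].to_numpy()
        raw[c] = vals
        stats_rows[c] = {
            "n": len(vals),
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        }
    table = pd.DataFrame(stats_rows).T[["n", "mean", "sd"]]
    usable = [c for c in classes if stats_rows[c]["n"] >= 2]
    if len(usable) >= 2:
        contrasts = tukey_kramer([raw[c] for c in usable], labels=list(usable))
    else:
        contrasts = pd.DataFrame(
            columns=["class_a", "class_b", "diff", "q", "p_adj", "stars"]
        )
    # pairs touching an unusable class appear with NaN statistics
    for a, b in combinations(classes, 2):
        if a not in usable or b not in usable:
            contrasts.loc[len(contrasts)] = [a, b, np.nan, np.nan, np.nan, ""]
    degenerate = bool(
        len(usable) >= 2
        and np.isclose(
            sum((stats_rows[c]["n"] - 1) * stats_rows[c]["sd"] ** 2 for c in usable), 0
        )
    )
    return ClassSummary(marker, table, contrasts.reset_index(drop=True), degenerate)


def class_mean_difference(
    summary: ClassSummary, class_a: str, class_b: str, decimals: int = 1
) -> float:
    """mean(class_b) - mean(class_a), rounded as printed in trait summaries."""
    for c in (class_a, class_b):
        if c not in summary.classes.index or summary.classes.loc[c, "n"] == 0:
            raise DataFormatError(f"class {c!r} is empty or absent")
    diff = summary.classes.loc[class_b, "mean"] - summary.classes.loc[class_a, "mean"]
    return round(float(diff), decimals)


def phenotype_correlation(
    flowering: pd.Series,
    maturity: pd.Series,
    censored: pd.Series | None = None,
    censor_policy: str = "exclude",
) -> float:
    """Pearson correlation of flowering and maturity times.

    ``censor_policy``: 'exclude' drops censored individuals (default);
    'include' keeps them at the truncated end-day value.  Needs >= 3
    complete pairs; zero variance gives NaN.
    """
    if censor_policy not in ("exclude", "include"):
        raise DataFormatError(f"unknown censor policy {censor_policy!r}")
    common = flowering.index.intersection(maturity.index)
    f = flowering.loc[common].astype(float)
    m = maturity.loc[common].astype(float)
    keep = np.isfinite(f) & np.isfinite(m)
    if censored is not None and censor_policy == "exclude":
        keep &= ~censored.reindex(common).fillna(False).astype(bool)
    f, m = f[keep], m[keep]
    if len(f) < 3:
        raise DataFormatError("fewer than 3 complete phenotype pairs")
    if np.std(f.to_numpy()) == 0 or np.std(m.to_numpy()) == 0:
        return float("nan")
    return float(np.corrcoef(f, m)[0, 1])
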