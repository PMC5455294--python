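"""Nonparametric per-trait group comparisons and range summaries.

Each trait is compared between groups with the Kruskal–Wallis rank test
(tie-corrected H, χ² reference distribution). Pairwise group comparisons
are condensed into the survey's letter-code matrices: each cell lists the
letters of the traits on which the two groups differ at α (a = surface,
b = profile, c = rectangle a, d = rectangle b, e = angle of curvature,
f = number of pits). No multiple-testing correction is applied by default,
matching the flat per-test α of the original tables; a Holm correction per
pair is available behind a flag.

Boxplot summaries use the 1.5·IQR whisker convention and can be formatted
in the "(min-outlier–)q25–q75(–max-outlier)" notation used by the species
descriptions.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import TRAIT_COLUMNS

#: trait letters of the published pairwise tables, in trait-column order
TRAIT_LETTERS = dict(zip(TRAIT_COLUMNS, "abcdef"))


def kruskal_wallis_h(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its χ² p-value.

    H = 12/(N(N+1)) · Σ n_i (r̄_i − (N+1)/2)², divided by the tie
    correction 1 − Σ(t³−t)/(N³−N). All-identical samples give (0, 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups length mismatch")
    labels, idx = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if np.bincount(idx).min() < 1:
        raise ValueError("every group needs at least one observation")
    N = len(values)
    if len(np.unique(values)) < 2:
        return 0.0, 1.0
    ranks = stats.rankdata(values)
    mean_rank = (N + 1) / 2.0
    H = 0.0
    for k in range(len(labels)):
        r = ranks[idx == k]
        H += len(r) * (r.mean() - mean_rank) ** 2
    H *= 12.0 / (N * (N + 1))
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    if tie <= 0:
        return 0.0, 1.0
    H /= tie
    p = float(stats.chi2.sf(H, len(labels) - 1))
    return float(H), p


def pairwise_trait_codes(
    table: pd.DataFrame,
    grouping: str = "population",
    alpha: float = 0.05,
    traits=None,
    holm: bool = False,
) -> pd.DataFrame:
    """Letter-code matrix of significantly differing traits per group pair.

    For every pair of groups and each trait, a two-group Kruskal–Wallis test
    is run; the trait's letter joins the cell when p < alpha. With
    `holm=True` the six per-pair p-values are Holm-adjusted first. Pairs
    containing a group with < 2 observations are marked "n/a".
    """
    traits = list(traits) if traits is not None else [
        c for c in TRAIT_COLUMNS if c in table.columns
    ]
    letters = [TRAIT_LETTERS.get(t, "?") for t in traits]
    groups = list(pd.unique(table[grouping]))
    out = pd.DataFrame("", index=groups, columns=groups, dtype=object)
    by = {g: sub for g, sub in table.groupby(grouping, sort=False)}
    for ga, gb in itertools.combinations(groups, 2):
        a, b = by[ga], by[gb]
        if len(a) < 2 or len(b) < 2:
            out.loc[ga, gb] = out.loc[gb, ga] = "n/a"
            continue
        pvals = []
        for t in traits:
            vals = np.concatenate([a[t].to_numpy(float), b[t].to_numpy(float)])
            labs = np.array([0] * len(a) + [1] * len(b))
            pvals.append(kruskal_wallis_h(vals, labs)[1])
        pvals = np.asarray(pvals)
        if holm:
            pvals = _holm(pvals)
        cell = "".join(
            letter for letter, p in zip(letters, pvals) if p < alpha
        )
        out.loc[ga, gb] = out.loc[gb, ga] = cell
    return out


def _holm(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


# ---------------------------------------------------------------------------
# boxplot summaries and the printed range notation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number boxplot summary with 1.5·IQR whiskers."""

    lower_whisker: float
    q25: float
    median: float
    q75: float
    upper_whisker: float
    outliers: tuple[float, ...]

    def quartet(self) -> tuple[float, float, float, float]:
        return (self.lower_whisker, self.q25, self.q75, self.upper_whisker)


def boxplot_summary(values) -> BoxplotSummary:
    """Quartiles (linear interpolation) and 1.5·IQR whiskers of one sample."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) < 4:
        raise ValueError(f"need at least 4 observations, got {len(v)}")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(x) for x in v[(v < lo_fence) | (v > hi_fence)])
    return BoxplotSummary(
        lower_whisker=float(inside.min()),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        upper_whisker=float(inside.max()),
        outliers=outliers,
    )


def boxplot_table(
    table: pd.DataFrame, grouping: str = "species", traits=None
) -> pd.DataFrame:
    """Tidy per-group, per-trait boxplot summaries."""
    traits = list(traits) if traits is not None else [
        c for c in TRAIT_COLUMNS if c in table.columns
    ]
    rows = []
    for g, sub in table.groupby(grouping, sort=True):
        for t in traits:
            s = boxplot_summary(sub[t])
            rows.append(
                {
                    grouping: g,
                    "trait": t,
                    "lower_whisker": s.lower_whisker,
                    "q25": s.q25,
                    "median": s.median,
                    "q75": s.q75,
                    "upper_whisker": s.upper_whisker,
                    "n_outliers": len(s.outliers),
                    "range": format_range_quartet(*s.quartet()),
                }
            )
    return pd.DataFrame(rows)


def format_range_quartet(lo: float, q25: float, q75: float, hi: float, nd: int = 0) -> str:
    """Render "(lo–)q25–q75(–hi)"; bounds equal to the core are omitted."""

    def f(x: float) -> str:
        return f"{x:.{nd}f}" if nd else f"{x:g}"

    head = f"({f(lo)}–)" if lo < q25 else ""
    tail = f"(–{f(hi)})" if hi > q75 else ""
    return f"{head}{f(q25)}–{f(q75)}{tail}"


_QUARTET_RE = re.compile(
    r"^(?:\((?P<lo>[\d.]+)–?\))?(?P<q25>[\d.]+)–(?P<q75>[\d.]+)(?:\(–?(?P<hi>[\d.]+)\))?$"
)


def parse_range_quartet(text: str) -> tuple[float, float, float, float]:
    """Parse the "(lo–)q25–q75(–hi)" notation back into a quartet."""
    m = _QUARTET_RE.match(text.replace(" ", "").replace("-", "–"))
    if not m:
        raise ValueError(f"cannot parse range string {text!r}")
    q25, q75 = float(m["q25"]), float(m["q75"])
    lo = float(m["lo"]) if m["lo"] else q25
    hi = float(m["hi"]) if m["hi"] else q75
    return lo, q25, q75, hi


def group_sd_table(
    table: pd.DataFrame, grouping: str = "species", traits=None
) -> pd.DataFrame:
    """Per-group sample standard deviations (n−1 denominator) per trait."""
    traits = list(traits) if traits is not None else [
        c for c in TRAIT_COLUMNS if c in table.columns
    ]
    sizes = table.groupby(grouping).size()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 rows: {small}")
    return table.groupby(grouping)[traits].std(ddof=1)
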