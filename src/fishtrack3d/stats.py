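"""Nonparametric group comparison and survival tabulation.

The screening design compares three exposure groups (control plus two
drug groups) on ~19 behavioral endpoints organised in four families
(kinematic, dynamic, vertical, horizontal).  Because behavioral endpoints
routinely violate normality and variance homogeneity, every endpoint is
tested with a tie-corrected Kruskal-Wallis omnibus test, followed — when
the omnibus passes — by Dwass-Steel-Critchlow-Fligner (DSCF) all-pairs
post-hoc comparisons.

The two-level alpha scheme divides the experimentwise level 0.05 by the
four endpoint families (family alpha 0.0125) and then by the three group
pairs (pairwise alpha 0.05/12, conventionally printed truncated as
0.0041).  P-values below 0.05 that miss their corrected level are reported
as *tendencies*, never as significant findings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError
from .endpoints import ENDPOINT_FAMILIES
from .simulate import SurvivalRecord

__all__ = [
    "AlphaScheme",
    "KruskalResult",
    "PairwiseComparison",
    "EndpointResult",
    "GroupComparisonReport",
    "kruskal_wallis",
    "dscf_posthoc",
    "apply_alpha_scheme",
    "survival_percentages",
    "analyze_experiment",
]


@dataclass(frozen=True)
class AlphaScheme:
    """Two-level Bonferroni scheme with tendency reporting.

    ``family_alpha = experimentwise_alpha / n_families`` gates the omnibus
    tests; ``pairwise_alpha = family_alpha / n_pairwise`` gates the
    post-hoc comparisons.  P-values below ``tendency_alpha`` that fail
    their corrected level are flagged as tendencies.
    """

    experimentwise_alpha: float = 0.05
    n_families: int = 4
    n_pairwise: int = 3
    tendency_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.pairwise_alpha <= self.family_alpha
                <= self.experimentwise_alpha <= self.tendency_alpha <= 1.0):
            raise ValidationError(
                "alpha scheme must satisfy 0 < pairwise <= family <= "
                "experimentwise <= tendency <= 1"
            )

    @property
    def family_alpha(self) -> float:
        return self.experimentwise_alpha / self.n_families

    @property
    def pairwise_alpha(self) -> float:
        return self.family_alpha / self.n_pairwise

    @property
    def pairwise_alpha_text(self) -> str:
        """Pairwise level truncated to 4 decimals, as printed in reports."""
        return f"{math.floor(self.pairwise_alpha * 1e4) / 1e4:.4f}"


class KruskalResult(tuple):
    """(H, p) with a ``degenerate`` flag for all-tied data."""

    def __new__(cls, H: float, p: float, degenerate: bool = False):
        self = super().__new__(cls, (H, p))
        return self

    def __init__(self, H: float, p: float, degenerate: bool = False):
        self.degenerate = degenerate

    @property
    def H(self) -> float:
        return self[0]

    @property
    def p(self) -> float:
        return self[1]


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: list) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H test with chi-squared p-value.

    Mid-ranks over the pooled sample;
    ``H = [12/(N(N+1)) * sum R_j^2/n_j - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N))``
    referred to chi-squared with k-1 degrees of freedom.  If every pooled
    value is identical the data carry no ordering information: H = 0,
    p = 1 and the result's ``degenerate`` flag is set.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("kruskal_wallis needs >= 2 groups")
    if any(a.size < 1 for a in arrays):
        raise ValidationError("every group needs >= 1 value")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise ValidationError("kruskal_wallis needs >= 3 values in total")
    if not np.all(np.isfinite(pooled)):
        raise ValidationError("non-finite values in input")

    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0, degenerate=True)

    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    h = 0.0
    offset = 0
    for n_j in sizes:
        r_j = ranks[offset:offset + n_j].sum()
        h += r_j * r_j / n_j
        offset += n_j
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - _tie_term(pooled) / (n_total ** 3 - n_total)
    h /= correction
    p = float(sps.chi2.sf(h, df=len(arrays) - 1))
    return KruskalResult(float(h), p, degenerate=False)


@dataclass
class PairwiseComparison:
    """One DSCF pairwise test between two groups."""

    group_a: int | str
    group_b: int | str
    statistic: float  # sqrt(2) * |standardized rank-sum|, the q value
    p: float
    degenerate: bool = False
    significant: bool | None = None
    tendency: bool | None = None


def _dscf_pair_q(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Studentized-range-scale statistic sqrt(2)*|z| for one group pair,
    re-ranking only the two pooled groups; degenerate (all-tied) pairs
    return (0, True)."""
    pooled = np.concatenate([a, b])
    n_total = pooled.size
    if np.all(pooled == pooled[0]):
        return 0.0, True
    ranks = sps.rankdata(pooled)
    n_a, n_b = a.size, b.size
    w = ranks[n_a:].sum()  # rank sum of the second group
    mean = n_b * (n_total + 1) / 2.0
    var = (n_a * n_b / 12.0) * (
        n_total + 1.0 - _tie_term(pooled) / (n_total * (n_total - 1.0))
    )
    if var <= 0:
        return 0.0, True
    z = (w - mean) / math.sqrt(var)
    return math.sqrt(2.0) * abs(z), False


def dscf_posthoc(
    groups: list,
    method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> list[PairwiseComparison]:
    """Dwass-Steel-Critchlow-Fligner all-pairs post-hoc comparisons.

    For every group pair, only the two groups are pooled and mid-ranked;
    the rank-sum statistic is standardized with the tie-corrected variance
    and ``sqrt(2) * |z|`` is referred to the studentized-range distribution
    with k groups and infinite degrees of freedom (``method="asymptotic"``,
    the default).  ``method="permutation"`` instead estimates the
    family-wise p as the permutation tail probability of the *maximum*
    pairwise statistic under full group-label relabeling (max-T), which is
    the finite-sample analog of the studentized-range reference.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 3:
        raise ValidationError("dscf_posthoc needs >= 3 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs >= 2 values")
    if method not in ("asymptotic", "permutation"):
        raise ValidationError(f"unknown method {method!r}")

    pairs = list(itertools.combinations(range(k), 2))
    q_obs = {}
    degenerate = {}
    for i, j in pairs:
        q, deg = _dscf_pair_q(arrays[i], arrays[j])
        q_obs[(i, j)] = q
        degenerate[(i, j)] = deg

    if method == "asymptotic":
        p_of = {
            pair: 1.0 if degenerate[pair]
            else float(sps.studentized_range.sf(q_obs[pair], k, np.inf))
            for pair in pairs
        }
    else:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(arrays)
        sizes = [a.size for a in arrays]
        cuts = np.cumsum(sizes)[:-1]
        exceed = {pair: 0 for pair in pairs}
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, cuts)
            q_max = max(_dscf_pair_q(parts[i], parts[j])[0] for i, j in pairs)
            for pair in pairs:
                if q_max >= q_obs[pair]:
                    exceed[pair] += 1
        p_of = {
            pair: 1.0 if degenerate[pair]
            else (exceed[pair] + 1) / (n_permutations + 1)
            for pair in pairs
        }

    return [
        PairwiseComparison(
            group_a=i, group_b=j,
            statistic=q_obs[(i, j)],
            p=min(1.0, p_of[(i, j)]),
            degenerate=degenerate[(i, j)],
        )
        for i, j in pairs
    ]


@dataclass
class EndpointResult:
    """Omnibus + post-hoc results for one endpoint."""

    endpoint: str
    family: str
    H: float
    p_omnibus: float
    degenerate: bool = False
    significant_omnibus: bool | None = None
    tendency_omnibus: bool | None = None
    pairwise: list[PairwiseComparison] = field(default_factory=list)


@dataclass
class GroupComparisonReport:
    """Machine-readable report over all endpoints of one experiment."""

    groups: list[str]
    scheme: AlphaScheme
    results: dict[str, EndpointResult] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "alpha": {
                "experimentwise": self.scheme.experimentwise_alpha,
                "family": self.scheme.family_alpha,
                "pairwise": self.scheme.pairwise_alpha,
                "pairwise_printed": self.scheme.pairwise_alpha_text,
                "tendency": self.scheme.tendency_alpha,
            },
            "endpoints": {
                name: {
                    "family": r.family,
                    "H": r.H,
                    "p": r.p_omnibus,
                    "degenerate": r.degenerate,
                    "significant": r.significant_omnibus,
                    "tendency": r.tendency_omnibus,
                    "pairwise": [
                        {
                            "groups": [str(self.groups[c.group_a])
                                       if isinstance(c.group_a, int) else c.group_a,
                                       str(self.groups[c.group_b])
                                       if isinstance(c.group_b, int) else c.group_b],
                            "statistic": c.statistic,
                            "p": c.p,
                            "significant": c.significant,
                            "tendency": c.tendency,
                        }
                        for c in r.pairwise
                    ],
                }
                for name, r in self.results.items()
            },
        }

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per (endpoint, pair); omnibus-only rows have
        empty pair columns."""
        rows = []
        for name, r in self.results.items():
            base = {
                "endpoint": name, "family": r.family,
                "H": r.H, "p_omnibus": r.p_omnibus,
                "significant_omnibus": r.significant_omnibus,
                "tendency_omnibus": r.tendency_omnibus,
            }
            if not r.pairwise:
                rows.append({**base, "pair": "", "dscf_statistic": np.nan,
                             "dscf_p": np.nan, "significant_pairwise": None,
                             "tendency_pairwise": None})
            for c in r.pairwise:
                ga = self.groups[c.group_a] if isinstance(c.group_a, int) else c.group_a
                gb = self.groups[c.group_b] if isinstance(c.group_b, int) else c.group_b
                rows.append({**base, "pair": f"{ga} vs {gb}",
                             "dscf_statistic": c.statistic, "dscf_p": c.p,
                             "significant_pairwise": c.significant,
                             "tendency_pairwise": c.tendency})
        return pd.DataFrame(rows)


def apply_alpha_scheme(
    report: GroupComparisonReport,
    scheme: AlphaScheme | None = None,
) -> GroupComparisonReport:
    """Set significance/tendency flags — a pure function of (p, scheme).

    ``significant_omnibus`` iff p < family alpha; pairwise flags are
    evaluated only under a significant omnibus (otherwise cleared);
    tendency iff p < tendency alpha but not significant.
    """
    scheme = scheme or report.scheme
    for r in report.results.values():
        r.significant_omnibus = r.p_omnibus < scheme.family_alpha
        r.tendency_omnibus = (not r.significant_omnibus
                              and r.p_omnibus < scheme.tendency_alpha)
        for c in r.pairwise:
            if r.significant_omnibus:
                c.significant = c.p < scheme.pairwise_alpha
                c.tendency = (not c.significant) and c.p < scheme.tendency_alpha
            else:
                c.significant = False
                c.tendency = False
    report.scheme = scheme
    return report


def survival_percentages(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Per-group survival table with percentages rounded to one decimal."""
    rows = []
    for r in records:
        surv = round(100.0 * (r.n_total - r.n_dead) / r.n_total, 1)
        rows.append({
            "compound": r.compound,
            "dose_mg_per_l": r.dose_mg_per_l,
            "exposure_h": r.exposure_h,
            "n_total": r.n_total,
            "n_dead": r.n_dead,
            "percent_survival": surv,
            "percent_mortality": round(100.0 * r.n_dead / r.n_total, 1),
        })
    return pd.DataFrame(rows)


def analyze_experiment(
    endpoint_table: pd.DataFrame,
    scheme: AlphaScheme = AlphaScheme(),
    pairwise_mode: str = "gated",
    group_order: list[str] | None = None,
) -> GroupComparisonReport:
    """Run the full statistical analysis over a per-pair endpoint table.

    ``endpoint_table`` holds one row per fish pair with a ``group`` column
    plus endpoint columns named as in
    :data:`fishtrack3d.endpoints.ENDPOINT_FAMILIES`.  Each endpoint gets a
    Kruskal-Wallis omnibus test; DSCF post-hocs run for endpoints whose
    omnibus passes the family alpha (``pairwise_mode="gated"``, the
    default) or for every endpoint (``"always"``, useful because tendencies
    on pairwise comparisons can be of interest even without a significant
    omnibus).
    """
    if "group" not in endpoint_table.columns:
        raise ValidationError("endpoint table lacks required column 'group'")
    if pairwise_mode not in ("gated", "always"):
        raise ValidationError(f"unknown pairwise_mode {pairwise_mode!r}")

    endpoint_cols = [c for c in endpoint_table.columns if c in ENDPOINT_FAMILIES]
    if not endpoint_cols:
        raise ValidationError(
            "endpoint table contains none of the expected endpoint columns "
            f"(e.g. {list(ENDPOINT_FAMILIES)[:3]})"
        )

    if group_order is None:
        group_order = list(dict.fromkeys(endpoint_table["group"]))
    n_groups = len(group_order)
    if n_groups < 3:
        raise ValidationError(
            f"the alpha scheme presumes >= 3 groups (3 pairwise "
            f"comparisons); got {n_groups}"
        )
    by_group = {g: endpoint_table[endpoint_table["group"] == g]
                for g in group_order}
    for g, sub in by_group.items():
        if len(sub) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 pairs")

    report = GroupComparisonReport(groups=list(group_order), scheme=scheme)
    for col in endpoint_cols:
        values = [by_group[g][col].to_numpy(dtype=float) for g in group_order]
        kw = kruskal_wallis(values)
        res = EndpointResult(
            endpoint=col,
            family=ENDPOINT_FAMILIES[col],
            H=kw.H,
            p_omnibus=kw.p,
            degenerate=kw.degenerate,
        )
        if pairwise_mode == "always" or kw.p < scheme.family_alpha:
            res.pairwise = dscf_posthoc(values)
        report.results[col] = res
    return apply_alpha_scheme(report, scheme)
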