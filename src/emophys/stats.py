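"""Cross-phase comparison: Shapiro-Wilk, Friedman, Tukey-type post hoc.

Features are compared across the three stimulation phases within
matched arousal sessions (or valence halves). Normality is screened with
Shapiro-Wilk; the omnibus test is the subject-blocked Friedman test, and
significant comparisons are followed by pairwise mean-rank comparisons
with a studentized-range (Tukey-type) familywise correction, gatekept by
the omnibus result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

TABLE_COLUMNS = ["subject", "phase", "session", "scope", "feature", "value"]

ALPHA_DEFAULT = 0.05


@dataclass
class PairwiseComparison:
    phase_a: str
    phase_b: str
    corrected_p: float
    significant: bool


@dataclass
class ComparisonResult:
    feature: str
    dimension: str  # "arousal" (whole session) or "valence" (low/high half)
    session: int
    scope: str
    normality_p: dict[str, float] = field(default_factory=dict)
    friedman_stat: float = float("nan")
    friedman_p: float = float("nan")
    n_blocks: int = 0
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def make_feature_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy long-format table: one value per (subject, phase, session,
    scope, feature)."""
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    dup = df.duplicated(subset=TABLE_COLUMNS[:-1])
    if dup.any():
        raise ValueError("duplicate feature-table keys")
    return df


def _pivot(table: pd.DataFrame, feature: str, session: int, scope: str
           ) -> pd.DataFrame:
    sel = table[(table["feature"] == feature) & (table["session"] == session)
                & (table["scope"] == scope)]
    wide = sel.pivot(index="subject", columns="phase", values="value")
    return wide.dropna(axis=0, how="any")


def normality_scan(table: pd.DataFrame, feature: str, session: int,
                   scope: str = "whole") -> dict[str, float]:
    """Shapiro-Wilk p per phase group; degenerate groups are NaN-marked."""
    sel = table[(table["feature"] == feature) & (table["session"] == session)
                & (table["scope"] == scope)]
    out: dict[str, float] = {}
    for phase, grp in sel.groupby("phase"):
        vals = grp["value"].dropna().to_numpy()
        if vals.size < 3 or np.ptp(vals) == 0:
            warnings.warn(f"normality scan skipped for {phase}: "
                          "too few or constant values")
            out[str(phase)] = float("nan")
            continue
        out[str(phase)] = float(spstats.shapiro(vals).pvalue)
    return out


def friedman_across_phases(table: pd.DataFrame, feature: str, session: int,
                           scope: str = "whole") -> tuple[float, float, int]:
    """Friedman chi-square over subject-blocked phase values.

    Subjects missing any phase are dropped (complete-block requirement);
    fewer than 5 complete blocks is an error.
    """
    wide = _pivot(table, feature, session, scope)
    n = len(wide)
    if n < 5:
        raise ValueError(f"only {n} complete subject blocks; need at least 5")
    cols = [wide[c].to_numpy() for c in wide.columns]
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        return 0.0, 1.0, n
    stat, p = spstats.friedmanchisquare(*cols)
    return float(stat), float(p), n


def _mean_ranks(wide: pd.DataFrame) -> tuple[np.ndarray, int, int]:
    ranks = spstats.rankdata(wide.to_numpy(), axis=1)
    return ranks.mean(axis=0), len(wide), wide.shape[1]


def posthoc_pairwise(table: pd.DataFrame, feature: str, session: int,
                     scope: str = "whole", alpha: float = ALPHA_DEFAULT,
                     _gate_checked: bool = False) -> list[PairwiseComparison]:
    """Pairwise mean-rank comparisons with studentized-range correction.

    Must only be called after a significant omnibus (contract enforced
    unless the caller asserts it has already gatekept).
    """
    if not _gate_checked:
        _, p, _ = friedman_across_phases(table, feature, session, scope)
        if not p < alpha:
            raise ValueError(
                "post-hoc comparison requires a significant Friedman omnibus"
            )
    wide = _pivot(table, feature, session, scope)
    mean_ranks, n, k = _mean_ranks(wide)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    phases = list(wide.columns)
    out: list[PairwiseComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = float(spstats.studentized_range.sf(z * np.sqrt(2.0), k, np.inf))
            out.append(PairwiseComparison(
                phase_a=str(phases[i]), phase_b=str(phases[j]),
                corrected_p=p, significant=bool(p < alpha)))
    return out


def compare_feature(table: pd.DataFrame, feature: str, session: int,
                    scope: str = "whole", alpha: float = ALPHA_DEFAULT
                    ) -> ComparisonResult:
    """Full comparison for one feature in one session window: normality
    scan, Friedman omnibus, and (when significant) Tukey-type post hoc."""
    dimension = "arousal" if scope == "whole" else "valence"
    res = ComparisonResult(feature=feature, dimension=dimension,
                           session=session, scope=scope)
    res.normality_p = normality_scan(table, feature, session, scope)
    stat, p, n = friedman_across_phases(table, feature, session, scope)
    res.friedman_stat, res.friedman_p, res.n_blocks = stat, p, n
    if p < alpha:
        res.pairwise = posthoc_pairwise(table, feature, session, scope,
                                        alpha=alpha, _gate_checked=True)
    return res


def comparison_report(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        base = dict(feature=r.feature, dimension=r.dimension, session=r.session,
                    scope=r.scope, friedman_stat=r.friedman_stat,
                    friedman_p=r.friedman_p, n_blocks=r.n_blocks)
        if not r.pairwise:
            rows.append({**base, "phase_a": "", "phase_b": "",
                         "corrected_p": float("nan"), "significant": False})
        for pw in r.pairwise:
            rows.append({**base, "phase_a": pw.phase_a, "phase_b": pw.phase_b,
                         "corrected_p": pw.corrected_p,
                         "significant": pw.significant})
    return pd.DataFrame(rows)
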