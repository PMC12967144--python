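"""Phase-wise summaries and significance testing.

Group comparisons use the two-tailed unpaired t-test with Welch's
correction for unequal variances; standard deviations use the n−1
denominator.  No multiple-testing correction is applied by default (the
pairwise tests are reported unadjusted); Holm adjustment is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volio import PHASES

__all__ = ["PhaseComparison", "welch_t_test", "significance_stars", "summarize_by_phase"]

#: p-value thresholds and their star annotations, most stringent first.
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class PhaseComparison:
    metric: str
    phase_a: str
    phase_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float
    stars: str


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, df, p)`` with ``t = (ā−b̄)/√(s²_a/n_a + s²_b/n_b)``,
    Welch–Satterthwaite degrees of freedom and the two-sided p from the
    Student-t survival function.  Two constant, equal groups give
    ``t = 0, p = 1`` by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def significance_stars(p: float) -> str:
    """Star annotation: * p≤0.05, ** p≤0.01, *** p≤0.001, **** p≤0.0001."""
    for thresh, stars in STAR_LEVELS:
        if p <= thresh:
            return stars
    return "ns"


def _holm_adjust(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def summarize_by_phase(
    morphometry: pd.DataFrame,
    phases: dict[int, str] | pd.Series,
    metric: str,
    cell_id_column: str = "cell_id",
    exclude_truncated: bool = True,
    holm: bool = False,
) -> tuple[pd.DataFrame, list[PhaseComparison]]:
    """Per-phase mean ± s.d. plus all pairwise Welch comparisons.

    ``morphometry`` carries one row per analysed object with the metric
    column and a cell id column mapping into ``phases``.  Phases appear in
    mitotic order (non-dividing first); pairwise tests run only where both
    groups have n ≥ 2.  Truncated objects are excluded from the statistics
    by default (they remain in upstream tables).  ``holm`` additionally
    Holm-adjusts the p-values (off by default: unadjusted tests are the
    reference behaviour).
    """
    if hasattr(phases, "to_dict"):
        phases = phases.to_dict()
    df = morphometry.copy()
    if metric not in df.columns:
        raise ValueError(f"metric column {metric!r} missing")
    if exclude_truncated and "truncated" in df.columns:
        df = df[~df["truncated"].astype(bool)]
    df = df.sort_values([cell_id_column] + (["object_id"] if "object_id" in df.columns else []), kind="stable")
    df["phase"] = df[cell_id_column].map(phases)
    unknown = sorted(set(df["phase"].dropna()) - set(PHASES))
    if unknown:
        raise ValueError(f"unknown phase labels: {unknown}")
    df = df.dropna(subset=["phase", metric])

    present = [p for p in PHASES if p in set(df["phase"])]
    summary_rows = []
    groups: dict[str, np.ndarray] = {}
    for ph in present:
        vals = df.loc[df["phase"] == ph, metric].to_numpy(dtype=float)
        groups[ph] = vals
        summary_rows.append(
            {
                "phase": ph,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    summary = pd.DataFrame(summary_rows)

    comparisons: list[PhaseComparison] = []
    raw_p: list[float] = []
    pairs = [
        (a, b)
        for i, a in enumerate(present)
        for b in present[i + 1 :]
        if len(groups[a]) >= 2 and len(groups[b]) >= 2
    ]
    for a, b in pairs:
        t, dfree, p = welch_t_test(groups[a], groups[b])
        raw_p.append(p)
        comparisons.append(
            PhaseComparison(
                metric=metric,
                phase_a=a,
                phase_b=b,
                n_a=len(groups[a]),
                n_b=len(groups[b]),
                mean_a=float(groups[a].mean()),
                mean_b=float(groups[b].mean()),
                sd_a=float(groups[a].std(ddof=1)),
                sd_b=float(groups[b].std(ddof=1)),
                t=t,
                df=dfree,
                p=p,
                stars=significance_stars(p),
            )
        )
    if holm and comparisons:
        adj = _holm_adjust(raw_p)
        comparisons = [
            PhaseComparison(**{**c.__dict__, "p": q, "stars": significance_stars(q)})
            for c, q in zip(comparisons, adj)
        ]
    return summary, comparisons
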