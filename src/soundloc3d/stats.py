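"""Repeated-measures statistical battery.

Balanced fully-within-participant ANOVA (any number of within factors, one
observation per participant x cell), Greenhouse-Geisser sphericity
correction, generalized eta squared (eta_g^2), Holm-Bonferroni step-down
adjustment, paired contrasts, and Kendall's tau-b rank correlation.

Within-subject sums of squares are computed by the classical balanced-design
decomposition: for each effect E the error term is the E x participant
interaction, F = MS_E / MS_{E x S}.  The Greenhouse-Geisser epsilon for an
effect with more than one degree of freedom comes from the covariance of the
participant-level orthonormal-contrast scores,

    eps = tr(S)^2 / (df * sum(S_ij^2)),    1/df <= eps <= 1,

and scales both degrees of freedom before the p value is computed.
Two-level factors are sphericity-trivial and left uncorrected.

Generalized eta squared uses the observed-variance denominator for a fully
within design (Olejnik & Algina 2003; Bakeman 2005):

    eta_g^2 = SS_E / (SS_E + SS_subjects + sum_k SS_{k x subjects}).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "rm_anova",
    "holm_adjust",
    "kendall_correlation",
    "condition_contrast",
    "contrast_family",
    "anova_table",
    "format_report",
]


@dataclass
class StatResult:
    name: str  # effect / contrast label
    statistic: str  # 'F', 't', 'tau'
    value: float
    df1: float | None = None
    df2: float | None = None
    p_raw: float = np.nan
    p_adjusted: float | None = None
    effect_size: float | None = None  # generalized eta squared for ANOVA terms
    correction: str = "none"  # 'none' | 'GG' | 'holm' | 'GG+holm'
    extras: dict = field(default_factory=dict)


def _cell_array(data: pd.DataFrame, dv: str, within: list[str], subject: str):
    """Pivot long data to a (n_subjects, l1, ..., lk) cell-mean array."""
    levels = [list(pd.unique(data[f])) for f in within]
    subjects = list(pd.unique(data[subject]))
    grouped = data.groupby([subject, *within], sort=False, observed=True)[dv].mean()
    full = pd.MultiIndex.from_product([subjects, *levels], names=[subject, *within])
    aligned = grouped.reindex(full)
    missing = aligned.index[aligned.isna()]
    if len(missing):
        raise ValueError(f"rm_anova requires a complete design; missing cells: {list(missing)[:10]}")
    y = aligned.to_numpy().reshape(len(subjects), *map(len, levels))
    return y, levels, subjects


def _effect_alpha(y: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Inclusion-exclusion effect term over the given axes (others averaged out)."""
    all_axes = tuple(range(y.ndim))
    alpha = np.zeros_like(y)
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            collapse = tuple(a for a in all_axes if a not in sub)
            m = y.mean(axis=collapse, keepdims=True) if collapse else y
            alpha = alpha + ((-1) ** (len(axes) - r)) * m
    return alpha


def _ss(y: np.ndarray, axes: tuple[int, ...]) -> tuple[float, int]:
    alpha = _effect_alpha(y, axes)
    # alpha is constant over collapsed axes; summing the broadcast square
    # over the full array supplies the replication multiplier.
    ss = float(np.sum(np.broadcast_to(alpha, y.shape) ** 2))
    df = int(np.prod([y.shape[a] - 1 for a in axes]))
    return ss, df


def _gg_epsilon(y: np.ndarray, factor_axes: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for the effect spanned by ``factor_axes``."""
    other = tuple(a for a in range(1, y.ndim) if a not in factor_axes)
    z = y.mean(axis=other) if other else y  # (n_subj, levels of E...)
    z = z.reshape(z.shape[0], -1)
    contrast = np.array([[1.0]])
    for a in factor_axes:
        contrast = np.kron(contrast, helmert(y.shape[a]).T)  # (m, df) orthonormal
    d = z @ contrast
    s = np.cov(d, rowvar=False)
    s = np.atleast_2d(s)
    df = s.shape[0]
    denom = df * float(np.sum(s * s))
    if denom == 0.0:
        return 1.0
    eps = float(np.trace(s)) ** 2 / denom
    return float(np.clip(eps, 1.0 / df, 1.0))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str] | str,
    subject: str = "participant",
    gg: bool = True,
) -> list[StatResult]:
    """Fully-within repeated-measures ANOVA on a long-format table.

    One row per observation; replicate rows per participant x cell are
    averaged first.  Returns one :class:`StatResult` per main effect and
    interaction, with GG-corrected p values (correction applied only to
    effects with more than 1 numerator df) and generalized eta squared.
    """
    within = [within] if isinstance(within, str) else list(within)
    y, levels, subjects = _cell_array(data, dv, within, subject)
    if len(subjects) < 3:
        raise ValueError("rm_anova needs at least 3 participants")
    factor_axes = tuple(range(1, y.ndim))

    ss_subj, _ = _ss(y, (0,))
    effects = [
        tuple(c)
        for r in range(1, len(factor_axes) + 1)
        for c in itertools.combinations(factor_axes, r)
    ]
    ss_err_total = sum(_ss(y, (0, *e))[0] for e in effects)

    results = []
    for e in effects:
        ss_e, df_e = _ss(y, e)
        ss_err, df_err = _ss(y, (0, *e))
        if ss_err == 0.0:
            f = np.inf if ss_e > 0 else 0.0
        else:
            f = (ss_e / df_e) / (ss_err / df_err)
        name = " x ".join(within[a - 1] for a in e)
        eps = _gg_epsilon(y, e) if (gg and df_e > 1) else 1.0
        df1, df2 = df_e * eps, df_err * eps
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else (1.0 if f == 0 else 0.0)
        ges = ss_e / (ss_e + ss_subj + ss_err_total) if (ss_e + ss_subj + ss_err_total) > 0 else 0.0
        results.append(
            StatResult(
                name=name,
                statistic="F",
                value=float(f),
                df1=float(df1),
                df2=float(df2),
                p_raw=p,
                effect_size=float(ges),
                correction="GG" if eps < 1.0 else "none",
                extras={"epsilon": eps, "ss": ss_e, "ss_error": ss_err, "df_uncorrected": (df_e, df_err)},
            )
        )
    return results


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def kendall_correlation(x, y) -> StatResult:
    """Kendall's tau-b (tie-corrected) with two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("kendall_correlation needs equal-length inputs of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    res = sps.kendalltau(x, y)
    return StatResult(
        name="kendall_tau",
        statistic="tau",
        value=float(res.statistic),
        p_raw=float(res.pvalue),
        extras={"n": int(x.size)},
    )


def condition_contrast(a, b, name: str = "contrast") -> StatResult:
    """Paired comparison of two per-participant value arrays (a vs. b).

    Reports the paired t statistic and the per-group mean +/- SE.  A
    zero-variance difference is degenerate: p = 1 for an identically zero
    difference, otherwise flagged with an undefined p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("contrast requires paired 1-D arrays of equal length")
    n = a.size
    diff = a - b
    extras = {
        "mean_a": float(a.mean()),
        "se_a": float(a.std(ddof=1) / np.sqrt(n)),
        "mean_b": float(b.mean()),
        "se_b": float(b.std(ddof=1) / np.sqrt(n)),
        "mean_diff": float(diff.mean()),
        "n": n,
    }
    if np.std(diff, ddof=1) == 0.0:
        if diff.mean() == 0.0:
            return StatResult(name, "t", 0.0, df1=None, df2=float(n - 1), p_raw=1.0, extras=extras)
        extras["degenerate"] = True
        return StatResult(name, "t", np.inf, df1=None, df2=float(n - 1), p_raw=np.nan, extras=extras)
    t, p = sps.ttest_rel(a, b)
    return StatResult(name, "t", float(t), df1=None, df2=float(n - 1), p_raw=float(p), extras=extras)


def contrast_family(pairs: dict) -> list[StatResult]:
    """Run a family of paired contrasts and Holm-adjust p values within it.

    ``pairs`` maps contrast name -> (a, b) paired arrays.  The family is the
    set of planned comparisons for one dependent variable (e.g., the
    within-sector condition contrasts).
    """
    results = [condition_contrast(a, b, name) for name, (a, b) in pairs.items()]
    ps = np.array([r.p_raw for r in results])
    valid = ~np.isnan(ps)
    if valid.any():
        adjusted = np.full_like(ps, np.nan)
        adjusted[valid] = holm_adjust(ps[valid])
        for r, p_adj in zip(results, adjusted):
            r.p_adjusted = None if np.isnan(p_adj) else float(p_adj)
            r.correction = "holm" if r.correction == "none" else r.correction + "+holm"
    return results


def anova_table(results: list[StatResult]) -> pd.DataFrame:
    """Machine-readable summary: term, F, df1, df2, p, p_adj, ges, correction."""
    return pd.DataFrame(
        [
            {
                "term": r.name,
                "statistic": r.statistic,
                "value": r.value,
                "df1": r.df1,
                "df2": r.df2,
                "p": r.p_raw,
                "p_adj": r.p_adjusted,
                "ges": r.effect_size,
                "correction": r.correction,
            }
            for r in results
        ]
    )


def format_report(results: list[StatResult]) -> str:
    """Human-readable block, one line per test, journal style."""
    lines = []
    for r in results:
        if r.statistic == "F":
            lines.append(
                f"{r.name}: F({r.df1:.2f}, {r.df2:.2f}) = {r.value:.2f}, "
                f"p = {r.p_raw:.4f}, ges = {r.effect_size:.3f}"
                + (f" [{r.correction}]" if r.correction != "none" else "")
            )
        elif r.statistic == "t":
            adj = f", p_holm = {r.p_adjusted:.4f}" if r.p_adjusted is not None else ""
            lines.append(
                f"{r.name}: {r.extras.get('mean_a', float('nan')):.1f} +/- "
                f"{r.extras.get('se_a', float('nan')):.1f} vs "
                f"{r.extras.get('mean_b', float('nan')):.1f} +/- "
                f"{r.extras.get('se_b', float('nan')):.1f}; "
                f"t({r.df2:.0f}) = {r.value:.2f}, p = {r.p_raw:.4f}{adj}"
            )
        else:
            lines.append(f"{r.name}: tau = {r.value:.3f}, p = {r.p_raw:.4f}")
    return "\n".join(lines)
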