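"""Gaussian linear models with drop1 likelihood-ratio tests, from scratch.

Expression fractions (and total quantum catch) are analysed with Gaussian
identity-link linear models of the form ``expression ~ species * island +
OR + genotype``.  Terms are tested by likelihood-ratio: the model is refitted
without the term and ``2 * (ll_full - ll_reduced)`` referred to a chi-square
with the difference in parameter count as degrees of freedom, respecting
marginality (an interaction is dropped before its main effects).  Categorical
terms use treatment coding with the alphabetically first level as reference.

Pairwise post-hoc contrasts use a seeded max-statistic permutation test in
place of the studentized-range (Tukey) adjustment: observed pairwise
mean-difference t statistics are compared with the permutation distribution
of the maximum absolute statistic under label shuffling, which controls the
family-wise error rate without special distribution tables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LmFit",
    "LrtResult",
    "StatsError",
    "build_design",
    "fit_gaussian_lm",
    "lrt_drop1",
    "drop1",
    "backward_select",
    "pairwise_contrasts",
]

log = logging.getLogger("pundavision.stats")

VARIANCE_FLOOR = 1e-12


class StatsError(RuntimeError):
    pass


@dataclass(frozen=True)
class LmFit:
    response: str
    terms: tuple[str, ...]
    coef_names: tuple[str, ...]
    coefficients: np.ndarray
    rss: float
    sigma2: float  # ML estimate (rss / n), floored
    loglik: float
    n: int


@dataclass(frozen=True)
class LrtResult:
    term: str
    statistic: float
    df: int
    p_value: float


def _is_factor(s: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(s)


def _factor_columns(s: pd.Series, name: str) -> tuple[list[np.ndarray], list[str]]:
    levels = sorted(map(str, s.dropna().unique()))
    if len(levels) < 2:
        return [], []
    cols, names = [], []
    for level in levels[1:]:  # reference = alphabetically first
        cols.append((s.astype(str) == level).to_numpy(dtype=float))
        names.append(f"{name}[{level}]")
    return cols, names


def build_design(
    data: pd.DataFrame, terms: list[str] | tuple[str, ...]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Design matrix with intercept and treatment coding.

    Terms are column names or colon-joined interactions ("a:b").  Factors
    with fewer than 2 observed levels are dropped with a warning.  Returns
    (X, column names, effective terms kept).
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    kept: list[str] = []
    for term in terms:
        parts = term.split(":")
        part_cols: list[tuple[list[np.ndarray], list[str]]] = []
        degenerate = False
        for part in parts:
            if part not in data.columns:
                raise StatsError(f"term {term!r}: no column {part!r}")
            s = data[part]
            if _is_factor(s):
                c, nm = _factor_columns(s, part)
                if not c:
                    degenerate = True
                    break
                part_cols.append((c, nm))
            else:
                part_cols.append(([s.to_numpy(dtype=float)], [part]))
        if degenerate:
            log.warning("term %r dropped: a factor has < 2 observed levels", term)
            continue
        for combo in itertools.product(*[list(zip(c, nm)) for c, nm in part_cols]):
            col = np.ones(n)
            for c, _ in combo:
                col = col * c
            cols.append(col)
            names.append(":".join(nm for _, nm in combo))
        kept.append(term)
    return np.column_stack(cols), names, kept


def fit_gaussian_lm(
    data: pd.DataFrame, response: str, terms: list[str] | tuple[str, ...]
) -> LmFit:
    """Least-squares fit with the Gaussian maximum log-likelihood.

    Raises on a rank-deficient design, naming the aliased columns.
    """
    sub = data.dropna(subset=[response]).reset_index(drop=True)
    y = sub[response].to_numpy(dtype=float)
    x, names, kept = build_design(sub, terms)
    n, p = x.shape
    if n <= p:
        raise StatsError(f"n = {n} observations for {p} coefficients")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        aliased = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [names[j] for j in piv[len(diag):]]
        raise StatsError(f"rank-deficient design; aliased column(s): {', '.join(aliased)}")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, VARIANCE_FLOOR)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + rss / (n * sigma2))
    return LmFit(response, tuple(kept), tuple(names), beta, rss, sigma2,
                 float(loglik), n)


def _containing_terms(term: str, terms: list[str] | tuple[str, ...]) -> list[str]:
    parts = set(term.split(":"))
    return [
        t for t in terms
        if t != term and parts < set(t.split(":"))
    ]


def lrt_drop1(
    data: pd.DataFrame, response: str, terms: list[str] | tuple[str, ...], term: str
) -> LrtResult:
    """Likelihood-ratio test for dropping one term from the model."""
    if term not in terms:
        raise StatsError(f"term {term!r} not in the model")
    blocking = _containing_terms(term, terms)
    if blocking:
        raise StatsError(
            f"cannot drop {term!r} while {', '.join(map(repr, blocking))} remain(s) "
            f"(marginality)"
        )
    full = fit_gaussian_lm(data, response, terms)
    reduced = fit_gaussian_lm(data, response, [t for t in terms if t != term])
    df = len(full.coef_names) - len(reduced.coef_names)
    if df < 1:
        return LrtResult(term, 0.0, max(df, 0), 1.0)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LrtResult(term, stat, df, float(sps.chi2.sf(stat, df)))


def drop1(
    data: pd.DataFrame, response: str, terms: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """LRT for every droppable term (those not contained in a higher term)."""
    rows = []
    for term in terms:
        if _containing_terms(term, terms):
            continue
        res = lrt_drop1(data, response, terms, term)
        rows.append(
            {"response": response, "term": term, "chi2": res.statistic,
             "df": res.df, "p": res.p_value}
        )
    return pd.DataFrame(rows)


def backward_select(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Minimum adequate model by backward drop1, interactions first.

    Repeatedly drops the least significant droppable term with p >= alpha
    until none remains; returns the surviving terms and the drop trail.
    """
    terms = list(terms)
    trail = []
    while terms:
        table = drop1(data, response, terms)
        if table.empty:
            break
        worst = table.sort_values("p", ascending=False).iloc[0]
        if worst["p"] < alpha:
            break
        terms.remove(worst["term"])
        trail.append(dict(worst))
    return terms, pd.DataFrame(trail)


def pairwise_contrasts(
    data: pd.DataFrame,
    response: str,
    factor: str,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation max-|t| adjusted pairwise contrasts for one factor.

    Observed pairwise mean-difference t statistics (pooled within-group
    variance) are compared against the permutation distribution of the
    maximum absolute statistic under label shuffling, giving family-wise
    adjusted p-values.  Deterministic under a fixed seed and invariant to
    input row order (rows are canonically sorted before permuting).
    """
    if n_perm < 999:
        raise StatsError("n_perm must be >= 999")
    sub = data.dropna(subset=[response, factor])
    sub = sub.sort_values([factor, response], kind="mergesort").reset_index(drop=True)
    labels = sub[factor].astype(str).to_numpy()
    values = sub[response].to_numpy(dtype=float)
    levels = sorted(set(labels))
    if len(levels) < 3:
        raise StatsError(f"factor {factor!r} has {len(levels)} level(s); need >= 3")
    masks = {lv: labels == lv for lv in levels}
    ns = {lv: int(m.sum()) for lv, m in masks.items()}
    unstable = {lv for lv, n in ns.items() if n < 2}
    for lv in unstable:
        log.warning("level %r has < 2 observations; its contrasts are unstable", lv)

    def pair_stats(v: np.ndarray) -> dict[tuple[str, str], float]:
        means = {lv: v[m].mean() for lv, m in masks.items()}
        sse = sum(float(((v[m] - means[lv]) ** 2).sum()) for lv, m in masks.items())
        dof = len(v) - len(levels)
        sp2 = max(sse / dof, VARIANCE_FLOOR) if dof > 0 else VARIANCE_FLOOR
        out = {}
        for a, b in itertools.combinations(levels, 2):
            se = np.sqrt(sp2 * (1.0 / ns[a] + 1.0 / ns[b]))
            out[(a, b)] = (means[a] - means[b]) / se
        return out

    observed = pair_stats(values)
    rng = np.random.default_rng(seed)
    max_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(values)
        max_stats[i] = max(abs(t) for t in pair_stats(perm).values())

    rows = []
    for (a, b), t in sorted(observed.items()):
        p_adj = (1.0 + float((max_stats >= abs(t)).sum())) / (n_perm + 1.0)
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "estimate": float(values[masks[a]].mean() - values[masks[b]].mean()),
                "t": float(t),
                "p_adj": p_adj,
                "unstable": a in unstable or b in unstable,
                "n_perm": n_perm,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
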