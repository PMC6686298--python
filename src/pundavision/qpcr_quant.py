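"""Relative opsin expression from raw qPCR amplification curves.

The estimator follows the window-of-linearity idea: for each well, find the
contiguous stretch of cycles over which baseline-subtracted fluorescence is
log-linear, fit ``log10(F)`` against cycle there, and read off the per-well
amplification efficiency ``E = 10**slope`` and the initial fluorescence-scale
template amount ``N0 = 10**intercept``.  Fractional threshold cycles (Ct) come
from inverting the fitted line at a plate-common threshold.  A serially
diluted multi-opsin construct run on the same plate calibrates Ct against
log10 concentration (slope ``m`` cycles/decade, intercept ``b``), and relative
expression of opsin *i* is::

    N_i = 10**((Ct_i - b) / m) / sum_j 10**((Ct_j - b) / m)

The inversion uses base 10 because the calibration regresses Ct on log10
concentration; relative weights depend on the base, so the two must agree.
Efficiency percentages use the (E - 1) * 100 convention, under which perfect
doubling is 100% and the 75-125% quality band is meaningful.

Quality control mirrors standard practice: both duplicate wells must have
efficiency in the configured band and the duplicate Ct standard deviation
must not exceed 0.5 cycles; afterwards, expression values are screened per
opsin and population with a 1.5 x IQR fence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CONSTRUCT, OPSINS

__all__ = [
    "AmplificationCurve",
    "WindowFit",
    "CtValue",
    "ConstructCalibration",
    "QpcrError",
    "NoAmplificationError",
    "WindowNotFoundError",
    "CalibrationError",
    "curves_from_plate",
    "fit_window_of_linearity",
    "plate_common_threshold",
    "compute_ct",
    "fit_construct_calibration",
    "relative_expression",
    "apply_duplicate_qc",
    "iqr_outlier_filter",
    "quantify_plate",
    "filter_population_outliers",
]

log = logging.getLogger("pundavision.qpcr")


class QpcrError(RuntimeError):
    """Base class for quantification failures."""


class NoAmplificationError(QpcrError):
    """No fluorescence rise above baseline noise."""


class WindowNotFoundError(QpcrError):
    """Fewer than the minimum number of usable log-linear points."""


class CalibrationError(QpcrError):
    """The construct dilution series cannot be regressed."""


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's fluorescence-by-cycle trace (cycles implicitly 1..C)."""

    well_id: str
    sample_id: str
    opsin: str
    fluorescence: np.ndarray
    dilution_log10_conc: float | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.fluorescence)


@dataclass(frozen=True)
class WindowFit:
    """Log-linear window regression for one well."""

    well_id: str
    window: tuple[int, int]  # inclusive cycle range
    slope_log10: float
    intercept_log10: float  # log10 fluorescence at cycle 0
    r2: float
    efficiency: float  # 10**slope_log10, ~2 for perfect doubling
    n0_raw: float  # 10**intercept_log10

    @property
    def efficiency_pct(self) -> float:
        return (self.efficiency - 1.0) * 100.0


@dataclass(frozen=True)
class CtValue:
    well_id: str
    ct: float
    threshold: float
    extrapolated: bool = False


@dataclass(frozen=True)
class ConstructCalibration:
    """OLS of construct Ct on log10 concentration: ct = m*x + b."""

    slope: float  # m, cycles per decade; negative for an amplifying construct
    intercept: float  # b, cycles
    r2: float
    n_points: int


def curves_from_plate(plate: pd.DataFrame) -> list[AmplificationCurve]:
    curves = []
    for well, grp in plate.groupby("well_id", sort=False):
        grp = grp.sort_values("cycle")
        dil = grp["dilution_log10_conc"].iloc[0]
        curves.append(
            AmplificationCurve(
                well_id=str(well),
                sample_id=str(grp["sample_id"].iloc[0]),
                opsin=str(grp["opsin"].iloc[0]),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
                dilution_log10_conc=None if pd.isna(dil) else float(dil),
            )
        )
    return curves


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r2 of a simple linear regression."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = float(((y - (slope * x + intercept)) ** 2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def fit_window_of_linearity(
    curve: AmplificationCurve,
    baseline_cycles: int = 3,
    *,
    min_window: int = 4,
    max_window: int = 6,
    band: tuple[float, float] = (0.05, 0.80),
) -> WindowFit:
    """Locate the log-linear window of an amplification curve and fit it.

    The baseline is the mean of the first ``baseline_cycles`` fluorescence
    readings (pass 0 for already baseline-corrected data).  Candidate windows
    are contiguous cycle runs of length ``min_window..max_window`` whose
    baseline-subtracted fluorescence lies between ``band`` fractions of the
    observed plateau (the maximum); among candidates with rising fluorescence
    the one maximising r2 of log10(F) vs cycle wins, ties going to the
    earlier (then longer) window.
    """
    f = np.asarray(curve.fluorescence, dtype=float)
    n = len(f)
    if n < 15:
        raise QpcrError(f"well {curve.well_id}: need >= 15 cycles, got {n}")
    if baseline_cycles > 0:
        baseline = float(f[:baseline_cycles].mean())
        noise = float(f[:baseline_cycles].std())
    else:
        baseline = 0.0
        noise = 0.0
    g = f - baseline
    peak = float(g.max())
    if peak <= 0 or peak <= 5.0 * noise:
        raise NoAmplificationError(
            f"well {curve.well_id}: no amplification (no point exceeds "
            f"5x baseline noise)"
        )
    lo, hi = band
    usable = (g >= lo * peak) & (g <= hi * peak) & (g > 0)
    if int(usable.sum()) < min_window:
        raise WindowNotFoundError(
            f"well {curve.well_id}: window not found "
            f"({int(usable.sum())} usable point(s) in the {lo:.0%}-{hi:.0%} band)"
        )
    cycles = np.arange(1, n + 1, dtype=float)
    best: tuple[float, WindowFit] | None = None
    for start in range(n):
        for length in range(max_window, min_window - 1, -1):
            stop = start + length
            if stop > n or not usable[start:stop].all():
                continue
            x = cycles[start:stop]
            y = np.log10(g[start:stop])
            slope, intercept, r2 = _ols_line(x, y)
            if slope <= 0:
                continue
            if best is None or r2 > best[0] + 1e-12:
                fit = WindowFit(
                    well_id=curve.well_id,
                    window=(start + 1, stop),
                    slope_log10=slope,
                    intercept_log10=intercept,
                    r2=min(max(r2, 0.0), 1.0),
                    efficiency=10.0 ** slope,
                    n0_raw=10.0 ** intercept,
                )
                best = (r2, fit)
    if best is None:
        raise WindowNotFoundError(
            f"well {curve.well_id}: window not found (no rising window of "
            f">= {min_window} points)"
        )
    return best[1]


def plate_common_threshold(fits: Iterable[WindowFit]) -> float:
    """Geometric mean of the fitted window-midpoint fluorescences."""
    mids = []
    for fit in fits:
        mid = 0.5 * (fit.window[0] + fit.window[1])
        mids.append(fit.slope_log10 * mid + fit.intercept_log10)
    if not mids:
        raise QpcrError("no fitted wells to derive a plate threshold from")
    return float(10.0 ** np.mean(mids))


def compute_ct(fit: WindowFit, threshold: float) -> CtValue:
    """Fractional cycle at which the fitted line crosses ``threshold``."""
    if threshold <= 0:
        raise QpcrError("threshold must be positive")
    ct = (np.log10(threshold) - fit.intercept_log10) / fit.slope_log10
    lo = fit.slope_log10 * fit.window[0] + fit.intercept_log10
    hi = fit.slope_log10 * fit.window[1] + fit.intercept_log10
    extrapolated = not (lo <= np.log10(threshold) <= hi)
    if extrapolated:
        log.warning(
            "well %s: threshold %.3g outside the fitted window span; "
            "Ct obtained by extrapolation", fit.well_id, threshold,
        )
    return CtValue(fit.well_id, float(ct), float(threshold), extrapolated)


def fit_construct_calibration(
    dilution_points: Sequence[tuple[float, float]],
    *,
    min_points: int = 4,
    min_span: float = 3.0,
) -> ConstructCalibration:
    """OLS of construct Ct on log10 concentration."""
    if len(dilution_points) < min_points:
        raise CalibrationError(
            f"need >= {min_points} dilution points, got {len(dilution_points)}"
        )
    x = np.array([p[0] for p in dilution_points], dtype=float)
    ct = np.array([p[1] for p in dilution_points], dtype=float)
    span = float(x.max() - x.min())
    if span < min_span:
        log.warning("construct dilution span %.2f < %.1f log10 units", span, min_span)
    slope, intercept, r2 = _ols_line(x, ct)
    if slope >= 0:
        raise CalibrationError(f"non-amplifying construct (slope {slope:.3f} >= 0)")
    return ConstructCalibration(slope, intercept, r2, len(dilution_points))


def relative_expression(
    cts: Mapping[str, float],
    calib: ConstructCalibration,
    *,
    base: float = 10.0,
) -> dict[str, float]:
    """Per-opsin expression fractions from mean Cts and the calibration.

    Opsins absent from ``cts`` (no passing wells) are excluded from the sum
    and absent from the result — missing, not zero.  The returned fractions
    sum to 1 over the opsins present.
    """
    if calib is None:
        raise QpcrError("construct calibration is required")
    present = {k: v for k, v in cts.items() if v is not None and np.isfinite(v)}
    if len(present) == 0:
        raise QpcrError("no opsins with passing Ct values")
    if len(present) < 2:
        raise QpcrError(
            f"need >= 2 opsins with passing Ct values, got {len(present)}"
        )
    # subtract the minimum exponent before exponentiating for stability
    expo = {k: (v - calib.intercept) / calib.slope for k, v in present.items()}
    shift = max(expo.values())
    weights = {k: base ** (e - shift) for k, e in expo.items()}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


def apply_duplicate_qc(
    wells: Mapping[tuple[str, str], Sequence[tuple[WindowFit, CtValue]]],
    *,
    efficiency_band_pct: tuple[float, float] = (75.0, 125.0),
    max_ct_sd: float = 0.5,
) -> pd.DataFrame:
    """Duplicate-level quality control per (sample, opsin).

    A pair passes iff both wells' efficiency percentages lie inside
    ``efficiency_band_pct`` and the duplicate Ct standard deviation
    (ddof=1) is at most ``max_ct_sd``.  Passing pairs contribute the mean Ct
    and, for diagnostics, the mean window-derived N0 estimate.
    """
    lo, hi = efficiency_band_pct
    rows = []
    for (sample_id, opsin), pairs in wells.items():
        effs = [fit.efficiency_pct for fit, _ in pairs]
        cts = [ct.ct for _, ct in pairs]
        reasons: list[str] = []
        if len(pairs) == 0:
            reasons.append("no amplification")
            ct_sd = np.nan
        elif len(pairs) < 2:
            reasons.append("no duplicate")
            ct_sd = np.nan
        else:
            ct_sd = float(np.std(cts, ddof=1))
            if ct_sd > max_ct_sd:
                reasons.append("ct_sd")
        if any(not (lo <= e <= hi) for e in effs):
            reasons.append("efficiency")
        passed = not reasons
        rows.append(
            {
                "sample_id": sample_id,
                "opsin": opsin,
                "n_wells": len(pairs),
                "efficiency_pct_min": float(min(effs)) if effs else np.nan,
                "efficiency_pct_max": float(max(effs)) if effs else np.nan,
                "ct_sd": ct_sd,
                "mean_ct": float(np.mean(cts)) if passed else np.nan,
                "mean_n0_raw": (
                    float(np.mean([fit.n0_raw for fit, _ in pairs])) if passed else np.nan
                ),
                "passed": passed,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def iqr_outlier_filter(
    values: Sequence[float], k: float = 1.5, atol: float = 0.005
) -> np.ndarray:
    """Keep mask under the Tukey fence Q1 - k*IQR .. Q3 + k*IQR.

    Quartiles use linear interpolation (numpy's default, R type 7).  With
    fewer than 4 values no filtering is applied (all kept, with a warning).

    ``atol`` is a measurement-resolution floor: values within ``atol`` of
    the population median are never flagged.  Without it, a population with
    (near-)constant expression collapses the fence to the width of the
    quantification residue and excludes fish on numerical noise.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        log.warning("IQR filter skipped: only %d value(s) (need >= 4)", len(v))
        return np.ones(len(v), dtype=bool)
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    in_fence = (v >= q1 - k * iqr) & (v <= q3 + k * iqr)
    return in_fence | (np.abs(v - np.median(v)) <= atol)


def quantify_plate(
    plate: pd.DataFrame,
    *,
    baseline_cycles: int = 3,
    efficiency_band_pct: tuple[float, float] = (75.0, 125.0),
    max_ct_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the whole per-plate chain: curves -> windows -> Ct -> QC -> profiles.

    Returns ``(expression, qc_report)``.  ``expression`` has one row per
    sample with per-opsin fractions (NaN where the opsin had no passing
    wells) and ``n_passing_opsins``; ``qc_report`` has one row per
    sample x opsin (the construct appears under sample-level QC too).
    """
    curves = curves_from_plate(plate)
    fits: dict[str, WindowFit] = {}
    fit_errors: dict[str, str] = {}
    for curve in curves:
        try:
            fits[curve.well_id] = fit_window_of_linearity(
                curve, baseline_cycles=baseline_cycles
            )
        except QpcrError as exc:
            fit_errors[curve.well_id] = str(exc)
            log.info("well %s dropped: %s", curve.well_id, exc)
    if not fits:
        raise QpcrError("no well on the plate produced a window fit")
    threshold = plate_common_threshold(fits.values())
    ct_values = {wid: compute_ct(fit, threshold) for wid, fit in fits.items()}

    by_curve = {c.well_id: c for c in curves}
    # construct calibration: mean Ct per dilution point
    dilution_cts: dict[float, list[float]] = {}
    for wid, ct in ct_values.items():
        c = by_curve[wid]
        if c.opsin == CONSTRUCT and c.dilution_log10_conc is not None:
            dilution_cts.setdefault(c.dilution_log10_conc, []).append(ct.ct)
    calib = fit_construct_calibration(
        [(x, float(np.mean(cs))) for x, cs in sorted(dilution_cts.items())]
    )

    groups: dict[tuple[str, str], list[tuple[WindowFit, CtValue]]] = {}
    for c in curves:
        if c.opsin == CONSTRUCT:
            continue
        groups.setdefault((c.sample_id, c.opsin), [])
        if c.well_id in fits:
            groups[(c.sample_id, c.opsin)].append(
                (fits[c.well_id], ct_values[c.well_id])
            )
    # wells that failed to fit still count toward group membership loss:
    # a group whose second well failed becomes a singleton and auto-fails.
    qc = apply_duplicate_qc(
        groups, efficiency_band_pct=efficiency_band_pct, max_ct_sd=max_ct_sd
    )

    expr_rows = []
    for sample_id, sample_qc in qc.groupby("sample_id", sort=False):
        cts = {
            row["opsin"]: row["mean_ct"]
            for _, row in sample_qc.iterrows()
            if row["passed"]
        }
        row: dict[str, object] = {"fish_id": sample_id}
        try:
            profile = relative_expression(cts, calib)
        except QpcrError as exc:
            log.warning("sample %s: %s", sample_id, exc)
            profile = {}
        for opsin in OPSINS:
            row[opsin] = profile.get(opsin, np.nan)
        row["n_passing_opsins"] = len(profile)
        expr_rows.append(row)
    expression = pd.DataFrame(expr_rows)
    expression.attrs["calibration"] = calib
    expression.attrs["threshold"] = threshold
    expression.attrs["fit_errors"] = fit_errors
    return expression, qc


def filter_population_outliers(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    k: float = 1.5,
    drop: str = "opsin",
) -> pd.DataFrame:
    """Apply the 1.5 x IQR fence per opsin x population (island x phenotype).

    With ``drop="opsin"`` (default) a flagged value makes that opsin missing
    for that fish and the fish's profile is recomputed from its remaining
    opsins (for fractions this equals renormalising over the survivors,
    since the per-opsin weights are unchanged).  With ``drop="fish"`` a
    single flagged opsin removes the whole fish.  Returns a new expression
    table with an ``n_filtered`` attr.
    """
    if drop not in ("opsin", "fish"):
        raise ValueError(f"drop must be 'opsin' or 'fish', got {drop!r}")
    merged = expression.merge(
        metadata[["fish_id", "island", "phenotype"]], on="fish_id", how="left"
    )
    out = expression.copy()
    n_filtered = 0
    for (island, phenotype), grp in merged.groupby(["island", "phenotype"]):
        for opsin in OPSINS:
            vals = grp[opsin]
            ok = vals.notna()
            if ok.sum() == 0:
                continue
            keep = iqr_outlier_filter(vals[ok].to_numpy(), k=k)
            dropped = vals[ok].index[~keep]
            n_filtered += len(dropped)
            if drop == "fish":
                out.loc[out.index.isin(dropped), list(OPSINS)] = np.nan
            else:
                out.loc[out.index.isin(dropped), opsin] = np.nan
    # renormalise each fish over its surviving opsins
    frac = out[list(OPSINS)]
    totals = frac.sum(axis=1, skipna=True)
    out[list(OPSINS)] = frac.div(totals.where(totals > 0), axis=0)
    out["n_passing_opsins"] = frac.notna().sum(axis=1)
    out.attrs["n_filtered"] = n_filtered
    return out
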