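"""Underwater light metrics: spectrum aggregation, orange ratio, OR profiles.

The orange ratio (OR) summarises how long-wavelength-shifted a light
environment is: integrated irradiance over 550-700 nm divided by that over
400-549 nm (both bands inclusive, trapezoidal rule on the native wavelength
grid; the 549-550 nm gap contributes to neither band).  OR increases with
depth everywhere in Lake Victoria because short wavelengths attenuate
faster, and it increases with turbidity at fixed depth.

Replicate spectra are averaged within each measurement day, then days are
averaged with equal weight.  Two islands need special handling: Anchor was
never measured, so its OR-by-depth profile is estimated as the per-depth
median of the Makobe and Python profiles (= their mean for two values); and
the most turbid island's spectra stop where light runs out, so OR for fish
caught deeper comes from a linear regression of OR on depth, fitted over all
measured depths of that island.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FishRecord

__all__ = [
    "OrProfile",
    "LightEnvError",
    "aggregate_spectra",
    "orange_ratio",
    "spectral_midpoint",
    "build_or_profile",
    "anchor_or_profile",
    "build_all_profiles",
    "assign_or",
]

log = logging.getLogger("pundavision.light")

OR_NUMERATOR_BAND = (550.0, 700.0)
OR_DENOMINATOR_BAND = (400.0, 549.0)


class LightEnvError(RuntimeError):
    pass


@dataclass(frozen=True)
class OrProfile:
    """Per-island orange-ratio-by-depth profile with an extrapolation line."""

    island: str
    depths: np.ndarray  # strictly increasing, metres
    or_values: np.ndarray
    slope: float  # OLS fit of OR on depth, for extrapolation below range
    intercept: float
    provenance: str  # "measured" or "median-estimated"


def aggregate_spectra(table: pd.DataFrame) -> pd.DataFrame:
    """Mean over replicates within a day, then unweighted mean across days.

    Input follows the spectra schema (island, date, depth_m, replicate,
    wavelength_nm, irradiance).  Wavelength grids must agree across the
    replicates and dates being averaged.  Returns columns island, depth_m,
    wavelength_nm, irradiance.
    """
    if "replicate" not in table.columns:
        table = table.assign(replicate=1)
    day_means = []
    for (island, date, depth), grp in table.groupby(["island", "date", "depth_m"]):
        grids = [
            np.sort(rep_grp["wavelength_nm"].to_numpy())
            for _, rep_grp in grp.groupby("replicate")
        ]
        for grid in grids[1:]:
            if len(grid) != len(grids[0]) or not np.array_equal(grid, grids[0]):
                raise LightEnvError(
                    f"mismatched wavelength grids among replicates at "
                    f"{island} {date} {depth} m"
                )
        if len(grids) < 2:
            log.warning(
                "%s %s %s m: only %d replicate spectrum (expected >= 2)",
                island, date, depth, len(grids),
            )
        mean = grp.groupby("wavelength_nm", as_index=False)["irradiance"].mean()
        mean.insert(0, "depth_m", depth)
        mean.insert(0, "date", date)
        mean.insert(0, "island", island)
        day_means.append(mean)
    days = pd.concat(day_means, ignore_index=True)
    out = []
    for (island, depth), grp in days.groupby(["island", "depth_m"]):
        grids = [np.sort(g["wavelength_nm"].to_numpy()) for _, g in grp.groupby("date")]
        for grid in grids[1:]:
            if not np.array_equal(grid, grids[0]):
                raise LightEnvError(
                    f"mismatched wavelength grids across dates at {island} {depth} m"
                )
        mean = grp.groupby("wavelength_nm", as_index=False)["irradiance"].mean()
        mean.insert(0, "depth_m", depth)
        mean.insert(0, "island", island)
        out.append(mean)
    return pd.concat(out, ignore_index=True)


def _band_integral(
    wavelength: np.ndarray, irradiance: np.ndarray, band: tuple[float, float]
) -> float:
    mask = (wavelength >= band[0]) & (wavelength <= band[1])
    if int(mask.sum()) < 2:
        raise LightEnvError(
            f"band {band} contains fewer than 2 grid points"
        )
    return float(np.trapezoid(irradiance[mask], wavelength[mask]))


def orange_ratio(wavelength: np.ndarray, irradiance: np.ndarray) -> float:
    """Integrated irradiance 550-700 nm over 400-549 nm (trapezoid).

    A zero denominator yields +inf with a structured warning (never a
    silently dropped spectrum).
    """
    wavelength = np.asarray(wavelength, dtype=float)
    irradiance = np.asarray(irradiance, dtype=float)
    num = _band_integral(wavelength, irradiance, OR_NUMERATOR_BAND)
    den = _band_integral(wavelength, irradiance, OR_DENOMINATOR_BAND)
    if den == 0.0:
        log.warning("orange ratio: zero short-wavelength integral; OR = +inf")
        return float("inf")
    return num / den


def spectral_midpoint(wavelength: np.ndarray, irradiance: np.ndarray) -> float:
    """Wavelength splitting the 400-700 nm integral into equal halves.

    The smallest wavelength at which the cumulative trapezoid integral
    reaches half the total, linearly interpolated within the straddling
    interval.
    """
    wavelength = np.asarray(wavelength, dtype=float)
    irradiance = np.asarray(irradiance, dtype=float)
    mask = (wavelength >= 400.0) & (wavelength <= 700.0)
    wl, ir = wavelength[mask], irradiance[mask]
    if len(wl) < 2:
        raise LightEnvError("need >= 2 grid points in 400-700 nm")
    seg = 0.5 * (ir[1:] + ir[:-1]) * np.diff(wl)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise LightEnvError("all-zero spectrum has no midpoint")
    half = 0.5 * total
    i = int(np.searchsorted(cum, half))
    if cum[i] == half:
        return float(wl[i])
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(wl[i - 1] + frac * (wl[i] - wl[i - 1]))


def build_or_profile(island: str, spectra: pd.DataFrame) -> OrProfile:
    """OR at every measured depth plus an OLS line of OR on depth.

    ``spectra`` is the aggregated table restricted (or restrictable) to one
    island.  At least two depths are required: a single-depth island cannot
    support the extrapolation regression.
    """
    sub = spectra[spectra["island"] == island]
    if sub.empty:
        raise LightEnvError(f"no spectra for island {island}")
    depths, ors = [], []
    for depth, grp in sub.groupby("depth_m"):
        depths.append(float(depth))
        ors.append(orange_ratio(grp["wavelength_nm"].to_numpy(),
                                grp["irradiance"].to_numpy()))
    depths = np.asarray(depths)
    ors = np.asarray(ors)
    order = np.argsort(depths)
    depths, ors = depths[order], ors[order]
    if len(depths) < 2:
        raise LightEnvError(
            f"{island}: need >= 2 depths to build an OR profile, got {len(depths)}"
        )
    slope, intercept = np.polyfit(depths, ors, 1)
    return OrProfile(island, depths, ors, float(slope), float(intercept), "measured")


def anchor_or_profile(makobe: OrProfile, python: OrProfile) -> OrProfile:
    """Anchor Island estimate: per-depth median of Makobe and Python.

    Only depths present in both source profiles are emitted (the median of
    two values equals their mean).
    """
    shared = np.intersect1d(makobe.depths, python.depths)
    if len(shared) < 2:
        raise LightEnvError("Makobe and Python share fewer than 2 depths")
    m = np.interp(shared, makobe.depths, makobe.or_values)
    p = np.interp(shared, python.depths, python.or_values)
    ors = np.median(np.vstack([m, p]), axis=0)
    slope, intercept = np.polyfit(shared, ors, 1)
    return OrProfile("Anchor", shared, ors, float(slope), float(intercept),
                     "median-estimated")


def build_all_profiles(spectra: pd.DataFrame) -> dict[str, OrProfile]:
    """Profiles for every measured island, plus the Anchor median estimate."""
    profiles = {
        island: build_or_profile(island, spectra)
        for island in sorted(spectra["island"].unique())
    }
    if "Anchor" not in profiles and {"Makobe", "Python"} <= profiles.keys():
        profiles["Anchor"] = anchor_or_profile(profiles["Makobe"], profiles["Python"])
    return profiles


def assign_or(fish: FishRecord, profile: OrProfile) -> tuple[float, str]:
    """OR at a fish's capture depth, with provenance.

    Between measured depths: linear interpolation.  Below the deepest
    measurement: the profile's regression line ("regression-extrapolated").
    Above the shallowest: the shallowest value, with a warning.
    """
    d = fish.capture_depth_m
    if d > profile.depths[-1]:
        return profile.slope * d + profile.intercept, "regression-extrapolated"
    if d < profile.depths[0]:
        log.warning(
            "fish %s captured at %.2f m, above the shallowest measurement "
            "(%.2f m); using the shallowest OR", fish.fish_id, d, profile.depths[0],
        )
        return float(profile.or_values[0]), profile.provenance
    return float(np.interp(d, profile.depths, profile.or_values)), profile.provenance
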