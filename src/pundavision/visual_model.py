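"""Quantum-catch visual modelling with Govardovskii A1 pigment templates.

A visual pigment's absorbance R(lambda) is modelled with the Govardovskii
A1 template (alpha plus beta band), parameterised only by the pigment's peak
wavelength lambda_max.  The quantum catch of opsin *i* for a fish in a light
environment is::

    Qc_i = N_i * integral_400^700 I(lambda) R_i(lambda) d lambda

with I normalised to unit integral over 400-700 nm (so Qc is a pure
spectral-overlap measure, invariant to overall intensity) and N_i the fish's
relative expression of that opsin.  The LWS lambda_max depends on genotype:
H 559 nm, P 544 nm, H/P heterozygote the median 551.5 nm; the recombinant M3
has no published lambda_max and is treated as P-valued for lambda_max
arithmetic but excluded from visual-performance rosters by default.

The transplant comparison evaluates residents of an island against
hypothetical same-colour immigrants from all other islands, everyone at the
resident group's frequency-weighted mean capture depth (each fish one
frequency unit) in the resident island's light.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import OPSINS

__all__ = [
    "PigmentRegistry",
    "QuantumCatch",
    "VisualModelError",
    "pigment_absorbance",
    "lws_lambda_max",
    "interpolate_spectrum",
    "quantum_catch",
    "frequency_weighted_mean_depth",
    "transplant_comparison",
]

log = logging.getLogger("pundavision.visual")

# Govardovskii A1 alpha-band constants
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


class VisualModelError(RuntimeError):
    pass


def pigment_absorbance(wavelength, lambda_max: float):
    """Govardovskii A1 absorbance template, alpha + beta band.

    Valid for wavelengths in roughly 300-800 nm; peaks within about 1% of
    1.0 at ``lambda_max``.
    """
    wl = np.asarray(wavelength, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    s_alpha = 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    s_beta = 0.26 * np.exp(-(((wl - lam_beta) / b_beta) ** 2))
    out = s_alpha + s_beta
    return float(out) if np.isscalar(wavelength) else out


@dataclass(frozen=True)
class PigmentRegistry:
    """Peak-absorbance wavelengths (nm) for the cone pigments."""

    lambda_max: dict = field(
        default_factory=lambda: {"SWS2b": 425.0, "SWS2a": 455.0, "RH2A": 528.0}
    )
    lws_alleles: dict = field(default_factory=lambda: {"H": 559.0, "P": 544.0})
    m3_lambda_max: float | None = None  # None: treat an M3 allele as P-valued

    def allele_lambda_max(self, allele: str) -> float:
        if allele == "M3":
            return (
                self.m3_lambda_max
                if self.m3_lambda_max is not None
                else self.lws_alleles["P"]
            )
        return self.lws_alleles[allele]


DEFAULT_REGISTRY = PigmentRegistry()

#: Genotype each colour class carries where the species are differentiated;
#: visual-performance rosters are restricted to these by default.
CANONICAL_GENOTYPE = {"blue": "PP", "red": "HH"}

_GENOTYPE_ALLELES = {
    "HH": ("H", "H"),
    "PP": ("P", "P"),
    "M3M3": ("M3", "M3"),
    "HP": ("H", "P"),
    "H-M3": ("H", "M3"),
    "P-M3": ("P", "M3"),
}


def lws_lambda_max(genotype, registry: PigmentRegistry = DEFAULT_REGISTRY) -> float:
    """LWS peak wavelength for a called genotype.

    Homozygotes use their allele's value; heterozygotes the median of the
    two allele values (551.5 nm for H/P).
    """
    label = getattr(genotype, "label", genotype)
    if label not in _GENOTYPE_ALLELES:
        raise VisualModelError(f"cannot assign a lambda_max to genotype {label!r}")
    a, b = _GENOTYPE_ALLELES[label]
    return float(
        np.median([registry.allele_lambda_max(a), registry.allele_lambda_max(b)])
    )


@dataclass(frozen=True)
class QuantumCatch:
    """Per-opsin and total light capture for one fish in one environment."""

    fish_id: str
    per_opsin: dict
    total: float
    island: str = ""
    depth_m: float = float("nan")
    genotype: str = ""


def quantum_catch(
    profile: dict,
    lws_lambda_max_nm: float,
    wavelength: np.ndarray,
    irradiance: np.ndarray,
    registry: PigmentRegistry = DEFAULT_REGISTRY,
    *,
    fish_id: str = "",
    island: str = "",
    depth_m: float = float("nan"),
    genotype: str = "",
) -> QuantumCatch:
    """Quantum catch of a fish's expression profile in a light environment.

    ``profile`` maps opsin name to expression fraction; missing/NaN opsins
    are skipped.  The spectrum must cover 400-700 nm and is normalised to a
    unit trapezoid integral over that band before integration.
    """
    wl = np.asarray(wavelength, dtype=float)
    ir = np.asarray(irradiance, dtype=float)
    mask = (wl >= 400.0 - 1e-9) & (wl <= 700.0 + 1e-9)
    if (wl[mask].min(initial=np.inf) > 400.0 + 1e-6
            or wl[mask].max(initial=-np.inf) < 700.0 - 1e-6):
        raise VisualModelError("spectrum must cover 400-700 nm")
    wl, ir = wl[mask], ir[mask]
    norm = float(np.trapezoid(ir, wl))
    if norm <= 0:
        raise VisualModelError("spectrum integrates to zero over 400-700 nm")
    ir = ir / norm
    per_opsin = {}
    for opsin in OPSINS:
        n_i = profile.get(opsin)
        if n_i is None or not np.isfinite(n_i):
            continue
        lam = lws_lambda_max_nm if opsin == "LWS" else registry.lambda_max[opsin]
        r = pigment_absorbance(wl, lam)
        per_opsin[opsin] = float(n_i) * float(np.trapezoid(ir * r, wl))
    return QuantumCatch(
        fish_id=fish_id,
        per_opsin=per_opsin,
        total=float(sum(per_opsin.values())),
        island=island,
        depth_m=depth_m,
        genotype=genotype,
    )


def frequency_weighted_mean_depth(depths) -> float:
    """Mean of individual capture depths (each fish = one frequency unit)."""
    depths = np.asarray(depths, dtype=float)
    if len(depths) == 0:
        raise VisualModelError("empty roster has no mean depth")
    return float(depths.mean())


def interpolate_spectrum(
    spectra: pd.DataFrame, island: str, depth_m: float
) -> tuple[np.ndarray, np.ndarray]:
    """Island spectrum at an arbitrary depth from the aggregated table.

    Linear interpolation per wavelength between the bracketing measured
    depths; outside the measured range the nearest depth's spectrum is used.
    """
    sub = spectra[spectra["island"] == island]
    if sub.empty:
        raise VisualModelError(f"no spectra for island {island}")
    depths = np.sort(sub["depth_m"].unique())

    def at(d: float) -> tuple[np.ndarray, np.ndarray]:
        grp = sub[sub["depth_m"] == d].sort_values("wavelength_nm")
        return grp["wavelength_nm"].to_numpy(float), grp["irradiance"].to_numpy(float)

    if depth_m <= depths[0]:
        return at(depths[0])
    if depth_m >= depths[-1]:
        return at(depths[-1])
    hi = int(np.searchsorted(depths, depth_m))
    lo = hi - 1
    if depths[hi] == depth_m:
        return at(depths[hi])
    wl_lo, ir_lo = at(depths[lo])
    wl_hi, ir_hi = at(depths[hi])
    if not np.array_equal(wl_lo, wl_hi):
        raise VisualModelError(f"{island}: wavelength grids differ across depths")
    w = (depth_m - depths[lo]) / (depths[hi] - depths[lo])
    return wl_lo, (1.0 - w) * ir_lo + w * ir_hi


def transplant_comparison(
    fish: pd.DataFrame,
    spectra: pd.DataFrame,
    registry: PigmentRegistry = DEFAULT_REGISTRY,
    *,
    canonical_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residents versus hypothetical immigrants, island by island.

    ``fish`` needs columns fish_id, island, phenotype, capture_depth_m,
    genotype, and one expression column per opsin.  For each resident island
    with spectra and each colour class, every resident and every same-colour
    fish from other islands is evaluated — with its own expression profile
    and genotype — at the resident group's frequency-weighted mean depth in
    the resident island's light.  With ``canonical_only`` (the default,
    mirroring the headline analysis) rosters contain only blue PP and red HH
    fish, which also drops mismatched-genotype fish, heterozygotes and M3
    carriers.  Islands without spectra are excluded with a logged reason.

    Returns ``(per_fish, summary)``; the summary has one row per
    (resident island, colour, source island) with n, mean and SE of total Qc.
    """
    measured = set(spectra["island"].unique())
    skipped = sorted(set(fish["island"]) - measured)
    for island in skipped:
        log.info("transplant: %s excluded (no spectral measurements)", island)

    rosters: dict[tuple[str, str], pd.DataFrame] = {}
    for (island, colour), grp in fish.groupby(["island", "phenotype"]):
        if colour not in CANONICAL_GENOTYPE:
            continue
        if canonical_only:
            grp = grp[grp["genotype"] == CANONICAL_GENOTYPE[colour]]
        else:
            grp = grp[grp["genotype"].isin(_GENOTYPE_ALLELES)]
        if not grp.empty:
            rosters[(island, colour)] = grp

    per_fish_rows = []
    summary_rows = []
    for (res_island, colour), residents in sorted(rosters.items()):
        if res_island not in measured:
            continue
        depth = frequency_weighted_mean_depth(residents["capture_depth_m"])
        wl, ir = interpolate_spectrum(spectra, res_island, depth)
        group_totals: dict[str, list[float]] = {}
        for (src_island, src_colour), roster in sorted(rosters.items()):
            if src_colour != colour:
                continue
            totals = []
            for _, row in roster.iterrows():
                profile = {o: row[o] for o in OPSINS}
                qc = quantum_catch(
                    profile,
                    lws_lambda_max(row["genotype"], registry),
                    wl,
                    ir,
                    registry,
                    fish_id=row["fish_id"],
                    island=res_island,
                    depth_m=depth,
                    genotype=row["genotype"],
                )
                totals.append(qc.total)
                per_fish_rows.append(
                    {
                        "resident_island": res_island,
                        "colour": colour,
                        "source_island": src_island,
                        "fish_id": row["fish_id"],
                        "evaluation_depth_m": depth,
                        "genotype": row["genotype"],
                        **{f"Qc_{o}": qc.per_opsin.get(o, np.nan) for o in OPSINS},
                        "Qc_total": qc.total,
                    }
                )
            totals = np.asarray(totals)
            group_totals[src_island] = totals
            summary_rows.append(
                {
                    "resident_island": res_island,
                    "colour": colour,
                    "source_island": src_island,
                    "group": "resident" if src_island == res_island else "immigrant",
                    "n": len(totals),
                    "mean_Qc_total": float(totals.mean()),
                    "se_Qc_total": (
                        float(totals.std(ddof=1) / np.sqrt(len(totals)))
                        if len(totals) > 1
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(per_fish_rows), pd.DataFrame(summary_rows)
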