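"""Synthetic study inputs with known ground truth.

Everything the pipeline consumes can be generated here: depth-resolved
irradiance spectra along a turbidity transect, qPCR plates with known
template amounts and efficiencies, amplicon sequences realising any LWS
genotype in either dialect and strand, and whole-study scenario bundles.

The light model is a surface spectrum attenuated exponentially with depth,
``I(lambda, z) = I0(lambda) * exp(-K(lambda) * z)`` with ``K(lambda) =
k_base + k_turb * exp(-(lambda - 400) / tau)``: short wavelengths attenuate
faster, and faster still in turbid water, so the orange ratio rises with
depth at every island and is ordered Luanso > Kissenda ~ Python > Anchor >
Makobe at any fixed depth.

Amplification curves use a saturating exponential ``F(c) = plateau * u /
(1 + u**s)**(1/s)`` with ``u = (N0 / plateau) * E**c``, which matches
``N0 * E**c`` in the early phase and bends into the plateau over roughly
one cycle for the default knee sharpness ``s = 4`` (real qPCR traces hold
log-linearity over several decades; a plain logistic knee, s = 1, bends a
full decade below the plateau and distorts the fitting window).

Two end-to-end scenario modes exist: "adaptive", where each population's
expression profile maximises its own quantum catch at its local depth (so
residents must beat immigrants by construction), and "decoupled", where
expression is drawn independently of island (so no systematic resident
advantage exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import light_env, visual_model
from .io_formats import CONSTRUCT, OPSINS, FastaRecord, write_fasta
from .lws_genotyping import ALLELE_CODONS, DIAGNOSTIC_SITES, REFERENCE, _PAIRS

__all__ = [
    "IslandLightParams",
    "DEFAULT_LIGHT_PARAMS",
    "MEASUREMENT_DATES",
    "generate_irradiance",
    "generate_plate",
    "generate_sequence",
    "PopulationSpec",
    "ScenarioConfig",
    "ScenarioBundle",
    "generate_scenario",
    "write_bundle",
]

log = logging.getLogger("pundavision.synth")


# --------------------------------------------------------------------------
# irradiance


@dataclass(frozen=True)
class IslandLightParams:
    """Attenuation parameters for one island.

    ``k_turb`` (per metre) scales the short-wavelength excess attenuation
    caused by suspended and dissolved matter; ``tau`` (nm) is its spectral
    decay scale; ``k_red`` and ``red_tau`` describe the long-wavelength
    absorption of water itself (the same at every island); ``k_base`` (per
    metre) is the wavelength-independent floor; ``depth_max`` (m) is how
    deep usable spectra were collected.  Turbidity must dominate the red
    absorption (k_turb well above ~0.1) for the orange ratio to rise with
    depth, as observed throughout the study region.
    """

    k_base: float = 0.08
    k_turb: float = 0.3
    tau: float = 100.0
    k_red: float = 0.15
    red_tau: float = 57.0
    depth_max: float = 6.0


#: Turbidity transect ordering: Luanso (Secchi ~0.5 m) down to Makobe (clear).
DEFAULT_LIGHT_PARAMS: dict[str, IslandLightParams] = {
    "Luanso": IslandLightParams(k_turb=0.55, depth_max=4.0),
    "Kissenda": IslandLightParams(k_turb=0.35, depth_max=6.0),
    "Python": IslandLightParams(k_turb=0.33, depth_max=6.0),
    "Anchor": IslandLightParams(k_turb=0.22, depth_max=6.0),
    "Makobe": IslandLightParams(k_turb=0.15, depth_max=8.0),
}

#: Islands with field spectra and their sampling-day counts; Anchor was
#: never measured.
MEASUREMENT_DATES: dict[str, int] = {
    "Luanso": 2,
    "Kissenda": 3,
    "Python": 4,
    "Makobe": 4,
}


def surface_irradiance(wavelength: np.ndarray) -> np.ndarray:
    """Broad daylight-like surface spectrum (µmol m-2 s-1 per nm)."""
    wl = np.asarray(wavelength, dtype=float)
    return 60.0 + 40.0 * np.exp(-(((wl - 550.0) / 120.0) ** 2))


def attenuation(params: IslandLightParams, wavelength: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelength, dtype=float)
    return (
        params.k_base
        + params.k_turb * np.exp(-(wl - 400.0) / params.tau)
        + params.k_red * np.exp((wl - 700.0) / params.red_tau)
    )


def model_spectrum(
    params: IslandLightParams, depth_m: float, wavelength: np.ndarray
) -> np.ndarray:
    """Noiseless model irradiance at one depth."""
    return surface_irradiance(wavelength) * np.exp(-attenuation(params, wavelength) * depth_m)


def generate_irradiance(
    islands: Mapping[str, IslandLightParams] | None = None,
    *,
    dates: Mapping[str, int] | None = None,
    depths: Sequence[float] | None = None,
    wavelength: np.ndarray | None = None,
    replicates: int = 2,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Field-style spectrum table: replicated scans on several days.

    Depths default to a 0.5 m grid from 0.5 m down to each island's
    ``depth_max``; noise is multiplicative lognormal per scan.
    """
    if islands is None:
        islands = {k: DEFAULT_LIGHT_PARAMS[k] for k in MEASUREMENT_DATES}
    if dates is None:
        dates = MEASUREMENT_DATES
    if wavelength is None:
        wavelength = np.arange(400.0, 701.0)
    rng = np.random.default_rng(seed)
    rows = []
    for island in sorted(islands):
        params = islands[island]
        island_depths = (
            depths
            if depths is not None
            else np.arange(0.5, params.depth_max + 1e-9, 0.5)
        )
        n_dates = dates.get(island, 2)
        for d in range(n_dates):
            date = f"2010-0{5 + d // 28}-{(d * 7) % 28 + 1:02d}"
            for depth in island_depths:
                clean = model_spectrum(params, float(depth), wavelength)
                for rep in range(1, replicates + 1):
                    noisy = clean
                    if noise_sigma > 0:
                        noisy = clean * np.exp(
                            rng.normal(0.0, noise_sigma, size=len(wavelength))
                        )
                    rows.append(
                        pd.DataFrame(
                            {
                                "island": island,
                                "date": date,
                                "depth_m": float(depth),
                                "replicate": rep,
                                "wavelength_nm": wavelength,
                                "irradiance": noisy,
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# qPCR plates


def amplification_curve(
    n0: float,
    efficiency: float,
    cycles: int,
    *,
    plateau: float = 1.0,
    baseline: float = 0.01,
    knee_sharpness: float = 4.0,
) -> np.ndarray:
    """Saturating-exponential fluorescence trace over cycles 1..C."""
    c = np.arange(1, cycles + 1, dtype=float)
    u = (n0 / plateau) * efficiency ** c
    s = knee_sharpness
    signal = plateau * u / (1.0 + u ** s) ** (1.0 / s)
    return baseline + signal


def generate_plate(
    samples: Mapping[str, Mapping[str, float]],
    *,
    efficiency: float = 2.0,
    cycles: int = 50,
    noise_sigma: float = 0.0,
    baseline: float = 0.01,
    baseline_noise: float = 1e-4,
    plateau: float = 1.0,
    knee_sharpness: float = 4.0,
    construct_log10: Sequence[float] = (-5.0, -6.0, -7.0, -8.0, -9.0, -10.0),
    failures: Mapping[tuple[str, str], str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One qPCR plate in long format, plus its ground-truth table.

    ``samples`` maps sample id to per-opsin initial template amounts N0 (in
    fluorescence units, i.e. the construct's 10**dilution_log10_conc scale).
    Each sample x opsin is run in duplicate; the construct series is run in
    duplicate at each dilution.  ``failures`` injects labelled QC failures:
    ``"efficiency"`` degrades both wells' amplification factor to 0.75 E
    (1.5 for perfect doubling, i.e. ~50% efficiency, far outside the 75-125%
    band), ``"ct_sd"`` advances the second replicate by 1.5 cycles.
    Identical seeds give byte-identical plates.
    """
    failures = dict(failures or {})
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    well_no = 0

    def emit(sample_id: str, opsin: str, n0: float, eff: float,
             dilution: float | None) -> None:
        nonlocal well_no
        well_no += 1
        well = f"W{well_no:03d}"
        f = amplification_curve(
            n0, eff, cycles,
            plateau=plateau, baseline=0.0, knee_sharpness=knee_sharpness,
        )
        if noise_sigma > 0:
            f = f * np.exp(rng.normal(0.0, noise_sigma, size=cycles))
        base = np.full(cycles, baseline)
        if noise_sigma > 0 and baseline_noise > 0:
            base = base + rng.normal(0.0, baseline_noise, size=cycles)
        f = np.maximum(f + base, 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "well_id": well,
                    "sample_id": sample_id,
                    "opsin": opsin,
                    "dilution_log10_conc": np.nan if dilution is None else dilution,
                    "cycle": np.arange(1, cycles + 1),
                    "fluorescence": f,
                }
            )
        )

    for x in construct_log10:
        for _ in range(2):
            emit(CONSTRUCT, CONSTRUCT, 10.0 ** x, efficiency, float(x))

    for sample_id in samples:
        n0s = samples[sample_id]
        total = sum(n0s.values())
        for opsin in OPSINS:
            if opsin not in n0s:
                continue
            n0 = float(n0s[opsin])
            mode = failures.get((sample_id, opsin))
            eff = efficiency * 0.75 if mode == "efficiency" else efficiency
            emit(sample_id, opsin, n0, eff, None)
            n0_rep2 = n0 * efficiency ** 1.5 if mode == "ct_sd" else n0
            emit(sample_id, opsin, n0_rep2, eff, None)
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "opsin": opsin,
                    "true_n0": n0,
                    "true_fraction": n0 / total,
                    "injected_failure": mode or "",
                }
            )
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# sequences

_IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _het_codon(codon_a: str, codon_b: str) -> str:
    out = []
    for x, y in zip(codon_a, codon_b):
        out.append(x if x == y else _IUPAC_PAIR[frozenset({x, y})])
    return "".join(out)


def generate_sequence(
    genotype: str, dialect: str = "gdna", strand: str = "+"
) -> str:
    """Amplicon sequence realising a genotype; heterozygous differing
    positions become IUPAC ambiguity codes (Sanger double peaks)."""
    a, b = _PAIRS[genotype]
    seq = list(REFERENCE.sequence(dialect))
    for site in DIAGNOSTIC_SITES:
        codon = _het_codon(ALLELE_CODONS[a][site], ALLELE_CODONS[b][site])
        off = REFERENCE.codon_offset(site, dialect)
        seq[off:off + 3] = list(codon)
    out = "".join(seq)
    if strand == "-":
        out = out.translate(_COMPLEMENT)[::-1]
    return out


# --------------------------------------------------------------------------
# whole-study scenarios


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling design for one island x colour population."""

    island: str
    phenotype: str
    n: int
    depth_mean: float  # m, truncated-normal centre
    depth_sd: float
    genotype_probs: dict  # genotype label -> probability


def _default_populations() -> tuple[PopulationSpec, ...]:
    # Sample sizes follow the field collection (Luanso 29, Kissenda 28,
    # Python 22, Anchor 11, Makobe 22); blue fish shallow (~1-2 m), red
    # deeper, overlapping at Luanso; genotype frequencies mirror the
    # observed pattern (blue ~PP, red ~HH where differentiated, all PP at
    # Luanso, M3 instead of H in Anchor reds).
    return (
        PopulationSpec("Luanso", "blue", 12, 1.5, 0.7, {"PP": 1.0}),
        PopulationSpec("Luanso", "intermediate", 5, 2.0, 0.8, {"PP": 1.0}),
        PopulationSpec("Luanso", "red", 12, 2.8, 1.2, {"PP": 1.0}),
        PopulationSpec("Kissenda", "blue", 14, 1.3, 0.6,
                       {"PP": 0.72, "HP": 0.21, "HH": 0.07}),
        PopulationSpec("Kissenda", "red", 14, 3.0, 1.2,
                       {"HH": 0.72, "HP": 0.18, "PP": 0.10}),
        PopulationSpec("Python", "blue", 11, 1.3, 0.6, {"PP": 0.8, "HP": 0.2}),
        PopulationSpec("Python", "red", 11, 3.0, 1.2, {"HH": 1.0}),
        PopulationSpec("Anchor", "blue", 6, 1.2, 0.5, {"PP": 1.0}),
        PopulationSpec("Anchor", "red", 5, 2.5, 1.0,
                       {"PP": 0.5, "M3M3": 0.4, "P-M3": 0.1}),
        PopulationSpec("Makobe", "blue", 11, 1.5, 0.7, {"PP": 0.95, "HP": 0.05}),
        PopulationSpec("Makobe", "red", 11, 5.0, 1.5, {"HH": 0.9, "HP": 0.1}),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a full synthetic data bundle.

    ``adaptive`` mode gives each population the expression profile that
    maximises total quantum catch at the population's own depth in its own
    light (floored simplex grid, step 0.05) and no individual scatter, so
    local superiority holds by construction.  ``decoupled`` mode gives every
    fish a logistic-normal jitter around one shared profile, independent of
    island.
    """

    mode: str = "decoupled"
    seed: int = 0
    populations: tuple[PopulationSpec, ...] = field(default_factory=_default_populations)
    base_profile: dict = field(
        default_factory=lambda: {"SWS2b": 0.02, "SWS2a": 0.08, "RH2A": 0.14, "LWS": 0.76}
    )
    expression_sigma: float = 0.08  # logistic-normal jitter (decoupled only)
    profile_floor: float = 0.05  # minimum per-opsin fraction (adaptive grid)
    grid_step: float = 0.05
    spectra_noise: float = 0.0
    plate_efficiency: float = 2.0
    plate_noise: float = 0.0
    total_n0_log10_mean: float = -7.0
    total_n0_log10_sd: float = 0.3
    min_depth: float = 0.5


@dataclass
class ScenarioBundle:
    """Generated inputs plus ground truth for recovery tests."""

    config: ScenarioConfig
    metadata: pd.DataFrame  # fish_id, island, phenotype, capture_depth_m
    spectra: pd.DataFrame
    plates: dict  # island -> plate DataFrame
    plate_truth: dict  # island -> truth DataFrame
    sequences: list  # FastaRecord
    true_expression: pd.DataFrame  # fish_id x opsin fractions
    true_genotypes: pd.DataFrame  # fish_id, dialect(s), genotype
    population_profiles: pd.DataFrame


def _truncated_normal(rng, mean, sd, low, size):
    out = np.empty(size)
    for i in range(size):
        v = rng.normal(mean, sd)
        while v < low:
            v = rng.normal(mean, sd)
        out[i] = v
    return np.round(out, 2)


def _simplex_grid(step: float, floor: float) -> np.ndarray:
    """All 4-part compositions with parts >= floor on a ``step`` lattice."""
    k = int(round((1.0 - 4 * floor) / step))
    grid = []
    for i in range(k + 1):
        for j in range(k - i + 1):
            for l in range(k - i - j + 1):
                m = k - i - j - l
                grid.append((i, j, l, m))
    return floor + step * np.asarray(grid, dtype=float)


def _optimal_profile(
    spectra: pd.DataFrame,
    params: IslandLightParams,
    island: str,
    depth: float,
    lws_lmax: float,
    cfg: ScenarioConfig,
) -> dict:
    """Grid-search the floored simplex for the max-Qc profile at a depth.

    Uses the same spectrum construction the transplant evaluation uses
    (aggregated table + depth interpolation) when the island was measured,
    and the noiseless light model otherwise (Anchor).
    """
    if island in set(spectra["island"]):
        wl, ir = visual_model.interpolate_spectrum(spectra, island, depth)
    else:
        wl = np.arange(400.0, 701.0)
        ir = model_spectrum(params, depth, wl)
    ir = ir / np.trapezoid(ir, wl)
    catch = np.array([
        np.trapezoid(
            ir * visual_model.pigment_absorbance(
                wl,
                lws_lmax if opsin == "LWS"
                else visual_model.DEFAULT_REGISTRY.lambda_max[opsin],
            ),
            wl,
        )
        for opsin in OPSINS
    ])
    grid = _simplex_grid(cfg.grid_step, cfg.profile_floor)
    best = grid[np.argmax(grid @ catch)]
    return dict(zip(OPSINS, best))


_POP_CODE = {"blue": "B", "intermediate": "I", "red": "R"}


def generate_scenario(config: ScenarioConfig | None = None) -> ScenarioBundle:
    """Generate a full input bundle with ground truth.

    A single master seed fans out (via ``numpy.random.SeedSequence.spawn``)
    to independent child streams for depths/genotypes, spectra, expression
    and plates, so each component is reproducible on its own.
    """
    cfg = config or ScenarioConfig()
    if cfg.mode not in ("adaptive", "decoupled"):
        raise ValueError(f"unknown scenario mode {cfg.mode!r}")
    ss = np.random.SeedSequence(cfg.seed)
    s_meta, s_spectra, s_expr, s_plates = ss.spawn(4)
    rng_meta = np.random.default_rng(s_meta)
    rng_expr = np.random.default_rng(s_expr)

    spectra = generate_irradiance(noise_sigma=cfg.spectra_noise, seed=s_spectra)
    agg = light_env.aggregate_spectra(spectra)

    meta_rows = []
    geno_rows = []
    for pop in cfg.populations:
        depths = _truncated_normal(rng_meta, pop.depth_mean, pop.depth_sd,
                                   cfg.min_depth, pop.n)
        labels = sorted(pop.genotype_probs)
        probs = np.array([pop.genotype_probs[l] for l in labels])
        genos = rng_meta.choice(labels, size=pop.n, p=probs / probs.sum())
        code = f"{pop.island[:2].upper()}-{_POP_CODE[pop.phenotype]}"
        for i in range(pop.n):
            fish_id = f"{code}-{i + 1:02d}"
            meta_rows.append(
                {"fish_id": fish_id, "island": pop.island,
                 "phenotype": pop.phenotype, "capture_depth_m": depths[i]}
            )
            geno_rows.append({"fish_id": fish_id, "genotype": genos[i]})
    metadata = pd.DataFrame(meta_rows)
    genotypes = pd.DataFrame(geno_rows)
    merged = metadata.merge(genotypes, on="fish_id")

    profile_rows = []
    pop_profiles: dict[tuple[str, str], dict] = {}
    if cfg.mode == "adaptive":
        for pop in cfg.populations:
            sub = merged[(merged["island"] == pop.island)
                         & (merged["phenotype"] == pop.phenotype)]
            canonical = visual_model.CANONICAL_GENOTYPE.get(pop.phenotype)
            roster = sub[sub["genotype"] == canonical] if canonical else sub
            if roster.empty:
                roster = sub
            depth = float(roster["capture_depth_m"].mean())
            modal = roster["genotype"].mode().iloc[0]
            lmax = visual_model.lws_lambda_max(modal)
            profile = _optimal_profile(
                agg, DEFAULT_LIGHT_PARAMS[pop.island], pop.island, depth, lmax, cfg
            )
            pop_profiles[(pop.island, pop.phenotype)] = profile
            profile_rows.append(
                {"island": pop.island, "phenotype": pop.phenotype,
                 "optimised_depth_m": depth, "lws_lambda_max": lmax, **profile}
            )
    else:
        for pop in cfg.populations:
            pop_profiles[(pop.island, pop.phenotype)] = dict(cfg.base_profile)
            profile_rows.append(
                {"island": pop.island, "phenotype": pop.phenotype,
                 "optimised_depth_m": np.nan, "lws_lambda_max": np.nan,
                 **cfg.base_profile}
            )

    expr_rows = []
    for _, row in merged.iterrows():
        base = pop_profiles[(row["island"], row["phenotype"])]
        w = np.array([base[o] for o in OPSINS])
        if cfg.mode == "decoupled" and cfg.expression_sigma > 0:
            w = w * np.exp(rng_expr.normal(0.0, cfg.expression_sigma, size=len(OPSINS)))
        w = w / w.sum()
        expr_rows.append({"fish_id": row["fish_id"], **dict(zip(OPSINS, w))})
    true_expression = pd.DataFrame(expr_rows)

    plates = {}
    plate_truth = {}
    plate_children = s_plates.spawn(len(metadata["island"].unique()))
    for child, island in zip(plate_children, sorted(metadata["island"].unique())):
        rng_n0 = np.random.default_rng(child)
        fish_ids = metadata.loc[metadata["island"] == island, "fish_id"]
        samples = {}
        for fish_id in fish_ids:
            total = 10.0 ** rng_n0.normal(cfg.total_n0_log10_mean,
                                          cfg.total_n0_log10_sd)
            frac = true_expression.set_index("fish_id").loc[fish_id, list(OPSINS)]
            samples[fish_id] = {o: total * float(frac[o]) for o in OPSINS}
        plate, truth = generate_plate(
            samples,
            efficiency=cfg.plate_efficiency,
            noise_sigma=cfg.plate_noise,
            seed=int(rng_n0.integers(2 ** 31)),
        )
        plates[island] = plate
        plate_truth[island] = truth

    sequences = []
    true_geno_rows = []
    for i, row in merged.iterrows():
        strand = "-" if i % 7 == 3 else "+"
        sequences.append(
            FastaRecord(row["fish_id"],
                        generate_sequence(row["genotype"], "gdna", strand), "gdna")
        )
        true_geno_rows.append(
            {"fish_id": row["fish_id"], "dialect": "gdna",
             "genotype": row["genotype"]}
        )
        if i % 5 == 0:
            sequences.append(
                FastaRecord(f"{row['fish_id']}|cdna",
                            generate_sequence(row["genotype"], "cdna", "+"), "cdna")
            )
            true_geno_rows.append(
                {"fish_id": row["fish_id"], "dialect": "cdna",
                 "genotype": row["genotype"]}
            )

    return ScenarioBundle(
        config=cfg,
        metadata=metadata,
        spectra=spectra,
        plates=plates,
        plate_truth=plate_truth,
        sequences=sequences,
        true_expression=true_expression,
        true_genotypes=pd.DataFrame(true_geno_rows),
        population_profiles=pd.DataFrame(profile_rows),
    )


def write_bundle(bundle: ScenarioBundle, outdir: str | Path) -> None:
    """Write a bundle as the directory tree the CLI pipeline consumes."""
    outdir = Path(outdir)
    (outdir / "plates").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    bundle.metadata.to_csv(outdir / "metadata.csv", index=False)
    bundle.spectra.to_csv(outdir / "spectra.csv", index=False)
    for island, plate in bundle.plates.items():
        plate.to_csv(outdir / "plates" / f"{island}.csv", index=False)
        bundle.plate_truth[island].to_csv(
            outdir / "truth" / f"plate_{island}.tsv", sep="\t", index=False
        )
    write_fasta(bundle.sequences, outdir / "sequences.fasta")
    bundle.true_expression.to_csv(outdir / "truth" / "expression.tsv",
                                  sep="\t", index=False)
    bundle.true_genotypes.to_csv(outdir / "truth" / "genotypes.tsv",
                                 sep="\t", index=False)
    bundle.population_profiles.to_csv(outdir / "truth" / "profiles.tsv",
                                      sep="\t", index=False)
    cfg = bundle.config
    snapshot = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "expression_sigma": cfg.expression_sigma,
        "spectra_noise": cfg.spectra_noise,
        "plate_efficiency": cfg.plate_efficiency,
        "plate_noise": cfg.plate_noise,
    }
    (outdir / "scenario.yaml").write_text(yaml.safe_dump(snapshot))
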