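"""Readers and writers for the pipeline's external file formats.

Every other module consumes the validated tables and records produced here.
All readers reject malformed input rather than silently coercing it; the one
deliberate exception is negative irradiance, which is clamped to zero with a
logged count (spectrometer noise near the detection limit routinely dips
below zero).

Conventions: CSV is comma-separated UTF-8 with ``.`` decimals and ISO-8601
dates; depths are metres (positive downward); wavelengths are nanometres.
Unknown extra columns are ignored with a log line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ISLANDS",
    "PHENOTYPES",
    "OPSINS",
    "CONSTRUCT",
    "FormatError",
    "FishRecord",
    "FastaRecord",
    "read_fish_metadata",
    "read_spectra",
    "read_plate",
    "read_fasta",
    "write_fasta",
    "write_table",
    "read_table",
]

log = logging.getLogger("pundavision.io")

#: Closed vocabulary of sampling locations (the turbidity transect, south to
#: north: Luanso is the most turbid, Makobe the clearest).
ISLANDS = ("Anchor", "Kissenda", "Luanso", "Makobe", "Python")

#: Male colour classes; intermediates occur in appreciable numbers only at
#: Luanso, where the blue and red forms are not genetically differentiated.
PHENOTYPES = ("blue", "intermediate", "red")

#: Cone opsin genes quantified by qPCR, short- to long-wavelength sensitive.
OPSINS = ("SWS2b", "SWS2a", "RH2A", "LWS")

#: Plate rows belonging to the serially diluted calibration construct.
CONSTRUCT = "construct"

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """An input file violates its schema or an invariant."""


@dataclass(frozen=True)
class FishRecord:
    """One sampled male: identity, location, colour class, capture depth."""

    fish_id: str
    island: str
    phenotype: str
    capture_depth_m: float

    def __post_init__(self) -> None:
        if self.island not in ISLANDS:
            raise FormatError(
                f"unknown island {self.island!r}; allowed: {', '.join(ISLANDS)}"
            )
        if self.phenotype not in PHENOTYPES:
            raise FormatError(
                f"unknown phenotype {self.phenotype!r}; allowed: {', '.join(PHENOTYPES)}"
            )
        depth = self.capture_depth_m
        if not np.isfinite(depth) or depth <= 0:
            raise FormatError(f"capture depth must be finite and > 0, got {depth!r}")


@dataclass(frozen=True)
class FastaRecord:
    """A base-called amplicon sequence with its gDNA/cDNA dialect flag."""

    seq_id: str
    bases: str
    dialect: str  # "gdna" (intron-containing) or "cdna"


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.info("%s: ignoring extra column(s): %s", path, ", ".join(extra))
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def read_fish_metadata(path: str | Path) -> list[FishRecord]:
    """Read fish metadata CSV (fish_id,island,phenotype,capture_depth_m)."""
    df = _read_csv(path, ["fish_id", "island", "phenotype", "capture_depth_m"])
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            depth = float(row["capture_depth_m"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: line {line}: non-numeric capture_depth_m "
                f"{row['capture_depth_m']!r}"
            ) from None
        try:
            records.append(
                FishRecord(str(row["fish_id"]), str(row["island"]),
                           str(row["phenotype"]), depth)
            )
        except FormatError as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from None
    return records


def read_spectra(path: str | Path) -> pd.DataFrame:
    """Read an irradiance spectrum table.

    Expected columns: island,date,depth_m,wavelength_nm,irradiance and an
    optional ``replicate`` column distinguishing repeat scans within one
    (island, date, depth) series.  Returns a table sorted by group and
    wavelength; negative irradiance is clamped to 0 and the count recorded in
    ``df.attrs["n_clamped"]``.
    """
    df = _read_csv(path, ["island", "date", "depth_m", "wavelength_nm", "irradiance"])
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)
    bad = set(df["island"]) - set(ISLANDS)
    if bad:
        raise FormatError(f"{path}: unknown island(s): {', '.join(sorted(map(str, bad)))}")
    keys = ["island", "date", "depth_m", "replicate"]
    dup = df.duplicated(subset=keys + ["wavelength_nm"])
    if dup.any():
        first = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate wavelength {first['wavelength_nm']} in group "
            f"{tuple(first[k] for k in keys)}"
        )
    neg = df["irradiance"] < 0
    n_clamped = int(neg.sum())
    if n_clamped:
        log.warning("%s: clamped %d negative irradiance value(s) to 0", path, n_clamped)
        df.loc[neg, "irradiance"] = 0.0
    df = df.sort_values(keys + ["wavelength_nm"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_clamped"] = n_clamped
    return df


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a long-format qPCR plate table.

    Columns: well_id,sample_id,opsin,dilution_log10_conc,cycle,fluorescence.
    Every well must carry a complete cycle series 1..C (C = plate-wide
    maximum); construct wells must carry a dilution; sample wells are
    expected in duplicate (a warning, not an error — the duplicate QC stage
    fails singletons explicitly).
    """
    df = _read_csv(
        path,
        ["well_id", "sample_id", "opsin", "dilution_log10_conc", "cycle", "fluorescence"],
    )
    allowed = set(OPSINS) | {CONSTRUCT}
    bad = set(df["opsin"]) - allowed
    if bad:
        raise FormatError(f"{path}: unknown opsin label(s): {', '.join(sorted(map(str, bad)))}")
    if (df["fluorescence"] < 0).any():
        well = df.loc[df["fluorescence"] < 0, "well_id"].iloc[0]
        raise FormatError(f"{path}: negative fluorescence in well {well}")
    n_cycles = int(df["cycle"].max())
    expected = np.arange(1, n_cycles + 1)
    for well, grp in df.groupby("well_id", sort=False):
        cyc = np.sort(grp["cycle"].to_numpy())
        if len(cyc) != n_cycles or not np.array_equal(cyc, expected):
            raise FormatError(
                f"{path}: well {well} has an incomplete cycle series "
                f"({len(cyc)} of {n_cycles} cycles)"
            )
    construct = df["opsin"] == CONSTRUCT
    if construct.any() and df.loc[construct, "dilution_log10_conc"].isna().any():
        raise FormatError(f"{path}: construct rows without dilution_log10_conc")
    reps = (
        df.loc[~construct, ["well_id", "sample_id", "opsin"]]
        .drop_duplicates()
        .groupby(["sample_id", "opsin"])
        .size()
    )
    odd = reps[reps != 2]
    if not odd.empty:
        log.warning(
            "%s: %d sample×opsin group(s) without exactly 2 replicate wells",
            path, len(odd),
        )
    return df.sort_values(["well_id", "cycle"], kind="mergesort").reset_index(drop=True)


def _parse_dialect(description: str) -> str:
    for token in description.split():
        if token.startswith("dialect="):
            value = token.split("=", 1)[1].lower()
            if value not in ("gdna", "cdna"):
                raise FormatError(f"unknown dialect {value!r} (expected gdna or cdna)")
            return value
    return "gdna"


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA; IUPAC nucleotide alphabet, dialect token in the header."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq).upper()
        for pos, base in enumerate(bases):
            if base not in IUPAC_NUCLEOTIDES:
                raise FormatError(
                    f"{path}: sequence {rec.id}: non-IUPAC character {base!r} "
                    f"at position {pos + 1}"
                )
        records.append(FastaRecord(rec.id, bases, _parse_dialect(rec.description)))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.bases), id=r.seq_id, description=f"dialect={r.dialect}")
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def write_table(df: pd.DataFrame, path: str | Path, *,
                version: str | None = None, config_hash: str | None = None) -> None:
    """Write a TSV with a header comment recording provenance.

    Numeric round-trip through :func:`read_table` is exact to the float repr
    (well inside 1e-12).
    """
    if version is None:
        from pundavision import __version__ as version
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pundavision={version} config={config_hash or 'none'}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
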