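"""LWS allele calling from exon-4/5 amplicon sequences.

Pundamilia carries three LWS alleles distinguished by the amino acids at
residues 216, 230 and 275: H (216Y, 230A, 275C; red-shifted), P (216F, 230T,
275I; blue-shifted) and the recombinant M3 (216Y, 230T, 275I).  Sanger
sequencing of heterozygotes shows double peaks at the differing nucleotide
positions, base-called as IUPAC ambiguity codes; a genotype is called by
matching the observed per-site amino-acid possibilities against the residue
union of each of the six unordered allele pairs.  The six unions are pairwise
distinct, so a match is unique whenever one exists; anything else is reported
as inconsistent rather than guessed.

The true Pundamilia LWS sequence is not bundled; the module ships a SYNTHETIC
reference amplicon that obeys every published structural constraint — the
printed primer pair, a 498 bp genomic amplicon containing a 91 bp intron
(407 bp in the cDNA dialect), and in-frame diagnostic codons at residues
216/230/275 — with stand-in codon choices (216 Y=TAT/F=TTT, 230 A=GCA/T=ACA,
275 C=TGC/I=ATC).  Real-data users can anchor on their own reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "DIAGNOSTIC_SITES",
    "ALLELES",
    "ALLELE_RESIDUES",
    "ALLELE_CODONS",
    "GENOTYPES",
    "AmpliconReference",
    "REFERENCE",
    "DiagnosticEvidence",
    "LwsGenotype",
    "GenotypeError",
    "locate_diagnostic_codons",
    "call_genotype",
    "genotype_sequence",
    "genotype_frequencies",
    "gdna_cdna_concordance",
]

log = logging.getLogger("pundavision.lws")

FORWARD_PRIMER = "GTTTGGTGTGCTCCTCCCAT"
REVERSE_PRIMER = "CAGAGCCATCGTCCACCTGT"

DIAGNOSTIC_SITES = (216, 230, 275)
ALLELES = ("H", "P", "M3")

ALLELE_RESIDUES = {
    "H": {216: "Y", 230: "A", 275: "C"},
    "P": {216: "F", 230: "T", 275: "I"},
    "M3": {216: "Y", 230: "T", 275: "I"},
}

#: Stand-in nucleotide codons realising the published amino acids.
ALLELE_CODONS = {
    "H": {216: "TAT", 230: "GCA", 275: "TGC"},
    "P": {216: "TTT", 230: "ACA", 275: "ATC"},
    "M3": {216: "TAT", 230: "ACA", 275: "ATC"},
}

#: Residues that can legitimately occur at each site across the three alleles.
SITE_RESIDUES = {
    216: frozenset("YF"),
    230: frozenset("AT"),
    275: frozenset("CI"),
}

#: The six unordered allele pairs in canonical order.
GENOTYPES = ("HH", "PP", "M3M3", "HP", "H-M3", "P-M3")

_PAIRS: dict[str, tuple[str, str]] = {
    "HH": ("H", "H"),
    "PP": ("P", "P"),
    "M3M3": ("M3", "M3"),
    "HP": ("H", "P"),
    "H-M3": ("H", "M3"),
    "P-M3": ("P", "M3"),
}


class GenotypeError(RuntimeError):
    pass


@dataclass(frozen=True)
class AmpliconReference:
    """Synthetic exon-4/intron/exon-5 amplicon and its codon coordinates."""

    exon4: str  # starts with the forward primer site
    intron: str
    exon5: str  # ends with the reverse-complemented reverse primer site
    first_residue: int  # protein residue encoded by the first exonic codon

    @property
    def gdna(self) -> str:
        return self.exon4 + self.intron + self.exon5

    @property
    def cdna(self) -> str:
        return self.exon4 + self.exon5

    def sequence(self, dialect: str) -> str:
        if dialect == "gdna":
            return self.gdna
        if dialect == "cdna":
            return self.cdna
        raise ValueError(f"unknown dialect {dialect!r}")

    def codon_offset(self, residue: int, dialect: str) -> int:
        """0-based offset of a residue's codon from the amplicon start."""
        exonic = 3 * (residue - self.first_residue)
        if exonic < 0 or exonic + 3 > len(self.exon4) + len(self.exon5):
            raise ValueError(f"residue {residue} outside the amplicon")
        if dialect == "gdna" and exonic >= len(self.exon4):
            return exonic + len(self.intron)
        return exonic


def _build_reference() -> AmpliconReference:
    """Construct the bundled synthetic reference (deterministic).

    Exon 4 is 240 bp and holds residues 216 and 230; exon 5 is 167 bp and
    holds residue 275; the 91 bp intron (GT..AG) sits between them; the
    gDNA amplicon is 498 bp delimited inclusively by the primer pair.  The
    exonic frame is anchored so that residue 166 starts at the first base of
    the forward primer site.  Filler bases are drawn from a fixed-seed
    generator, with any accidental second primer occurrence resolved.
    """
    rng = np.random.RandomState(20190709)
    bases = "ACGT"

    def rand(n: int) -> list[str]:
        return [bases[i] for i in rng.randint(0, 4, size=n)]

    first_residue = 166
    exonic = rand(407)
    exonic[0:20] = list(FORWARD_PRIMER)
    rc_rev = str(Seq(REVERSE_PRIMER).reverse_complement())
    exonic[387:407] = list(rc_rev)
    for residue, codon in ALLELE_CODONS["H"].items():  # reference carries H
        off = 3 * (residue - first_residue)
        exonic[off:off + 3] = list(codon)
    intron = rand(91)
    intron[0:2] = ["G", "T"]
    intron[-2:] = ["A", "G"]

    ref = AmpliconReference(
        exon4="".join(exonic[:240]),
        intron="".join(intron),
        exon5="".join(exonic[240:]),
        first_residue=first_residue,
    )
    for dialect in ("gdna", "cdna"):
        seq = ref.sequence(dialect)
        assert seq.count(FORWARD_PRIMER) == 1
        assert seq.count(rc_rev) == 1
        assert str(Seq(seq).reverse_complement()).count(FORWARD_PRIMER) == 0
    assert len(ref.gdna) == 498 and len(ref.intron) == 91 and len(ref.cdna) == 407
    return ref


REFERENCE = _build_reference()


@dataclass(frozen=True)
class DiagnosticEvidence:
    """Possible amino acids at each diagnostic site after IUPAC expansion.

    Expansion of a heterozygous codon written with per-position IUPAC codes
    can produce amino acids no allele carries (the positionwise union of two
    codons contains extra codons); the evidence keeps only residues that
    some allele carries at that site.  An observed codon supporting none of
    them yields an empty set and an inconsistent call downstream.
    """

    residues: dict[int, frozenset[str]]

    def is_valid(self) -> bool:
        return all(self.residues.get(site) for site in DIAGNOSTIC_SITES)


@dataclass(frozen=True)
class LwsGenotype:
    """An unordered allele pair, or a non-call status."""

    alleles: tuple[str, str] | None
    status: str  # "ok", "inconsistent", "unanchored", "length mismatch"
    evidence: DiagnosticEvidence | None = None

    @property
    def label(self) -> str:
        if self.alleles is None:
            return self.status
        return _pair_label(self.alleles)


def _pair_label(pair: tuple[str, str]) -> str:
    a, b = sorted(pair, key=ALLELES.index)
    if a == b:
        return a + b
    return a + b if len(a) == len(b) == 1 else f"{a}-{b}"


def _expand_codon(codon: str) -> set[str]:
    """Amino acids reachable from an IUPAC-ambiguous codon."""
    choices = [ambiguous_dna_values[b] for b in codon]
    return {
        str(Seq("".join(c)).translate())
        for c in itertools.product(*choices)
    }


def _find_primer(seq: str, primer: str, max_mismatches: int) -> int:
    """Leftmost primer position allowing up to ``max_mismatches`` substitutions."""
    if max_mismatches <= 0:
        return seq.find(primer)
    for i in range(len(seq) - len(primer) + 1):
        mismatches = sum(a != b for a, b in zip(seq[i:i + len(primer)], primer))
        if mismatches <= max_mismatches:
            return i
    return -1


def locate_diagnostic_codons(
    seq: str,
    dialect: str = "gdna",
    reference: AmpliconReference = REFERENCE,
    *,
    max_primer_mismatches: int = 0,
) -> DiagnosticEvidence:
    """Extract and expand the three diagnostic codons from an amplicon.

    The sequence is anchored by an exact forward-primer match (the reverse
    complement is tried automatically); codons are read at fixed offsets
    from the anchor.  ``max_primer_mismatches`` relaxes anchoring for
    sequences with a miscalled base inside the primer site — determinism
    first, so the default is exact matching.  A sequence whose
    primer-delimited span differs in length from the reference raises a
    frame ("length mismatch") error.
    """
    seq = seq.upper()
    anchor = _find_primer(seq, FORWARD_PRIMER, max_primer_mismatches)
    if anchor < 0:
        seq = str(Seq(seq).reverse_complement())
        anchor = _find_primer(seq, FORWARD_PRIMER, max_primer_mismatches)
    if anchor < 0:
        raise GenotypeError("unanchored: forward primer not found in either orientation")
    ref_len = len(reference.sequence(dialect))
    rc_rev = str(Seq(REVERSE_PRIMER).reverse_complement())
    end = _find_primer(seq[anchor:], rc_rev, max_primer_mismatches)
    end = end + anchor if end >= 0 else -1
    if end < 0 or end + len(rc_rev) - anchor != ref_len:
        raise GenotypeError(
            f"length mismatch: primer-delimited span is not {ref_len} bp "
            f"({dialect} dialect)"
        )
    residues = {}
    for site in DIAGNOSTIC_SITES:
        off = anchor + reference.codon_offset(site, dialect)
        codon = seq[off:off + 3]
        observed = _expand_codon(codon)
        residues[site] = frozenset(observed) & SITE_RESIDUES[site]
    return DiagnosticEvidence(residues)


def call_genotype(evidence: DiagnosticEvidence) -> LwsGenotype:
    """Match evidence against the residue unions of all six allele pairs.

    A pair matches iff at every site the union of its two alleles' residues
    equals the observed set; heterozygous pairs therefore require ambiguity
    at exactly the sites where the two alleles differ.  The six union
    signatures are pairwise distinct, so at most one pair matches.
    """
    if not evidence.is_valid():
        return LwsGenotype(None, "inconsistent", evidence)
    matches = []
    for label, (a, b) in _PAIRS.items():
        if all(
            frozenset({ALLELE_RESIDUES[a][s], ALLELE_RESIDUES[b][s]})
            == evidence.residues[s]
            for s in DIAGNOSTIC_SITES
        ):
            matches.append((a, b))
    if not matches:
        return LwsGenotype(None, "inconsistent", evidence)
    assert len(matches) == 1, "allele-pair union signatures must be distinct"
    return LwsGenotype(matches[0], "ok", evidence)


def genotype_sequence(
    seq: str,
    dialect: str = "gdna",
    reference: AmpliconReference = REFERENCE,
    *,
    max_primer_mismatches: int = 0,
) -> LwsGenotype:
    """Anchor, extract and call in one step; anchoring failures become statuses."""
    try:
        evidence = locate_diagnostic_codons(
            seq, dialect, reference, max_primer_mismatches=max_primer_mismatches
        )
    except GenotypeError as exc:
        status = "unanchored" if "unanchored" in str(exc) else "length mismatch"
        return LwsGenotype(None, status, None)
    return call_genotype(evidence)


def genotype_frequencies(calls: pd.DataFrame) -> pd.DataFrame:
    """Allele counts and frequencies per island x phenotype group.

    ``calls`` needs columns island, phenotype and genotype (pair labels).
    Homozygotes contribute two copies of their allele, heterozygotes one of
    each; non-calls are skipped.  Empty groups are omitted.
    """
    rows = []
    for (island, phenotype), grp in calls.groupby(["island", "phenotype"]):
        counts = dict.fromkeys(ALLELES, 0)
        for label in grp["genotype"]:
            if label not in _PAIRS:
                continue
            for allele in _PAIRS[label]:
                counts[allele] += 1
        total = sum(counts.values())
        if total == 0:
            continue
        for allele in ALLELES:
            rows.append(
                {
                    "island": island,
                    "phenotype": phenotype,
                    "allele": allele,
                    "count": counts[allele],
                    "frequency": counts[allele] / total,
                }
            )
    return pd.DataFrame(rows)


def gdna_cdna_concordance(calls: pd.DataFrame) -> pd.DataFrame:
    """Flag fish whose gDNA and cDNA calls differ.

    ``calls`` needs columns fish_id, dialect and genotype.  Fish with only
    one dialect are skipped.
    """
    rows = []
    for fish_id, grp in calls.groupby("fish_id"):
        by_dialect = dict(zip(grp["dialect"], grp["genotype"]))
        if {"gdna", "cdna"} <= set(by_dialect):
            rows.append(
                {
                    "fish_id": fish_id,
                    "gdna": by_dialect["gdna"],
                    "cdna": by_dialect["cdna"],
                    "concordant": by_dialect["gdna"] == by_dialect["cdna"],
                }
            )
    return pd.DataFrame(rows)
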