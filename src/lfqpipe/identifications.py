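"""Peptide-spectrum-match parsing, filtering, and protein-level assembly.

A shotgun-proteomics search engine emits one peptide-spectrum match (PSM)
per assigned tandem spectrum, scored by an E-value (the expected number of
equal-or-better random matches).  This module turns a table of PSMs into a
confident protein list:

* discard PSMs whose E-value exceeds a threshold (default 0.05, strictly
  greater-than is discarded);
* group the survivors by protein accession and discard proteins supported
  by fewer than two *distinct* peptide sequences (the two-peptide rule);
* compute sequence coverage by marking every residue touched by any
  occurrence of any matched peptide;
* estimate a target-decoy false discovery rate by applying identical logic
  to matches against a randomized (decoy) database.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from pyteomics import fasta as _fasta

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: canonical column order of the PSM TSV dialect
PSM_COLUMNS = (
    "spectrum_id",
    "replicate_id",
    "condition_id",
    "scan_number",
    "precursor_mz",
    "peptide",
    "accession",
    "e_value",
)

DECOY_PREFIX = "DECOY_"


class PSMParseError(ValueError):
    """Raised when a PSM table is malformed (missing column, bad field)."""


@dataclass(frozen=True)
class PeptideSpectrumMatch:
    """One spectrum-to-peptide assignment.

    ``spectrum_id`` is opaque but unique within a replicate; ``scan_number``
    indexes into that replicate's MS1 chromatogram; ``precursor_mz`` is the
    reported precursor mass-to-charge in Th.
    """

    spectrum_id: str
    replicate_id: str
    condition_id: str
    scan_number: int
    precursor_mz: float
    peptide: str
    accession: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be > 0, got {self.precursor_mz}")
        if self.scan_number < 1:
            raise ValueError(f"scan_number must be >= 1, got {self.scan_number}")
        if not self.peptide or not set(self.peptide) <= AMINO_ACIDS:
            raise ValueError(f"peptide must be a nonempty standard-residue string, got {self.peptide!r}")


@dataclass
class ProteinIdentification:
    """A protein accession with its supporting peptide and spectrum evidence."""

    accession: str
    species: str
    sequence: str
    peptides: set[str] = field(default_factory=set)
    spectra: set[str] = field(default_factory=set)
    coverage_percent: float = 0.0
    is_decoy: bool = False
    psms: list[PeptideSpectrumMatch] = field(default_factory=list)


def parse_psm_table(path, dialect: str = "tsv", **kwargs) -> list[PeptideSpectrumMatch]:
    """Read a PSM table in the named dialect.

    ``tsv`` is the canonical exchange format (tab-separated, header row, one
    row per (PSM, accession) pair).  ``xtandem-xml`` maps an X!tandem output
    file onto the same record type; since X!tandem output carries no
    replicate/condition labels, pass ``replicate_id=`` and ``condition_id=``.
    """
    if dialect == "tsv":
        return _parse_psm_tsv(path)
    if dialect == "xtandem-xml":
        return _parse_xtandem(path, **kwargs)
    raise ValueError(f"unknown PSM dialect: {dialect!r}")


def _parse_psm_tsv(path) -> list[PeptideSpectrumMatch]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise PSMParseError(f"PSM table {path} is missing required column(s): {', '.join(missing)}")
    psms: list[PeptideSpectrumMatch] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            psms.append(
                PeptideSpectrumMatch(
                    spectrum_id=row.spectrum_id,
                    replicate_id=row.replicate_id,
                    condition_id=row.condition_id,
                    scan_number=int(row.scan_number),
                    precursor_mz=float(row.precursor_mz),
                    peptide=row.peptide,
                    accession=row.accession,
                    e_value=float(row.e_value),
                )
            )
        except ValueError as exc:
            raise PSMParseError(f"{path}, line {line_no}: {exc}") from exc
    return psms


def _parse_xtandem(path, replicate_id: str = "", condition_id: str = "") -> list[PeptideSpectrumMatch]:
    from pyteomics import tandem

    proton = 1.00727646677
    psms: list[PeptideSpectrumMatch] = []
    with tandem.read(str(path)) as reader:
        for entry in reader:
            scan = int(entry["support"]["fragment ion mass spectrum"]["id"])
            z = max(int(entry.get("z", 1)), 1)
            # "mh" is the singly-protonated mass M+H; convert to (M + zH)/z
            mz = (float(entry["mh"]) + (z - 1) * proton) / z
            for protein in entry["protein"]:
                pep = protein["peptide"]
                psms.append(
                    PeptideSpectrumMatch(
                        spectrum_id=f"{replicate_id or 'run'}:{scan}",
                        replicate_id=replicate_id,
                        condition_id=condition_id,
                        scan_number=scan,
                        precursor_mz=mz,
                        peptide=pep["seq"],
                        accession=protein["label"].split()[0],
                        e_value=float(pep["expect"]),
                    )
                )
    return psms


def write_psm_table(psms, path) -> None:
    """Write PSMs in the canonical TSV dialect (inverse of the tsv reader)."""
    df = pd.DataFrame(
        [
            {c: getattr(p, c) for c in PSM_COLUMNS}
            for p in psms
        ],
        columns=list(PSM_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def filter_psms(psms, threshold: float = 0.05) -> list[PeptideSpectrumMatch]:
    """Keep PSMs with E-value <= threshold (strictly greater is discarded)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return [p for p in psms if p.e_value <= threshold]


def read_fasta_database(path, species_regex: str | None = None) -> dict[str, tuple[str, str]]:
    """Load a protein FASTA as ``{accession: (sequence, species)}``.

    The species is parsed from the header's ``OS=`` token when present,
    otherwise via ``species_regex`` (first group), otherwise empty.
    """
    db: dict[str, tuple[str, str]] = {}
    with _fasta.read(str(path)) as reader:
        for header, sequence in reader:
            accession = header.split()[0]
            species = ""
            m = re.search(r"OS=(.+?)(?=\s+\w\w=|$)", header)
            if m:
                species = m.group(1).strip()
            elif species_regex:
                m = re.search(species_regex, header)
                if m:
                    species = m.group(1)
            db[accession] = (sequence, species)
    return db


def compute_coverage(sequence: str, peptides) -> float:
    """Percent of residues covered by any occurrence of any peptide.

    A boolean mask the length of the protein is built; every position of
    every (possibly overlapping) substring match of every peptide is marked,
    and coverage is 100 x marked / length.  Peptides absent from the
    sequence contribute nothing.
    """
    if not sequence:
        raise ValueError("sequence must be nonempty")
    covered = bytearray(len(sequence))
    for pep in peptides:
        if not pep:
            continue
        start = sequence.find(pep)
        while start != -1:
            for i in range(start, start + len(pep)):
                covered[i] = 1
            start = sequence.find(pep, start + 1)
    return 100.0 * sum(covered) / len(sequence)


def assemble_proteins(
    psms,
    database: dict[str, tuple[str, str]],
    min_distinct_peptides: int = 2,
    decoy_prefix: str = DECOY_PREFIX,
) -> list[ProteinIdentification]:
    """Group filtered PSMs by accession into protein identifications.

    Proteins with fewer than ``min_distinct_peptides`` distinct peptide
    sequences are discarded (two-peptide rule).  Order follows first
    appearance of each retained accession in the PSM list.
    """
    unresolved = sorted({p.accession for p in psms} - database.keys())
    if unresolved:
        raise KeyError(f"accession(s) not in database: {', '.join(unresolved)}")
    by_acc: dict[str, ProteinIdentification] = {}
    for psm in psms:
        prot = by_acc.get(psm.accession)
        if prot is None:
            sequence, species = database[psm.accession]
            prot = ProteinIdentification(
                accession=psm.accession,
                species=species,
                sequence=sequence,
                is_decoy=psm.accession.startswith(decoy_prefix),
            )
            by_acc[psm.accession] = prot
        prot.peptides.add(psm.peptide)
        prot.spectra.add(psm.spectrum_id)
        prot.psms.append(psm)
    retained = [p for p in by_acc.values() if len(p.peptides) >= min_distinct_peptides]
    for prot in retained:
        prot.coverage_percent = compute_coverage(prot.sequence, prot.peptides)
    return retained


def estimate_fdr(target_proteins, decoy_proteins, level: str = "protein") -> float:
    """Target-decoy false discovery rate: decoys passing / targets passing.

    Both lists must result from identical filtering (same E-value threshold
    and two-peptide rule).  ``level='psm'`` counts supporting spectra
    instead of proteins.
    """
    if level == "protein":
        n_target, n_decoy = len(target_proteins), len(decoy_proteins)
    elif level == "psm":
        n_target = sum(len(p.spectra) for p in target_proteins)
        n_decoy = sum(len(p.spectra) for p in decoy_proteins)
    else:
        raise ValueError(f"unknown FDR level: {level!r}")
    if n_target == 0:
        if n_decoy > 0:
            warnings.warn("no passing targets but passing decoys: FDR set to 1.0")
            return 1.0
        return 0.0
    return n_decoy / n_target
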