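"""Protein records, annotated FASTA I/O, and average-mass arithmetic.

Masses are *average* (isotope-abundance-weighted) throughout: the proteins of
interest are intact 15–45 kDa species measured in positive linear MALDI-TOF
mode, where isotope envelopes are unresolved and the centroid of the envelope
— not the monoisotopic peak — is what the instrument reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "AVERAGE_RESIDUE_MASS",
    "WATER_AVERAGE_MASS",
    "PROTON_AVERAGE_MASS",
    "PYRIDYLETHYL_DELTA",
    "ProteinRecord",
    "MassTable",
    "read_fasta",
    "write_fasta",
    "mature_sequence",
    "average_mass",
    "cysteine_count",
    "round_half_up",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: IUPAC average residue (i.e. dehydrated) masses in Da, to 4 decimals.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788,
    "C": 103.1388,
    "D": 115.0886,
    "E": 129.1155,
    "F": 147.1766,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "K": 128.1741,
    "L": 113.1594,
    "M": 131.1926,
    "N": 114.1038,
    "P": 97.1167,
    "Q": 128.1307,
    "R": 156.1875,
    "S": 87.0782,
    "T": 101.1051,
    "V": 99.1326,
    "W": 186.2132,
    "Y": 163.1760,
}

WATER_AVERAGE_MASS = 18.0153
PROTON_AVERAGE_MASS = 1.0073

#: Mass added per cysteine by 4-vinylpyridine alkylation (one pyridylethyl
#: group).  +104.14 Da is the 4-VP molecular mass minus one hydrogen; it is
#: the value the reference identification tables were computed with, and is
#: therefore the default even though the full Michael adduct would add
#: 105.14 Da.  Override via ``MassTable.with_overrides`` if desired.
PYRIDYLETHYL_DELTA = 104.14

_ALP_TYPES = frozenset({"ax", "ay", "bx", "by", "c", "other"})


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed MW tables).

    Python's builtin ``round`` is banker's rounding; reported masses use
    decimal half-up, so e.g. 18.415 kDa prints as 18.42.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProteinRecord:
    """An annotated amino-acid sequence.

    Parameters
    ----------
    id:
        Sequence label, e.g. ``"TaALP-ay-7DS"``.
    cultivar:
        Wheat variety the sequence was observed in (``"Mace"``,
        ``"Spitfire"``, ``"synthetic"``, or empty).
    locus:
        Chromosome-arm label (``"7DS"``, ``"4AL"``, ...) or empty.
    alp_type:
        One of ``ax, ay, bx, by, c, other``.
    sequence:
        Upper-case string over the 20 standard one-letter codes.
    signal_peptide_end:
        1-based index of the last signal-peptide residue; 0 means the
        sequence is already mature.
    """

    id: str
    sequence: str
    cultivar: str = ""
    locus: str = ""
    alp_type: str = "other"
    signal_peptide_end: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in AVERAGE_RESIDUE_MASS:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        if self.alp_type not in _ALP_TYPES:
            raise ValueError(
                f"record {self.id!r}: unknown ALP type {self.alp_type!r}"
            )
        if self.signal_peptide_end:
            if not 1 <= self.signal_peptide_end < len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: signal_peptide_end="
                    f"{self.signal_peptide_end} outside [1, {len(self.sequence) - 1}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MassTable:
    """Average residue masses plus modification mass deltas.

    ``mod_deltas`` must contain ``"pyridylethyl"`` (the 4-vinylpyridine
    cysteine adduct); further deltas (oxidation, acetylation, ...) are added
    by :func:`alpform.proteoform.ptm_catalogue` or configuration overrides.
    """

    residue_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASS)
    )
    water: float = WATER_AVERAGE_MASS
    proton: float = PROTON_AVERAGE_MASS
    mod_deltas: Mapping[str, float] = field(
        default_factory=lambda: {"pyridylethyl": PYRIDYLETHYL_DELTA}
    )

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.residue_mass)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        bad = [aa for aa, m in self.residue_mass.items() if m <= 0]
        if bad:
            raise ValueError(f"non-positive residue masses for: {bad}")
        if "pyridylethyl" not in self.mod_deltas:
            raise ValueError("mod_deltas must define 'pyridylethyl'")

    def with_overrides(
        self,
        residue_mass: Mapping[str, float] | None = None,
        mod_deltas: Mapping[str, float] | None = None,
        water: float | None = None,
        proton: float | None = None,
    ) -> "MassTable":
        """Return a copy with selected entries replaced."""
        return MassTable(
            residue_mass={**self.residue_mass, **(residue_mass or {})},
            water=self.water if water is None else water,
            proton=self.proton if proton is None else proton,
            mod_deltas={**self.mod_deltas, **(mod_deltas or {})},
        )


DEFAULT_MASS_TABLE = MassTable()


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed or validated."""


def _parse_header(description: str) -> dict[str, str]:
    tokens = description.split()
    annotations: dict[str, str] = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            annotations[key] = value
    return annotations


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read annotated FASTA into :class:`ProteinRecord` objects.

    Header annotations are whitespace-separated ``key=value`` tokens after
    the record id: ``cultivar=``, ``locus=``, ``type=`` and ``sp_end=``.
    Headers without annotations yield defaults (no cultivar/locus, type
    ``other``, mature sequence).

    Raises
    ------
    FastaParseError
        On malformed FASTA, unknown ALP type, illegal residue characters or
        invalid signal-peptide boundaries; the message names the offending
        record and position.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with path.open() as handle:
        first = handle.read(1)
        if first and first not in ">;\n":
            raise FastaParseError(
                f"{path}: line 1 does not start a FASTA record (expected '>')"
            )
        handle.seek(0)
        for entry in SeqIO.parse(handle, "fasta"):
            ann = _parse_header(entry.description)
            sp_end = int(ann.get("sp_end", "0") or 0)
            try:
                records.append(
                    ProteinRecord(
                        id=entry.id,
                        sequence=str(entry.seq).upper(),
                        cultivar=ann.get("cultivar", ""),
                        locus=ann.get("locus", ""),
                        alp_type=ann.get("type", "other"),
                        signal_peptide_end=sp_end,
                    )
                )
            except ValueError as exc:
                raise FastaParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records with their annotations as ``key=value`` header tokens.

    Inverse of :func:`read_fasta` for canonicalised input: defaults are
    omitted, annotation order is fixed.
    """
    out: list[SeqRecord] = []
    for rec in records:
        parts = []
        if rec.cultivar:
            parts.append(f"cultivar={rec.cultivar}")
        if rec.locus:
            parts.append(f"locus={rec.locus}")
        if rec.alp_type != "other":
            parts.append(f"type={rec.alp_type}")
        if rec.signal_peptide_end:
            parts.append(f"sp_end={rec.signal_peptide_end}")
        out.append(
            SeqRecord(Seq(rec.sequence), id=rec.id, description=" ".join(parts))
        )
    with Path(path).open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(out)


def mature_sequence(record: ProteinRecord) -> str:
    """Sequence with the signal peptide (residues 1..sp_end) removed.

    Identity when the record carries no signal-peptide annotation.  Reported
    masses describe mature proteins, so all downstream mass computation runs
    on this form.
    """
    if record.signal_peptide_end:
        return record.sequence[record.signal_peptide_end :]
    return record.sequence


def strip_signal_peptide(record: ProteinRecord) -> ProteinRecord:
    """Return a mature copy of *record* (``signal_peptide_end`` cleared)."""
    if not record.signal_peptide_end:
        return record
    return replace(
        record, sequence=mature_sequence(record), signal_peptide_end=0
    )


def average_mass(seq: str, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Average molecular mass of an unmodified peptide in Da.

    Sum of residue masses plus one water (the termini).  Full precision;
    round only at the reporting layer (:func:`round_half_up`).
    """
    if not seq:
        raise ValueError("average_mass of an empty sequence is undefined")
    try:
        return sum(table.residue_mass[aa] for aa in seq) + table.water
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc


def cysteine_count(seq: str) -> int:
    """Number of cysteines, i.e. of 4-vinylpyridine alkylation sites."""
    return seq.count("C")
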