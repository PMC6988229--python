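"""Identification tables, homolog counting, and gel-MW calibration.

Merges SDS-PAGE band metadata (band label, RP-HPLC peak, retention time,
peptide-sequencing identity) with intact-mass assignments into the flat
identification table used to summarise which ALP homologs a cultivar
expresses.  Band identities from peptide sequencing are often slash
compounds (e.g. ``TaALP-by-7DS/4AL/7AS``) because homeologous copies on
the A/B/D subgenomes exceed 93% identity and cannot be told apart from the
observed peptides; a packaged normalisation table expands each compound to
the homolog set it denotes.  C-terminal (partial) forms are counted as
distinct entries — they are distinct molecular species on the gel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from alpform.peak_match import Assignment
from alpform.seq_model import round_half_up

__all__ = [
    "BandRecord",
    "IdentificationTable",
    "BandCollisionWarning",
    "build_identification_table",
    "normalize_identity",
    "count_distinct_homologs",
    "estimate_band_mw",
    "BandMWEstimate",
    "load_reference_bands",
    "load_reference_masses",
    "load_reference_motif_sites",
    "load_identity_map",
]


class BandCollisionWarning(UserWarning):
    """A band label occurs more than once within one cultivar run."""


@dataclass(frozen=True)
class BandRecord:
    """One SDS-PAGE band with its HPLC and sequencing metadata."""

    band_label: str
    hplc_peak: str
    retention_time: float
    identity: str
    cultivar: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError(
                f"band {self.band_label!r}: retention time must be positive"
            )


@dataclass
class IdentificationTable:
    """Band rows left-joined with zero-or-more mass assignments."""

    frame: pd.DataFrame
    collisions: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("alpform").joinpath("data", name)))


def load_identity_map() -> pd.DataFrame:
    """Normalisation table: sequencing identity → homolog set, ALP flag."""
    df = pd.read_csv(_data_path("identity_normalization.tsv"), sep="\t")
    df["homologs"] = df["homologs"].str.split(";")
    return df


def load_reference_bands() -> list[BandRecord]:
    """The packaged band/peak/identity transcription (59 rows, 2 cultivars)."""
    df = pd.read_csv(_data_path("reference_bands.tsv"), sep="\t")
    id_map = load_identity_map().set_index("identity")
    records = []
    for row in df.itertuples(index=False):
        partial = False
        if row.identity in id_map.index:
            partial = bool(id_map.loc[row.identity, "partial"])
        records.append(
            BandRecord(
                band_label=row.band_label,
                hplc_peak=row.hplc_peak,
                retention_time=float(row.retention_time_min),
                identity=row.identity,
                cultivar=row.cultivar,
                partial=partial,
            )
        )
    return records


def load_reference_masses() -> pd.DataFrame:
    """The packaged per-homolog mass summary (calculated, alkylated, cleaved)."""
    return pd.read_csv(_data_path("reference_masses.tsv"), sep="\t")


def load_reference_motif_sites() -> pd.DataFrame:
    """The packaged predicted N-myristoylation sites (19 hexapeptides)."""
    return pd.read_csv(_data_path("reference_myristoylation_sites.tsv"), sep="\t")


def normalize_identity(
    identity: str, id_map: pd.DataFrame | None = None
) -> tuple[list[str], bool]:
    """Expand a sequencing identity to (homolog names, is_alp).

    Slash compounds expand via the packaged table when present; otherwise a
    generic rule splits ``<prefix>-<arm1>/<arm2>/...`` on ``/`` and
    re-attaches the prefix.  Partial ``peptide N`` suffixes map onto their
    parent homolog.  Identities that are not ALPs (or are unreadable) are
    returned as-is with ``is_alp=False``.
    """
    if id_map is None:
        id_map = load_identity_map()
    lookup = id_map.set_index("identity")
    if identity in lookup.index:
        row = lookup.loc[identity]
        return list(row["homologs"]), bool(row["is_alp"])
    if "TaALP" not in identity:
        return [identity], False
    # generic fallback: "TaALP-by-7DS/4AL" -> TaALP-by-7DS, TaALP-by-4AL
    head, slash, rest = identity.partition("/")
    if not slash:
        return [identity], True
    stem, _, first_arm = head.rpartition("-")
    names = [head] + [f"{stem}-{arm}" for arm in rest.split("/")]
    return names, True


def build_identification_table(
    bands: Sequence[BandRecord],
    assignments: Sequence[Assignment] = (),
    strict: bool = False,
) -> IdentificationTable:
    """Left-join band metadata with mass assignments on homolog identity.

    An assignment attaches to a band when its proteoform's ``parent_id``
    is among the band's normalised homolog names.  Unmatched bands are
    retained with empty assignment columns.  Band-label collisions within
    a cultivar are faithfully reported on the returned table (and trigger
    :class:`BandCollisionWarning`); ``strict=True`` raises instead —
    published tables do contain verbatim collisions, so the default
    reports rather than rejects them.
    """
    id_map = load_identity_map()
    seen: dict[tuple[str, str], int] = {}
    collisions: list[tuple[str, str]] = []
    for band in bands:
        key = (band.cultivar, band.band_label)
        seen[key] = seen.get(key, 0) + 1
    collisions = [key for key, n in seen.items() if n > 1]
    if collisions and strict:
        raise ValueError(
            "duplicate band labels within a cultivar: "
            + ", ".join(f"{c}/{b}" for c, b in sorted(collisions))
        )
    if collisions:
        warnings.warn(
            f"{len(collisions)} band-label collision(s) retained verbatim",
            BandCollisionWarning,
            stacklevel=2,
        )

    by_parent: dict[str, list[Assignment]] = {}
    for a in assignments:
        if a.proteoform is not None:
            by_parent.setdefault(a.proteoform.parent_id, []).append(a)

    rows = []
    for band in bands:
        homologs, is_alp = normalize_identity(band.identity, id_map)
        attached = [a for h in homologs for a in by_parent.get(h, [])]
        base = {
            "cultivar": band.cultivar,
            "hplc_peak": band.hplc_peak,
            "band_label": band.band_label,
            "retention_time_min": band.retention_time,
            "identity": band.identity,
            "homologs": ";".join(homologs),
            "is_alp": is_alp,
            "partial": band.partial,
        }
        if attached:
            for a in attached:
                rows.append(
                    {
                        **base,
                        "assigned_mz": a.mz,
                        "assigned_label": a.proteoform.label,
                        "assigned_mass_da": a.proteoform.mass,
                        "error_da": a.error_da,
                    }
                )
        else:
            rows.append(
                {
                    **base,
                    "assigned_mz": np.nan,
                    "assigned_label": "",
                    "assigned_mass_da": np.nan,
                    "error_da": np.nan,
                }
            )
    columns = [
        "cultivar",
        "hplc_peak",
        "band_label",
        "retention_time_min",
        "identity",
        "homologs",
        "is_alp",
        "partial",
        "assigned_mz",
        "assigned_label",
        "assigned_mass_da",
        "error_da",
    ]
    frame = pd.DataFrame(rows, columns=columns).sort_values(
        ["cultivar", "hplc_peak", "band_label"], kind="stable"
    )
    frame = frame.reset_index(drop=True)
    return IdentificationTable(frame=frame, collisions=sorted(collisions))


def count_distinct_homologs(
    table: IdentificationTable, alp_only: bool = True
) -> int:
    """Number of distinct homolog identities across cultivars.

    Identities are the normalised (expanded) homolog names; C-terminal
    partial forms count as their own entries, while ``peptide N`` fragments
    fold into their parent homolog.  Non-ALP rows are excluded unless
    ``alp_only=False``.
    """
    frame = table.frame
    if alp_only:
        frame = frame.loc[frame["is_alp"].astype(bool)]
    names: set[str] = set()
    for cell in frame["homologs"]:
        names.update(n for n in cell.split(";") if n)
    return len(names)


@dataclass(frozen=True)
class BandMWEstimate:
    """Result of gel calibration; flags queries outside the standard range."""

    mw_kda: float
    extrapolated: bool


def estimate_band_mw(
    standards: Sequence[tuple[float, float]], migration: float
) -> BandMWEstimate:
    """Estimate a band's MW from protein standards by log-linear calibration.

    Fits least-squares ``log10(MW) = a + b * migration`` over the standards
    (the classical SDS-PAGE calibration: mobility is linear in log mass)
    and evaluates at the query migration.  Queries outside the standards'
    migration span are flagged as extrapolated.
    """
    if len(standards) < 2:
        raise ValueError("need at least 2 standards for calibration")
    mws = np.array([s[0] for s in standards], dtype=float)
    migs = np.array([s[1] for s in standards], dtype=float)
    if np.any(mws <= 0):
        raise ValueError("standard MWs must be positive")
    if np.ptp(migs) == 0:
        raise ValueError("standards have zero migration spread")
    slope, intercept = np.polyfit(migs, np.log10(mws), 1)
    mw = float(10 ** (intercept + slope * migration))
    extrapolated = not (migs.min() <= migration <= migs.max())
    return BandMWEstimate(mw_kda=round_half_up(mw, 2), extrapolated=extrapolated)
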