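"""Tolerance-based assignment of MALDI-TOF peaks to proteoform hypotheses.

Spectra are positive linear-mode MALDI of intact proteins, acquired over
15,000–45,000 m/z.  Peaks are assumed singly protonated by default
([M+H]+, z = 1); the proton is subtracted before comparison with neutral
theoretical masses.  Because mass accuracy in linear mode on intact
proteins is on the order of 0.1%, the default tolerance is relative
(0.1% of the theoretical mass) rather than a fixed Da window.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from alpform.proteoform import Proteoform
from alpform.seq_model import DEFAULT_MASS_TABLE, MassTable

__all__ = [
    "DEFAULT_MASS_RANGE",
    "Peak",
    "PeakList",
    "Tolerance",
    "Assignment",
    "PeakParseError",
    "read_peaks",
    "neutral_mass",
    "match",
    "assignments_to_frame",
]

#: Acquisition window (Da) of the linear-mode runs.
DEFAULT_MASS_RANGE = (15000.0, 45000.0)


class PeakParseError(ValueError):
    """Raised on malformed peak-list files; names the offending row."""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity}")


@dataclass(frozen=True)
class PeakList:
    """Observed peaks of one spectrum, sorted by m/z ascending."""

    spectrum_id: str
    peaks: tuple[Peak, ...]
    charge_assumption: int = 1
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def in_range(self, peak: Peak) -> bool:
        low, high = self.mass_range
        return low <= peak.mz <= high


def read_peaks(
    path: str | Path,
    spectrum_id: str | None = None,
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
) -> PeakList:
    """Load a delimited (comma/tab/space) peak list.

    Accepts an optional header row (``mz``/``m/z`` + ``intensity``) or two
    bare numeric columns; a single column is read as m/z with zero
    intensity.  Peaks outside *mass_range* are retained — downstream code
    can flag them via :meth:`PeakList.in_range`.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open(newline="") as handle:
        text = handle.read()
    for row_no, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        cells = [c for c in csv.reader([line], skipinitialspace=True).__next__()]
        if len(cells) == 1:
            cells = line.split()
        if row_no == 1 and cells and not _is_number(cells[0]):
            continue  # header
        try:
            mz = float(cells[0])
            intensity = float(cells[1]) if len(cells) > 1 else 0.0
        except (ValueError, IndexError) as exc:
            raise PeakParseError(
                f"{path}: row {row_no}: non-numeric cell in {line!r}"
            ) from exc
        try:
            peaks.append(Peak(mz=mz, intensity=intensity))
        except ValueError as exc:
            raise PeakParseError(f"{path}: row {row_no}: {exc}") from exc
    return PeakList(
        spectrum_id=spectrum_id or path.stem,
        peaks=tuple(peaks),
        mass_range=mass_range,
    )


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def neutral_mass(
    mz: float, z: int = 1, table: MassTable = DEFAULT_MASS_TABLE
) -> float:
    """Neutral mass from an [M+zH]z+ ion: ``mz*z − z*proton``."""
    if z < 1:
        raise ValueError(f"charge must be ≥ 1, got {z}")
    return mz * z - z * table.proton


@dataclass(frozen=True)
class Tolerance:
    """Absolute (Da) or relative (fraction of theoretical mass) window.

    ``Tolerance(relative=0.001)`` is the default: 0.1% of the hypothesis
    mass, ~18 Da at 18 kDa.
    """

    absolute: float | None = None
    relative: float | None = 0.001

    def __post_init__(self) -> None:
        if (self.absolute is None) == (self.relative is None):
            raise ValueError("specify exactly one of absolute or relative")
        value = self.absolute if self.absolute is not None else self.relative
        if value <= 0:
            raise ValueError("tolerance must be positive")

    def window(self, theoretical_mass: float) -> float:
        if self.absolute is not None:
            return self.absolute
        return self.relative * theoretical_mass


@dataclass(frozen=True)
class Assignment:
    """One (peak, proteoform) pairing within tolerance; rank 1 = best.

    ``proteoform`` is ``None`` for peaks with no candidate (rank 0).
    """

    spectrum_id: str
    mz: float
    observed_mass: float
    proteoform: Proteoform | None
    error_da: float | None = None
    error_ppm: float | None = None
    rank: int = 0

    @property
    def assigned(self) -> bool:
        return self.proteoform is not None


def match(
    peaks: PeakList,
    hypotheses: Sequence[Proteoform],
    tolerance: Tolerance = Tolerance(),
    neutral_input: bool = False,
    unique: bool = False,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[Assignment]:
    """Assign every peak to all hypotheses within tolerance.

    For each peak the candidates are ranked by |error| in Da, then by fewer
    extra PTMs, then by fewer cleavages (full-length preferred) — a
    parsimony order — then by parent id for determinism.  Peaks with no
    candidate are emitted unassigned.  By default one hypothesis may explain
    several peaks and vice versa; ``unique=True`` applies a greedy 1:1
    filter (best |error| first), which is the right mode for scoring
    simulations.

    ``neutral_input=True`` treats the m/z values as neutral masses (no
    proton subtraction) for peak lists that were already deconvoluted.
    """
    z = peaks.charge_assumption
    assignments: list[Assignment] = []
    for peak in peaks.peaks:
        observed = peak.mz if neutral_input else neutral_mass(peak.mz, z, table)
        candidates = []
        for hypo in hypotheses:
            err = observed - hypo.mass
            if abs(err) <= tolerance.window(hypo.mass):
                candidates.append((hypo, err))
        if not candidates:
            assignments.append(
                Assignment(
                    spectrum_id=peaks.spectrum_id,
                    mz=peak.mz,
                    observed_mass=observed,
                    proteoform=None,
                )
            )
            continue
        candidates.sort(
            key=lambda item: (
                abs(item[1]),
                item[0].n_extra_mods,
                0 if item[0].label in ("MW1", "MW2", "custom") else 1,
                item[0].parent_id,
                item[0].fragment,
            )
        )
        for rank, (hypo, err) in enumerate(candidates, start=1):
            assignments.append(
                Assignment(
                    spectrum_id=peaks.spectrum_id,
                    mz=peak.mz,
                    observed_mass=observed,
                    proteoform=hypo,
                    error_da=err,
                    error_ppm=err / hypo.mass * 1e6,
                    rank=rank,
                )
            )
    if unique:
        assignments = _greedy_unique(assignments)
    return assignments


def _greedy_unique(assignments: list[Assignment]) -> list[Assignment]:
    """Greedy 1:1 peak↔hypothesis filter, best absolute error first."""
    unassigned = [a for a in assignments if not a.assigned]
    ranked = sorted(
        (a for a in assignments if a.assigned),
        key=lambda a: (abs(a.error_da), a.rank),
    )
    used_peaks: set[tuple[str, float]] = set()
    used_hypos: set[int] = set()
    kept: list[Assignment] = []
    for a in ranked:
        peak_key = (a.spectrum_id, a.mz)
        hypo_key = id(a.proteoform)
        if peak_key in used_peaks or hypo_key in used_hypos:
            continue
        used_peaks.add(peak_key)
        used_hypos.add(hypo_key)
        kept.append(
            Assignment(
                spectrum_id=a.spectrum_id,
                mz=a.mz,
                observed_mass=a.observed_mass,
                proteoform=a.proteoform,
                error_da=a.error_da,
                error_ppm=a.error_ppm,
                rank=1,
            )
        )
    kept.sort(key=lambda a: a.mz)
    return kept + unassigned


def assignments_to_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Tabulate assignments in stable column order."""
    rows = []
    for a in assignments:
        p = a.proteoform
        rows.append(
            {
                "spectrum_id": a.spectrum_id,
                "mz": a.mz,
                "observed_mass": a.observed_mass,
                "parent_id": p.parent_id if p else "",
                "label": p.label if p else "unassigned",
                "fragment": f"{p.fragment[0]}-{p.fragment[1]}" if p else "",
                "mods": p.mods_text if p else "",
                "theo_mass": p.mass if p else float("nan"),
                "error_da": a.error_da,
                "error_ppm": a.error_ppm,
                "rank": a.rank,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "spectrum_id",
            "mz",
            "observed_mass",
            "parent_id",
            "label",
            "fragment",
            "mods",
            "theo_mass",
            "error_da",
            "error_ppm",
            "rank",
        ],
    )
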