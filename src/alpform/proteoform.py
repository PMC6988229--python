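"""Proteoform hypothesis enumeration and the intact-mass model.

The hypothesis space for one protein mirrors the four-column mass summary
used to identify ALP subunits:

* ``MW1`` — mature full-length protein, unmodified;
* ``MW2`` — mature full-length protein with every cysteine alkylated by
  4-vinylpyridine (+104.14 Da per Cys);
* ``MW2c`` — a cleavage fragment, unalkylated;
* ``MW2d`` — a cleavage fragment, alkylated.

Cleavage points come from two rule kinds: a cut immediately *before* a
predicted N-myristoylation glycine (the downstream fragment then starts
with the glycine that would carry the myristate) and a cut inside an
Asn-Glu (N-E) dipeptide, the junction at which the farinin precursor is
known to be split.  Each hypothesis may additionally carry a bounded number
of generic PTM deltas (oxidation, acetylation, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from alpform.motif_scan import MotifHit, PrositePattern, scan
from alpform.seq_model import (
    DEFAULT_MASS_TABLE,
    MassTable,
    ProteinRecord,
    average_mass,
    cysteine_count,
    mature_sequence,
)

__all__ = [
    "Proteoform",
    "CleavageRule",
    "EnumerationOptions",
    "alkylated_mass",
    "default_cleavage_rules",
    "enumerate_cleavages",
    "enumerate_proteoforms",
    "ptm_catalogue",
    "proteoforms_to_frame",
]

#: Average-mass deltas (Da) for the PTMs invoked to explain residual
#: calculated-vs-measured discrepancies.  Values are standard average-mass
#: shifts; extensible via config.
_DEFAULT_PTM_DELTAS: dict[str, float] = {
    "oxidation": 16.00,
    "acetylation": 42.04,
    "formylation": 28.01,
    "phosphorylation": 79.98,
}


def ptm_catalogue(overrides: Mapping[str, float] | None = None) -> dict[str, float]:
    """Name → signed average-mass delta (Da) for generic single PTMs.

    The 4-vinylpyridine cysteine adduct is *not* in this catalogue — it is
    stoichiometric (one per cysteine) and handled by :func:`alkylated_mass`.
    """
    catalogue = dict(_DEFAULT_PTM_DELTAS)
    if overrides:
        catalogue.update(overrides)
    return catalogue


def alkylated_mass(
    mass: float, n_cys: int, table: MassTable = DEFAULT_MASS_TABLE
) -> float:
    """Mass after blocking *n_cys* cysteines with 4-vinylpyridine.

    Adds one pyridylethyl group (+104.14 Da by default) per cysteine.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if n_cys < 0:
        raise ValueError(f"n_cys must be non-negative, got {n_cys}")
    return mass + n_cys * table.mod_deltas["pyridylethyl"]


@dataclass(frozen=True)
class CleavageRule:
    """A rule producing candidate cleavage points.

    ``kind`` is one of ``before_motif`` (cut between start−1 and start of
    each motif hit), ``after_motif`` (between end and end+1), or
    ``dipeptide`` (cut between the two residues of each occurrence of a
    2-residue sequence such as ``"NE"``).
    """

    kind: str
    dipeptide: str = ""
    pattern_name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"before_motif", "after_motif", "dipeptide"}:
            raise ValueError(f"unknown cleavage rule kind {self.kind!r}")
        if self.kind == "dipeptide" and len(self.dipeptide) != 2:
            raise ValueError(
                f"dipeptide rule needs exactly 2 residues, got {self.dipeptide!r}"
            )


def default_cleavage_rules() -> list[CleavageRule]:
    """Cut before each predicted myristoylation glycine, and inside N-E."""
    return [
        CleavageRule(
            kind="before_motif",
            pattern_name="myristoylation",
            description="cut before the glycine of a predicted N-myristoylation site",
        ),
        CleavageRule(
            kind="dipeptide",
            dipeptide="NE",
            description="cut at the Asn-Glu junction (farinin-type precursor split)",
        ),
    ]


def enumerate_cleavages(
    seq: str,
    rules: Sequence[CleavageRule],
    hits: Sequence[MotifHit] = (),
) -> list[int]:
    """Candidate cut positions on *seq*, sorted and de-duplicated.

    A cut at position ``k`` splits the chain between residues ``k`` and
    ``k+1`` (1-based).  Cuts at 0 or at the full length would leave an
    empty fragment and are discarded.
    """
    length = len(seq)
    cuts: set[int] = set()
    for rule in rules:
        if rule.kind == "before_motif":
            for hit in hits:
                cuts.add(hit.start - 1)
        elif rule.kind == "after_motif":
            for hit in hits:
                cuts.add(hit.end)
        else:  # dipeptide
            a, b = rule.dipeptide
            for i in range(length - 1):
                if seq[i] == a and seq[i + 1] == b:
                    cuts.add(i + 1)
    return sorted(c for c in cuts if 0 < c < length)


@dataclass(frozen=True)
class Proteoform:
    """One (fragment × modification set) hypothesis with its average mass.

    ``fragment`` is a 1-based inclusive interval on the mature sequence.
    ``label`` follows the four-column convention: MW1 (full, unalkylated,
    unmodified), MW2 (full, alkylated), MW2c (fragment, unalkylated), MW2d
    (fragment, alkylated).  A full-length unalkylated form carrying extra
    PTMs is no longer the bare calculated mass and is labelled ``custom``;
    the other classes keep their label with the PTM listed in ``mods``.
    """

    parent_id: str
    fragment: tuple[int, int]
    alkylated: bool
    n_cys: int
    mass: float
    extra_mods: tuple[tuple[str, int], ...] = ()
    label: str = "custom"

    def __post_init__(self) -> None:
        start, end = self.fragment
        if not 1 <= start <= end:
            raise ValueError(f"invalid fragment interval {self.fragment}")
        if self.mass <= 0:
            raise ValueError(f"non-positive mass {self.mass}")

    @property
    def n_extra_mods(self) -> int:
        return sum(count for _, count in self.extra_mods)

    @property
    def mods_text(self) -> str:
        parts = []
        if self.alkylated:
            parts.append(f"pyridylethyl×{self.n_cys}")
        parts.extend(f"{name}×{count}" for name, count in self.extra_mods)
        return "+".join(parts) if parts else "none"


@dataclass(frozen=True)
class EnumerationOptions:
    """Switches controlling the size of the hypothesis space."""

    alkylation: bool = True
    include_unalkylated: bool = True
    ptm_deltas: Mapping[str, float] = field(default_factory=dict)
    max_extra_mods: int = 1


def _label(full: bool, alkylated: bool, has_extra_mods: bool) -> str:
    if full and not alkylated:
        # MW1 denotes the bare calculated mass: no alkylation, no extra PTMs.
        return "custom" if has_extra_mods else "MW1"
    if full:
        return "MW2"
    return "MW2d" if alkylated else "MW2c"


def enumerate_proteoforms(
    record: ProteinRecord,
    rules: Sequence[CleavageRule] = (),
    hits: Sequence[MotifHit] = (),
    options: EnumerationOptions = EnumerationOptions(),
    table: MassTable = DEFAULT_MASS_TABLE,
    pattern: PrositePattern | None = None,
) -> list[Proteoform]:
    """Deterministic, de-duplicated hypothesis list for one protein.

    Emits the full-length forms, then for every cut position both fragments,
    each in unalkylated and alkylated flavours as enabled; each base form is
    optionally combined with up to ``max_extra_mods`` single-PTM deltas.
    Output order and content are invariant to the order of *rules* and
    *hits*; duplicates are removed by (fragment, modification set), never by
    mass, so hypotheses with equal mass but different provenance survive.

    If *pattern* is given and *hits* is empty, motif hits are computed here.
    """
    seq = mature_sequence(record)
    if pattern is not None and not hits:
        hits = scan(seq, pattern, record_id=record.id)
    cuts = enumerate_cleavages(seq, rules, hits)

    intervals: list[tuple[int, int]] = [(1, len(seq))]
    for cut in cuts:
        intervals.append((1, cut))
        intervals.append((cut + 1, len(seq)))

    flavours: list[bool] = []
    if options.include_unalkylated:
        flavours.append(False)
    if options.alkylation:
        flavours.append(True)

    seen: set[tuple] = set()
    out: list[Proteoform] = []
    full_interval = (1, len(seq))
    for start, end in intervals:
        frag_seq = seq[start - 1 : end]
        base_mass = average_mass(frag_seq, table)
        n_cys = cysteine_count(frag_seq)
        for alk in flavours:
            mass = alkylated_mass(base_mass, n_cys, table) if alk else base_mass
            mod_combos: list[tuple[tuple[str, int], ...]] = [()]
            if options.max_extra_mods >= 1:
                for name in sorted(options.ptm_deltas):
                    for count in range(1, options.max_extra_mods + 1):
                        mod_combos.append(((name, count),))
            for mods in mod_combos:
                key = ((start, end), alk, mods)
                if key in seen:
                    continue
                seen.add(key)
                delta = sum(
                    options.ptm_deltas[name] * count for name, count in mods
                )
                out.append(
                    Proteoform(
                        parent_id=record.id,
                        fragment=(start, end),
                        alkylated=alk,
                        n_cys=n_cys,
                        mass=mass + delta,
                        extra_mods=mods,
                        label=_label(
                            (start, end) == full_interval, alk, bool(mods)
                        ),
                    )
                )
    return out


def proteoforms_to_frame(forms: Iterable[Proteoform]) -> pd.DataFrame:
    """Tabulate hypotheses with masses in Da and kDa (2 decimals at report)."""
    from alpform.seq_model import round_half_up

    rows = [
        {
            "parent_id": p.parent_id,
            "fragment_start": p.fragment[0],
            "fragment_end": p.fragment[1],
            "label": p.label,
            "n_cys": p.n_cys,
            "mods": p.mods_text,
            "mass_da": round_half_up(p.mass, 2),
            "mass_kda": round_half_up(p.mass / 1000.0, 2),
        }
        for p in forms
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "parent_id",
            "fragment_start",
            "fragment_end",
            "label",
            "n_cys",
            "mods",
            "mass_da",
            "mass_kda",
        ],
    )
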