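"""Synthetic ALP-like sequences and noisy MALDI peak lists with ground truth.

No raw spectra or sequences are deposited for the study system, so the
pipeline is exercised on generated data that reproduces its measured
characteristics: type-a subunits of 149–162 mature residues with 14
cysteines, type-b subunits of 261–267 residues with 18–19 cysteines, 0–2
embedded N-myristoylation hexapeptides drawn from the published predicted
sites, an N-terminal signal peptide, and per-protein linear-mode peak lists
carrying Gaussian mass error plus uniform noise peaks inside the
15–45 kDa acquisition window.

The background residue composition is prolamin-like (Gln/Pro/Phe-enriched,
~111 Da mean residue mass) and deliberately avoids glycine and the small
residues of the myristoylation consensus, so that the only motif matches
are the planted ones; every generated record is verified against the
scanner before being emitted.  Randomness flows from a single integer seed
through per-protein substreams, so record *i* is identical no matter how
many proteins are requested.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from alpform.motif_scan import MYRISTOYLATION_PATTERN, MotifHit, parse_pattern, scan
from alpform.peak_match import (
    DEFAULT_MASS_RANGE,
    Peak,
    PeakList,
    Tolerance,
    match,
)
from alpform.proteoform import (
    CleavageRule,
    EnumerationOptions,
    Proteoform,
    alkylated_mass,
    enumerate_cleavages,
    enumerate_proteoforms,
)
from alpform.seq_model import (
    DEFAULT_MASS_TABLE,
    ProteinRecord,
    average_mass,
    cysteine_count,
    write_fasta,
)

__all__ = [
    "MOTIF_HEXAPEPTIDES",
    "GeneratorParams",
    "TruthRecord",
    "SyntheticBundle",
    "generate",
    "write_bundle",
    "score_recovery",
]

#: The published predicted N-myristoylation hexapeptides; planted motifs are
#: sampled from this set.
MOTIF_HEXAPEPTIDES = (
    "GQSFGQ",
    "GQSFSQ",
    "GQRFGQ",
    "GTPFSQ",
    "GLRMSL",
    "GMYQAQ",
    "GSEQCQ",
    "GMSQSQ",
    "GIPMAR",
    "GGWVCE",
)

# Background alphabet: no G (so motif starts are only where planted), no C
# (cysteines are placed explicitly), and none of the small residues STAN
# that could complete a spurious consensus window downstream of a motif's
# internal glycine.  Weights give a Gln/Pro-rich prolamin-like composition
# with a ~112 Da mean residue mass, matching the ~111 Da/residue implied by
# the published subunit masses.
_BACKGROUND_RESIDUES = "QPVLIFEDMYHKRW"
_BACKGROUND_WEIGHTS = np.array(
    [0.18, 0.30, 0.15, 0.12, 0.08, 0.04, 0.04, 0.05,
     0.01, 0.01, 0.01, 0.005, 0.0025, 0.0025]
)


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition parameters of the generator.

    Lengths and cysteine counts mirror the published per-homolog summary;
    ``mass_error_sd`` (Da) and ``noise_peak_rate`` (expected uniform noise
    peaks per spectrum, Poisson) set the measurement-noise regime.
    ``p_cleave`` is the probability that a predicted cleavage actually
    produced an observable fragment pair.
    """

    n_proteins: int = 10
    a_fraction: float = 0.5
    a_length_range: tuple[int, int] = (149, 162)
    b_length_range: tuple[int, int] = (261, 267)
    a_cys_range: tuple[int, int] = (14, 14)
    b_cys_range: tuple[int, int] = (18, 19)
    n_motifs_range: tuple[int, int] = (0, 2)
    signal_peptide_range: tuple[int, int] = (15, 25)
    p_cleave: float = 0.5
    mass_error_sd: float = 2.0
    noise_peak_rate: float = 1.0
    include_proton: bool = True
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.a_fraction, self.p_cleave):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for lo, hi in (
            self.a_length_range,
            self.b_length_range,
            self.a_cys_range,
            self.b_cys_range,
            self.n_motifs_range,
            self.signal_peptide_range,
        ):
            if lo > hi or lo < 0:
                raise ValueError(f"empty or negative range ({lo}, {hi})")
        if self.mass_error_sd < 0 or self.noise_peak_rate < 0:
            raise ValueError("noise parameters must be non-negative")
        # infeasible combinations caught before any output
        max_fixed = self.n_motifs_range[1] * 6 + max(
            self.a_cys_range[1], self.b_cys_range[1]
        )
        min_len = min(self.a_length_range[0], self.b_length_range[0])
        if max_fixed > min_len:
            raise ValueError(
                f"constraints infeasible: up to {max_fixed} constrained residues "
                f"in sequences as short as {min_len}"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated protein."""

    record_id: str
    motif_positions: tuple[int, ...]  # 1-based starts on the mature sequence
    proteoforms: tuple[Proteoform, ...]  # emitted (observable) species
    peak_origins: tuple[tuple[float, int], ...]  # (mz, proteoform idx | -1=noise)


@dataclass
class SyntheticBundle:
    records: list[ProteinRecord]
    truth: list[TruthRecord]
    peak_lists: list[PeakList]
    manifest: dict


def _draw_background(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.choice(len(_BACKGROUND_RESIDUES), size=n, p=_BACKGROUND_WEIGHTS)
    return [_BACKGROUND_RESIDUES[i] for i in idx]


def _build_mature(
    rng: np.random.Generator,
    length: int,
    n_cys: int,
    n_motifs: int,
    pattern,
) -> tuple[str, tuple[int, ...]] | None:
    """One attempt at a constrained mature sequence; None on verification failure."""
    seq = _draw_background(rng, length)

    # non-overlapping motif placements, 0-based starts, at least one residue
    # apart so adjacent motifs cannot merge into new windows
    starts: list[int] = []
    tries = 0
    while len(starts) < n_motifs and tries < 200:
        tries += 1
        cand = int(rng.integers(1, length - 6 + 1))  # never at position 1
        if all(abs(cand - s) >= 7 for s in starts):
            starts.append(cand)
    if len(starts) < n_motifs:
        return None
    starts.sort()
    for s in starts:
        motif = MOTIF_HEXAPEPTIDES[rng.integers(len(MOTIF_HEXAPEPTIDES))]
        seq[s : s + 6] = list(motif)

    motif_span = {p for s in starts for p in range(s, s + 6)}
    free = [i for i in range(length) if i not in motif_span]
    have_cys = sum(1 for i in motif_span if seq[i] == "C")
    need = n_cys - have_cys
    if need < 0 or need > len(free):
        return None
    for i in rng.choice(len(free), size=need, replace=False):
        seq[free[int(i)]] = "C"

    mature = "".join(seq)
    if cysteine_count(mature) != n_cys:
        return None
    hits = scan(mature, pattern)
    if [h.start for h in hits] != [s + 1 for s in starts]:
        return None
    return mature, tuple(s + 1 for s in starts)


def generate(params: GeneratorParams) -> SyntheticBundle:
    """Deterministically generate records, ground truth, and peak lists.

    Per protein: the mature sequence satisfies the requested length,
    cysteine-count and motif constraints exactly; the emitted proteoforms
    are the alkylated full-length form plus, for each cleavage point kept
    with probability ``p_cleave``, the alkylated fragment pair.  Each
    emitted species contributes one peak at its true mass (+1 proton when
    ``include_proton``) perturbed by Gaussian error; Poisson-many uniform
    noise peaks are added inside the acquisition window.
    """
    pattern = parse_pattern(MYRISTOYLATION_PATTERN, name="myristoylation")
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_proteins)
    table = DEFAULT_MASS_TABLE

    records: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    peak_lists: list[PeakList] = []

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        is_a = rng.random() < params.a_fraction
        if is_a:
            length = int(rng.integers(*params.a_length_range, endpoint=True))
            n_cys = int(rng.integers(*params.a_cys_range, endpoint=True))
            alp_type = "ay" if rng.random() < 0.5 else "ax"
        else:
            length = int(rng.integers(*params.b_length_range, endpoint=True))
            n_cys = int(rng.integers(*params.b_cys_range, endpoint=True))
            alp_type = "by" if rng.random() < 0.5 else "bx"
        n_motifs = int(rng.integers(*params.n_motifs_range, endpoint=True))

        built = None
        for _ in range(50):
            built = _build_mature(rng, length, n_cys, n_motifs, pattern)
            if built is not None:
                break
        if built is None:  # pragma: no cover - rejection loop safety net
            raise RuntimeError(f"could not satisfy constraints for protein {i}")
        mature, motif_positions = built

        sp_len = int(rng.integers(*params.signal_peptide_range, endpoint=True))
        signal = "M" + "".join(_draw_background(rng, sp_len - 1))
        record = ProteinRecord(
            id=f"SYN-{alp_type}-{i:03d}",
            sequence=signal + mature,
            cultivar="synthetic",
            alp_type=alp_type,
            signal_peptide_end=sp_len,
        )
        records.append(record)

        # emitted proteoforms: alkylated full-length, plus alkylated
        # fragment pairs for cleavages kept with probability p_cleave
        hits = [
            MotifHit(record.id, start, mature[start - 1 : start + 5], "myristoylation")
            for start in motif_positions
        ]
        cuts = enumerate_cleavages(
            mature, [CleavageRule(kind="before_motif")], hits
        )
        emitted: list[Proteoform] = []
        full_mass = alkylated_mass(average_mass(mature, table), n_cys, table)
        emitted.append(
            Proteoform(
                parent_id=record.id,
                fragment=(1, length),
                alkylated=True,
                n_cys=n_cys,
                mass=full_mass,
                label="MW2",
            )
        )
        for cut in cuts:
            if rng.random() >= params.p_cleave:
                continue
            for start, end in ((1, cut), (cut + 1, length)):
                frag = mature[start - 1 : end]
                ncf = cysteine_count(frag)
                emitted.append(
                    Proteoform(
                        parent_id=record.id,
                        fragment=(start, end),
                        alkylated=True,
                        n_cys=ncf,
                        mass=alkylated_mass(average_mass(frag, table), ncf, table),
                        label="MW2d",
                    )
                )

        origins: list[tuple[float, int]] = []
        peaks: list[Peak] = []
        proton = table.proton if params.include_proton else 0.0
        for idx, form in enumerate(emitted):
            mz = form.mass + proton + rng.normal(0.0, params.mass_error_sd)
            peaks.append(Peak(mz=mz, intensity=float(rng.uniform(20, 100))))
            origins.append((mz, idx))
        for _ in range(rng.poisson(params.noise_peak_rate)):
            mz = float(rng.uniform(*params.mass_range))
            peaks.append(Peak(mz=mz, intensity=float(rng.uniform(1, 30))))
            origins.append((mz, -1))

        truths.append(
            TruthRecord(
                record_id=record.id,
                motif_positions=motif_positions,
                proteoforms=tuple(emitted),
                peak_origins=tuple(origins),
            )
        )
        peak_lists.append(
            PeakList(
                spectrum_id=record.id,
                peaks=tuple(peaks),
                mass_range=params.mass_range,
            )
        )

    manifest = {"generator": "alpform.synthetic_data", "params": asdict(params)}
    return SyntheticBundle(
        records=records, truth=truths, peak_lists=peak_lists, manifest=manifest
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write FASTA + per-spectrum peak CSVs + truth TSV + manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.records, outdir / "proteins.fasta")
    with (outdir / "truth.tsv").open("w") as fh:
        fh.write(
            "record_id\tmotif_positions\tfragment_start\tfragment_end\t"
            "label\tn_cys\tmass_da\n"
        )
        for truth in bundle.truth:
            pos = ",".join(map(str, truth.motif_positions))
            for form in truth.proteoforms:
                fh.write(
                    f"{truth.record_id}\t{pos}\t{form.fragment[0]}\t"
                    f"{form.fragment[1]}\t{form.label}\t{form.n_cys}\t"
                    f"{form.mass:.4f}\n"
                )
    for peaks in bundle.peak_lists:
        with (outdir / f"peaks_{peaks.spectrum_id}.csv").open("w") as fh:
            fh.write("mz,intensity\n")
            for p in peaks.peaks:
                fh.write(f"{p.mz:.4f},{p.intensity:.2f}\n")
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def score_recovery(
    bundle: SyntheticBundle,
    tolerance: Tolerance = Tolerance(relative=0.001),
) -> tuple[int, int]:
    """(recovered, emitted) count of true proteoforms found at rank 1.

    For each protein the full hypothesis space is re-enumerated from the
    sequence alone (the generator's choices are not consulted), peaks are
    matched, and an emitted species counts as recovered when some peak's
    rank-1 assignment is that species.
    """
    rules = [CleavageRule(kind="before_motif")]
    pattern = parse_pattern(MYRISTOYLATION_PATTERN, name="myristoylation")
    options = EnumerationOptions(alkylation=True, include_unalkylated=True)
    include_proton = bundle.manifest["params"]["include_proton"]

    recovered = 0
    emitted_total = 0
    for record, truth, peaks in zip(
        bundle.records, bundle.truth, bundle.peak_lists
    ):
        hypotheses = enumerate_proteoforms(
            record, rules=rules, options=options, pattern=pattern
        )
        assignments = match(
            peaks,
            hypotheses,
            tolerance=tolerance,
            neutral_input=not include_proton,
        )
        # a zero-Cys "alkylated" fragment is the same molecule as its
        # unalkylated twin, so species identity is (fragment, mass), not
        # the alkylation flag
        rank1 = {
            (a.proteoform.fragment, round(a.proteoform.mass, 6))
            for a in assignments
            if a.rank == 1 and a.proteoform is not None
        }
        for form in truth.proteoforms:
            emitted_total += 1
            if (form.fragment, round(form.mass, 6)) in rank1:
                recovered += 1
    return recovered, emitted_total
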