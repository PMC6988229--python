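# Methods

## Mass model

All masses are **average** (isotope-abundance-weighted). The proteins of
interest are intact 15–45 kDa chains measured in positive linear MALDI-TOF
mode, where the isotope envelope is unresolved and the reported peak is the
envelope centroid; monoisotopic arithmetic would be systematically ~6–20 Da
light at these sizes. Residue masses are the standard IUPAC average values
to 4 decimals (G 57.0519 … W 186.2132), water 18.0153 Da, proton 1.0073 Da.
An unmodified peptide's mass is the residue sum plus one water. Internal
arithmetic is full precision; rounding (decimal half-up, 2 decimals in Da
or kDa) happens only at the reporting layer, because that is the precision
at which the reference identification tables are printed.

**Alkylation.** Reduction + 4-vinylpyridine blocks every cysteine thiol
with one pyridylethyl group. The default mass increment is **+104.14 Da
per cysteine** — the 4-VP molecular mass minus one hydrogen — because the
reference mass tables were computed with that value and the package must
reproduce their arithmetic. Chemically, Michael addition of 4-VP adds the
full 105.14 Da (no hydrogen leaves), and some descriptions of the same
workflow quote 105.1 Da; the delta is therefore a config knob
(`alkylation_delta`, `MassTable.with_overrides`), with the discrepancy
deliberately surfaced rather than silently fixed. At 14–19 cysteines the
two conventions differ by 14–19 Da, comparable to the matching tolerance —
worth knowing when interpreting borderline assignments.

**PTM catalogue.** Generic single-site deltas used to explain residual
calculated-vs-measured gaps: oxidation +16.00, formylation +28.01,
acetylation +42.04, phosphorylation +79.98 Da (average values). At most
one extra PTM per hypothesis by default (`max_extra_mods=1`) to keep the
hypothesis space and the false-match risk bounded; disulphide-bond effects
(−2 Da per bond) are below the working tolerance and not modelled.

## Motif scanning

The scanner implements fixed-width PROSITE-style patterns: fixed residues,
`[...]` inclusion sets, `{...}` exclusion sets, `x(n)` wildcards. The
default pattern is the classical N-myristoylation consensus
`G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}`. Because the workflow uses the motif as
a marker for candidate proteolytic cleavage (not for confirmed lipidation),
*every* sequence position is scanned and internal hits are reported;
coordinates are 1-based inclusive. Whether published site coordinates are
on precursor or mature frames is ambiguous, so both are available
(`mature=` flag / `--precursor`); mass computation always uses the mature
chain. Variable-range repeats `x(m,n)` and `<`/`>` anchors are out of
scope. Correctness is pinned to an exhaustive per-window oracle by a
property test over random sequences.

## Cleavage and proteoform enumeration

Cut positions come from two rules, applied together by default:

* **before_motif** — cut immediately N-terminal of a predicted
  myristoylation glycine, chosen because N-myristoylation requires the
  glycine to become the fragment's N-terminus; the alternative
  (after_motif) is implemented for completeness.
* **dipeptide NE** — cut inside an Asn-Glu bond, the junction at which the
  related farinin precursor is proteolytically split.

Cuts that would leave an empty fragment are discarded. For each protein
the hypothesis list is: full-length {unalkylated, alkylated}, plus both
fragments of every cut in both alkylation states, each optionally combined
with one PTM delta. De-duplication is by (fragment, modification set) —
never by mass, since equal-mass hypotheses with different provenance must
stay distinguishable in reports. The list is invariant to rule/hit order.
Fragment masses obey the hydrolysis identity
`m(N) + m(C) = m(full) + H₂O`, enforced by a property test to 1e-6 Da.

Published cleaved-fragment masses are treated as *data to match*, not
values to re-derive: the exact sequences behind them are not deposited, and
one published pair (TaALP-by-7DS, 25439.88/27406.12 Da) differs by an
amount that is no integer multiple of 104.14 Da (residual 12.4 Da at 19
adducts). The consistency check reports that pair as anomalous by name.

## Peak matching

Peaks are assumed [M+H]⁺ (z = 1); one proton is subtracted before
comparison (`--neutral-input` disables this for deconvoluted lists —
whether published figure labels are protonated or neutral is not stated,
so both conventions are supported). The default tolerance is **relative,
0.1% of the theoretical mass**: linear-mode accuracy on intact proteins,
and the scale of agreement shown by the reference assignments (e.g.
32.43 vs 32.46 kDa). Candidates per peak are ranked by |error| in Da, then
fewer extra PTMs, then full-length before fragment (parsimony), then
parent id (determinism). Many-to-many matches are allowed by default —
one homolog legitimately explains several peaks — with a greedy 1:1 mode
(`unique=True`) for simulation scoring. Shrinking the tolerance can only
remove assignments (anti-monotonicity property test).

## Synthetic data

The generator emulates the measured inputs of the study system:

| parameter | default | rationale |
|---|---|---|
| type-a length / Cys | 149–162 res / 14 | published per-homolog counts |
| type-b length / Cys | 261–267 res / 18–19 | published per-homolog counts |
| motifs per protein | 0–2 | published site lists show 0–2 |
| signal peptide | 15–25 res | typical secreted-prolamin range |
| p_cleave | 0.5 | cleavage observed for some, not all, subunits |
| mass_error_sd | 2 Da | linear-mode calibration error |
| noise_peak_rate | 1.0 /spectrum (Poisson) | ≈20% noise peaks given 2–4 true species |
| mass window | 15–45 kDa | acquisition range |

Backgrounds are drawn from a Gln/Pro-rich prolamin-like composition with a
~112 Da mean residue mass (matching the ~111 Da/residue implied by the
published subunit masses) over an alphabet that excludes glycine, cysteine
and the small residues of the consensus, so the only motif matches are the
planted hexapeptides (sampled from the 19 published sites); every record
is verified against the scanner and cysteine counter before being emitted,
with deterministic rejection-resampling. Randomness derives from one
integer seed via per-protein `SeedSequence` substreams, so record *i* is
stable under changes to `n_proteins`.

Emitted (observable) species per protein are the alkylated full-length
form plus, for each cut kept with probability `p_cleave`, the alkylated
fragment pair — mirroring an alkylated sample. Each species contributes
one peak (true mass + proton + Gaussian error); Poisson-many uniform noise
peaks are added inside the acquisition window.

**What the generator does not emulate:** real homeolog near-identity
(>93%) and the resulting shared peptides, adduct/matrix satellite peaks,
peak-intensity physics, retention-time or gel-migration behaviour, and
partially alkylated species. Recovery results on synthetic data therefore
demonstrate the correctness and noise tolerance of the assignment logic,
not identification performance on real cultivar extracts.

**Recovery scoring** re-enumerates the hypothesis space from the sequences
alone and asks whether each emitted species is some peak's rank-1
assignment. Species identity is (fragment, mass): a cysteine-free fragment
is the same molecule whether or not the sample was alkylated, so the
alkylation flag cannot distinguish the degenerate pair. At σ = 0 recovery
is exactly 100%; at σ = 2 Da with ~20% noise it is ≥95% — residual misses
are short fragments whose 0.1% relative window is narrower than the 2 Da
error, plus rare hypothesis pairs a few Da apart.

## Identification tables

Band identities are normalised through a packaged versioned map:
homeolog compounds (`TaALP-by-7DS/4AL/7AS`) expand to their member
homologs, `peptide 1/2` partials fold into their parent, C-terminal
partial forms remain distinct countable entries (they are distinct
species on the gel, and the only convention under which the homolog
census closes), and non-ALP identities are retained but flagged. The
packaged 59-row band table is a verbatim transcription, including its
band-label collisions (e.g. Spitfire `13b` in two peaks, `17a` three
times in one peak); the builder reports collisions on the result and
warns by default, raising only in `strict` mode.

Gel calibration fits least-squares `log10(MW) = a + b·migration` over
≥2 protein standards — the classical SDS-PAGE law — and flags
extrapolation outside the standards' migration span.

## Problem sizes and determinism

The test suite and acceptance script use 50-protein simulations (~100
emitted species), 200–1000-case property tests, and the packaged reference
tables; everything completes in seconds. All stochastic tests fix their
seeds; hypothesis tests run derandomised.
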