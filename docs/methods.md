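# Methods

`sipseq` implements the computational chain of a DNA stable-isotope probing
(DNA-SIP) metagenomics study of gaseous-alkane degraders, together with a
forward simulator that makes every stage testable without external data.
This note records the models, the parameters that matter, and the design
choices that were genuinely open.

## Gradient banding model

A taxon's DNA is modelled as a single Gaussian band on the buoyant-density
axis of an equilibrated CsCl gradient. The band centre follows the
Schildkraut-type affine relation

    rho = 1.660 + 0.098 * GC + E * 0.036   [g/ml]

where GC is the genomic GC fraction and E the ¹³C atom-fraction excess of
the DNA (E = 1 for full labelling, adding the standard SIP literature shift
of 0.036 g/ml). The gradient spans `density_min`–`density_max`
(defaults 1.698–1.752 g/ml), cut into `n_fractions` (12) equal-width
half-open intervals, numbered 1 = densest to match heavy-first fraction
collection. Per-fraction DNA mass is the Gaussian integral over the
interval with band sd `band_sigma` (default 0.004 g/ml); mass outside the
gradient is renormalised into range so total DNA is conserved exactly.
Sequencing is a two-stage multinomial: each fraction receives
`round(depth * mass_share)` reads, distributed over taxa in proportion to
their DNA mass in that fraction. Refractive index is the inverse of the
density calibration below. No gradient-relaxation dynamics, diffusion
asymmetry, or qPCR noise is modelled: a single Gaussian per taxon is
sufficient to generate the heavy/light contrast the classifier consumes,
and that is all the downstream stages require of it.

Every vial draws from its own RNG stream derived from
(seed, substrate, isotope, replicate), so any vial is reproducible in
isolation and replicate vials differ only by stream.

### Default synthetic community

The default community has 30 taxa, 3 of which consume both design
substrates (ethane, propane) at 100 atom% excess and hold 6 % of the
community each; the remaining abundance is a flat Dirichlet split.
GC ranges were chosen from the banding model, not tuned: non-consumers
draw GC from [0.50, 0.64], so their unlabelled DNA bands in or just above
the light window and only Gaussian tails reach the heavy window (the
well-known unlabelled background of real SIP gradients); consumers draw GC
from [0.42, 0.52], so their fully labelled DNA bands inside the heavy
window while their unlabelled copies (¹²C control vials) band below the
light window. With the default gradient the 12 fraction midpoints place
4 fractions in the heavy window and 2 in the light window, matching the
3–4 heavy / 2–3 light fractions pooled in practice.

What the simulator does **not** emulate: chimeras, cross-feeding of the
¹³C label, partial labelling kinetics, amplicon primer bias, or
compositional overdispersion beyond multinomial noise. Passing recovery
tests therefore show the classifier is correct *given* clean banding, not
that it is robust to every artefact of real amplicon data.

## Density calibration and pooling

Refractive index converts to buoyant density as
`rho = 10.9276 * RI − 13.593` g/ml, the standard CsCl refractometer
calibration; both coefficients are configurable because the conversion is
temperature-specific. Pooling windows default to the study windows —
heavy 1.7296–1.7491 g/ml, light 1.7123–1.7216 g/ml — with **inclusive**
endpoints, because the printed bounds are themselves densities of pooled
fractions. Fractions between the windows are discarded. A vial with an
empty window is flagged unusable, never silently dropped.

## Labelled-taxon classification

Within each pool, relative abundances are normalised to 100 %; taxa absent
from a pool get 0 (absence is evidence in amplicon profiling, not
missingness). A taxon is labelled iff all three criteria hold, all strict:

1. heavy(¹³C) > 1.0 % (configurable floor);
2. heavy(¹³C) > light(¹³C);
3. heavy(¹³C) − light(¹³C) > heavy(¹²C) − light(¹²C).

Duplicate vials are averaged per pool before the criteria are applied.
This was an open choice (per-replicate AND is the alternative, available
via `replicate_rule="all"`); averaging was chosen as the less brittle rule
under multinomial noise and is the documented default. Strictness matters
at the margins: a taxon at exactly 1.0 % heavy abundance is *not* labelled,
and identical ¹²C/¹³C profiles always fail criterion 3.

## Headspace accounting

Gas concentrations (% v/v) convert to µmol through the ideal gas law at
25 °C / 101.325 kPa defaults; dissolved-gas partitioning into the liquid
phase is ignored (a few-percent effect for short alkanes at this
temperature). µmol of alkane scale by carbon number to µmol C, and
cumulative consumption per gram of sample is clipped to its running
maximum rather than smoothed — this preserves the monotone contract
without inventing a filter. Harvest times are the earliest grid point at
which cumulative consumption reaches the target (100 or 200 µmol C g⁻¹ in
the study design). Consumption rates are least-squares slopes of
cumulative consumption over the declining phase, defined as the window
until substrate first falls below 5 % of its initial concentration (the
rate window was not externally specified; 5 % excludes the depleted
plateau without truncating slow vials), reported as replicate mean ± sd.

## Alignment core

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment under
Gotoh's three-state affine-gap recurrences, with a run of k gap columns
costing `gap_open + k*gap_extend` (defaults 5 + 2k) and the standard
restriction that insertion and deletion runs may not be adjacent.
Nucleotide scoring is +1/−2; protein scoring is BLOSUM62. Traceback is
deterministic with tie-break diagonal > up > left (up = gap in the
subject); co-optimal local maxima resolve to the first cell in row-major
order. The DP kernels are numba-compiled; correctness is pinned by an
exhaustive path-enumeration oracle over short sequences in the test suite.

E-values use the Karlin–Altschul formula `E = K·m·n·exp(−λ·s)` with
published gapped defaults (nucleotide λ = 1.33, K = 0.621; BLOSUM62
λ = 0.267, K = 0.041). These are thresholds for filtering, not
reproductions of BLAST's internal edge-corrected estimates; exact e-values
from other tools will differ, the pass/fail decisions at 1e-5 do not in
the regimes exercised here. Identity defaults to the all-columns (BLAST)
convention; the ungapped mode is available and the mode is recorded.

For a short query against a long target (genome fragments, reads), an
exhaustive full-matrix local DP is quadratic in the target and needlessly
slow. The search first locates the best candidate window with a fast infix
edit-distance scan (edlib; the whole query placed anywhere in the target),
pads it by 80 bp, and runs the exact affine DP inside the window, on both
strands. All reported scores and identities come from the exact DP. The
locator is exact for the edit-distance optimum; in the regimes that decide
thresholds here (high-identity hits vs. no credible hit) the located
window contains the affine optimum as well.

## Relatedness indices

* **ANI** — fragments of 1020 bp (tails ≥ 100 bp kept, shorter dropped)
  cut from the query genome, each locally aligned to the other genome;
  fragments with ≥ 30 % identity over ≥ 70 % of their length contribute
  (the JSpecies fragment convention); ANI is the mean identity of
  contributing fragments, symmetrised by averaging both directions.
  Random unrelated genomes yield no passing fragment and an explicit
  "undefined" result.
* **AAI** — reciprocal best hits between proteomes under local protein
  alignment with ≥ 20 % identity, e-value ≤ 1e-5 and ≥ 50 % query
  coverage; AAI is the mean identity over RBH pairs. The RBH thresholds
  are documented defaults (the convention leaves them open), so AAI values
  are comparable but not bit-identical across tools.
* **TETRA** — tetranucleotide z-scores against a maximal-order Markov
  (trinucleotide) expectation, Teeling-style, counted on both strands so
  the 256-component signature is reverse-complement invariant and
  contig-order invariant; similarity is the Pearson correlation of two
  signatures. Windows containing non-ACGT bases are dropped.

Species calls use ANI ≥ 95 % when ANI is defined, otherwise AAI ≥ 70 %
(both inclusive at the boundary). MAG quality filtering retains
completeness > 70 % and contamination < 5 %, both strict, excluding records
with missing metadata explicitly. Dereplication single-links genomes at
ANI ≥ 95 % and keeps the highest-scoring member of each cluster with the
dRep-style score `completeness − 5·contamination` (ties broken by id);
undefined pairwise ANI counts as below threshold.

## SDIMO screening and recruitment

The marker panel covers the SDIMO alpha-subunit families mmoX, bmoX
(Group III), prmA (Groups V and VI depending on reference origin), dmpN
(Group II), tmoA (Group I) and the membrane-bound pMMO alpha subunit.
Queries are assigned to the group of their best-scoring panel reference
when identity ≥ 40 % (a nearest-reference surrogate for maximum-likelihood
tree placement; the floor keeps the alpha-subunit families separable and
is configurable), otherwise "undefined" — the outcome real divergent SDIMO
clusters produce. The bundled panel is **synthetic**: random stand-in
sequences generated by `sipseq.sdimo.synthetic_panel`, labelled as such;
real reference sequences can be dropped in via the manifest TSV.

Genome abundance in a metagenome is the fraction of queries recruited by a
best local alignment with identity strictly > 95 % and e-value strictly
< 1e-5, either strand, one recruitment per query. Reads vs. assembled
scaffolds are both accepted; the choice is recorded in the result.
Queries under 100 bp are skipped (counted) because their e-values are
unreliable.

## Problem sizes and tolerances

The bundled test bench runs at desk scale by design: 200 kb synthetic
genomes for ANI recovery (expected identity 100·(1−d) % within ±0.5 at
d = 1/5/10 %), 40–100 protein proteomes for AAI, 100 reads for recruitment
mixtures, 20 seeds for labelling recovery and planted-marker screens, and
exhaustive alignment enumeration at lengths ≤ 8. Floating-point contracts:
DNA mass conservation to 1e-6 ng, pool count conservation exact (integer),
RI round-trip to 1e-9, density monotonicity exact.

## Known limitations

* The banding model has no gradient-relaxation or diffusion kinetics;
  `band_sigma` is a phenomenological width.
* E-values are scheme-level Karlin–Altschul estimates without finite-size
  edge correction.
* Group assignment by nearest reference cannot resolve queries equidistant
  from two groups the way a phylogeny can; the "undefined" floor is the
  guard.
* The windowed search can in principle miss an affine-score optimum whose
  edit-distance placement differs by more than the window margin; this
  does not affect threshold decisions at the identities used here.
* AAI depends on RBH thresholds; cross-tool comparisons should expect
  sub-percent differences.
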