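# Methods

This note documents the models and procedures implemented in `rampkit`:
the pathway representation, the RAMP profiling procedure, the kinetic
simulator and its defaults, the synthetic measurement generator, the
affected-step inference engine, and the numerical choices behind them.

## Pathway model

The transcript is a fixed sequence of seven segments — 5′ETS, 18S, ITS1,
5.8S, ITS2, 28S, 3′ETS — with configurable lengths. The shipped defaults
follow the standard mouse rDNA annotation: 4007, 1870, 999, 157, 1089,
4730 and 565 nt. Coordinates are 1-based within each segment, and a
cleavage "after position p" splits the transcript between p and p+1, so
the 5′ product ends at p and the 3′ product starts at p+1. Site 2b sits
after ITS1 +58 (the 36S 5′ end is therefore ITS1 +59); site 2c is
heterogeneous, represented by its observed interval +837..+857 with the
midpoint +847 used for all length arithmetic. Consequently the 32.5S
precursor retains 999 − 847 = 152 nt (~150 nt) of ITS1, which the Xrn2
exonuclease removes to give 32S.

Species are defined by explicit extents (lists of segment intervals), so
every endonucleolytic reaction can be checked to partition its substrate
exactly, and discarded spacer pieces (5′ETS fragments, the internal ITS1
fragment released by the 2b + 2c cleavage pair) are explicit species with
fast disposal reactions — conservation is checkable rather than assumed.
`validate()` returns violations as data: segment bounds, extent
contiguity, partition/containment of reaction products, acyclicity of the
species graph, and producer/consumer connectivity.

Modelling choices worth calling out:

* **PTP as a node.** 47S, 46S and 45S co-migrate on agarose gels and are
  measured as one pool ("primary transcript plus"). The kinetic and
  measurement models treat PTP as a single node fed by transcription and
  consumed by the 2b and 2c cleavages; the three member species keep
  their individual extents for sequence arithmetic (PTP cleavages are
  validated against the most-processed member, 45S) but are exempt from
  connectivity checks.
* **The 2b-first SSU precursor.** The 5′ product of 2b-first cleavage
  (5′ETS + 18S + ITS1 1..58) has no standard sedimentation name; it is
  modelled as species `SSU-2b-pre`, consumed by a single lumped 5′ETS
  removal tagged with both `SSU-A0` and `site1` (the same machineries act
  on this route) and emitting 18SE. It is excluded from ratio panels.
* **19S extent.** 19S is taken as the 5′ product of site-1 cleavage of
  29S, i.e. the 5′ETS interval from A0+1 to the segment end. The default
  A0 position (+2000) and A′ position (+650) inside the 5′ETS are
  adjustable defaults; no panel quantity depends on them.
* **The 5′-end assortment is collapsed.** The heterogeneous population of
  18S precursors with various 5′ ends is represented by the three named
  species 34S, 29S, 20S.

## RAMP profiles

A profile is an ordered panel of normalized log2 ratios. The default
mouse panel is tile 1 = {34S, 36S, 29S, 20S, 19S, 18SE, 32S, 12S}/PTP and
tile 2 = {34S/36S, 29S/34S, 20S/34S, 18SE/34S, 18SE/20S, 32S/36S,
12S/32S}; the order is fixed so profiles stay visually and numerically
comparable. Ratios are always formed within one lane of one blot
(cross-lane or cross-blot requests are provenance errors), each profile
comes from one knockdown/reference sample pair of one experiment, and
replicates are combined as mean ± sample SD (n−1). Below-detection
signals propagate as missing flags; no pseudocounts are ever added,
because a pseudocount in a log ratio is a silent bias.

Invariance: in exact arithmetic, multiplying all signals of a lane
(loading) or of a blot (probe efficiency) by any positive constant leaves
every profile value identical. In IEEE doubles `(a·s)/(b·s)` can differ
from `a/b` in the last ulp unless `s` is a power of two, so the tests
assert bit-identity for power-of-two scalings and ≤ 1e−12 log2 agreement
for arbitrary positive scalings.

## Kinetic model

The simulator is a deterministic mass-action first-order network: a
constant transcription rate ρ (molecules/time) into PTP, and one rate
constant per reaction (1/time). The observables of interest are bulk
steady-state ratios, so no stochastic mode is provided. Because the
species graph is a DAG, the steady state solves a triangular linear
system (`numpy.linalg.solve`, residual checked to 1e−10 relative);
mature rRNAs are terminal sinks whose inflow is the terminal flux, and a
*non-mature* species with inflow but no outflow raises a named error.

Conservation is stated in nucleotide-weighted form: ρ × len(45S) equals
the sum over terminal routes of flux × length, where exonucleolytic steps
contribute the residues they trim. (Molecule counting cannot balance — a
single transcript yields one 18S, one 5.8S, one 28S and several discarded
pieces; the per-species statements flux(18S) = flux(5.8S) = flux(28S) = ρ
hold exactly and are tested.)

The time-course oracle integrates dx/dt = b + Mx with fixed-step explicit
RK4 from empty initial conditions. For a linear autonomous system the RK4
fixed point coincides with the true steady state, so the end-point error
is pure transient decay; integration horizons are set in units of the
slowest total outflow (30/k_min in the oracle comparisons — chains of
near-equal rates relax with secular t^k·e^{−kt} terms, slower than
e^{−kt}). Steps beyond the RK4 stability bound (≈2.78/fastest outflow)
are rejected with a suggested dt; the default is 0.5/fastest outflow.

### Default rate constants

All constants are 1/h, chosen once to reflect steady-state precursor
patterns of rapidly dividing 3T3-like cells and then left alone:

| reaction | k | rationale |
| --- | --- | --- |
| 2b@PTP / 2c@PTP | 1.2 / 0.8 | 2b route moderately favoured in fast growth (~60/40 split); comparable 34S and 36S pools |
| A0@34S | 0.8 | with 2c@36S = 1.2 gives a baseline 34S/36S near 1 |
| 1@29S, 2b@20S, 1@SSU-2b-pre | 1.0 | unremarkable mid-pathway steps |
| 2c@36S | 1.2 | |
| xrn2@32.5S | 5.0 | the ITS1 remnant is removed rapidly |
| 4b@32S | 0.4 | 32S is an abundant, long-lived precursor |
| mat@18SE | 1.0 | late SSU maturation |
| mat@12S / mat@28.5S | 0.8 / 4.0 | 12S abundant, 28.5S scarce |
| decay@19S | 2.0 | 19S is detectable but unstable |
| fragment disposal | 50 | 10 × the fastest processing constant; fragments never dominate |

Transcription ρ = 100/h; all abundances scale linearly with it and no
ratio depends on it.

### Perturbations and scenarios

A perturbation maps factor tags to multiplicative rate factors; every
reaction carrying a tag is scaled (multiple mapped tags multiply, so
composing perturbations composes factors). The scenario battery encodes
the knockdown classes as tag sets: Rcl1-like {site1, 2b}, Fcf1-like
{SSU-A0, 2b}, Utp23-like {late-18SE strongly, SSU-A0 and site1 mildly at
0.7 — the mild 5′ETS effects ship enabled}, Pes1- and Nog1-like {2c,
ITS2}, plus growth-state scenarios that move the 2b-feeding constant down
(quiescence) or up (rapid growth), shifting which ITS1 site is cleaved
first. Default study conditions: main inhibition factor 0.25, mild factor
0.7, σ_log 0.1, three replicates.

Each scenario declares the expected sign (−1/0/+1 at the 1.5-fold
threshold) of every panel entry **at steady state**. These include the
reported knockdown signatures (SSU-early: 34S/36S up, 36S/PTP down;
Utp23-like: 18SE/PTP up with branch ratios flat; LSU: 12S/32S down,
36S/PTP up, 34S/36S down). One caveat is intrinsic to steady-state
analysis: flux conservation forces the flux through an inhibited linear
step back to its input value, with the substrate accumulating to
compensate. Some transient features of 72-h knockdowns — e.g. reduced
20S/PTP when an *upstream* SSU step is blocked — are therefore not
steady-state predictions, and the battery's expectations are the model's
own steady-state signs rather than a transcription of every verbal
observation. The diagnostic signs listed above are steady-state-robust,
which is what makes them good diagnostics.

## Synthetic measurement tables

The generator emulates exactly the nuisances RAMP is designed to cancel:
per-lane loading factors and per-blot probe-efficiency factors (lognormal,
SD 0.3 and 0.5 by default in noisy runs) and multiplicative lognormal
signal noise exp(N(0, σ²)) with σ = 0.1 in natural-log units. The default
design lays the panel out on four blots whose species lists follow
probe-target containment (ITS1-85 3′ of site 2b; ITS1-54 5′ of it; an
ITS2 probe 5′ of 4b; a 5′ETS probe between A0 and site 1). All sampling
is driven by explicit seeds; a fixed seed reproduces a byte-identical
table.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: gel co-migration ambiguity and band overlap,
background and saturation of phosphorimager plates, partial RNA
degradation, transcription fluctuation between paired samples beyond
what pairing removes, and the transient (non-steady-state) dynamics of
finite-duration knockdowns.

## Affected-step inference

At steady state every panel entry's knockdown shift is a signed sum of
per-step log2 inhibition factors: a /PTP ratio reports the branch share
feeding the species minus its own consumption rate; a product/substrate
ratio is the *difference of the two consumption rates* and is therefore
two-sided evidence (29S/34S down = A0 slow relative to site 1; 29S/34S up
= site 1 slow relative to A0 — the product accumulates when its consumer
is blocked). The engine writes these relations as a linear design over
the six panel-covered steps (2b, 2c, SSU-A0, site1, ITS2, late-18SE) plus
one free term for the shared downstream flux, estimates the step
inhibitions by least squares over all non-missing entries, and applies
the threshold θ = log2 1.5 ≈ 0.585 (the minimal interpretable 1.5-fold
change): below −θ inhibited, above +θ stimulated, otherwise unchanged.
Scores are estimates clipped at ±2θ into [−1, 1]. A step whose column is
not in the row space of the available entries (e.g. the absolute 2c
anchor when all /PTP entries are missing) is reported indeterminate, not
guessed. The branch-choice ratio 34S/36S additionally yields an explicitly
relative verdict (2b inhibited relative to 2c or vice versa) — a single
profile cannot separate a change affecting both routes equally.

This panel-wide estimator was chosen over per-ratio rules because single
ratios confound adjacent steps (the panel has no 20S/29S entry, so site-1
inhibition is only visible as 29S accumulation) and because pooling all
informative entries reduces the variance of each verdict under
measurement noise. Verdicts remain *relative* statements about the
knockdown versus its paired reference.

Recovery performance under the default study conditions (σ = 0.1, three
replicates, 1–2 perturbed steps at factors 0.5/0.25/0.1) is measured by
the acceptance script as the fraction of random scenarios whose inhibited
set is recovered exactly.

## Profile comparison

Distances over shared non-missing entries (at least 3): Pearson
correlation, cosine similarity, and sign concordance (fraction of entries
with equal θ-thresholded signs). Clustering is agglomerative with average
linkage on 1 − Pearson; profiles are sorted by label before clustering so
the tree is independent of input order. Sign-robustness comparisons
across depletion levels use θ = 1e−9: ratios untouched by a scenario are
zero only to solver round-off, and a literal θ = 0 would read that noise
as a sign.

## Synthetic reference sequence

The real mouse rDNA record must be supplied by the user (FASTA with
coordinates, or a GenBank file whose rRNA features define the segments
with spacers inferred as gaps). `synthetic_mouse_reference()` is an
explicitly synthetic stand-in — documented segment lengths with each
segment drawn at the documented base composition, ITS1 at exactly
700/999 = 70.1% G+C — adequate for pipeline tests, GC arithmetic and
probe logic, but not for sequence-faithful analyses (no real motifs, no
primer design). GC content excludes ambiguity codes from numerator and
denominator, and is invariant under reverse complement.

## Known limitations

* Steady-state only: no transient knockdown dynamics, no metabolic
  labelling read-out; see the caveat under the scenario battery.
* Hybridization is interval containment — no melting thermodynamics, no
  cross-hybridization.
* The inference design matrix is specific to the default mouse panel and
  the canonical wiring; custom panels require extending `compare._COEFFS`.
* Rate constants are not fitted to data (published blots provide no
  numeric signal tables); they are documented, plausible defaults, and
  all qualitative conclusions rest on sign patterns that are insensitive
  to them.
* Yeast-style cotranscriptional cleavage is out of scope; the model
  splits only the complete transcript.
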