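# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of the package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Mass calculus

All masses are monoisotopic. Residue masses are the standard 20-residue
table to six decimals; the constants are water 18.010565 Da, proton
1.0072765 Da, hydrogen 1.0078250 Da. A disulfide bond removes two hydrogen
atoms (2.015650 Da). Modifications are fixed deltas with site rules:
carbamidomethyl (+57.021464, Cys), Met oxidation (+15.994915), Asn/Gln
deamidation (+0.984016), N-terminal Gln pyroglutamate (−17.026549).
Bridged cysteines are never carbamidomethylated; carbamidomethyl is modeled
only for free-cysteine QC.

**Charge carrier.** Every charge state uses the proton mass. Published
parent-ion tables of this kind are not always mutually consistent at the
sub-mDa level between MH⁺ and higher charge states (some entries only
reproduce under a hydrogen-atom carrier per extra charge); a single
physical convention plus the ±0.005 Da comparison tolerance absorbs this.

**Fragments.** Only single-bond b/y cleavages are predicted (charges up to
2 by default); no internal ions and no neutral losses. A fragment
containing the bridged cysteine carries the full partner peptide minus two
hydrogens — the S-S bond is treated as surviving backbone fragmentation.

**Published-value regression.** The bundled evidence table (59
disulfide-bridged species of the four *T. urticae* OBPs, 146 theoretical
m/z cells over charges 1–4) is recomputed and compared within ±0.005 Da.
Two consistency checks run on the *published* numbers only, so flagging
never depends on our own theory: (i) the neutral masses implied by one
species' different charge states must agree within 0.02 Da; (ii) a
modified species and its unmodified twin must differ in printed MH⁺ by the
modification delta within 0.0005 Da. Species failing either check are
flagged and excluded from the pass/fail surface but still reported with
their recomputed values — they are never silently "fixed". Two such cases
exist in the bundled table (one cross-charge transposition at z=3, one
deamidation twin whose printed difference is 0.9831 instead of 0.984016).

## Digestion

Classical cleavage rules: trypsin after K/R, chymotrypsin after F/W/Y/L,
both blocked by a following proline (the block can be disabled per enzyme
rule). Chymotrypsin is modeled without Met specificity: the observed
chymotryptic termini in the bundled evidence are W/Y/F/L, and species
ending at M or V are consistently marked aspecific. Sequential digestion
applies the second enzyme to every product of the first, with the
missed-cleavage budget applied per enzyme, and de-duplicates by span.
Protein termini count as specific. Semi-specific expansion generates all
truncations of a fully-specific peptide that keep one specific terminus
and at least `min_length` residues; it is opt-in and intended for
cysteine-containing peptides only (combinatorial control). The default
minimum peptide length is 2 because two-residue bridged peptides occur in
the evidence; `digest` accepts `min_length=1` where exhaustive tilings are
needed.

## Crosslink search

Candidates are all unordered pairs of cysteine-containing peptides
(including modified variants, at most 2 modifications per peptide), one
S–S bond per species, oriented so the peptide nearer the protein
N-terminus comes first; pairs with overlapping host spans — including a
peptide with itself — are excluded, so no intra-peptide (loop) links are
enumerated. Precursor matching converts each observed (m/z, z) to a
neutral mass and accepts the candidate with the smallest |ppm error|
within the tolerance (default ±10 ppm), ties broken by species id. MS2
annotation counts fragment peaks within ±0.05 Da of predicted b/y ions and
scores a match as `n_matched − 10·mean|Da error|` — a deliberately
transparent heuristic, not a calibrated statistic; conclusions rest on
mass agreement and topology recovery, not score values.

Topology inference weights each cysteine-pair edge by the number of
distinct supporting species (sequence + modifications, not spectral
counts) and selects a matching greedily by descending weight with ties
broken by position pair. A skipped edge that ties a chosen conflicting
edge's weight flags the call as ambiguous. Unpaired cysteines are
reported.

## Binding

Concentrations are μM; signals are unitless. Saturation fits use
nonlinear least squares with positivity bounds, initialized at
K_d⁰ = median ligand concentration and F_max⁰ = max signal. Competition
fits use F = F₀/(1 + L/IC₅₀) with the Hill slope fixed at 1 (the IC₅₀ is
defined as a half-signal point, not a slope), initialized from the
reciprocal-linear form 1/F = 1/F₀ + L/(F₀·IC₅₀); a model-free
linear-interpolation crossing of F₀/2 is reported alongside as QC. The
Cheng–Prusoff-type conversion K_d = IC₅₀/(1 + [probe]/K_probe)
approximates free probe by total probe (2 μM by default); no free-probe or
inner-filter correction is applied. Tryptophan-quenching titrations are
ingested as curves but yield no dissociation constant, since quenching
does not report the bound-probe concentration. An "IC50 not reached" error
is raised when the signal never falls to half its initial value and the
extrapolated IC₅₀ exceeds four times the largest titrated concentration.

## Phylogenetics

Pairwise identity has two modes: *ungapped* anchors both sequences at the
C-terminus and compares the overlap (suited to homolog pairs differing by
an N-terminal extension, the geometry seen in these proteins); *aligned*
counts identities over columns where neither row of a supplied alignment
is gapped. Multiple alignment itself is out of scope — alignments are
inputs. The Kimura protein correction d = −ln(1 − p − p²/5) raises an
explicit saturation error for p ≥ 0.8541 rather than returning infinity.
Neighbor-joining is the standard Saitou–Nei agglomeration; ties in Q are
broken by the lexicographically smallest pair of cluster labels (a cluster
is labelled by its smallest leaf name), negative branch lengths are
clamped to zero with the deficit moved to the sister branch, and Newick is
emitted with six decimals. On additive matrices the output reproduces all
path lengths exactly (property-tested against randomly generated trees).

## Synthetic data

The generators emulate the statistical structure each pipeline stage
assumes, under a single integer seed.

* **Proteins**: length 180, exactly six cysteines at well-separated
  positions (minimum gap 8), remaining residues uniform over the other 19
  letters; a planted matching in the adjacent, interlocked, or random
  pattern.
* **Peak lists**: sequential tryptic/chymotryptic digest (up to 2 missed
  cleavages, lengths 2–30), two species planted per bridge, each emitted
  at charges 1–4 with multiplicative mass error ~N(0, 2 ppm), plus 5×
  uniformly distributed decoy peaks; every peak is recorded in a
  ground-truth ledger. Planted species use peptides carrying exactly one
  cysteine each — the form every bridged peptide in the published evidence
  takes — because a two-cysteine peptide makes the cysteine assignment
  mass-degenerate and the deterministic tie-break arbitrary; multi-cysteine
  peptides remain in the candidate search space. Bridges that admit too
  few species (cysteines too close to each other or a terminus) trigger a
  warning and protein regeneration from a derived seed.
* **Titrations**: eight points over 2–16 μM with 1% proportional Gaussian
  noise, from the one-site model (saturation) or the unit-slope
  displacement model with IC₅₀ = K_d·(1 + [probe]/K_probe) (competition).

What the generators do *not* model — chromatography, intensity/isotope
structure, correlated mass error, real spectral noise in MS2, free-probe
depletion — bounds what passing tests show: recovery rates and fit biases
demonstrate correctness of the computational pipeline under its stated
noise model, not performance on raw instrument data.

## Problem sizes and determinism

The stock analyses use 100 seeded replicates for topology recovery and
for each binding-recovery condition; a replicate simulates one 180-residue
protein (~900 crosslink candidates, ~140 peaks) or one 8-point titration,
so each analysis completes in seconds. All randomness flows from
`numpy.random.default_rng` seeded per configuration; repeated runs are
bit-identical, and the writers emit full float precision so files
round-trip through the package's readers exactly.

## Known limitations

* No FDR control or target–decoy calibration for crosslink matches; the
  score is heuristic.
* Loop-links (intra-peptide bridges) and peptides with both termini
  aspecific are not enumerated; the evidence contains neither.
* The C-terminally anchored ungapped identity is a special-purpose
  comparison, not a general aligner.
* Reported dissociation constants can be validated only by
  simulation-recovery, since the underlying raw titration data are not
  published.
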