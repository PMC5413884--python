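# Methods

This note documents the models, defaults and numerical choices behind
`fernhnl`, and what the synthetic fixtures do and do not emulate.

## Discovery model

The pipeline assumes the study design of peptide-evidence-based enzyme
discovery: an assembled (isotig/contig) transcriptome of the active tissue,
and a list of peptide sequences identified by LC-MS/MS from an
activity-containing gel band. Spectral scoring, FDR control and assembly are
upstream of the package boundary — inputs are already-identified peptides and
already-assembled contigs.

**ORF model.** An ORF is ATG-initiated and extends to the first in-frame
stop; ORFs reaching the contig end without a stop are reported and flagged
3′-partial, because transcriptome contigs truncate. Within one stop segment
only the longest (first-ATG) ORF is reported. Coordinates are 1-based
inclusive on the forward strand with the stop codon inside the span,
following GenBank convention. Default minimum length is 50 aa: a ~20 kDa
target (~180 aa) sits far above it while micro-ORF noise is suppressed. The
ORF-calling convention of the original workflow is not documented anywhere;
these defaults are this package's own documented choice.

**Masses** are average (not monoisotopic) residue masses plus one water,
taken from the pyteomics composition tables, because the quantity is compared
against apparent gel-band masses, not against m/z values.

**Digestion and matching.** Trypsin cleaves C-terminal to K/R except before
P. Peptides shorter than 5 residues are treated as unmatchable noise;
candidate ORFs need ≥ 2 distinct peptides (the usual two-rank-1-peptides
identification criterion). Matching is exact substring search with I/L
equated by default (isobaric residues are indistinguishable to the
instrument). A peptide matching several ORFs is credited to all of them — no
parsimony/razor assignment, since isoform variants legitimately share most
peptides. Coverage is the merged-interval union length over protein length;
rounding happens only at reporting.

**Exclusion funnel.** Three independent filters, each computable in
isolation; finalists are their conjunction, so application order is
irrelevant:

* *Mass window*: pass iff |m − m₀| ≤ tol·m₀, defaults m₀ = 20 kDa,
  tol = 0.25. The fractional window stands in for the visual "band at about
  20 kDa" judgement; blue-native PAGE apparent masses are that uncertain.
* *Signal peptide*: a protein is flagged secretory when its first 30 residues
  contain ≥ 1 K/R within the first 8 (charged n-region) and an 8-residue
  window with mean Kyte–Doolittle hydropathy ≥ 2.0 (h-region). This explicit
  heuristic replaces an external predictor so the filter is deterministic,
  testable and replaceable; it is a coarse stand-in, not a SignalP
  re-implementation.
* *Known-protein similarity*: a candidate is excluded when its best
  Smith–Waterman hit against any reference reaches identity ≥ 0.40 **and**
  query coverage ≥ 0.50. Both cutoffs are package defaults declared in
  config; the original study's exact criteria are unpublished, so these are
  substitutes, not reconstructions.

Finalists are ordered by (distinct peptides desc, coverage desc, |m − m₀|
asc, id lexicographic) — a deterministic total order; excluded candidates are
reported with their failing flags rather than dropped.

## Alignment conventions

BLOSUM62 with BLAST-style affine gaps: a gap of length L costs
open + L·extend with defaults 11/1 (mapped to Biopython's PairwiseAligner as
open_gap_score −12, extend_gap_score −1). Identity = matches / full alignment
length including gap columns — a conservative, common convention; published
percent-identity figures that used a different denominator can differ by a
few points. Similarity counts columns with positive substitution score
("positives"). Translated search is exhaustive local alignment of the query
against all six frame translations of every transcript: at desk scale
(hundreds of contigs) no seeding heuristic is needed and results are exact
and deterministic. No E-value statistics are computed; selections combine an
identity threshold with a raw score floor.

## Kinetics

Michaelis–Menten fits use unweighted least squares (scipy `curve_fit`,
trust-region with non-negativity bounds), started from K_m ∈ {min, median,
max} of the probed concentrations with the best-SSE solution kept; a relative
weighting option exists. Standard errors come from the fit covariance. A fit
whose K_m lands more than three decades outside the probed concentration
range is flagged as failed rather than silently reported. The default
concentration grid is a 12-point two-fold dilution series 18 → 0.0088 mM,
the mandelonitrile cleavage-assay range.

Unit conversions: k_cat [s⁻¹] = v_max [µmol·min⁻¹·mg⁻¹] × M [kDa] / 60
(kDa ≡ mg/µmol); efficiency = k_cat/K_m [s⁻¹·mM⁻¹]; catalyst loading [mol%] =
100 · (mass/M) / substrate µmol. The benzaldehyde extinction coefficient for
photometric rate conversion is a config value — it is assay-specific and not
hard-coded. For two-phase cyanohydrin synthesis the enzyme is assumed active
in the aqueous phase only; with partition coefficient P = C_org/C_aq, mass
balance gives the de-facto substrate concentration C_aq = n/(V_aq + P·V_org),
exact to machine precision by construction.

## Structure analysis

PDB files are parsed via gemmi behind a light fixed-column validator (so
malformed coordinate lines are reported with their line number); the first
alternate location is kept and the REMARK 2 resolution is captured. Hydrogen
positions are ignored: polar contacts use heavy-atom distances with a 3.6 Å
ceiling, appropriate for typical ~1.8–2 Å crystal structures. Ligand contacts
list every protein residue with a heavy atom within 4 Å (default) of a ligand
heavy atom. The water chain is a greedy nearest-neighbour walk over water
oxygens from the water closest to a start selection, step limit 3.5 Å, ties
broken by lower serial number, with optional termination at solvent exposure
(< N protein heavy atoms within 5 Å). This is deliberately a chain semantics,
not a volumetric tunnel computation: it captures "a line of waters leaving
the site" and nothing more.

## Synthetic fixtures

The generator reproduces the statistical shape of the study conditions: 60
isotigs by default, one planted target ORF of 168 aa (~20 kDa at mean residue
mass), 3 isoenzymes with at most ⌊0.065·L⌋ point substitutions (identity
≥ 93.5% by construction, verified by alignment), evidence on exactly 36 ORFs,
exactly 6 of which survive all filters, and target peptide coverage 0.72
within one residue of rounding. Failing decoys split 0.4/0.3/0.3 between
wrong-size, signal-peptide and known-homolog classes (the real composition of
such candidate sets is never published; this mix is a free parameter, not an
inference). UTR flanks of 20–120 nt place planted ORFs in varying frames and
on both strands, with an in-frame stop planted directly before each start
codon so the ORF caller recovers exactly the planted protein.

Two deliberate deviations from naive uniform-residue simulation, both for
testability: planted proteins are assembled from *tryptic blocks* (fragments
of 5–22 residues ending in K/R, no internal K/R, no P after a cleavage site),
so every digest fragment is evidence-eligible and coverage planning by
subset-sum over fragment lengths is exact; and isoenzyme variants use point
substitutions only (no indels), so identity bounds are exactly computable.
Isoenzyme mutations are placed inside strictly more of the target's selected
evidence peptides than the variant receives private peptides, which
guarantees the planted target always carries the most distinct evidence and
ranks first. Back-translation uses a fixed most-frequent-codon table —
deterministic, and avoiding codon-usage modelling.

Consequently, passing the funnel tests shows the pipeline's logic is correct
under clean conditions; it does **not** show robustness to real-data
phenomena the generator omits: sequencing/assembly errors, chimeric contigs,
frameshifts, peptide identification errors, shared peptides between unrelated
proteins, non-uniform amino-acid composition, or codon-usage structure.
Kinetic noise is multiplicative Gaussian on the rate; real assay noise also
has additive and systematic components. Toy structures contain idealised
coordinates, not crystallographic ones.

## Determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; the seed is recorded in the truth table and the
report provenance block. Fixture generation, discovery reports and FASTA
output are byte-identical across reruns of the same seed and configuration.

## Known limitations

* The signal-peptide heuristic has no cleavage-site model and will miss
  atypical signal sequences; it exists to make the funnel reproducible.
* Identity definitions differ across tools; cross-tool comparisons of
  percent identity should expect small systematic offsets.
* Converting v_max to k_cat requires the molar mass actually used for the
  enzyme preparation; for multimeric or tagged constructs the choice is the
  caller's and materially changes k_cat.
* The translated search is exhaustive and scales as O(query × transcriptome);
  it is meant for desk-scale databases, not genome-scale scans.
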