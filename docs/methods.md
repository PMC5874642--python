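# Methods

`epiprof` implements the classic desk workflow for characterizing a protein
antigen candidate: physicochemical profiling, hydropathy analysis, linear
B-cell epitope prediction by the Kolaskar–Tongaonkar method, integration of
the epitope calls with membrane topology, and Ramachandran quality control
of a structural model. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data generators do and
do not emulate.

## Sequence handling

Proteins are validated against the 20 standard one-letter residues. The
default policy rejects non-standard letters (B, Z, X, U, O) because every
scale lookup downstream is undefined for them; a `mask` policy removes them
and records their positions instead. mRNA input is normalized U→T and
translated from frame 0 of the provided sequence with the standard genetic
code, stopping at (and excluding) the first stop codon — the input is
assumed to be the CDS itself, so no ORF scanning is performed. All
coordinates in the package are 1-based and inclusive, the convention of
epitope tables and topology files.

## Physicochemical descriptors

All descriptors follow the conventions of the widely used ExPASy ProtParam
tool, with every constant shipped as a versioned plain-text table:

- **Molecular weight**: sum of average residue masses (the ExPASy table)
  plus one water (18.01524 Da). The ExPASy masses differ from IUPAC-average
  tables by fractions of a dalton over a ~400-residue protein, which matters
  when matching published values to 0.01 Da.
- **Theoretical pI**: the unique root of the Henderson–Hasselbalch net
  charge over the termini and the D, E, C, Y, H, K, R side chains with the
  Bjellqvist pKa set, found by bisection on pH ∈ [0, 14] to |ΔpH| < 1e-4.
  The set includes residue-specific pKa overrides for the terminal residues;
  a consequence worth knowing is that *appending* an acidic residue can
  slightly raise the pI (it changes which residue carries the C-terminal
  pKa), while *inserting* one mid-sequence is a pure charge addition and
  behaves monotonically.
- **Charge counts**: negatives = Asp+Glu, positives = Arg+Lys; His is
  excluded, matching the ProtParam convention.
- **Instability index**: (10/L)·Σ DIWV(xᵢ, xᵢ₊₁) over the L−1 dipeptides
  with the Guruprasad weight table; values above 40 are called "unstable".
- **Aliphatic index**: X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) over
  mole-percents (Ikai).
- **GRAVY**: mean Kyte–Doolittle value over all residues.
- **Extinction at 280 nm**: 5500·Trp + 1490·Tyr, plus 125 per cystine pair
  (floor(#Cys/2)) in the oxidized estimate.
- **Half-life**: N-end-rule lookup of the N-terminal residue
  (mammalian reticulocyte / yeast / E. coli columns).

Full precision is kept internally; reports round MW, pI and the instability
index to 2 decimals and GRAVY to 3, matching how these numbers are
conventionally printed. Composition percentages are exact internally and
rounded only for display; note that the upstream tool prints composition to
one decimal, so published composition figures should be compared at that
precision.

## Hydropathy

A uniform moving window (default 9, the common server default; always odd)
over the Kyte–Doolittle scale, with the window mean attached to the center
residue; termini that cannot host a full window carry no score, and no edge
extrapolation is done. Runs of centers scoring above 1.8 — the classic
threshold for transmembrane character — are reported as hydrophobic
segments. The window-1 profile mean equals GRAVY exactly, which the tests
use as an internal consistency check.

## Kolaskar–Tongaonkar epitope prediction

The scale assigns each residue an antigenic propensity (shipped table,
values in (0.5, 1.5)). The procedure: average the propensity over every
overlapping heptapeptide; allocate each window's average ⟨Ap⟩ to one anchor
residue of the window; flag scored residues with ⟨Ap⟩ ≥ 1.0; report maximal
runs of at least `min_len` consecutive flagged residues as epitopes.

Two conventions are shipped because the method's description and the
behaviour of the hosted server that popularized it disagree:

- `described` (default): anchor = the **fourth** residue of the
  heptapeptide, `min_len` = 6 — the procedure as usually stated.
- `server`: anchor = the **third** residue, `min_len` = 7 — established
  empirically; this is the configuration that reproduces epitope tables
  computed with the hosted server, including the 14-epitope MIC-A table
  this package uses as its worked example.

Under `rule="conditional"` (the original publication's variant) the cut
drops to the protein's mean window propensity when that mean is below 1.0.

A protein's **overall antigenic propensity** is reported as the mean of the
raw per-residue scale values; this is the quantity conventionally quoted
against the 1.0 benchmark (for MIC-A it is 1.0289, while the mean over
heptapeptide windows is 1.0301 — the profile carries both).

### The reference MIC-A protein

The worked example is the 383-residue MIC-A precursor (the translation of
GenBank KY500939.1). The shipped FASTA is labelled *reconstructed*: the
sequence was assembled from the published epitope table (which pins 227
residues at exact coordinates) plus the canonical MIC-A precursor, and then
verified against every published descriptor of the protein — molecular
weight to 0.01 Da (a near-cryptographic checksum over the composition),
pI, both charge counts, the dipeptide-order-sensitive instability index to
0.01, GRAVY to 0.001, the composition percentages, and the six named
Ramachandran outlier residues. All checks pass, so the sequence is correct
with overwhelming probability. One row of the published epitope table is
internally inconsistent (a 62-residue string printed for a 63-position
span, with one residue dropped); the tests assert that row by content
rather than by its corrupted coordinates.

## Topology integration

The transmembrane HMM itself is out of scope; the module parses its
standard long-format output (segments labelled inside / outside / TMhelix
that must tile the sequence, with inside and outside never adjacent) and
classifies each epitope by the majority label over its residues, with the
deterministic tie-break TMhelix > inside > outside. The call's score is the
mean per-residue posterior of the assigned label when posteriors are
available, else the fraction of epitope residues carrying the label — an
operational definition; published "TMHMM score" columns have no stated
definition and are not claimed to be reproduced. The `antigenic_flag`
encodes the source study's bookkeeping convention (inside ⇒ antigenic); it
is a flag, not a biological assertion. A helix starting within the first 30
residues is flagged as a possible signal peptide.

## Backbone QC

phi(i) = torsion(C(i−1), N(i), CA(i), C(i)) and psi(i) = torsion(N(i),
CA(i), C(i), N(i+1)), computed with the IUPAC sign convention in
(−180°, 180°]; omega is computed and reported but not used in
classification. Angles are undefined at termini, across chain breaks
(C–N distance > 2.5 Å) and where backbone atoms are missing; such residues
are excluded from percentages and counted separately. PDB reading keeps the
highest-occupancy alternate location and preserves insertion codes.

Region definitions are a documented **rectilinear polygonal approximation**
of the general-case favoured/allowed regions (α, β and left-handed-α for
favoured; broader boxes for allowed), shipped as a plain-text table and
fully swappable. Membership is boundary-inclusive, with a point on an edge
assigned to the more permissive class. No Gly/Pro/pre-Pro special casing is
applied. Consequently the favoured/allowed/outlier percentages are
implementation-defined: they are *not* comparable against percentages
computed with density-based contours (e.g. the published 93.3/4.4/2.2 split
for the MIC-A homology model, whose coordinates are not deposited), and the
package makes no such claim. What is guaranteed, and tested, is the
geometry: build-then-measure round trips on a 30° phi/psi grid recover the
inputs to 1e-6°, and classification agrees with an independent
point-in-polygon oracle everywhere.

## Synthetic data

All generators are pure functions of (parameters, seed) — a single integer
seed, no global state — so every fixture is regenerable from a manifest and
byte-identical across runs.

- **Planted epitopes**: background residues are drawn from the scale's
  sub-1.0 entries (mean ≈ 0.87) and planted spans from its five highest
  entries (mean ≈ 1.27, contrast ≈ 0.40 ≥ any requested contrast up to
  that). Because every planted residue scores above 1.0 and every
  background residue below it, any heptapeptide fully inside a planted span
  must qualify and any all-background window cannot; recovery of spans of
  length ≥ 12 is therefore provable, up to window erosion of about 3
  residues at each edge (the tests assert the planted centers are always
  covered; recall is 1.0 over 50 seeds at contrast 0.15).
- **Back-translation** draws uniform synonymous codons and appends a stop,
  so CDS translation inverts it exactly. No real organism's codon-usage
  bias is emulated.
- **Backbone builder**: sequential internal-coordinate placement (NeRF)
  with fixed ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å;
  angles 111.2°, 117.2°, 121.7°), uniform phi/psi/omega. The α-helical
  defaults give a rise per residue of ≈1.5 Å.
- **Topology writer** emits TMHMM long format that round-trips through the
  parser.

What the generators do *not* emulate: realistic amino-acid composition or
evolutionary correlation, codon bias, posterior-probability structure of a
real topology predictor, or the side chains and non-ideality of real
structures. Passing tests therefore demonstrate algorithmic correctness on
inputs with the assumed statistical structure, not predictive accuracy on
real proteins (the underlying method's reported accuracy is about 75%).

## Problem sizes and defaults

The property studies run at sizes chosen to make the checks exhaustive yet
quick on a laptop: 500 random profiles for the caller/oracle comparison,
1000 random sequences for the physchem oracles, 50 seeds × 3 planted spans
for recall, a 12×12 phi/psi grid for the round trip, and 1000 random points
for the classifier/oracle agreement. The whole suite runs in a few seconds.

## Known limitations

- Only linear (continuous) B-cell epitopes; no conformational epitopes,
  no MHC/T-cell prediction, no immunogenicity claim.
- The pI model ignores His-tag-like contexts, phosphogroups and
  temperature; masses are average, not monoisotopic.
- The Ramachandran polygons are deliberately simple; swap in a custom
  region table for contour-grade classification.
- The `server` epitope convention is an empirical characterization of a
  third-party web service; the service itself is not archived here.
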