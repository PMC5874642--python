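# epiprof

Immunoinformatic profiling of protein antigens, built for vaccine-target
triage: given a protein (or its coding mRNA), `epiprof` computes the full
panel of ProtParam-style physicochemical descriptors, a Kyte–Doolittle
hydropathy profile, linear B-cell epitope predictions by the
Kolaskar–Tongaonkar method, the membrane-topology placement of each epitope
from TMHMM-style output, and Ramachandran backbone QC of a structural
model — as a library, a CLI, and a single machine-readable report.

The audience is anyone doing desk characterization of an antigen candidate
(for example a stress-induced NKG2D ligand such as MIC-A, the package's
worked example) who wants the classic web-server workflow as reproducible,
tested, offline code.

## The core method

For a protein x₁…x_L and the Kolaskar–Tongaonkar propensity scale a(·),
every overlapping heptapeptide gets an average antigenic propensity

    ⟨Ap⟩ᵢ = (1/7) Σ_{j=i}^{i+6} a(x_j),

allocated to one anchor residue of the window. Scored residues with
⟨Ap⟩ ≥ 1.0 are potentially antigenic, and maximal runs of at least
`min_len` such residues are reported as epitopes. The protein's overall
antigenic propensity is the mean of a(x_j) over all residues; values above
1.0 mark a promising antigen. Around this sit the standard descriptors
(MW, pI by Henderson–Hasselbalch bisection, instability index
II = (10/L)·Σ DIWV(xᵢ,xᵢ₊₁), aliphatic index, GRAVY), windowed
hydropathy with the 1.8 transmembrane threshold, majority-vote epitope
topology, and phi/psi classification against shipped region polygons.
See `docs/methods.md` for every convention and constant.

## Worked example

The package ships the 383-residue MIC-A precursor (translation of GenBank
KY500939.1; the FASTA is labelled *reconstructed* — see `docs/methods.md`
for how it was assembled and verified). With a TMHMM-style topology file
(here: outside 1–305, helix 306–328, inside 329–383):

```bash
MICA=$(python -c "from epiprof import tables; print(tables.reference_mica_path())")
epiprof epitopes "$MICA" --convention server --tmhmm mica.tmhmm
```

prints (abridged):

```
# overall antigenic propensity 1.0289
index  sequence     start  end  length  mean_ap  location       topology_score
1      LGPVFLLL...      3   66      64   1.0609  Outside        1.0
2      RMTLAHI         97  103       7   1.0296  Outside        1.0
...
12     STHPVPSG...    291  333      43   1.1184  Transmembrane  0.53488
13     EGPELVSL...    339  356      18   1.0874  Inside         1.0
14     TQLGFQPLMS     363  372      10   1.0315  Inside         1.0
```

Fourteen antigenic determinants are called; the overall propensity 1.0289
exceeds the 1.0 benchmark, so the protein as a whole is a promising
antigen; epitope 12 sits on the membrane helix (majority fraction 0.535 of
its residues), and the C-terminal epitopes fall on the cytoplasmic side.
The physicochemical panel for the same protein:

```bash
epiprof physchem "$MICA"
```

reports MW 42915.4 Da, pI 6.49, 41 negative vs 37 positive residues,
instability index 49.59 (called "unstable" in solution), GRAVY −0.429
(hydrophilic overall), aliphatic index 74.07, and leucine as the most
abundant residue (9.40%). The full pipeline —
`epiprof report "$MICA" --convention server --tmhmm mica.tmhmm [--pdb model.pdb]` —
emits one JSON report covering all stages, with skipped stages marked.

A `--translate` flag accepts the coding mRNA instead of the protein;
`epiprof ramaqc model.pdb` summarizes backbone phi/psi quality on its own.

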