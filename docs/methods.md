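# Methods

## Scope and design

The package compares two labelled protein populations along four axes:
amino-acid composition, sequence-level physicochemistry, salt-bridge
geometry, and backbone conformation. Sequence inputs are FASTA; structure
inputs are PDB coordinate files. All group statistics treat the two
populations as independent samples — even when the sets are homolog-paired,
the reported tests (independence χ², unpaired t) are population-level. An
index-matched pairing is used only for the optional cross-group correlation
rows, which require equal group sizes.

## Composition and Sturges binning

Each protein is reduced to the percentage of each of the 20 residues over
its full chain length (termini included). For a group of N proteins the
per-residue occupancy histogram uses Sturges class intervals:
k_raw = 1 + 3.322·log₁₀N, rounded half-up to k; class width
h_raw = (max−min)/k, rounded to the nearest integer (with a fallback to the
raw width when rounding would give zero). Both raw and rounded values are
kept on the `BinningScheme`. Because the edge list steps by the rounded h
from the range minimum and must cover the maximum, the realised bin count
can exceed k (N=200 over 0–20% gives k=9 but ten 2-point classes); the
scheme records both. Bins are half-open [lo, hi) with the final bin closed,
so a value equal to an internal edge belongs to the upper class. In the
pipeline the binning range defaults to 0–20%; if any observed percentage
exceeds the last edge, the final bin is extended to the observed maximum
rather than rejecting the protein.

## Net charge and isoelectric point

Charge is modelled with one Henderson–Hasselbalch term per ionizable group
class (Asp, Glu, Cys, Tyr, C-terminus acidic; His, Lys, Arg, N-terminus
basic), each fully independent — no electrostatic coupling, no
structure-aware pKa shifts, and all cysteines treated as free thiols. The
default pKa table (N-term 9.0, C-term 3.1, Asp 3.65, Glu 4.25, Cys 8.3,
Tyr 10.07, His 6.0, Lys 10.5, Arg 12.5) is a textbook-style set; it
reproduces the classic ribonuclease Sa benchmark (7 Asp, 5 Glu, 2 His,
0 Lys, 5 Arg + termini → integer charge −7 at pH 7, flipping to +3 after
five Lys-for-acid replacements). An EMBOSS-style table is included and the
set is swappable via config, since published pI values vary by about half a
pH unit across pKa dialects. Q(pH) is strictly decreasing, so the
isoelectric point is found by bisection on [0, 14] to machine precision;
the implementation is checked in the tests against a 10⁻⁴-step grid scan.
Note that at the interval boundaries the charge has not fully saturated for
Arg (pKa 12.5 leaves a ~3% residual per Arg at pH 14); the limit properties
Q→#basic / −#acidic are therefore exact only slightly outside the titration
window.

Reported charges are kept raw for statistics; an integer-rounded value
(half away from zero) is added for display, matching how such numbers are
conventionally quoted.

## Salt bridges

A salt bridge is recorded when the minimum distance between a side-chain
carboxylate oxygen (Asp OD1/OD2, Glu OE1/OE2) and a side-chain nitrogen
(Lys NZ; Arg NH1/NH2/NE; His ND1/NE2) is within the cutoff, default 3.2 Å
(the VMD saltbr oxygen–nitrogen default). His nitrogens are included
deliberately so that ASP-HIS and GLU-HIS dyads are counted. Multiple atom
contacts within one residue pair collapse to a single record (bridges are
counted, not atom contacts). Missing side-chain atoms silently exclude a
pair. Rates are reported per 100 residues of the structure; dyad
composition as a percentage of bridges found. The detector is validated
against a brute-force all-pairs scan with the same atom sets on randomized
structures.

## Backbone torsions and Ramachandran accounting

φ(i) = C(i−1)–N(i)–CA(i)–C(i), ψ(i) = N(i)–CA(i)–C(i)–N(i+1),
ω(i) = CA(i−1)–C(i−1)–N(i)–CA(i), signed by the IUPAC convention and
reported in (−180°, 180°] (cross-checked against Biopython's
`calc_dihedral`). A peptide bond with C–N distance > 2.5 Å is treated as a
chain break: no torsion spans it. Residues missing N/CA/C are skipped and
their neighbours' dependent angles left undefined.

Region classification uses rectangular windows, a deterministic,
fully-editable stand-in for density-contour tables (which are not published
in a reusable form by the classic structure-analysis servers): helix
φ∈[−160,−45], ψ∈[−70,−5]; sheet φ∈[−180,−45], ψ∈[90,180]∪[−180,−150];
left-handed helix φ∈[35,90], ψ∈[−10,70]; a bridging band φ∈[−180,−45],
ψ∈(−5,90) counted as core loop/turn; a disallowed rectangle (φ>0 with
ψ∈[−120,−30]) for non-Gly residues; everything else is an outlier. Glycine
additionally tries the point-mirrored coordinates (no Cβ); proline is
restricted to φ∈[−110,−35]; pre-proline residues are tallied but use the
generic windows. Because the windows are rectangles rather than fitted
contours, absolute region percentages on real structures will differ from
contour-based servers; within-pipeline group contrasts are the supported
use. Planarity: cis |ω| ≤ 30°, trans within 20° of ±180°, nonplanar
otherwise — conventional crystallographic thresholds, both configurable.
The outlier percentage is computed per chain and then averaged (mean and
range), mirroring chain-wise reporting; all other region percentages are
over residues with both φ and ψ defined. The count of HETATM-excluded
residues is carried through as "non-protein" for table parity but never
classified.

## Tyrosine-site scan

The Tyr scanner is rule-based and labelled as such in every output
("rule-based, not GPS"): `all_tyr` enumerates every tyrosine;
`acidic_flank` (default) keeps tyrosines with ≥1 Asp/Glu within ±4
positions, a crude acidophilic-kinase-motif proxy. It is a declared
stand-in for trained phospho-site predictors, which are out of scope;
its rates support group contrasts, not site-level prediction.

## Statistics

χ² of independence on the 2×K group-by-bin table, from the defining formula
with expected counts from the margins and no continuity correction. Columns
whose expected count falls below 5 in either row are merged into the
nearest lower-index column first (Cochran guidance); df = K′−1 after
pooling. The two-sample t is pooled-variance (Student); Pearson r carries
the usual t-based two-sided significance. Statistic values are computed
from the formulas; tail probabilities come from scipy's reference
distributions, and all three are cross-checked against scipy.stats in the
tests. No multiple-testing correction is applied to the per-residue χ²
table. Significance tiers (p<0.05/0.01/0.001) appear as star annotations
only.

## Synthetic data

`generate_sequences` draws i.i.d. residues from a per-group frequency
vector, with lengths from a truncated normal (minimum 30). The default
vectors place the thermophile-like group higher in Ala (10% vs 7%), Gly
(9% vs 6%), Val (8% vs 6.5%), Glu (9% vs 6%), Asp, Pro, Tyr and Cys, and
lower in Gln (2% vs 4.5%), Asn and Arg (3% vs 5.5%), with mean lengths
301 vs 328; these directions are the contrasts the pipeline is designed to
detect, with magnitudes chosen once to be unambiguous at 200 proteins per
group. Because the acidic/basic balance is deliberately lopsided, the
synthetic group means of charge and pI are farther apart than real
homolog sets would be — the generator demonstrates direction recovery, not
realistic effect sizes. Residue order carries no signal (i.i.d.), so
motif-level statistics on these sequences are uninformative beyond their
composition; this is adequate for every statistic in the pipeline.

`build_backbone` places N/CA/C atoms by sequential natural-extension
(NeRF) internal-coordinate chaining with fixed bond lengths (N–CA 1.458,
CA–C 1.525, C–N 1.329 Å) and angles (N–CA–C 111.2°, CA–C–N 116.2°,
C–N–CA 121.7°), honouring requested per-residue φ/ψ/ω exactly (round-trip
agreement to 10⁻⁶ degrees). Planted salt bridges are Asp OD1 / Lys NZ
pseudo-atoms on the line between the two CA atoms at an exact target
separation — no rotamer realism, which is irrelevant to a detector that
only reads the named O/N atoms. Placement fails loudly if the CA
separation cannot accommodate the target distance.

`generate_study_fixture` writes the desk-scale study mirror: 2×200
sequences and 2×10 toy 60-residue structures, with 6 planted bridges per
thermophile-like structure vs 5 (exactly a 1.2× rate contrast) and a
helix-richer region mix (7 helix / 3 sheet vs 5 / 5). Within each group
the planted rate is constant, so the salt-bridge rate t statistic is
degenerate by construction; the supported comparison there is the group
mean ratio. All generator outputs are pure functions of spec + seed.

## Numerical choices and degenerate inputs

- Bisection for pI runs to interval width 10⁻⁹ (or tighter than the given
  tolerance), and requires a sign change — censuses with no acidic or no
  basic group raise rather than returning a boundary value.
- A pooled two-sample t with zero pooled variance returns t=0 when the
  means agree and raises when they differ (no finite statistic exists).
- Dihedrals raise on collinear consecutive points; ±180° are identified.
- PDB reading keeps the first model, the first alternate location, and
  standard residues only; OXT and other non-backbone atoms are carried but
  ignored by geometry operations.
- TSV outputs are byte-reproducible for a fixed config and fixture.

## Problem sizes

The shipped analysis and acceptance runs use the desk-scale fixture
(400 sequences of mean length ~300; 20 structures of 60 residues), which
exercises every code path in a few seconds while keeping all planted
contrasts decisively detectable. Larger inputs are supported directly; all
algorithms are linear or quadratic in chain length per structure.

## Known limitations

- Charge/pI ignore ionic strength, temperature and structural context.
- Ramachandran windows are rectangles; absolute percentages differ from
  contour-based tools.
- The Tyr scanner is not a predictor and its rates have no site-level
  meaning.
- Synthetic sequences are i.i.d.; synthetic structures are single-chain
  poly-Ala backbones with pseudo-atom side chains. Passing
  parameter-recovery tests shows the pipeline recovers planted contrasts,
  not that real thermophile/mesophile sets will show them.
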