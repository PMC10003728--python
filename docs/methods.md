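# Methods

## Scope and data model

The package analyses conformational ensembles of single antibody variable
domains.  An `Ensemble` holds ordered frames of backbone coordinates
(N, CA, C per residue, Å) for one domain, optionally with experimental
Cα B-factors taken from the reference (first) model — experimental
flexibility is a property of the deposited structure, not of the
simulation, so later models never overwrite it.  Residues are indexed
0-based and contiguous internally; author PDB numbering is metadata only,
because insertion codes in antibody numbering schemes make raw `resSeq`
unsafe as an array index.  Ensembles travel as multi-model PDB text; the
package neither runs simulations nor computes alignments — an MSA
(FASTA/Clustal) covering all domains is an input.

Every frame supplied is analysed with equal weight.  Subsampling or
stride selection is left to the caller.

## Protein Block assignment

Local backbone conformation is encoded with the 16-prototype structural
alphabet: residue *i* is described by the window
(ψ<sub>i−2</sub>, φ<sub>i−1</sub>, ψ<sub>i−1</sub>, φ<sub>i</sub>,
ψ<sub>i</sub>, φ<sub>i+1</sub>, ψ<sub>i+1</sub>, φ<sub>i+2</sub>) and
assigned to the prototype minimising the RMSDA, the root mean square of
the componentwise angular differences wrapped to (−180°, 180°].  The
prototype table ships as a documented package constant
(`data/pb_prototypes.tsv`, values from the original structural-alphabet
publication).  Angles are degrees end to end; torsions follow the IUPAC
sign convention (trans = 180°).  The two residues at each chain end have
incomplete windows and receive the out-of-alphabet label 'Z', as does any
position with an undefined window angle.  Exact RMSDA ties are broken by
alphabetical label order — an arbitrary but deterministic rule; ties have
measure zero on real data.

'Z' entries are excluded from both the numerator and denominator of
per-position block frequencies, so a column's `count` records genuine
observations; an all-'Z' column is flagged undefined and propagates as
NaN rather than as a number.

## Flexibility statistics

* `Neq = exp(−Σₓ fₓ ln fₓ)` (natural logarithm, 0·ln 0 := 0): the
  effective number of blocks sampled, in [1, 16].
* `ΔNeq = |Neq¹ − Neq²|`.
* `ΔPB = Σₓ |f¹ₓ − f²ₓ|` ∈ [0, 2]; `ΔAA` is the same statistic over the
  20 amino-acid letters with gaps and 'X' excluded.
* RMSF: Cα fluctuation about the ensemble mean after rigid-body fitting.
  Fitting is iterative (fit to the first frame, recompute the mean, refit
  to the mean) with the Kabsch solution constrained to proper rotations;
  by default all Cα atoms drive the fit, with an optional mask for
  core-only fitting.  Note that large-amplitude loops drag a global fit:
  quiet residues inherit some apparent motion, which is faithful to how
  practitioners compute RMSF but means baselines are not exactly zero.
* Normalisation: per-domain z-score `(vᵢ − μ)/σ` with the *population*
  standard deviation (the convention of the B-factor-normalisation
  literature); a sample-sd variant is available via `ddof=1`.  A constant
  profile is a hard error, not a silent zero.

## MSA projection and regions

Per-residue metrics are compared across domains in MSA-column space.  A
residue contributes to a column only where the domain has a residue
there; gap columns carry NaN, never zero, and every aggregation reports
its per-column occupancy.  Region intervals (FR1–4, CDR1–3, optional
CDR4) are 1-based inclusive column coordinates in configuration and
presets; the literature gives slightly different CDR boundaries in
different places (CDR1 starting at 25 or 26; CDR3 ending at 139 or 140),
so both variants ship as named presets (`main`, `alt`) and overlapping
intervals are resolved by CDR-over-FR priority, then by listed order.
The discrepancy is surfaced rather than silently merged.

## Clustering of dynamics profiles

The distance between two domains is the mean absolute difference of
their column-projected RMSF profiles over the columns where *both* are
present (pairwise deletion), matching the published formula
`d(v,w) = 1/(n−m) Σ|vᵢ−wᵢ|` with n − m the shared-column count — the only
reading of "number of gaps" under which a pair distance is well defined.
Although that formula is sometimes described as a normalised Euclidean
distance, it is implemented exactly as printed (mean absolute
difference); a root-mean-square variant is available behind a flag for
sensitivity checks.  An alternative metric averages per-column ΔPB over
columns defined in both domains.

Domains are grouped by agglomerative clustering with complete linkage
(scipy).  Flat clusters come from a user-supplied `k` (default 4) or a
height cut; since no published rule states how dense clusters and
singletons were separated, the implementation scans the dendrogram from
`k` flat clusters upward until at least `k` clusters reach the minimum
size (default 2), flagging smaller clusters as singletons.  Cluster
numbers are assigned by first appearance in the domain list, making
labels deterministic.  Clusterings are compared by a contingency table
plus the adjusted Rand index (label-permutation invariant).

## Flexibility quadrants

Crossing the per-domain normalised RMSF with Neq at thresholds 2.0 and
3.0 (both configurable) yields four classes: flexible (> 2 and > 3),
mobile (> 2 and ≤ 3), deformable (≤ 2 and > 3), rigid otherwise.  The
source definitions write strict inequalities for the two high-RMSF
quadrants and are silent at exactly Neq = 3; this implementation sends
that boundary to mobile so the four labels partition the plane.  The
deformable/rigid names for the two low-RMSF quadrants follow the
qualitative definitions of mobility and deformability (a rigid fragment
displaced as a whole vs local conformational change without net
displacement); only the two high-RMSF labels are normative.

Cluster-versus-dataset deviation profiles pool block counts over member
frames at each column (frame-weighted) and compare them with the pooled
dataset; amino-acid profiles weight each domain once, since sequences are
static.  CDR termini statistics use the domain's first and last occupied
column inside the CDR interval and report the per-frame CA–CA distance
mean and population sd; a domain absent from the interval yields a
flagged missing entry.

## Synthetic ensembles

The generator exists to give every stage a ground truth without bulky
trajectories.  What it emulates: per-position block mixtures with
controllable effective state counts; Gaussian positional noise with an
exact RMSF closed form (per-axis σ gives expected RMSF σ√3 without
fitting); multi-class families sharing a gapped MSA with class-specific
profiles.  What it does not emulate: force-field physics, side chains,
correlated loop motions, solvent, or the actual distribution of
nanobody conformations — so green tests demonstrate statistical and
algorithmic correctness, not biological realism.

Mechanisms:

* **Window generator** — draws a source block per frame/position by
  weight, emits its prototype 8-vector plus wrapped Gaussian angular
  noise (degrees).  Deliberately bypasses chain consistency so the
  assignment/frequency pipeline has exact per-draw truth.
* **Backbone builder** — sequential internal-to-Cartesian (NeRF)
  placement under ideal bond geometry (N–CA 1.458 Å, CA–C 1.525 Å,
  C–N 1.329 Å; angles 111.2°/116.2°/121.7°), ω fixed at 180°.  Dihedral
  extraction inverts it to numerical precision.
* **Family generator** — two orthogonal mechanisms drive regions into
  target quadrants: rigid per-region translations (per-frame shared
  Gaussian shift; global displacement with unchanged internal dihedrals:
  mobility) and switching among up to six backbone dihedral states
  chosen so that each state, repeated along a segment, assigns to a
  *different* block with a wide RMSDA margin (local diversity: Neq ≈ k).
  State conformers are rebuilt per domain and Kabsch-aligned onto the
  base region to minimise incidental displacement.  Flexible regions use
  both mechanisms; deformable regions use states only.  Gaps are inserted
  at region edges only, never in the 5-column core a block window needs,
  and ground-truth quadrant labels are emitted for core columns only.

Two layout constraints matter.  First, a z-score saturates at
√((1−p)/p) for a hot fraction p of the chain, so targeted loops must
stay a small fraction of the domain (the default layout uses four
7-column loops on 120 columns, p ≈ 0.12) or no region can clear the
normalised-RMSF threshold of 2.  Second, deformable is inherently
relative: a domain consisting only of a deformable loop z-scores that
loop above 2; deformable targets land as intended when the domain also
carries at least one mobile or flexible region, as real domains do.

All generators are pure functions of (spec, seed); identical seeds give
bit-identical output.

## Numerical choices and problem sizes

Angles wrap to (−180°, 180]; coordinates are float64 Å.  Frequency
vectors validate to Σf = 1 within 1e−9; undefined statistics propagate as
NaN, never as 0.  The test suite exercises the pipeline at deliberately
modest sizes — 10⁴ random vectors for oracle equivalence, 2000-frame
ensembles for the sampling closed forms, 20-domain families for
parameter recovery — chosen so the statistical assertions (3-standard-
error bands, ≥ 0.9 ARI, ≥ 90 % quadrant recovery) have comfortable power
at fixed seeds.

## Known limitations

No mmCIF input, no antibody renumbering (Kabat/IMGT/Chothia), no
structure repair, no DSSP secondary structure, no trajectory formats
beyond multi-model PDB in the core (binary formats can be converted
upstream).  Neq is estimated without small-sample bias correction, so
short ensembles underestimate conformational diversity.  Dataset-specific
biology (particular cluster memberships, per-CDR medians) depends on the
ensembles analysed and is not asserted anywhere in the package.
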