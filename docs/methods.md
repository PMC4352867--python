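# Methods

## Scope and data model

`glycodelta` compares glycosylated (GP) and deglycosylated (P) forms of
the same protein along two arms: a static arm over pairs of PDB
structures and a dynamic arm over coordinate trajectories. Structures
are held in a small hierarchical model (chains → residues → atoms) read
from fixed-column PDB v3 text. Residue identity follows author
numbering (chain id, residue number, insertion code) because
glycosylation sites are conventionally referred to that way (e.g.
Asn-60). Alternate locations are collapsed to the highest-occupancy
conformer (ties: first in file). CONECT records are kept as a
serial-number bond-hint table. mmCIF, assemblies and B-factor analysis
are out of scope. Multi-model files yield the first model when read as
a structure; the trajectory loader reads every model.

Nonstandard amino acids (MSE included) map to `'X'` in one-letter
sequences. The pair matcher demands strict identity, and mapping MSE to
`'M'` would let a selenomethionine variant silently match a methionine
sequence; `'X'`-to-`'X'` matching keeps the contract exact.

## Glycan annotation

Saccharide recognition is name-based against a configurable vocabulary
of PDB chemical-component codes (NAG, BMA, MAN, FUC, SIA, …).
Geometric ring detection is deliberately omitted: name matching is
deterministic and mirrors how carbohydrate components are deposited; a
sugar-shaped residue under an unknown code is not detected, and the
vocabulary is the extension point.

A glycosylation site is reported when an Asn ND2 (N-linked) or Ser
OG / Thr OG1 (O-linked) atom lies within **1.9 Å** of a saccharide
anomeric carbon (C1 preferred; any sugar carbon if C1 is absent), or
when a CONECT record links the residues. The cutoff covers C–N/C–O
covalent bonds (~1.43–1.45 Å) with crystallographic tolerance while
staying well below nonbonded contact distances (≥ 2.4 Å). Glycan size
is the number of saccharide residues in the connected component rooted
at the attached sugar, where two sugars are bonded if an O–C atom pair
between them is ≤ 1.9 Å or a CONECT joins them. Sites whose sequence
context violates the Asn-X-Ser/Thr (X ≠ Pro) sequon are reported with a
`sequon_ok=False` flag rather than dropped — a covalent attachment is
evidence regardless of the motif.

Protein–glycan hydrogen bonds use a heavy-atom criterion: N/O on the
protein side within **3.5 Å** of N/O in the site's glycan tree, with no
angular term. A distance-only rule is crude but fully stated and
testable; with hydrogens absent from most crystal structures any
angular term would itself be a model.

## Pair sets

Chains are filtered per entry by greedy redundancy removal in file
order at **90%** global-alignment identity, then by a **50-residue**
minimum length (shorter chains rarely have well-defined tertiary
structure). Identity is matches divided by alignment length, so gaps —
terminal gaps included — count against identity; this denominator is
conservative and unambiguous. GP/P pairs are all
(glycosylated, carbohydrate-free) chain combinations with exactly
identical sequences — exact string equality replaces a sequence-search
tool, which is the same contract with no external dependency. P/P
pairs are all unordered combinations of carbohydrate-free chains whose
sequence also occurs among the glycosylated chains, giving a baseline
for pure crystal-condition variability. Pairs are clustered at 100%
sequence identity (plus the site, for local analyses) and cluster means
feed cumulative histograms: fraction of clusters ≤ t for RMSD, ≥ t for
TM-score.

## Similarity scoring

Superposition is the closed-form Kabsch solution (SVD of the
cross-covariance; smallest singular direction flipped when the optimal
orthogonal matrix would be a reflection). Collinear point sets are
flagged degenerate — the RMSD is still unique — rather than rejected.

Residue equivalence between pair members is fixed by Needleman–Wunsch
global alignment (match +1, mismatch −1, gap −2) of the one-letter
sequences; only identically matching columns enter the correspondence.
This absorbs numbering offsets and missing loops, which defeat naive
number-based pairing even at 100% sequence identity. Mapped residues
lacking a Cα in either member are dropped from scoring.

TM-score uses the fixed correspondence (structural alignment search is
out of scope because pair members are sequence-identical), normalized
by the carbohydrate-free member's length L with
d₀ = 1.24·(L−15)^{1/3} − 1.8, floored at 0.5 Å, defined for L ≥ 20.
The score is maximized by seeding superpositions from the full
alignment plus contiguous fragments (L/2 and L/4 windows, half-window
stride) and iterating "superpose on residues with dᵢ < d_cut, rescore"
until the included set stabilizes, with d_cut = max(d₀, 2 Å) relaxed in
0.5 Å steps whenever fewer than three residues qualify; the maximum
over all visits is returned, so the result can never fall below the
single full-set superposition score.

The local shell around a site is every residue whose Cα lies within
**15 Å** (inclusive) of the glycosylated Asn's Cα, defined on the
glycosylated member only (for P/P pairs, on member A at the site
inherited from the GP set). Local RMSD superposes on the mapped shell
residues only — the default, consistent with least-squares fitting of
the equivalent local pairs — with a `superpose="global"` mode that fits
globally and measures over the shell, for comparison.

## Trajectory analysis

Trajectories are ordered Cα frames for a fixed selection, read from
multi-model PDB. An inclusive author-number range can restrict the
selection before any analysis (used for weakly coupled two-domain
systems, where only the glycan-bearing domain is informative); frame
superposition then uses the analyzed selection only. RMSD is measured
per frame against the initial structure after rigid superposition. The
RMSF reference is the average structure of the trailing window (default
fraction 0.25, mirroring a last-50-of-200-ns convention): window frames
are fitted to the window's first frame and averaged, then the fit
target is refined by re-superposing onto the running average and
re-averaging, twice (converged on all fixtures). RMSF_j is the root
mean square, over window frames fitted to that reference, of the
deviation of residue j. Replicates are summarized by the grand mean
and SE = sd/√R (SE = 0 flagged when R = 1). The residue with the
largest RMSF increase upon deglycosylation is reported with its Cα
distance to each site; ties break to the lowest residue number.

## Statistics

The comparison is a one-tailed paired t-test by system: d = P − GP,
t = mean(d)/(sd(d)/√n), df = n − 1, p the upper tail, significance
declared at p < 0.05 (strict). Zero-variance inputs are resolved
explicitly instead of NaN: all-zero differences give p = 0.5, constant
nonzero differences give p = 0 or 1 by sign; both carry a `degenerate`
flag. Only the two planned tests (RMSD, RMSF) are run, so no
multiple-testing correction is applied.

## Synthetic data: what it emulates and what it does not

Toy proteins are ideal-geometry Cα traces (helix: 1.5 Å rise,
100°/residue, radius 2.28 Å giving 3.8 Å Cα–Cα; extended; or an
L-shaped two-domain helix) with minimal N/CA/C/O backbones and
outward-pointing Asn/Ser/Thr attachment atoms at designated sites.
Filler sequences exclude N/P/S/T so sequon context is controlled
exactly. Mock glycans are linear NAG-code placeholders wired at
covalent geometry (C1 1.45 Å from ND2, glycosidic O–C 1.43 Å) with
CONECT hints — detection keys on names, distances and connectivity, not
carbohydrate chemistry. Perturbations are Gaussian coordinate noise,
loop translations, and domain rotations about a hinge Cα. Corpus
generation writes GP and P entries per sequence (P copies carry 0.3 Å
noise as stand-in for independent crystallographic determinations,
chosen so pair RMSDs land in the sub-ångström range typical of
redeterminations) along with a truth manifest computed from the filter
rules by plain combinatorics.

Trajectory frames are base + sustained displacement + iid Gaussian
noise with per-residue amplitudes σ_j, optionally under a slow rigid
drift to exercise superposition. Independence across frames and
residues gives the closed-form expectation RMSF = σ√3 and makes
parameter recovery checkable; it also means no correlated motions, no
relaxation times and no solvent — so passing tests demonstrate the
estimators and the statistics, not force-field realism. One caveat the
tests exposed: the ideal helix has a screw symmetry (rotation about its
axis ≈ translation along it), so perturbations constructed along that
symmetry are nearly invisible to optimal superposition; fixtures use
off-axis perturbations.

The packaged dynamics experiment uses 6 systems × 3 replicates per
form, 40-residue systems and 60-frame trajectories (sizes chosen to
keep the simulation cheap while leaving sampling error well below the
effects measured). Per-system mean amplitudes are drawn uniform on
0.2–0.5 Å (±30% per residue), with deglycosylated amplitudes 1.15× the
glycosylated ones. Each run additionally receives a sustained loop
displacement drawn uniform on 0–6 Å — identically distributed for both
forms, emulating conformational changes (loop movement, domain
rearrangement) that are not caused by the glycan, with some runs
transitioning far and others barely moving. Under these conditions
mean RMSD against the initial structure is dominated by the
glycan-independent displacements while RMSF cleanly tracks the
amplitude contrast, so the paired RMSF test is significant and the
paired RMSD test is not — the qualitative outcome the pipeline is meant
to resolve.

## Numerical choices and degenerate inputs

- Kabsch requires ≥ 3 points; covariance rank < 2 sets a degeneracy
  flag. Proper rotations only (det = +1).
- Sequence-identity alignment uses a small gap penalty (−0.1) so gaps
  open only when they buy matches; identity of 1.0 short-circuits the
  aligner.
- Shell boundaries, residue ranges and length filters are inclusive
  (≤ 15 Å, ≥ 50 residues) as documented at each operation.
- Empty inputs raise (empty chains, empty histograms, n < 2 t-tests,
  < 3 mapped Cα) rather than returning silent placeholders; the one
  deliberate exception is a corpus with no pairs, which completes with
  a logged warning.
- All generators are deterministic given (spec, seed); replicate seeds
  are spawned from the master seed via `numpy` `SeedSequence`.

## Known limitations

Saccharide recognition misses sugars under non-vocabulary codes.
Glycan counting is per residue, with no branch topology or anomeric
annotation. The hydrogen-bond rule has no angular term. The synthetic
corpus cannot reproduce corpus-scale fractions reported from full-PDB
snapshots, and the synthetic trajectories cannot reproduce
absolute RMSF values from long explicit-solvent MD; both arms verify
the machinery and the inferential logic, not those numbers. Binary
trajectory formats are not read; convert to multi-model PDB first.
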