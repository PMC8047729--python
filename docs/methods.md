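# Methods

`fibrilscreen` implements a computational route from an amyloid-fibril
structure to a ranked small-molecule series: define a surface pocket, build
its exemplar pseudoligand, screen a library by pharmacophore alignment, fit
radioligand binding data, and correlate relative binding free energies with
pose scores to judge which fibril polymorph best explains a SAR series.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Structures and pockets

PDB coordinate records are read through biotite; alternate locations
collapse to the highest-occupancy conformer. A pocket is a set of residues
(author numbering) on selected chains plus one anchor residue; a serial
residue index across chains is available as an alternative addressing mode
because fibril depositions are referred to in both conventions and the two
cannot always be reconciled. The "central strand" defaults to the middle
chain in file order and is overridable.

Polar amide hydrogens are rebuilt on backbone nitrogens when the deposition
has none (N–H 1.01 Å along the outward bisector of N–CA and N–C(prev));
chemotyping needs donor-H directions and ssNMR/cryo-EM depositions vary in
hydrogen content. No other hydrogens are built.

Pocket superposition between two structures uses the Kabsch algorithm
(SVD, proper rotation enforced) on CA atoms by default, all atoms
optionally, and reports RMSD. A single idealized straight strand is
degenerate for CA-only superposition; the implementation rejects collinear
point sets rather than returning an arbitrary rotation.

## Exemplar generation

The pocket is cast onto a uniform grid (default spacing 0.75 Å, margin
3.5 Å around the pocket bounding box). Grid points are kept when they are
outside every van der Waals sphere inflated by a 1.4 Å solvent probe,
within 12 Å of the anchor-residue centroid, and 6-neighbour connected to
the accepted point nearest that centroid. Fixed element radii are used
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.10 Å) for reproducibility rather than
force-field fidelity.

Each accepted point is chemotyped by the protein feature it faces:

* **ACCEPTOR** — 2.5–3.5 Å from a protein donor hydrogen, within 45° of the
  N→H axis;
* **DONOR** — the same window along an acceptor-oxygen lone-pair direction
  (the attached-heavy-atom→O axis); protein-side acceptors are restricted
  to oxygens, which covers carbonyl/hydroxyl chemistry on fibril surfaces
  (histidine-type N acceptors are a known omission);
* **HYDROPHOBIC** — at least 3 apolar heavy atoms (C, S) within 4.5 Å and
  no polar heavy atom (N, O) within 3.5 Å.

Polar labels take priority over hydrophobic; a donor/acceptor conflict is
resolved by the closer interaction partner, donors winning exact ties.
Surviving points are thinned greedily to a 1.5 Å minimum separation,
visiting points by (chemotype priority, grid index) so the output is
deterministic. All thresholds live in `ExemplarParams` and are
config-exposed. Exemplars serialize to a one-point-per-line text format, a
JSON parameter sidecar, and a pseudo-PDB (HETATM per point, element coding
the chemotype) for visualization.

## Pharmacophore models, overlap and alignment

Molecules and exemplars reduce to sets of spherical Gaussian features.
Molecule rules: DONOR at each O–H/N–H heavy atom; ACCEPTOR at each N/O
with an available lone pair, excluding amide and quaternary nitrogens
(pyrrole-type aromatic N–H therefore still counts as an acceptor — a
deliberate simplification); HYDROPHOBIC at the centroid of each
all-carbon/sulfur ring and of each connected acyclic cluster of ≥3 apolar
heavy atoms. SMILES inputs get one ETKDG conformer from a fixed embedding
seed; SDF inputs use their first conformer.

The overlap volume between two models sums Grant–Pickup pair integrals
over features of matching kind,

    V_AB = Σ_ij h_i h_j (π/(α_i+α_j))^{3/2} exp(−α_i α_j d_ij² / (α_i+α_j)),

with a single default sharpness α = 0.7 Å⁻² and height 1 (exemplar point
weights map to heights). The score is the volumetric Tanimoto
T = V_AB/(V_AA + V_BB − V_AB). Hydrogen-bond direction vectors are not part
of the score; only position and kind.

Alignment maximizes T over rigid transforms with multi-start local
optimization: four principal-axes starts (the proper sign combinations)
plus seeded random rotations, refined by L-BFGS-B on a rotation-vector +
translation parameterization with an analytic gradient (the rotation part
uses the SO(3) left Jacobian). The returned pose is never worse than the
best start, so self-alignment is exact by construction. Screening uses 6
starts and 40 refinement iterations per molecule (converged on the
synthetic benchmark; the standalone `align` defaults are 20/150).

**Known metric property.** When the exemplar carries many more features
than a ligand, V_BB dominates the denominator and T becomes nearly linear
in V_AB. Placing several ligand features in one dense same-kind region of
the exemplar then raises V_AB more than the V_AA penalty, so randomly
placed feature sets can score comparably to a geometrically faithful
complement. The synthetic decoys therefore mismatch chemistry at the true
geometry (kind shuffles, deletions) — the recognition task the screen is
meant to test — rather than randomizing positions.

## Virtual screening

Every library entry is featurized and aligned to the exemplar; featureless
entries are skipped with a warning. Ranking is by Tanimoto descending with
ties broken by identifier; the top N (default 50) are flagged retained.
Each entry's alignment seed derives from (screen seed, library position),
so results are reproducible and independent of chunking. An optional
lead-like filter (250–350 Da, cLogP ≤ 3.5, ≤7 rotatable bonds) is off by
default. Two-dimensional similarity expansion uses RDKit path fingerprints
(2048 bits) with Tanimoto similarity; a greedy max-pairwise-similarity
diversity picker is provided but makes no claim to reproduce hand
selection.

## Binding assays

Single-point screens normalize counts to the specific window,
100·(sample − NS)/(total − NS), and compare compounds to a control with
one-way ANOVA plus Dunnett's many-to-one test. Adjusted p-values are
computed deterministically: conditioning on the shared control mean and
the pooled SD factorizes P(max_j |T_j| ≤ q) into a product over groups,
and the two integrals are evaluated by 64-node Gauss–Hermite and
Gauss–Legendre quadrature. The construction is exact for unbalanced group
sizes. Significance tiers follow the four-star convention
(0.0332/0.0021/0.0002/0.0001). A design in which every observation is
identical is flagged degenerate: F is NaN and all adjusted p-values are 1.

Competition curves fit Y = bottom + (top − bottom)/(1 + 10^(log x −
log IC50)) — one site, unit Hill slope — by unweighted least squares on
all replicate points (plotting conventions like mean ± s.d. describe
figures, not fits). The 95% CI is asymptotic on log10 IC50 and
back-transformed, hence asymmetric in molar units, matching how such
intervals are conventionally reported. Saturation data fit the hyperbola
Y = Bmax·X/(Kd + X) on specific binding (total minus nonspecific matched
on concentration and replicate, falling back to per-concentration means);
the Kd CI is handled the same way on the log scale. Requirements: ≥5
distinct concentrations spanning ≥2 decades (1 decade for saturation). No
ligand-depletion correction is applied.

## Pose scoring

The internal scorer is a deliberately simple stand-in with three terms:
soft-sphere repulsion Σ w_rep(1 − d/d₀)² below contact distance
(w_rep = 10), a polar–polar hydrogen-bond reward
−w_hb·exp(−(d − 2.9)²/(2·0.35²)) (w_hb = 2), and a pharmacophore-match
reward −w_pm·V(ligand, exemplar) (w_pm = 1). The receptor is held rigid —
no sidechain repacking — and only the ligand's six rigid degrees of
freedom are minimized (seeded multi-start Powell, descent guaranteed
because the start pose remains a candidate). Absolute values are
arbitrary; the SAR stage is validated on ordering and regression
properties, and externally computed score tables (CSV: compound_id,
structure_id, score) can be substituted wherever internal scores are used.

## SAR free-energy correlation

Experimental relative free energies use the log-ratio form
ΔΔG = R·T·ln(IC50/IC50_ref), R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, with T
defaulting to 310.15 K because the assays run at 37 °C. Simulated ΔΔG
divides score differences to the same reference compound by a fixed scale,
default 2.94 score units per kcal/mol; the division direction is an
assumption and the scale is a flag. Right-censored affinities (reported
only as a bound) are excluded from regression by default; an explicit
opt-in maps them to the bound. The reference compound enters the
regression at (0, 0) by default and can be excluded. Per structure, OLS of
simulated on experimental ΔΔG gives slope, intercept and R² (squared
Pearson correlation); Kendall τ measures rank agreement; structures rank
by R², then τ, then identifier.

## Synthetic ground truth

`make_groove` emits an idealized fibril groove as PDB text: parallel
strands (3.5 Å residue spacing along the strand, 4.8 Å stacking), with
flanking strands elevated 2.5 Å per step so the site is a concave channel,
and downward pseudo-carbons extending each strand to a common base depth so
the slab is solid and the only accessible region near the site is the
channel. Strand nitrogens sit off the CA axis (real strands zigzag; the
amide-H bisector is otherwise undefined). The central strand carries the
planted pharmacophoric sidechains — N–H for a donor, C=O for an acceptor,
a raised three-carbon patch for a hydrophobe — laterally staggered so the
site is not collinear (a collinear, uniformly spaced site makes kind
shuffles rigid translations of themselves). The default site plants five
features (donor, acceptor, hydrophobe, acceptor, donor), the size of a
typical lead-like pharmacophore model. The manifest records placements,
interaction axes, complementary ligand sites, counts and the seed; every
test reads ground truth from the manifest only.

`make_library` builds one active whose fragments sit exactly on the
complementary sites (formaldehyde O on acceptor sites, methanol O–H on
donor sites — carrying an incidental acceptor feature, as real hydroxyls
do — cyclopropane on hydrophobic sites, as disconnected fragments with
explicit coordinates) plus decoys that keep the geometry but break the
chemistry: kind-shuffled, one-feature-deleted, and feature-poor
single-hydrophobe molecules.

Assay simulators draw counts from the same curve models the fitters use,
with multiplicative Gaussian noise (CV-parameterized, truncated at −3σ so
counts stay positive) — counting-assay error scales with signal. Defaults
mirror the published designs: competition uses 12 concentrations log-spaced
10 pM–10 µM with n = 3 and TOTAL/NONSPECIFIC controls; saturation uses 8
concentrations 0.1–30 nM with a linear nonspecific term defaulting to 1%
of Bmax per nM (nonspecific binding was substantial in the motivating
assays). Noiseless data recover every generating parameter to ≤10⁻⁶
relative, tying the generators to the fitters' model definitions.

What the generators do not emulate: real fibril folds (the groove is
idealized, not a Greek-key cross-section), conformational flexibility,
radiochemistry (decay, molar activity, filtration losses), and plate
artefacts. Passing tests therefore demonstrate correctness of the
algorithms under the stated models, not performance on experimental
screens.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale: a
5-strand, 9-residue groove (~300 atoms, grids ≤ 40³), libraries of ~200
molecules, 1,000-replicate CI-calibration simulations, and 10,000-replicate
family-wise-error simulations. All randomness flows from named seeds
(numpy `SeedSequence` spawning for independent streams); generators are
pure functions of (seed, parameters), and the end-to-end pipeline produces
byte-identical outputs for identical configuration and seeds.

## Known limitations

* Rigid-ligand, rigid-receptor throughout: no torsional sampling, no
  sidechain repacking.
* One conformer per SMILES input by default.
* Three chemotypes only — no aromatic-vs-aliphatic distinction, charges,
  or exclusion volumes; H-bond directionality is used for exemplar
  chemotyping but not in the alignment score.
* The volumetric Tanimoto degrades as the exemplar grows much larger than
  the ligand (see the metric property above).
* Asymptotic (not profile) confidence intervals; they calibrate correctly
  at the simulated designs but can be optimistic for poorly identified
  fits.
* The internal pose score is not a physical energy; absolute values carry
  no meaning across systems.
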