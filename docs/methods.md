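# Methods

This note records the models, conventions and design choices behind each
analysis, the assumptions of the synthetic generator, and the limits of what
the test suite demonstrates.

## Structures, trajectories and selections

Structures are ordered atom lists with one coordinate set (Å); trajectories
are frame stacks over a shared topology with a fixed stride (default 20 ps,
the analysis stride the package assumes when a file carries no times).
Atoms are addressed as `chain:resid:name`, with insertion codes appended to
the resid and prime characters normalized (`C3*` ≡ `C3'`).  The PDB
reader keeps every ATOM/HETATM record including waters and ions, resolves
altlocs to the highest-occupancy conformer (ties alphabetically), and
reports parse failures with the line number; the writer refuses fields that
do not fit fixed columns (resid > 9999) rather than truncating.  Water
residues are recognized under HOH, WAT, TIP3 and SOL.  The XYZ dialect is
`count / comment (optionally "t= <ps>") / element x y z` per frame.

The selection language (`chain`, `resid a-b`, `resname`, `name`, `element`,
`water`, combined with `and`/`or`/`not` and parentheses) is evaluated with
a recursive-descent parser over boolean index masks; resolution is
deterministic, order-preserving, and inclusive on both range ends.

## Superposition and series metrics

Rigid-body superposition is the unweighted Kabsch SVD solution with the
determinant corrected to +1; sets with fewer than three atoms or collinear
geometry are rejected as degenerate.  RMSD series fit each frame on a fit
selection and measure on a possibly different selection (protein fit /
nucleic-acid measure is the intended separation); distances are plain
Euclidean per frame.  No periodic-boundary imaging is applied — inputs are
assumed whole molecules.

## Translocation vectors

The axis u is the unit vector through the two anchor atoms **in the
reference frame** and is held fixed for the whole series.  Recomputing the
axis per frame would mix axis rotation into the translocation signal; a
per-frame axis remains available behind `per_frame_axis=True` for
comparison.  Frames are superposed on a caller-chosen protein-core
selection before projection.  The analysis default excludes the bridge
helix (1067–1104) and trigger loop (1219–1265) from the Cα fit, since
those are the mobile elements; for toy systems without a hinge schedule
the entire helix serves as the rigid core (a wider fit suppresses the
rotation noise that a short flank at a long lever arm would transmit to
the probe).  The sign convention makes forward translocation positive.
Summaries report both the series mean (full or a trailing window) and the
final point, because a run can be characterized by either its average
register or its endpoint; both are emitted.

## Hinge metrics

Backbone dihedrals use the standard four-point torsion with the IUPAC sign
convention, verified against an independent implementation; termini yield
NaN.  Δψ is wrapped into (−180°, 180°], so a 170° → −170° change reads
+20°.

Helix bend angles fit one axis per flank as the principal component of the
flank's Cα coordinates after a 4-residue running mean (one helical turn),
which cancels the spiral so that an ideal straight helix reads < 1°; axes
are oriented N→C, with the end-to-end vector breaking eigenvalue ties.
Flanks require at least 4 Cα each.

Secondary structure uses the Kabsch–Sander electrostatic criterion
(E < −0.5 kcal/mol, with the amide H reconstructed 1.0 Å from N anti to the
preceding C=O when absent) and the DSSP bridge/turn patterns, reduced to
five classes: two consecutive 4-turns (or 5-turns; π folded into H) → H,
two consecutive 3-turns → G, bridge/ladder patterns → E (isolated bridges
folded into E), remaining turn residues → T, else C.  Residues missing the
carbonyl O are labeled C with a warning.  The bridge patterns follow the
DSSP reference code (`hb(i+1, j−1) ∧ hb(j+1, i−1)` for the offset
antiparallel case); with that orientation the assignment matches an
independent DSSP implementation exactly on ideal helices and two-strand
antiparallel sheets.

## Contacts and switch residues

Hydrogen bonds require donor–acceptor distance ≤ 3.5 Å and a D–H⋯A angle
≥ 120° at the donor; ion pairs require opposite formal charges with closest
charged-group heavy atoms ≤ 4.0 Å.  These cutoffs are package conventions,
exposed in `ContactCriteria`, not literature claims.  Donor/acceptor and
charge-group typing tables ship with the package (protein side chains,
backbone, nucleic acids including both phosphate-oxygen naming dialects,
water, Mg); unknown residue types are skipped with a warning.  Histidine is
neutral by default; a config set of `chain:resid` keys marks protonated
histidines as cations.  When a donor has no hydrogen in the input, the
backbone amide H is reconstructed geometrically; side-chain and water
donors without hydrogens and without a unique reconstruction fall back to
the distance criterion alone (the angle is waived).  The fast path uses a
k-d tree; tests assert exact set equality with O(n²) scans.

Occupancy is the fraction of sampled frames in which a residue pair has at
least one qualifying contact.  A switch call compares per-partner
occupancies between two ensembles; the score max_p |occ_A − occ_B| is
symmetric in the ensembles and invariant to frame order, and the default
call threshold of 0.5 encodes "holds a distinctly different partner in the
two ensembles" as an explicit knob.

## Hydration

A water's position is its O atom.  Defaults follow first-solvation-shell
(3.5 Å) and Mg inner-sphere (2.5 Å) conventions; "tightly bound" is a
residence definition — within the inner cutoff in ≥ 80 % of sampled frames
— which is this package's operational criterion, chosen because residence
separates coordinating waters from shell visitors robustly at the noise
levels of interest.

## Assay quantification

The runoff model is a single-phase rising exponential with free amplitude
(a flag pins A, e.g. to 1); fitting is Levenberg–Marquardt least squares
with standard errors from the asymptotic covariance.  With only four time
points the residual-based noise estimate behind those errors is poor, so a
known measurement σ can be supplied for absolute-σ covariance; the
Monte-Carlo calibration in the tests shows mean rate recovery within 5 %
and 1σ-interval coverage in the 60–80 % band under that option.  Fidelity
is reported as the raw error fraction err/(err+correct); gel backgrounds
are assumed pre-subtracted (an optional constant background could be added
per lane, deliberately out of scope).  Exo III pre/post fractions are
normalized over the two bands; replicate spread is summarized as the sample
SD across lanes.

## The synthetic toy TEC

The generator emulates the structural roles the analyses touch, not the
physics: an ideal α-helix (φ/ψ = −57°/−47°, giving the canonical 1.5 Å
rise and 100° twist) built by NeRF internal-coordinate chain construction,
numbered 1067–1104 to stand in for the bridge helix; pseudo LYS/ASP side
chains carrying one charged atom each for planted ion pairs; a rigid
two-strand ladder of DA/DT pseudo-nucleotides (one C3′ per residue, 3.4 Å
rise) as the translocating duplex; two MG ions, an ATP-like ligand with N3
and Pα atoms; resident waters pinned at planted distances, transient
visitors doing reflected random walks (0.4 Å/axis/frame, reflected at a
20 Å outer sphere and excluded from the 2.8 Å inner coordination sphere of
their center), and bulk waters on a jittered 3.1 Å grid.  Scheduled motions
are applied per frame from the exact built geometry: flank rotation about
an axis through the hinge Cα (bend), rotation of downstream atoms about
the hinge CA–C bond (plants Δψ exactly), ladder translation at the drift
rate, and repositioning of the swap residue's NZ next to its current
partner.  Isotropic Gaussian noise (default σ = 0.1 Å, a modest thermal
jitter) is added to every atom of every frame except frame 0, which is the
exact reference configuration every displacement metric is defined
against.  Everything is bit-reproducible from the seed; planted placements
closer than 1.5 Å between components are a hard error.

Preset scenarios mirror the qualitative contrast between the two
trigger-loop ensembles at study scale (525 frames × 20 ps = 10.5 ns):
the open-like preset drifts forward 0.3 Å/ns (~3 Å over the run), bends
30° early and holds it, keeps three resident waters at Mg-I and a hydrated
ATP N3, and holds the swapped ion-pair partner; the closed-like preset
drifts −0.2 Å/ns, stays straight, keeps one bound water and a dehydrated
N3, and holds the original partner.  These are planted magnitudes chosen to
mirror the biological contrast, not reproductions of any particular
simulation.

What the generator does **not** emulate: force fields, solvent structure
and electrostatics, correlated (non-isotropic) fluctuations, periodic
boundaries, realistic side-chain geometry, or base-pair-resolved duplex
mechanics (both toy probes ride one rigid ladder, so upstream and
downstream register cannot decouple as they do in a real hybrid).  Passing
tests therefore demonstrate that the *metrics* recover planted geometric
and statistical truths at realistic noise, not that any biological claim is
reproduced.

An ideal antiparallel two-strand β-sheet builder complements the helix for
secondary-structure validation; strand torsions are −139°/135° and the
second strand's rigid placement is refined numerically (Nelder–Mead over
the 6-dof transform) to the canonical 2.9 Å N–O registry.  It is
deterministic.

## Problem sizes and numerical tolerances

Recovery checks run ten seeds at 500 frames and ≈ 1 940 atoms (1 700 bulk
waters), the scale at which the whole suite stays fast while the statistics
are meaningful.  Tolerances follow the estimator noise: noise-free drift
endpoints to 0.05 Å; noisy (σ = 0.3 Å) drift via a 100-point trailing mean
to 3σ/√100; bend to 4°, Δψ plateau to 3°, switch scores ≥ 0.85 for planted
0.9/0.05 occupancies, resident-water counts exactly.  Single-frame endpoint
assertions allow 4σ because one frame carries full per-frame noise.
Exponential fits are exact (residual < 1e−8) on noiseless data.

## Known limitations

* The five-class secondary structure omits DSSP's I/B/S distinctions by
  design; boundary residues of helices and sheets can legitimately differ
  from other implementations by one residue.
* Contact typing is table-driven; exotic residues and modified bases need
  table extensions.
* No water-mediated bridges, π-stacking or energetic scoring of contacts.
* Minimum-image distances are not applied anywhere; boxed inputs must be
  pre-imaged.
* The selection grammar has no `within <r> of` clause; shell queries go
  through the hydration module.
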