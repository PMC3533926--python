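# tecdyn

Trajectory metrics and assay quantification for RNA polymerase elongation
complex (TEC) dynamics.

Multi-subunit RNA polymerases cycle between two conformations during each
nucleotide-addition step: a *catalytic* form in which the mobile trigger loop
closes over the NTP substrate, and a *translocating* form in which the loop
opens and nucleic acids slide forward by one base.  Comparing molecular
dynamics trajectories of the two forms requires a battery of quantitative
monitors — how far the DNA and RNA moved, how helices bend at their
glycine/proline hinges, which side chains traded their ion-pair and
hydrogen-bond partners, and how hydrated the active site is — plus the
standard in vitro readouts (elongation rates, fidelity, exonuclease III
translocation-state footprints) used to test the predictions.  `tecdyn`
implements those computations as a tested, reusable library with a command
line, and ships a synthetic toy-TEC generator so every metric can be
validated against planted ground truth without multi-gigabyte trajectories.

It is written for structural biologists and simulation analysts who have
elongation-complex trajectories (or gel quantifications) and want these
specific metrics with explicit, inspectable conventions.

## The metrics

**Translocation** is measured against a *translocation vector*: with u the
unit vector through two anchor atoms (3′ carbons bracketing the downstream
DNA/DNA duplex or the upstream RNA/DNA hybrid) in the reference frame, each
frame reports

d(t) = (x_probe(t) − x_probe(0)) · u

after superposing the frame onto the reference on a rigid protein core
(Kabsch least-squares fit).  Positive d is forward translocation; the
reference frame sits at (0, 0) by construction.

**Hinge dynamics** are tracked three ways: Δψ(t) = wrap(ψ(t) − ψ(0)), the
change of a hinge residue's backbone psi dihedral; the bend angle between
helix axes fitted (principal axis of the smoothed Cα trace, oriented N→C)
to the flanks on either side of a hinge, separating straight (B1) from bent
(B2) bridge-helix modes; and per-residue secondary-structure timelines using
the Kabsch–Sander hydrogen-bond energy

E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,  bond if E < −0.5

reduced to five classes {H, G, E, T, C} (α-helix, 3₁₀-helix, β-strand,
turn, coil).

**Switch residues** are side chains whose contact partners differ between
the closed and open ensembles.  For each candidate, per-partner occupancies
(fraction of frames with a geometric hydrogen bond or ion pair) are computed
in both trajectories and the switch score is max_p |occ_A(p) − occ_B(p)|;
a score ≥ 0.5 (configurable) flags a switch.

**Hydration** counts water oxygens within a shell of a named center (ATP N3,
RNA 3′-O, Mg-I) per frame, and calls a water *tightly bound* if it stays
within the inner coordination cutoff (2.5 Å) for ≥ 80 % of frames.

**Assays**: runoff accumulation is fit with f(t) = A(1 − e^{−kt}) by least
squares (rates reported relative to wild type with propagated errors);
competition-fidelity gels give the misincorporated fraction
err/(err + correct); exonuclease III band tables give pre/post-translocated
fractions and the fold change upon adding the incoming NTP.

## Worked example

The generator presets mirror the study conditions of a closed/open
comparison: 525 frames at 20 ps (10.5 ns), a 38-residue bridge-helix stand-in
numbered 1067–1104 with a hinge at 1079, a 12-bp nucleic ladder, two Mg ions,
an ATP-like ligand and explicit waters.

```python
from tecdyn.synthetic_data import (closed_tec_params, open_tec_params,
    build_toy_tec, simulate_trajectory, toy_downstream_spec, toy_upstream_spec,
    toy_hinge)
from tecdyn.translocation import translocation_series, translocation_summary
from tecdyn.hinge_dynamics import helix_bend_angle
from tecdyn.hydration import bound_waters

for tag, maker in (("closed", closed_tec_params), ("open", open_tec_params)):
    p = maker(seed=1)
    traj = simulate_trajectory(build_toy_tec(p), p)
    pts = translocation_series(traj, toy_downstream_spec(p), toy_upstream_spec(p),
                               fit_selection="chain A and resid 1067-1077 and name CA")
    up, down, end = translocation_summary(pts, window=50)
    bend = helix_bend_angle(traj.frame_structure(len(traj) - 1), toy_hinge(p))
    n, _ = bound_waters(traj, "M:1:MG")
    print(f"{tag:6s} downstream endpoint {end.downstream:+.2f} A  "
          f"trailing mean {down:+.2f} A  bend {bend:5.1f} deg  bound waters {n}")
```

prints

```
closed downstream endpoint -1.88 A  trailing mean -1.96 A  bend   0.9 deg  bound waters 1
open   downstream endpoint +3.25 A  trailing mean +2.99 A  bend  29.9 deg  bound waters 3
```

— the open-like run is forward-translocated by ~3 Å with a stably bent
(~30°) helix and three Mg-bound waters, while the closed-like run is held
back (~−2 Å), straight, and dehydrated to a single bound water: the planted
contrasts are recovered quantitatively.  On the assay side,

```python
from tecdyn.assay_quant import ntp_stimulation
fold, pct = ntp_stimulation(0.25, 0.51)   # post fraction without/with NTP
print(f"fold {fold:.2f}, percent increase {pct:.0f}%")
```

prints `fold 2.04, percent increase 104%`: a post-translocated fraction
moving from 25 % to 51 % is an approximately 2-fold stimulation.

The same pipelines are available from the shell, e.g.

```
tec-dyn simulate tec --preset open --seed 1 --out-prefix scratch/open
tec-dyn translocate --top scratch/open.pdb --traj scratch/open.xyz \
    --spec downstream --fit "chain A and resid 1067-1077 and name CA" \
    --out scratch/trans.tsv
tec-dyn compare --config compare.yaml --out-dir scratch/out
```

`compare` runs the full closed-vs-open workflow (translocation, hinge
metrics, switch residues, hydration) and writes one TSV per metric, a
summary table, and a JSON manifest of config/input hashes; identical inputs
reproduce byte-identical outputs.

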