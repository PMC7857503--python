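# Methods

This note documents the models implemented in `lipbind`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## Equilibrium partitioning model

Membrane binding of a peripheral protein is treated as partitioning
between the aqueous phase and the membrane pseudo-phase, quantified by a
dimensionless mole-fraction partition coefficient K_x. In the
competition FRET assay the protein is pre-bound to liposomes and
displaced by a soluble polyanion (IP₆); the intensity follows the
single-site competitive-inhibition hyperbola

    F([I]) = ΔF_max · (1 − [I]/(IC₅₀ + [I])) + C.

The conversion to K_x is

    K_x = (IC₅₀/K_I − 1) · [H₂O]/[L],    ΔG° = −RT ln K_x

with:

| parameter | default | unit | rationale |
|---|---|---|---|
| K_I | 1.8 | μM | protein–IP₆ dissociation constant measured for this domain |
| [H₂O] | 55.5 | M | bulk water molarity at 25 °C; configurable (55.3 vs 55.5 changes ΔG° by <0.01 kcal/mol, far inside the printed ±0.1) |
| [L] | assay-specific | μM | accessible lipid; sonicated liposomes expose ≈½ of total lipid on the outer leaflet, so 125 μM total → 62.5 μM accessible |
| T | 298.15 | K | assay temperature (25 °C); 298 vs 298.15 K is a 0.05 % effect |
| R | 1.987×10⁻³ | kcal·mol⁻¹·K⁻¹ | gas constant |

Fit initialisation: IC₅₀ from the titrant concentration at half the
signal drop, ΔF_max from the first-minus-last signal span, C from the
high-titrant plateau; all parameters bounded below by zero. Control
correction is additive — the lipid-only control measures the titrant's
direct effect on acceptor fluorescence, so its drift relative to its
first point is subtracted; a ratio correction is applied only for the
separate buffer-dilution control (fractional signal loss). IC₅₀
uncertainty can be taken either as the fit standard error (reported in
`CompetitionFit.stderr`) or as the SD across replicate titrations
(compute by fitting each replicate); both are exposed because the two
conventions differ.

## Stopped-flow kinetics

Association: F = ΔF_max(1 − e^(−k_obs t)) + C. Dissociation: one or two
falling exponentials. Replicate shots (≥8 per sample in the emulated
protocol) are averaged pointwise on a shared time base before fitting;
the dead time of an average is the maximum over inputs. Points with
t < dead time (default 1.4 ms) are excluded, not deconvolved — the
instrument mixes during that window and the samples carry no usable
signal.

Model selection (`model="auto"`): both candidates are fitted and the
corrected Akaike information criterion (AICc) on Gaussian residuals
decides, with one guard — a double fit whose rates agree within 1 % or
whose minor amplitude is <1 % of the total carries no evidence for a
second component and defers to the single model. On noiseless
single-exponential data the unguarded AICc always prefers the double
model (it reproduces the data exactly with a redundant component), so
the guard is load-bearing.

Biexponential initialisation uses log-linear peeling (fit the slow tail,
then the fast residual) plus a second start derived from the
single-exponential fit (rates 4k and k/3 bracketing it); the converged
start with the lower residual sum of squares wins. Peeling alone is
fragile when the tail anchor point is noisy.

k_on,x = (k_obs − k_off)·[H₂O]/[L] with [L] the post-mixing accessible
lipid (equal-volume mixing halves the syringe concentration: 75 μM
accessible → 37.5 μM). Which k_off to subtract (fast, slow, or
amplitude-weighted) is a required choice exposed to the caller
(`koff_component` in the pipeline); the fast component reproduces the
published plasma-membrane-composition entry and is used in the
acceptance computation.

## Membrane geometry

The bilayer normal is z. The membrane position is the unweighted mean z
of lipid phosphorus atoms in the protein-facing leaflet. Leaflet
assignment is operational: if the P-atom z-spread exceeds 15 Å the atoms
are split at the mean z into upper/lower, and the protein-facing leaflet
is the one whose mean lies nearer the protein COM; a spread below 15 Å
is treated as a single leaflet (this threshold separates genuine
bilayers, whose leaflets are tens of Å apart, from flat single-leaflet
fixtures with a little roughness).

Protein COM is mass-weighted over all protein atoms present (heavy atoms
only when hydrogens are absent, as in crystal structures). Depth is
z(Cα) − plane (a named side-chain atom can be substituted); negative
means inserted. Loop tips are the centroid of three consecutive Cα
atoms (β2–β3: 388–390; β6–β7: 450–452; β3–β4: 406–408, human
numbering); angles α and β are subtended at the protein COM. Whether the
original analysis used an all-atom or Cα-only COM for the angle vertex
is not documented; the all-atom convention is used here and the ±3°
acceptance band on the crystal-structure angles absorbs the difference.

Electrostatic contacts: a basic residue contacts a lipid molecule when
its class anchor (Lys NZ, cutoff 5.0 Å; Arg CZ, 6.3 Å; His imidazole
ring heavy-atom COM over CG/ND1/CD2/CE1/NE2, 6.1 Å — tautomer
independent) lies within the cutoff of ≥1 headgroup heavy atom of that
molecule; multiple atoms of one lipid still count once. Headgroup atom
lists default to CHARMM36-style names (anionic lipids from the
phosphodiester linkage outward, PC from the glycerol backbone outward,
PIP₂ including the 4- and 5-phosphates) and are fully overrideable,
since naming is force-field dependent and the original atom selections
are not published. Periodic boundaries: minimum image in x–y when a box
is present; z is non-periodic (it is the bilayer normal).

Windowed statistics default to the last half of the trajectory
(mirroring "last 100 ns of a 200 ns run"); the SD is the population SD
across saved frames. The per-frame count of basic residues with ≥1
contact (split by lipid type) counts residues, not contacts.

## Docking-pose tabulation

The published clustering procedure is not available, so the package
re-decides it: single-linkage agglomerative clustering on Euclidean
distance between pose reference points (ligand heavy-atom centroid),
cut at 5 Å — equivalent to connected components of the ≤5 Å contact
graph, deterministic given input order (labels sorted by descending
cluster size, ties by first pose index). Each cluster is assigned as a
whole to the nearest site centre (anchor atoms of the site's residues)
within an 8 Å assignment radius, else to "other". Both radii are
surfaced in config and recorded in output metadata.

## Modification mass arithmetic

Monoisotopic masses are used for peptides and fragments (elemental and
residue masses from pyteomics). Phosphogluconoylation is fixed as
C₆H₁₁O₉P (ring-opened 6-phosphogluconolactone adduct; monoisotopic
258.014 Da, average 258.12 Da — both round to the reported +258).
Intact-protein shifts are compared at 1 Da tolerance because the
substrate is a deconvoluted average-mass spectrum; peptide/fragment
matching uses ±20/±50 ppm. Fragment ladders are singly charged b/y ions
(b = Σresidues + proton; y = Σresidues + water + proton); a modification
at position i shifts exactly the ions containing i. Because the intact
spectrum constrains the total added mass, site assignments are
enumerated under that constraint: a single +258 makes modification of
two candidate lysines mutually exclusive. Elemental counts in a
modification may be negative (deamidation is H₋₁N₋₁O₊₁).

## Synthetic data: what it does and does not emulate

Generators produce hyperbolic titrations, exponential traces with
dead-time flags, planar bilayer + pseudo-protein frames, and Gaussian
pose mixtures, all with additive Gaussian noise and bit-reproducible
seeding. Defaults mirror the study conditions: 1 μM protein with 125 μM
total lipid, 8 replicate shots, 1.4 ms dead time, frames every 0.1 ns,
protein COM 23 Å above the phosphate plane, 510 poses.

The coordinate generator builds the pseudo-protein mirror-symmetric
about its COM (every residue has a point-reflected twin) so the COM is
exact by construction; loop tips are placed on rays at the prescribed
α/β angles, and scheduled contacts are realised by dipping a side-chain
anchor toward dedicated lipids (with the twin mirrored so the COM never
moves). Ground truth therefore contains *analytic* values for every
metric, and the closure tests demand exact agreement (1e-9 Å for
geometry, 1e-6 relative for noiseless fits).

What passing these tests shows: the estimators are unbiased and correct
on data generated by their own model classes, and the geometry code
implements its definitions exactly. What they do not show: robustness to
real instrument artefacts (lamp drift, mixing transients, non-Gaussian
detector noise), force-field realism of lipid conformations, or
correctness of the CHARMM36 headgroup atom lists against the original
(unpublished) selections. Published kinetic and contact tables that
depend on undeposited raw traces and trajectories are therefore covered
by these regime-matched synthetic round trips, not reproduced from data.

## Problem sizes

Recovery studies use 100 synthetic titrations (20 points each), 50–100
dissociation traces (1500 points each), 25–50 random contact fixtures
(~200 atoms), 5–20 coordinate frames, and 510-pose clouds — sizes chosen
so each study estimates its statistic stably while the full suite stays
interactive.

## Known limitations

* No deconvolution of dead-time-truncated signal; fast phases with
  k_obs ≳ 1/dead-time are unrecoverable by design.
* The leaflet split assumes a roughly planar, non-curved bilayer whose
  leaflets are separated along z.
* Single-linkage clustering chains through bridging poses; with the 5 Å
  default this is only a concern when site centres are <~10 Å apart.
* Charge-1 fragment ions only; multiply charged ladders are out of
  scope.
* NaCl screening titrations are control-corrected and normalised but not
  fitted to a binding model (none is defined for them).
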