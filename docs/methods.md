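# Methods

`pbpsensor` implements a contact-change pipeline for designing
effector-insertion biosensors on hinge-type binding proteins
(periplasmic binding proteins and relatives). This note records the
model, the parameters that matter, the numerical conventions, and what
the synthetic fixtures do and do not demonstrate.

## The model

Periplasmic binding proteins (PBPs) are two-lobe "Venus flytrap"
scaffolds: ligand binding closes the lobes around the substrate.
Fusing a circularly permuted fluorescent protein (cpGFP) into the
scaffold can transduce that conformational change into a fluorescence
change — if the insertion site experiences enough change in its local
environment. The pipeline's premise is that good insertion sites are
residues whose **inter-residue contacts differ between the closed and
open states**, and that replicate MD trajectories of the closed→open
transition expose those residues better than a static crystal-pair
comparison does.

The stages are:

1. **State classification.** Each replicate trajectory gets a per-frame
   Cα RMSD against its starting (closed) conformation after Kabsch
   superposition. A replicate is *closed* when the mean RMSD over the
   trailing window (default 50 ns) is strictly below the threshold
   (default 2.5 Å), *open* otherwise; a mean exactly at the threshold
   is called open, since the defining inequalities are strict on both
   sides and leave equality unassigned.
2. **Hysteresis contacts.** For every residue pair (i, j) with
   |i − j| > 2, the per-frame closest-atom distance (heavy atoms by
   default) feeds a dual-cutoff state machine: a contact *forms* when
   the distance drops below `r_start` (5.0 Å) and *breaks* only when it
   exceeds `r_end` (8.0 Å). The gap suppresses flicker from thermal
   noise at the cutoff. These thresholds are sometimes quoted as
   "0.5/0.8" by nm-based contact tools; sub-Ångström closest-atom
   cutoffs are physically impossible, so this package fixes the units
   at 5.0/8.0 Å and leaves both configurable.
3. **Pearson-vs-time matrix.** For each pair that is ever in contact,
   the distance truncated at `r_end` (so that far-apart excursions
   carry no weight) is Pearson-correlated with frame time. Positive
   pixels are contacts present early (closed state, lost on opening);
   negative pixels are contacts formed late (open state). A pair whose
   truncated distance or whose time base has zero variance scores 0 by
   convention. An alternative mode correlates the binary contact
   indicator with time instead; its raw correlation is negated so the
   sign convention (positive = closed-state contact) is shared. Only
   replicates classified open enter the ensemble matrix, which is the
   pixel-wise arithmetic mean of the per-replicate matrices. A
   crystal-pair mode treats two static structures as a 2-frame
   trajectory, yielding pixels in {−1, 0, +1}.
4. **Hotspot clustering.** On the strict upper triangle (the matrix is
   symmetric; using both triangles would duplicate every cluster),
   8-connected components of same-sign nonzero pixels form *peaks*
   (positive) and *valleys* (negative). Each cluster is scored by mean,
   median and maximum-absolute pixel value; peaks and valleys are
   ranked separately (valleys on |mean| and |median|), and a cluster is
   retained only if it reaches the percentile threshold (default 99th,
   linearly interpolated) **in all three statistics simultaneously**.
   Interpolated percentiles keep the criterion usable for small cluster
   counts: a strict "greater than the 99th percentile" on a singleton
   group would retain nothing. Retained clusters report their i- and
   j-axis residue spans and the sorted residue union; candidate
   insertion sites are enumerated over each span every
   `insertion_stride` residues (default 3), always including the span
   end.
5. **Construct assembly.** Inserting an effector "at residue i" places
   the cassette between scaffold positions i and i+1 with linkers
   res(i+1)-Ala-Ser (N-terminal) and Ala-Ser-res(i) (C-terminal), so
   residues i and i+1 each appear twice and every fusion is exactly
   scaffold + effector + 6 residues long. This is the only reading
   consistent with both linker definitions of the established cpGFP
   insertion scheme.
6. **Assay reduction.** Plate tables reduce in a fixed order: mean over
   technical replicates per (construct, concentration, biological
   replicate); subtraction of the empty-vector control's mean at the
   matching concentration; ΔF/F0 = (F_X − F_0)/F_0 against the 0 mM
   condition; then mean ± sample SD across biological replicates. A
   construct is *viable* when any concentration's |ΔF/F0| exceeds the
   threshold (default 0.25). ΔF/F0 is formed per biological replicate
   and then averaged (honest replicate SDs); a pooled-means mode
   reproduces tables computed the other way. F_0 = 0 yields a missing
   value with a warning — near-zero denominators make the ratio an
   artefact, not a signal.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `rmsd_threshold` | 2.5 | Å | closed/open split on trailing-window mean RMSD |
| `window_ns` | 50 | ns | trailing window for classification, RMSF, dihedral means |
| `r_start` | 5.0 | Å | contact formation cutoff |
| `r_end` | 8.0 | Å | contact termination cutoff and distance truncation |
| `percentile` | 99 | — | cluster retention percentile per sign group |
| `insertion_stride` | 3 | residues | spacing of enumerated insertion sites |
| `viability_threshold` | 0.25 | — | \|ΔF/F0\| bar for a viable sensor |
| `neighbor_exclusion` | 2 | residues | \|i − j\| band excluded from contact analysis |

Residue indices are 1-based everywhere.

## Secondary metrics

For comparison with the contact method, the package also computes the
classical profiles: the four-Cα pseudo-dihedral at residue i (torsion
of Cα(i−1), Cα(i), Cα(i+1), Cα(i+2); undefined at the first residue
and the last two), differenced between two crystal structures
(ΔDihe-Crys) or between state ensembles (ΔDihe-MD); and the
closed-minus-open per-residue Cα RMSF difference (ΔRMSF) over the
trailing window, with each frame superposed onto the window-mean
structure. Angular work uses circular means and wrapped differences —
arithmetic means of angles near ±180° are meaningless — and Δ-dihedral
profiles report the absolute wrapped difference of the per-state
circular means. (Taking absolute values *after* ensemble averaging is
one of two defensible orders; the alternative — averaging absolute
per-simulation differences — inflates values for residues that merely
fluctuate.) Torsions use the atan2 formulation with the standard MD
sign convention (cis = 0°, trans = 180°, result in (−180°, 180°]).

## Numerical conventions

- **Superposition** is Kabsch via SVD (through
  `scipy.spatial.transform.Rotation.align_vectors`). Point sets whose
  centered covariance has rank < 2 (coincident or collinear) are
  rejected: the optimal rotation is not unique there.
- **Correlation snapping**: a computed Pearson value within 1e-12 of
  ±1 is reported as exactly ±1, restoring the exact bound that float
  rounding (~1e-16 per term) destroys for perfectly linear signals.
  Real-data correlations are never near that band.
- **Percentiles** use NumPy's linear interpolation; retention compares
  with ≥ (up to a 1e-12 float guard, relevant only when a statistic is
  its own group threshold).
- **Boundary calls**: RMSD exactly at the threshold → open; |ΔF/F0|
  exactly at the viability threshold → not viable (both rules are
  strict inequalities).
- **Frame times** default to the frame index when no sampling interval
  is supplied, so "ns" windows degrade gracefully to frame-count
  windows.

## Synthetic fixtures

The hinge fixture builds a 26-residue toy: two rigid 12-residue Cα
strands facing each other 4.5 Å apart (within contact range), bridged
by two static hinge pseudo-residues placed beyond the strand ends.
The mobile lobe separates on a monotone opening-angle schedule
(default linear ramp to 20°). The default motion is a **linearized
hinge**: lobe separation equals lever-arm × angle (arm 8.6 Å, so the
full ramp opens the inter-lobe gap from 4.5 to 7.5 Å — inside `r_end`
for the whole trajectory). That linearization is deliberate: each
facing pair's distance is then an affine function of time, so its
Pearson pixel is exactly +1 at zero noise and the generator's ground
truth (the exact set of threshold-crossing pairs, derived
geometrically and independently of the analysis code) is sharp. A
finite-rotation mode swings the lobe about the hinge pivot instead;
distances are then monotone but nonlinear, and only the pixel signs
are exact. Isotropic Gaussian coordinate noise (seeded) can be added
per atom per frame; a two-atom-per-residue variant exercises the
all-pairs minimum-distance path.

Analysis parameters for the fixture are scaled to its size
(`fixture_config`): RMSD threshold 1.0 Å (the toy's opening shifts
whole-molecule Cα RMSD by ~1.1 Å, not the several Å of a 370-residue
protein), trailing window of half the fixture span, retention
percentile 90 (the toy matrix produces a handful of clusters, not
hundreds). These are the fixture's study conditions, fixed with its
geometry.

The plate simulator draws readings as background + F0·(1 + ΔF/F0) +
Gaussian noise per technical replicate (defaults: F0 1000, background
100, noise SD 20 in arbitrary plate units; 3 biological × 3 technical
replicates, plus an empty-vector control series), so the reduction
pipeline can be checked against known truth and inverted exactly at
zero noise.

**What passing tests show — and don't.** The fixtures verify the
analysis chain: state machines, correlations, clustering, assembly
arithmetic, and the reduction order, against independent oracles and
exact ground truth. They do not show that contact hotspots in real MD
predict functional insertion sites: the toy has no force field,
solvent, ligand, side chains, or thermal kinetics, its contacts change
monotonically rather than stochastically, and its noise is isotropic
and uncorrelated. Claims about real proteins require real
trajectories.

## Acceptance script problem sizes

`scripts/acceptance.py` runs a 10-replicate ensemble (8 opening, 2
static; 26 residues × 21 frames each, coordinate noise 0.05 Å) through
the full pipeline — PDB round-trip, classification, per-replicate
matrices, ensemble mean, hotspot report, construct design at the
proposed sites, and a simulated 8-construct plate with truths spanning
strong, marginal and flat responders. These sizes give stable
statistics for every reported quantity while keeping a single-CPU run
in seconds.

## Known limitations

- The minimum-distance kernel is O(frames × residue-pairs × atom-pairs)
  and aimed at analysis-scale selections (Cα/heavy atoms of one
  protein), not at solvated systems.
- Binary trajectory formats are supported only through user-registered
  adapter callables; the core reads multi-model PDB text.
- The crystal-pair matrix mode requires identical residue numbering in
  both structures (atom layouts may differ).
- No dose–response modelling: the assay stage reports per-concentration
  ΔF/F0, not EC50 fits.
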