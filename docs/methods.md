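# Methods

## The design problem

A chemibody joins an antibody that binds a surface epitope to a small
molecule that occupies a deep pocket of the same target, through a
flexible linker attached at an engineered cysteine. Whether the hybrid
gains potency from the chelate effect depends almost entirely on the
linker: too short and the bound pose is strained or unreachable; too
long and the bound state pays an entropic penalty. This package models
that trade-off and the assay analytics used to test it.

## Site selection

Antibody residues are scored on four criteria, each individually
toggleable with user-set thresholds (`SiteCriteria`):

| criterion | quantity | default threshold |
|---|---|---|
| exposure | per-residue SASA / Gly-X-Gly reference area | ≥ 0.30 |
| antigen contact | heavy-atom pairs within 4.5 Å of the antigen | ≤ 2 |
| proximity | Cβ → ligand attachment atom distance | ≤ 30 Å |
| orientation | angle between Cα→Cβ and Cβ→attachment atom | ≤ 90° |

SASA is Shrake–Rupley (probe 1.4 Å, 960 deterministic Fibonacci sphere
points per atom, Bondi radii, via biotite) and relative exposure divides
by the theoretical extended Gly-X-Gly areas (Tien et al. 2013). The
thresholds are package defaults, not measured constants: the four
criteria are inherently qualitative, so the defaults were chosen once
to be permissive enough to admit typical CDR-adjacent surface residues
and are meant to be overridden when screening a real Fab. Glycine (a legitimate candidate site) gets an ideal Cβ constructed
from its backbone N/Cα/C; native cysteines are flagged rather than
excluded. Candidates (residues passing all enabled criteria) are ranked
by an equal-weight min-max-normalized composite; ties break by residue
number. Alternate locations keep the highest-occupancy conformer;
author residue numbering is preserved verbatim.

Both absolute and relative SASA are reported, since either reading of
"high solvent exposure" is defensible; the pass criterion uses the
relative value.

## Conjugate model

The modeled species truncates both partners to the parts that matter
for linker mechanics, mirroring a bound-pose calculation in which
everything outside the linker is frozen crystallographic context:

    acetyl–piperazine — CH2C(=O)NH — (CH2CH2O)n-chain — NHC(=O)CH2 — S(H)

* the warhead is kept up to and including its piperazine ring (the ring
  atoms carry the `head` anchor tag and are held fixed); an optional
  `full_warhead` variant retains the trifluorophenyl butanoyl moiety;
* the antibody is reduced to the cysteine Sγ (the `tail` anchor) plus
  the bromoacetamide-derived thioether tail;
* each PEG unit adds exactly one CH2CH2O (7 atoms, 44.0262 Da), so
  formula and mass arithmetic across the series is exact by
  construction.

Monoisotopic masses use a bundled most-abundant-isotope table; average
masses use IUPAC standard atomic weights; [M+H]+ adds 1.00728 Da. The
builder accepts 0–32 PEG units.

`max_extension` bounds the anchor-to-anchor reach by laying the
shortest bond path out as a planar all-trans chain with ideal bond
lengths and angles (sp3 111°, sp2 120°). With bond lengths and angles
fixed, no torsion assignment can beat the planar extended arrangement,
so this is a true upper bound and a cheap feasibility screen: the
conjugate first out-reaches a 28 Å head-centroid-to-sulfur separation
at n = 5 (~27.5 Å extended, marginal) and clears it comfortably from
n = 6.

## Constrained conformational search

Energies are MMFF94 as shipped by RDKit. (MMFF94x, the variant
implemented in MOE and common in conjugate-design work, differs in
parameterization details, so absolute strain values are
force-field-dependent.) The search is a stochastic torsion walk
emulating a low-mode search without molecular dynamics:

1. propose: perturb 1–3 randomly chosen rotatable torsions of a
   randomly chosen retained conformer by ±60°/±120°/180° plus Gaussian
   jitter (σ = 20°);
2. re-impose the anchors and minimize (anchored atoms frozen in
   `fixed` mode, tethered with a user force constant in `harmonic`
   mode);
3. retain if no retained conformer is within 0.25 Å RMSD (over
   non-anchored heavy atoms, no superposition — the anchors define the
   frame; Kabsch superposition is used in free searches) and the energy
   is within `window + margin` of the running minimum. The analysis
   window is 2.0 kcal/mol; the 3 kcal/mol margin keeps near-window
   conformers from being discarded before a lower minimum is found;
4. stop after 300 consecutive rejections (reject limit) or
   `max_iterations` proposals.

Initial conformations come from three sources: a "tow" of the seed
conformer (the sulfur is dragged to its anchor position in ≤3 Å steps
with minimization after each, so the chain follows instead of
tangling), distance-geometry embeds restrained to the anchor
coordinates (these fail cleanly for infeasible separations), and an
all-anti extended chain, also towed. Anchors farther apart than
`max_extension` + 2 Å produce a warning and a best-effort strained
ensemble — never an empty result, since a ground state always exists.

**Strain** is `E_min(constrained) − E_min(unconstrained)` for the
identical molecular species. The unconstrained reference makes strain
non-negative (up to minimizer tolerance) and matches the reading that
lower strain is more favorable. Because the difference of two
stochastic minima is noisy, the two searches are coupled: the best
unconstrained minima are towed into the constrained search as extra
starts, and the constrained minimum is relaxed without anchors and
offered to the reference side. Errors common to both sides then cancel
in the difference. `repeats` independent seeds are run (scan default 2)
keeping the best minimum on each side; constrained ensembles are merged
and re-deduplicated before counting conformers in the window.

Determinism: every stochastic operation derives from an explicit
integer seed; identical (graph, anchors, parameters) reproduce the
ensemble bit-for-bit.

### Problem sizes

Scan defaults (`max_iterations = 120–200`, 2 repeats, 6 constrained
embeds, 12 free embeds) were chosen as the desk-scale point where the
strain profile across n = 3–8 stabilizes to a few kcal/mol; a scan of
six lengths runs in minutes on one CPU. Residual search noise of that
order remains in the flat part of the profile — conclusions that hinge
on ~1 kcal/mol differences between long linkers need larger budgets.

## Assay analytics

POC (percent of control) is the affine normalization
`100·(signal − full-inhibition) / (no-inhibitor − full-inhibition)`.
The 4PL model is fit on the POC scale by Levenberg–Marquardt on pooled
replicate points (not means; an option fits means), with both plateaus
free — partial inhibitors genuinely plateau above 0% control, so
clamping would bias IC50. IC50 is multi-started at the geometric mean
of the dose range and at the first dose crossing half-maximal response,
with both hill-slope signs; the lowest RSS wins, and the equivalent
swapped-plateau/negated-hill parameterization is canonicalized to
`top > bottom`. Non-convergence is flagged on the result rather than
raised. Michaelis–Menten fits initialize from the Lineweaver–Burk
double-reciprocal line.

The strain–potency correlation defaults to log10 IC50 because measured
potencies span orders of magnitude; the raw-scale correlation is also
reported, and the joined per-length table is returned for audit.

## Synthetic data

Generators are pure functions of (spec, seed) and always return their
ground truth alongside the data.

* `make_anchor_pair`: the piperazine head at its MMFF-equilibrium chair
  coordinates (centroid at origin), the sulfur at the requested
  centroid separation (default 28 Å, the design span) along a
  seed-fixed random direction. The direction is randomized to avoid
  axis-aligned artifacts but restricted to the hemisphere facing the
  linker-bearing ring nitrogen: a bound pose cannot place the
  conjugation site behind the rigid warhead, and unrestricted
  directions occasionally demand that the linker wrap around the
  frozen ring, inflating strain by hundreds of kcal/mol.
* `make_toy_complex`: planted-truth antibody/antigen/ligand geometry —
  "good" sites satisfy all four criteria by construction, buried
  residues sit inside a 110-atom occluding shell, interface residues
  get antigen atoms planted at 3.5 Å, filler residues are exposed but
  point away from the ligand. It emulates the *logic* of a real
  complex, not its physics: residues are disconnected ideal-backbone
  templates, so passing tests demonstrate the correctness of the
  scoring machinery, not its behavior on real antibody surfaces
  (where exposure values are lower and criteria interact).
* assay simulators: multiplicative Gaussian noise (CV-parameterized),
  because fluorescence assay error scales with signal; 12-point
  half-log triplicate panels for dose-response, a 2-fold 0.5–128 µM
  ladder for kinetics. Real plate data additionally carry edge effects,
  outliers, and heteroscedastic controls that this model omits.

The pipeline's synthetic potency ground truth log-interpolates between
a potent plateau (0.56 nM) and the unconjugated level (105 nM) as
strain grows to 50 kcal/mol — a deliberately simple monotone link so
the correlation stage has a known answer.

## Known limitations

* MMFF94 ≠ MMFF94x: absolute strain energies (especially for
  infeasible, highly stretched linkers where the anharmonic stretch
  region is probed) can differ substantially between force-field
  variants and anchor conventions; the strain *profile* across linker
  lengths is the robust output.
* With the truncated conjugate model and the centroid-to-sulfur
  separation convention, the strain profile decreases smoothly past the
  feasibility transition rather than flattening sharply, because a
  barely-reaching linker must stay near full extension and forfeits the
  gauche and intramolecular-contact stabilization of its coiled free
  state. Which length first counts as "within the plateau" therefore
  depends on the anchor convention and force field, not only on
  geometry.
* Protein flexibility, solvent, and entropy beyond conformer counting
  are out of scope; anchors are rigid.
* The search samples torsions only; ring puckers come from the embed
  stage.
* 4PL standard errors are asymptotic (from the LM covariance), not
  profile-likelihood intervals.
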