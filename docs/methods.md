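# Methods

This note documents the models implemented in `nmrdock`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Chemical-shift perturbation analysis

The combined amide perturbation is `Δδ_HN = sqrt(Δδ_H² + (Δδ_N/5)²)`; the
1/5 scale compensates the larger ¹⁵N shift dispersion and is exact, not
configurable.  Differences are bound − free.  When a residue shows two
bound-state peaks (slow exchange), the farther peak is used and the row is
flagged `two_state`; this is the conservative choice for interface mapping.
Residues missing from the bound list are reported as `missing`, never
imputed.  Tryptophan side-chain indole peaks are carried as separate
entries and classified, but excluded from the threshold statistics, whose
backbone-amide population they do not share.

Significance is decided by iterative trimmed statistics: exclude values
above μ + k_trim·σ, recompute until stable, cut at μ + k_cut·σ (defaults
k_trim = 3, k_cut = 1, both configurable; the cutoff is stored in the
table metadata).  A known limitation, visible in the synthetic benchmark:
when the perturbed fraction is large (≈ 25 % of a small domain) the
trimming cascade may never trigger, leaving the cutoff inside the
perturbed band (missed weak interface residues); when the far field is
shallow, the cascade can run deep and leave the cutoff near the noise
floor (second-shell false positives).  The interface-recovery check
therefore pools both mapped surfaces — receptor-observed and
ligand-observed titrations, as binding studies map both sides — and counts
recovery among residues observable in both conditions.

## PRE distance restraints

Forward model: `Γ₂(r) = K/r⁶ · (4τc + 3τc/(1 + ω_H²τc²))` and
`I/I₀ = R₂dia/(R₂dia + Γ₂) · exp(−Γ₂ t_evol)`.  The composite attenuation
(steady-state line broadening × evolution-period loss) is chosen over a
pure-exponential or pure-Lorentzian form because it is monotone and
invertible over the whole distance range, which the pipeline requires.
Defaults, all exposed in `PREParameters`: K = 1.23e-32 cm⁶ s⁻²
(converted to Å⁶ s⁻²), τc = 15 ns (appropriate for a micelle-embedded
complex), R₂,dia = 50 s⁻¹, t_evol = 10 ms, ω_H for an 18.8 T magnet.
These are literature-standard constants; they are surfaced explicitly
because intensity-ratio data alone cannot fix them.

Ratios are normalized by the median raw ratio of a reference set of
unaffected residues (`auto` = top quartile).  Conversion to restraints
uses detection cutoffs lo = 0.15 and hi = 0.85: below lo only an upper
bound at r(lo) is known, above hi only a lower bound at r(hi); in between
the model is inverted by root bracketing (Brent, 1e-3 Å) and a range
restraint of target ± 4 Å is emitted (a standard PRE uncertainty; both
margin and cutoffs configurable).  Under the default parameters the
invertible window [r(0.15), r(0.85)] spans ≈ 14.3–22.6 Å.  Note that for
*any* r⁻⁶ attenuation model the ratio band 0.15–0.85 maps to at most a
≈ 1.8-fold range in distance, so no parameter choice widens that window
substantially; the numeric inversion itself, with clipping disabled, is
accurate to 0.01 Å from ≈ 2 Å out to beyond 30 Å and is tested there.

Multiple label sites (the two native cysteines of the ligand domain) give
one ambiguous restraint per amide with minimum-distance semantics — the
experiment cannot tell which label caused the attenuation, so a restraint
is satisfied if any site satisfies it.  Plain r⁻⁶ aggregation is *not*
used here: with two equidistant sites it would understate the distance by
11 %.

## STD proximity restraints

Attenuation is 1 − I_on/I_off per residue; a residue is flagged when it
exceeds both an absolute threshold and 3× the median absolute attenuation
(noise floor).  Each flagged residue contributes an unambiguous upper
bound of 6 Å from its amide (H if present, else N) to the saturated
source atom.  The saturation chemical shift (≈ 11.6 ppm for an isolated
downfield amide) is metadata only; geometry uses the atom, never the ppm.

The flag threshold defaults to 0.05.  This follows from the transfer
model used throughout the package — maximal transfer 0.5 decaying
linearly to zero at 6 Å — under which 0.05 flags contacts out to
≈ 5.4 Å while sitting 5σ above the simulated intensity noise (sd 0.01).
A threshold much above ≈ 0.1 would demand source–amide distances below
van-der-Waals contact and could never fire; thresholds for real data
should be set from the observed noise floor.

## Restraint assembly and evaluation

Ambiguous interaction restraints: one per active residue, from its heavy
atoms to the union of heavy atoms of the partner's active ∪ passive
residues, with r⁻⁶ effective distance `d_eff = (ΣΣ d⁻⁶)^(−1/6)` and a
flat-bottom quadratic penalty above the bound.  Passive residues are
exposed residues within 6.5 Å of an active one; exposure is a coarse
neighbour-count proxy (heavy atoms within 10 Å below the chain's 60th
percentile) rather than a surface-area calculation — only a rough filter
is needed.

The AIR effective upper bound defaults to **4.25 Å**, not the 2 Å
conventional with all-atom selections.  With backbone+CB-only models the
r⁻⁶ sum runs over ~20× fewer pairs, and the measured effective distances
of true-interface AIRs at the generator's bound pose span 3.3–4.05 Å
across seeds; 4.25 Å is the tightest bound a correct pose always
satisfies at this atom density.  Restraint weights default to 1.0 (CSP,
PRE) and 2.0 (STD — sparse and high-confidence).

Restraints serialise to a CNS-style `.tbl` dialect (`assign (sel) (sel)
d dminus dplus`, OR-ed residue selections for ambiguity) with a metadata
comment per restraint so that kind/source/weight/aggregation round-trip
exactly; distances are written with three decimals and restraints are
built on a 1e-3 Å grid, so read(write(x)) == x.

## Docking engine

A deliberately simplified, fully deterministic stand-in for the large
data-driven docking programs: it keeps their decision surface (restraint
energies, composite score, Z-score, clustering, a configurable number of
rigid-body trials — default 10) and drops flexible refinement, solvation
and molecular dynamics.  The receptor is fixed; only the ligand moves.

* Orientations: Shoemake-uniform quaternions, 200 by default.
* Placement: ligand centroid on a sphere of radius Rg(receptor) +
  Rg(ligand) + 5 Å around the centroid of restraint-active receptor
  atoms; each placement backs out along its direction until clash-free
  (the receptor is elongated, so a fixed radius can intersect it).
* Minimisation: derivative-free greedy random search over the six
  rigid-body degrees of freedom — a translation line search toward the
  restraint centre, then 20 proposal steps with geometrically decaying
  scales (2 Å/12° down 20-fold), restarted from 10 jittered copies
  (2 Å / 8°); the result is never worse than the input.
* Second stage: the 20 best-scoring poses are re-minimised with a finer
  schedule (60 steps, 1 Å/6°), mirroring the coarse-then-refine structure
  of production docking protocols.
* Score: `w_air·E_air + w_pre·E_pre + w_std·E_std + w_clash·E_clash`
  with defaults 1.0/1.0/2.0/0.01; the clash term is a soft-sphere overlap
  `Σ max(0, 0.8(rᵢ+rⱼ) − d)²` over inter-chain heavy atoms (radii
  C 1.7, N 1.55, O 1.52, S 1.8, P 1.8, H 1.1 Å, default 1.7).
* Selection: Z-scores standardise the score over the whole ensemble
  (sample sd; all zero when scores are identical); single-linkage
  clustering on pairwise ligand RMSD at 5 Å, computed over the interface
  residues of the best-scoring pose; ranking by score with deterministic
  tie-breaks (lower E_air, then pose index).

Performance notes: restraint selections are compiled once into flat pair
index arrays (one vectorised gather + `reduceat` per evaluation), and the
clash term uses a k-nearest query against a receptor KD-tree with an
exact fallback for atoms with many contacts — the tree result equals the
brute-force double loop to 1e-9 and is tested against it.

## Synthetic benchmark

The generator builds, from ideal backbone geometry (NeRF chain extension
at canonical φ/ψ), a three-helix receptor bundle and a four-strand sheet
plus one short helix as the ligand, pressed onto the outward face of the
first receptor helix until the closest inter-chain approach equals 3.0 Å.
A placement is accepted when the 5 Å interface has ≥ 6 residues per side,
no inter-chain distance is below 2.8 Å, and some cross-chain amide pair
lies within 5 Å (the STD anchor).  One Lys–Asp salt bridge (NZ/OD1/OD2
added explicitly), two labelled cysteines (SG) on the ligand helix, and
the saturation-source amide are recorded in the ground truth, together
with every distance the forward models need.  Only backbone + CB atoms are
built — the restraints in this pipeline are backbone/pseudo-atom based —
and the whole object is a pure function of (parameters, seed).

Simulated observables use exactly the forward models the analysis inverts:
CSP magnitudes A·exp(−d_min/λ) (A = 0.15 ppm, λ = 4 Å, noise 0.005 ppm,
5 % random dropout, optional slow-exchange doubling), PRE ratios from the
Solomon–Bloembergen model at the true amide–label distances (3 % noise),
STD attenuation from the linear ramp at the true amide–source distances
(1 % noise).  Peak positions are random within realistic ppm ranges
(¹H 7–10, ¹⁵N 105–130): CSP analysis uses only differences, so absolute
shift realism is cosmetic.

What passing these tests shows: the analysis correctly inverts its own
forward models at realistic noise, the restraint machinery is faithful,
and the docking engine recovers a known pose from exact restraints (top
pose within 3 Å interface-ligand RMSD in ≥ 16/20 seeds, with the
restraint-free clash-only control far worse).  What it does not show:
robustness to model mis-specification (real PRE data violate the single
correlation-time assumption), to assignment errors, to flexible
interfaces, or to the conformational averaging of real spin labels.

## Numerical and reproducibility choices

Distances in Å throughout; residue numbers as in the source PDB.
Quaternions are scalar-first, right-handed, active; tested against a
rotation-matrix oracle.  PDB reading keeps MODEL 1, altloc ' '/'A',
rejects insertion codes, skips waters.  All randomness flows from a
single seed through `numpy` SeedSequence spawning; reports embed the
resolved configuration and its hash, contain no timestamps, and
regenerate bit-identically for the same configuration and seed.  Docking
problem sizes in the shipped tests (ensembles of 20–200 orientations,
20 seeds for the statistical checks) were chosen to keep a full run on a
single CPU in the tens of minutes while leaving the statistical
conclusions stable.
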