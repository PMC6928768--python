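# Methods

## Icosahedral symmetry

The 60 proper rotations of the icosahedral group are generated at run
time from two generators — a 72° rotation about the icosahedron vertex
(0, 1, φ) (φ the golden ratio) and a 180° rotation about z — and closed
numerically, in the standard setting that places the three mutually
perpendicular 2-fold axes on the coordinate axes (the orientation
curated capsid structures ship in). Construction is self-verifying:
order 60, orthogonality and det = +1 to 1e-10, closure to 1e-8
(Frobenius), and conjugacy classes of sizes {1 identity, 15 two-fold,
20 three-fold, 24 five-fold} are all asserted every time the group is
built, so a transcription error cannot survive. Folds are classified
from the trace (trace = 1 + 2cos θ) and axes are +1-eigenvectors
oriented positive-z first (then x, then y).

Assembly applies all 60 operators to every chain of the asymmetric
unit; subunit labels are class letter (source chain) + operator index,
1-based, so `A1` is the identity copy. Published per-capsid labeling
conventions differ only by a permutation of copy indices; geometry, not
labels, is the contract, and the relative operator R_j·R_i⁻¹ between
any two subunits is recovered exactly as a group member.

## Interface detection and fold classes

A residue is an interface residue of a subunit pair when any heavy atom
lies within the contact cutoff (default 4.5 Å, the conventional
close-contact radius; configurable) of a heavy atom of the partner.
Search uses a k-d tree over all heavy atoms; because the tree query is
exact, results are identical to the all-pairs computation, which the
test suite re-verifies on random configurations. `num_contacts` is the
number of distinct partner residues in contact (contact-table
semantics); atomic contact counts are kept alongside.

An interface's fold class is the fold of the relative operator between
its subunits. Contacts between chains of one asymmetric unit (relative
operator = identity) are quasi-equivalent by construction; cross-class
contacts whose contact centroid lies more than 10° off the relative
operator's rotation axis do not wrap a true icosahedral axis and are
likewise tagged `quasi` rather than forced into 2/3/5.

## SASA and BSA

Solvent-accessible surface areas use the Shrake–Rupley construction:
each heavy atom's sphere of radius r_vdw + 1.4 Å (water probe) is
sampled at 960 deterministic golden-spiral points; points inside any
neighbor's expanded sphere are buried. Van der Waals radii are Bondi
values shipped as a table; unknown elements raise with the offending
atoms listed. Per-residue SASA is the sum over the residue's heavy
atoms; BSA = SASA(subunit alone) − SASA(complex), asserted ≥ −0.5 Ų
(discretization tolerance) and clamped at 0 for reporting. Whether a
quantity is computed in the dimer or full-capsid context is the
caller's choice and should be reported with results; both are
supported.

## CapsidMaps and conservation

Interface residues are projected about the capsid center (assumed at
the origin; optional centroid re-centering) to ψ = arccos(v_z/|v|) ∈
[0°, 180°] and φ = atan2(v_y, v_x) ∈ [−180°, 180°); the radial distance
is discarded, making maps comparable across capsid sizes. The
representative point per residue is the side-chain heavy-atom centroid
(Cα for glycine and bead models; a Cα-only mode exists for sensitivity
checks) — side chains carry the interface chemistry.

Sequence conservation is strict column identity with no gaps; column ↔
residue-number correspondence is derived by counting non-gap positions
against a per-virus numbering offset. Spatial conservation keys
residues through MSA columns (the residue compared across viruses is
the *aligned* one, not a nearest map neighbor), compares chains
class-wise (A with A, …), and requires |Δφ| ≤ 3° (computed on the
circle, so maps do not split at ±180°) and |Δψ| ≤ 3° against every
other member by default; a quorum fraction is available instead. The
per-asymmetric-unit map is *equivariant* under rotations (its points
rotate with the structure); the rotation-invariant object is the pooled
angle set of all 60 copies, and both properties are tested. Hot spots
are the intersection of the three per-virus sets, reported in the
reference virus's numbering (configurable, first member by default).

## WHAM, PMF and binding energies

Window data are ξ samples (nm) under harmonic biases (kJ·mol⁻¹·nm⁻²,
converted at exactly 4.184 kJ/kcal; k_B = 0.0019872 kcal·mol⁻¹·K⁻¹,
default 300 K). Histograms share one grid; bins are left-closed /
right-open with the final edge nudged past the maximum sample, and
counts conserve samples exactly.

The WHAM equations are solved in two stages: first the equivalent
convex log-likelihood
A(f) = −Σⱼ Nⱼfⱼ + Σ_b M_b ln Σₖ Nₖ exp(fₖ − wₖᵦ/k_BT)
is minimized with L-BFGS (its stationarity condition *is* the WHAM
fixed point; direct Picard iteration alone can need >10⁵ sweeps on
stiff-window problems), then the direct iteration is run to verify and
polish self-consistency to max|ΔFⱼ| < 1e-8 kcal/mol (gauge F₁ = 0).
Everything is computed in log space with log-sum-exp stabilization; the
`converged` flag is honest and an unconverged solution is refused
downstream unless forced. Windows whose occupied supports do not chain
together raise a disconnected-support error naming the gap.

The PMF is g = −k_BT ln P on occupied bins, zeroed on the mean over the
last occupied 5% of the sampled ξ range — a plateau average is robust
to single-bin noise. ΔG is the global minimum (ties toward smaller ξ);
a minimum inside the reference plateau means no stable complex and is
flagged with ΔG = 0. ΔΔG is a plain difference with errors summed in
quadrature; uncertainties come from a circular block bootstrap over
each window's series (block length 1 by default — exact-sampler data
are uncorrelated; set the block length to the correlation time for MD
data, and subsample by a stride if desired; no automatic equilibration
detection is attempted).

**Bin width.** The API default is 0.05 nm, but accuracy requires bins
that resolve the biased distributions: at k = 2000 kJ·mol⁻¹·nm⁻² and
300 K the window width is σ = √(k_BT/k) ≈ 0.035 nm, so analyses at that
stiffness use 0.02 nm (≈ σ/2). Coarser bins leave a visible binning
bias because the bias potential is evaluated at bin centers.

## Synthetic fixtures

`make_toy_family` builds Cα-bead capsid families whose ground truth is
known by construction and returned with the data. Planted interface
residues sit a fixed 1.8 Å perpendicular to a 2-fold axis (each chain
gets its own equatorial axis; near-polar axes are avoided because φ
degenerates at the poles), so their own 2-fold image lies 3.6 Å away —
inside the 4.5 Å cutoff at *any* radius, which is what makes the
angular noise of conserved positions harmless: noisy directions are
re-projected onto the axis-hugging radius. Non-conserved interface
residues move to a different 2-fold axis (≥ 36° away) in non-reference
members, staying genuine interface residues while leaving the 3°
overlap window by an order of magnitude. Non-interface residues wind
into a ~3.9 Å-spaced helix at a much larger radius along the direction
that maximizes the minimal symmetry-image distance, with chains
staggered radially so the only contacts in the assembled capsid are the
planted ones — every member is re-checked by a brute-force contact scan
at build time and an infeasible specification raises. Sequences are
gap-free with planted columns held identical and accidental
conservation of other columns actively broken, so alignment column i
maps to residue i+1 for every member.

What the toy family does *not* emulate: side-chain geometry and
chemistry, gapped alignments and numbering offsets, quasi-equivalent
conformational differences between chains, crystallographic noise.
Passing the planted-recovery tests therefore demonstrates the
correctness of the pipeline's set logic, geometry and thresholds — not
performance on real structural data, which depends on curation and
orientation of the inputs.

`sample_umbrella` draws each window's samples exactly from
p(ξ) ∝ exp(−(U+w)/k_BT) by inverse-CDF interpolation on a 10⁴-point
grid over the potential's support (trapezoid CDF; a window whose biased
density collapses below grid resolution raises). There is no
Markov-chain or time-correlation error, so WHAM must recover U up to
pure counting statistics. Potential forms: harmonic, a symmetric
quartic double well, and a Morse-like binding curve
U = D((1−e^{−(ξ−ξ₀)/w})² − 1) with depth D, minimum ξ₀ and plateau → 0.
Defaults (D = 5 kcal/mol, ξ₀ = 2.5 nm, w = 0.4 nm, plateau 7 nm) mirror
a subunit dimer pulled from contact to non-interacting separation; with
42 windows that span gives ≈ 0.11 nm spacing. At 5×10⁴ samples/window
the recovered ΔG carries ≈ 0.06 kcal/mol of window-linking statistical
noise (measured over independent seeds, mean error ≈ 0), which is why
recovery checks average a few seeded replicates when asserting the
absence of systematic bias.

## Known limitations

- Inputs must share the standard icosahedral orientation; no automatic
  superposition between differently oriented capsids is attempted.
- Quasi-equivalent (hexamer-style) contacts are tagged, not classified.
- The reaction coordinate is assumed non-periodic (COM separation).
- Bootstrap errors are a stand-in for whatever error model produced
  published ± values; no claim of equivalence is made.
- mmCIF and binary trajectory formats are out of scope; chains with
  more than 62 subunits are written as one MODEL per subunit (a
  documented PDB dialect the reader understands).
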