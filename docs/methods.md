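# Methods

## Model

A protein chain is reduced to its Cα atoms joined by ~3.8 Å virtual bonds.
Internal coordinates are the virtual-bond angles θ (planar angle at each
interior Cα, in [0°, 180°]) and the virtual-bond dihedrals γ (right-handed
torsion over four consecutive Cα atoms, reported in [0°, 360°) so that the
240° helix-exit basin keeps a single coordinate). Angles are degrees at
every interface and radians internally.

The multitorsional potential of a window of `m` residues starting at
residue `i` couples every θ and γ of the window in one product per
multiplicity `M`:

- the first and the penultimate dihedral enter through
  `sin[M(γ+Ψ)]` factors — they control the direction in which the chain
  enters/leaves a folded stretch;
- every interior dihedral enters through `cos[M(γ+Ψ)]` — with γ ≈ 30–70°
  (α-helix) and Ψ small and negative these factors are positive and keep
  all window terms of a helix the same sign, which is precisely the
  cooperativity being modeled;
- every factor carries `(sin θ)^M` (window ends) or `(sin θ)^{2M}`
  (interior), so terms vanish as the geometry opens away from θ ≈ 90° and
  the potential needs no secondary-structure assignment.

The chain energy sums all windows with `7 ≤ m ≤ m_max`; `m_max = 20` by
default (window count grows linearly in chain length, and contributions
decay geometrically with `m`, so longer windows add nothing measurable).
Each Ψ is indexed by the *ordered* pair of reduced residue types
(G/A/P: glycine, proline, alanine-class-for-everything-else) on the axis
bond of its γ — nine parameters. Multiplicities share one Ψ table; the
per-M weights `w_M ≥ 0` are the only multiplicity-specific parameters.

When the term is added to a host force field it is scaled by
`f_n(T) = ln(e + e⁻¹) / ln(exp(x) + exp(−x))`, `x = (T/T_o)^(n−1)`, with
`T_o = 300 K` and order `n = 4` for this term (configurable in
`TemperatureConfig`): cooperative terms melt as T rises above `T_o`.

## Conventions and numerical choices

- **Dihedral sign**: right-handed, `atan2((n₁×n₂)·b̂₂, n₁·n₂)`; a mirror
  reflection maps γ → 360° − γ.
- **Collinear triples** (θ = 0° or 180°): the adjacent γ is marked
  undefined rather than NaN-propagated; every energy term containing it
  carries a vanishing sin θ factor, and the corresponding Cartesian
  gradients are set to zero (the true directional derivative of each term
  vanishes there).
- **Chain breaks**: a virtual bond is contiguous iff its length lies in
  [2.8, 4.8] Å (3.8 Å ± generous tolerance) and, when reading PDB, the
  author residue numbers are consecutive. Windows touching an undefined
  angle contribute zero; segments never span a break, even under a HELIX
  record.
- **Chain building** (fixture generator): first three atoms placed
  canonically (origin, +x axis, xy-plane), the rest by natural-extension
  placement; `internal_from_trace ∘ build_trace_from_internal` is the
  identity on internal coordinates to ≲1e-13°.
- **Gradients**: analytic throughout — product-rule derivatives w.r.t.
  every θ/γ (prefix/suffix exclusion products per window), chained through
  the standard Cartesian derivatives of bond angles and dihedrals.
  Validated against central finite differences (max relative deviation
  ~1e-10 on random traces).

## Folded-helical (FH) segment extraction

An `m`-residue window starting at residue `k` (0-based) is folded-helical
if its interior angles satisfy θ < 100° (vertices `k+2 … k+m−3`) and
γ ∈ [0°, 70°] *closed* (axis indices `k+2 … k+m−4`); the two residues at
each end stay unconstrained. Extraction returns **maximal** windows (a
returned segment cannot be extended one residue either way) — sub-windows
are regenerated inside the chain-energy sums, so keeping them would double
count. Since growing a window only adds constraints, the right end of the
longest valid window is monotone in the start index, which gives a simple
linear-scan extraction with an O(n²) worst case.

Stretches covered by PDB HELIX records qualify independently of the angle
test; the record covers the *constrained* interior, so the segment extends
one residue past each record end. Record-derived stretches that overlap
angle-derived ones are merged into their union and flagged
`by_helix_record`. PDB reading (ATOM/HELIX, altloc by highest occupancy
with ties to 'A'/blank) is delegated to gemmi.

Datasets serialize to TSV with one row per θ position; because a fragment
has one more θ than γ, the γ/pair columns of the last row per segment are
empty.

## Maximum-likelihood fit

FH fragments are modeled as Boltzmann-distributed under the fragment
energy `V` with a *flat* base measure dΘ dΓ (θ ∈ (0°, 180°),
γ ∈ [0°, 360°)). The objective is
`L = Σ_j V_j/RT + Σ_j ln Q_{n_j}`. Two structural facts shape the
implementation:

1. **Q_n is independent of Ψ at fixed weights.** Every γ appears in `V`
   only through γ+Ψ, and γ integrates over a full circle, so the Ψ shifts
   change variables away. Fitting Ψ therefore only minimizes `Σ V/RT`
   (BFGS with analytic ∂L/∂Ψ — the phase-angle gradient equals the summed
   dihedral gradient — to gradient-norm ≲1e-6; Ψ wrapped to (−180°, 180°];
   optional ±60°/±120° multistart guards against periodic local minima).
   `RT` is a positive rescaling and cannot move the argmin.
2. **`min_Ψ Σ V` is concave in (w₁, w₂).** It is a minimum of functions
   linear in the weights, so scanning weights on `w₁ + w₂ = 1` *without*
   the ln Q terms always ranks an extreme weight lowest. The weight scan
   therefore offers `include_lnQ=True`, adding plain-Monte-Carlo
   `ln Q_n` estimates (seeded, with standard errors available from
   `estimate_partition`), which makes the ranking a proper likelihood
   comparison; the default keeps the raw `Σ V/RT` objective used for the
   Ψ fit itself.

`estimate_partition` integrates `exp(−V/RT)` over the flat measure in
degree units; with the potential switched off it returns exactly
`180^(n−2)·360^(n−3)`, and the standard error scales as `n_samples^(−1/2)`.
For datasets mixing residue compositions within one fragment length, the
ln Q estimate uses the first fragment's composition — adequate for the
homogeneous synthetic sets used here, a documented approximation otherwise.

## Synthetic fragment generator

`sample_boltzmann_fragments` draws fragment angle sets from
`exp(−V/RT)·dΘdΓ` by Metropolis sampling: `count` independent
single-fragment chains are run in parallel (vectorized single-site sweeps),
each proposal mixing a Gaussian step of σ = 10° with a full-range redraw at
probability 0.15 so chains hop between the potential's periodic basins;
θ proposals outside (0°, 180°) are rejected, γ wraps. Default burn-in is
1,000 sweeps plus 10 decorrelation sweeps, and each chain's final state is
one sample — parallel chains replace serial thinning, giving independent
draws at the same cost. Everything is reproducible from the seed.

**Calibration of the generator temperature.** `V` is a bounded, weak
potential (|V| ≲ 3 for a 10-residue fragment) on a 15-dimensional angle
space; at RT = 1 the Boltzmann ensemble is indistinguishable from uniform
noise and nothing helical is generated. The recovery studies therefore run
at **RT = 0.05**, where sampled fragments genuinely look folded-helical
(θ = 90° ± 14°) and the likelihood carries enough information to pin the
alanine-pair phase angle to a few degrees from a few hundred fragments.
The weight-scan demonstration runs at **RT = 0.2**: there the integrand of
`Q_n` spans a modest dynamic range and plain Monte Carlo estimates of
`ln Q_n` are well-conditioned (at RT = 0.05 they would need importance
sampling). Because the fit-side RT only rescales the objective, the
generator RT does not bias the recovered Ψ.

What the generator does *not* emulate: sequence heterogeneity along a
fragment (recovery sets are alanine-only, so only Ψ_AA is identifiable),
experimental coordinate noise, the length mixture of a real segment
corpus, and any correlation between neighboring fragments of one chain.
Passing recovery tests show the estimator is correct and well-conditioned
on model-generated data; they say nothing about model adequacy for real
PDB geometry.

## Diagnostic maps

The **terminal-dihedral surface** fixes an idealized fragment (default
n = 20, all θ = 90°, interior γ = 45°, all pairs alanine-type) and sweeps
its first and last dihedral (γ_N, γ_C) over [0°, 360°)², evaluating the
full fragment energy at each grid point (default grid 5°; 1° for the
headline numbers, ~1 s per surface vectorized). A useful structural fact,
exploited in the tests: in this construction γ_N enters only the windows
anchored at the fragment head (as the leading sine factor) and γ_C only
those ending at the tail, the two meeting in the single full-length
window. For a single-multiplicity parameter set the surface is therefore
`const − B·sin(γ_N+Ψ) − B·sin(γ_C+Ψ) − C·sin(γ_N+Ψ)·sin(γ_C+Ψ)` with
B ≫ C > 0, and its extrema sit exactly at γ = 90°−Ψ (minimum) and
270°−Ψ (maximum) on each axis — 180° apart by construction. Mixed
multiplicities shift the minimum toward 90° (set B: 89° at 1° grid).

`locate_extrema` reports grid-local extrema under periodic boundaries
(8-neighborhood; plateau cells count when at least one neighbor is
strictly worse, so a constant surface has none). The **component map**
tabulates every window term U(i, m), indexed by the window *start*
residue i and length m; its nansum reconstructs the chain energy exactly,
helical stretches appear as blocks of negative entries, and windows
spanning a helix boundary are near zero or positive.

## Problem sizes and runtime

Defaults keep everything desk-scale: 1° surfaces are 360² ≈ 1.3·10⁵
energy evaluations (vectorized, seconds); the recovery study samples
5,000 fragments of length 10 (about three minutes, dominated by the
Metropolis burn-in); the brute-force oracle checks run on chains of
n ≤ 25. Corpus-scale refitting of the nine Ψ from the PDB (10⁶ segments
from ~10⁵ structures) is deliberately out of scope: the fitting machinery
is validated by parameter recovery on synthetic data instead, and the
bundled sets A/B/C ship as data files.

## Known limitations

- The extended-strand analogue of the potential is not implemented; only
  the folded (helical) variant is.
- The potential is applied per contiguous chain segment; windows never
  cross chain breaks, and multi-chain coupling is out of scope.
- `ln Q_n` by plain Monte Carlo degrades at low RT (see calibration note).
- Extraction returns maximal segments; if a corpus convention counted all
  qualifying sub-windows instead, counts would differ (energies would not:
  the chain sums regenerate sub-windows internally).
- HELIX-derived and angle-derived segments are merged by interval union;
  no deduplication policy beyond that is applied.
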