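"""Maximum-likelihood recovery of a known phase angle from synthetic data.

Samples fragments from the Boltzmann distribution of the fragment potential
at the mixed-multiplicity parametrization (Ψ_AA = −27.1°, w = (0.6, 0.4)),
then refits the phase angles and compares with the generator value.  A
small run (600 fragments) already lands within a couple of degrees; the
acceptance suite repeats this with 5,000 fragments.
"""

from mtorpot import bundled_param_set, fit_phase_angles, sample_boltzmann_fragments

true = bundled_param_set("B")
print(f"generator: psi_AA = {true.psi_deg['AA']} deg, weights (0.6, 0.4), RT = 0.05")

fragments = sample_boltzmann_fragments(true, n=10, count=600, RT=0.05,
                                       seed=2026, burn_in=400, thin=10)
print(f"sampled {fragments.count} fragments of length {fragments.n}; "
      f"mean theta = {fragments.theta.mean():.1f} deg "
      f"(folded-helical geometry clusters near 90)")

result = fit_phase_angles(fragments, fixed_weights=(0.6, 0.4))
err = result.psi_deg["AA"] - true.psi_deg["AA"]
print(f"fitted psi_AA = {result.psi_deg['AA']:+.2f} deg "
      f"(error {err:+.2f} deg, converged={result.converged}, "
      f"|grad| = {result.grad_norm:.1e})")
print("Only the AA pair is identifiable from alanine-only fragments; the")
print("other eight phase angles keep their zero initialization.")
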