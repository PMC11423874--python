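"""The bi-exponential NAD(P)H decay model and its metabolic readouts.

Builds a typical macrophage decay parameter set and prints the derived
quantities: the amplitude-weighted mean lifetime (tau_avg, higher =
more oxidative phosphorylation), the protein-bound NAD(P)H fraction,
and the optical redox ratio from channel intensities.
"""

from flimmet import (
    DecayParams,
    average_lifetime,
    bound_fraction,
    evaluate_decay,
    optical_redox_ratio,
)

# 70% free NAD(P)H at 0.5 ns, 30% protein-bound at 2.8 ns
params = DecayParams(alpha1=0.7, tau1=0.5, alpha2=0.3, tau2=2.8)

print(f"I(0)      = {evaluate_decay(params, 0.0):.3f}   (= alpha1 + alpha2 + C)")
print(f"I(1 ns)   = {evaluate_decay(params, 1.0):.3f}")
print(f"tau_avg   = {average_lifetime(params):.3f} ns  "
      "(amplitude-weighted mean lifetime)")
print(f"bound frac= {bound_fraction(params):.3f}     "
      "(share of protein-bound NAD(P)H)")

orr = optical_redox_ratio(fad_intensity=150.0, nadph_intensity=100.0)
print(f"ORR       = {orr:.3f}     (FAD / NAD(P)H intensity)")
# tau_avg = 1.19 ns sits between the free (0.5 ns) and bound (2.8 ns)
# lifetimes; a population with larger tau_avg or ORR is more oxidative.
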