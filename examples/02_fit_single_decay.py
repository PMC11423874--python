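"""Fit one TCSPC photon histogram and check the fit quality.

Simulates a 10^5-photon decay histogram (256 bins over the 12.5 ns
period of an 80 MHz laser), fits the bi-exponential model by
Neyman-weighted least squares, and prints the recovered parameters,
the reduced chi-square, and whether the fit passes the < 1.3 rule.
"""

from flimmet import DecayParams, TimeAxis, fit_decay, simulate_decay_histogram

truth = DecayParams(alpha1=0.7, tau1=0.5, alpha2=0.3, tau2=2.8)
axis = TimeAxis()  # 256 bins, 12.5 ns period

hist = simulate_decay_histogram(truth, n_photons=100_000, axis=axis, rng=42)
result = fit_decay(hist, axis)

print(f"true   tau1={truth.tau1} ns, tau2={truth.tau2} ns, bound=0.30, "
      f"tau_avg=1.190 ns")
print(f"fitted tau1={result.params.tau1:.3f} ns, tau2={result.params.tau2:.3f} ns, "
      f"bound={result.bound_fraction:.3f}, tau_avg={result.tau_avg:.3f} ns")
print(f"reduced chi2 = {result.reduced_chi2:.3f}  "
      f"(good fit: {result.quality_pass}, threshold 1.3)")
# With 1e5 photons tau_avg is typically recovered within 1-2%, and a
# correctly specified fit gives reduced chi2 near 1.
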