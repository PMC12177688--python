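"""Phasor analysis of a single TCSPC decay.

Simulates a monoexponential decay at 5.9 ns (the lifetime of the dye
bound to the HT-CMHYA mutant in cells) with 10^6 photons at a 25 ns
repetition period, then recovers the lifetime three ways: phase lifetime,
modulation lifetime, and a Poisson maximum-likelihood fit.
"""

from pocketflim import fit_monoexponential, phasor_lifetime, phasor_transform, simulate_decay

TAU_TRUE = 5.9  # ns

decay = simulate_decay(TAU_TRUE, n_photons=10**6, n_bins=256, period=25.0, seed=1)
p = phasor_transform(decay)
tau_phase, tau_mod = phasor_lifetime(p)
fit = fit_monoexponential(decay)

print(f"true lifetime        : {TAU_TRUE:.3f} ns")
print(f"phasor (g, s)        : ({p.g:.4f}, {p.s:.4f})")
print(f"phase lifetime       : {tau_phase:.3f} ns")
print(f"modulation lifetime  : {tau_mod:.3f} ns")
print(f"ML fit               : {fit.tau:.3f} +/- {fit.tau_se:.3f} ns")
print()
print("For a pure monoexponential decay, the phasor lies on the universal")
print("semicircle and all three estimators agree with the true lifetime to")
print("within shot noise; a phase lifetime below the modulation lifetime")
print("would instead flag a mixture of species.")
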