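"""Estimate burst size, latent period and adsorption rate from curves.

Simulates noisy one-step growth and adsorption time series with known
parameters and recovers them with the estimators.
"""

import phagekit as pk
from phagekit.simulate import simulate_kinetics

sim = simulate_kinetics(
    burst=38, latent=35, adsorption_rate=0.5, noise_sd=0.1, n_replicates=4, seed=11
)

est = pk.one_step_growth(sim.growth, adsorption_duration=sim.truth.adsorption_duration)
print(f"burst size:    {est.burst_size:.1f} particles/cell  (truth 38)")
print(f"latent period: {est.latent_period:.0f} min            (truth 35)")
print(f"baseline (infection centers): {est.baseline:.1f} PFU, "
      f"plateau mean {est.plateau_mean:.1f} PFU over grid points "
      f"{est.plateau_window[0]}..{est.plateau_window[1] - 1}")
# burst size = mean plaque count at the first plateau / mean count before
# the initial increase; latent period = last pre-rise time + adsorption time

fit = pk.adsorption_kinetics(sim.adsorption[0], sim.truth.input_titer)
print(f"adsorption rate: {fit.rate:.3f} /min (truth 0.5), R^2={fit.r_squared:.3f}")
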