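"""Simulate a boreal June-September season of drivers and paired chamber fluxes.

The generator produces half-hourly xylem temperature, light (PPFD), humidity
and sap flux density, then assembles dark-chamber (-R' + T) and transparent-
chamber (-R' + P + T) net CO2 fluxes from known monthly parameters, with
Gaussian measurement noise.  Negative flux = efflux to the atmosphere.
"""

import stemflux as sf

drivers = sf.generate_drivers(sf.SimConfig(seed=1))
truth = sf.default_truth(noise_sd=0.1, rng_seed=1)
dark, transparent, components = sf.generate_true_fluxes(drivers, truth)

print(f"{len(drivers)} half-hour steps, "
      f"{drivers.index[0]:%Y-%m-%d} .. {drivers.index[-1]:%Y-%m-%d}")
print("\ndriver ranges:")
print(drivers[["temp", "ppfd", "rh", "sapflux"]].describe()
      .loc[["min", "mean", "max"]].round(1))
print("\nmean fluxes (umol m-2 s-1): "
      f"dark {dark['fco2'].mean():.3f}, transparent {transparent['fco2'].mean():.3f}")
print("mean true components: "
      f"R' {components['r_prime'].mean():.3f}, P {components['p_true'].mean():.3f}, "
      f"T {components['t_true'].mean():.3f}")
print("\nThe transparent chamber loses less CO2 than the dark one because bark")
print("photosynthesis refixes part of the respired CO2 during daylight.")
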