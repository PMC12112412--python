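"""Synthetic station weather and thermal-time accumulation.

Draws 5 years of daily weather for the Sadoré climate envelope and
accumulates growing degree days with a 15 C base and 34 C optimum. The
annual rainfall of the generated series sits near the station's 565 mm
long-run mean; the thermal-time sum is what drives phenology in
degree-day-based crop models.
"""

import yieldstab as ys

weather = ys.generate_weather("sadore", n_years=5, seed=3)
annual = weather.groupby(weather["date"].dt.year)["rain"].sum()
print("annual rainfall (mm):")
print(annual.round(0).to_string())
print(f"mean {annual.mean():.0f} mm (station long-run mean ~565 mm)")

params = ys.ThermalTimeParams(tbd=15.0, tod=34.0)
one_year = weather.iloc[:365]
gdd = ys.cumulative_thermal_time(one_year, params)
print(f"\nthermal time accumulated over year 1: {gdd.iloc[-1]:.0f} degC d")
print(f"single hot day (mean 40 C) contributes {ys.thermal_time(40.0, params):.0f} degC d (plateau)")
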