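"""Build a synthetic historical weather library, classify years into
warm/cold x wet/dry anomaly quadrants, and select analog donor years.

Run:  python examples/weather_library.py
"""

from collections import Counter

from eonrcast import (
    WeatherGenConfig,
    classify_year,
    generate_weather_library,
    select_scenario_years,
    splice,
)

lib = generate_weather_library(WeatherGenConfig(seed=1))
print(f"library: {len(lib)} years ({lib.years[0]}-{lib.years[-1]})")
print(f"long-term mean annual precip : {lib.mean_annual_precip():7.1f} mm")
print(f"long-term mean annual temp   : {lib.mean_annual_temp():7.2f} degC")

census = Counter(classify_year(lib, y, "annual").quadrant for y in lib.years)
print("\nannual anomaly quadrant census (every year falls in exactly one):")
for quad, n in sorted(census.items()):
    print(f"  {quad[0]:>4}/{quad[1]:<3} : {n} years")

target = 2010
print(f"\nanalog donor years for a {target} forecast:")
for scenario, label in [
    ("I", "same annual quadrant"),
    ("II", "same summer quadrant"),
    ("III", "5 prior years"),
    ("V", "20 prior years"),
    ("full35", "entire library"),
]:
    years = select_scenario_years(lib, target, scenario)
    shown = f"{years[:4]}..." if len(years) > 4 else f"{years}"
    print(f"  scenario {scenario:<6} ({label:<21}): {len(years):2d} donors {shown}")

# splice the observed spring of 2010 with a donor's summer/fall
donor = select_scenario_years(lib, target, "III")[0]
spliced = splice(lib[target], lib[donor], splice_doy=150)
print(
    f"\nspliced series: observed {target} weather through day 150, "
    f"then donor {donor}; total precip {spliced.precip.sum():.0f} mm "
    f"(observed year had {lib[target].precip.sum():.0f} mm)"
)
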