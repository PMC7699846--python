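"""Generate a synthetic check-in scenario and look at the hourly ramp.

The default configuration emulates the night of the 2014 Shanghai New
Year's Eve stampede: a 48-hour Poisson background of geotagged posts over
central Shanghai plus a four-hour evening hotspot at the Bund whose
intensity ramps in proportion to the reported crowd sizes
(120k : 160k : 240k : 310k people).
"""

from collections import Counter

import crowdwatch as cw

config = cw.ScenarioConfig(seed=42)
records, truth = cw.generate_scenario(config)

print(f"{len(records)} check-ins generated, "
      f"{int(truth.event_flags.sum())} from the event hotspot")

hourly = Counter(r.timestamp.replace(minute=0, second=0, microsecond=0)
                 for r in records)
ev0, ev1 = config.event_window
print("\nhour                       count")
for hour in sorted(h for h in hourly if abs((h - ev0).total_seconds()) <= 3 * 3600):
    marker = "  <- event window" if ev0 <= hour < ev1 else ""
    print(f"{hour:%Y-%m-%d %H:%M}   {hourly[hour]:5d}{marker}")

print("\nBackground hours hold ~120 posts; the event ramp peaks in the "
      "23:00 hour at roughly twice the background, mirroring the reported "
      "doubling of city-wide check-ins on the night of the disaster.")
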