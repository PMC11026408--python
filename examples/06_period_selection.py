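"""Select analysis windows clear of large volcanic eruptions.

Eruptions injecting >= 10 Tg of stratospheric sulfate perturb climate
sharply for a few years, violating the linear-trend assumption behind
the climate speed; any 20-year window within 5 years of one is dropped.
"""

import climspeed as cs

record = [
    cs.EruptionRecord(939, 25.0),   # large: excludes nearby windows
    cs.EruptionRecord(1100, 4.0),   # small: below the 10 Tg threshold
    cs.EruptionRecord(1258, 60.0),  # very large
]
periods = cs.select_clean_periods(record, (851, 1849), window=20,
                                  buffer_years=5, mass_threshold_tg=10.0)
print(f"{len(periods)} clean non-overlapping 20-yr windows out of 49 candidates")
dropped = 49 - len(periods)
print(f"{dropped} windows dropped near the {sum(e.sulfate_tg >= 10 for e in record)} large eruptions")
print("first five:", ", ".join(f"{p.start_year}-{p.end_year}" for p in periods[:5]))
# listed mode instead validates a user-supplied window list against the
# record, warning about any window that conflicts with a large eruption
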