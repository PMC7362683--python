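"""Rebuild the cohort x age-column staircase from published wave counts.

The published wave x age-group table of a four-wave 50+ panel is enough
to reconstruct the full cohort-sequential bookkeeping: each (wave, age
column) cell belongs to exactly one birth cohort under the anchor/offset
rule, so redistributing the cells yields the cohort x age-column table
without any micro-data.
"""

import aldlca as a

schedule = a.mhas_schedule()
wave_tab, cohort_tab = a.count_tables(None, schedule, cells=a.MHAS_TABLE1)

print("Input: wave x age-column counts")
print(a.MHAS_TABLE1.to_string(), end="\n\n")
print("Reconstructed: cohort x age-column staircase")
print(cohort_tab.to_string(), end="\n\n")
print("cohort totals:", cohort_tab.sum(axis=1).to_dict())
print("grand total:  ", int(cohort_tab.to_numpy().sum()))

# Each cohort occupies a short diagonal of age columns; reading down the
# columns, adjacent cohorts overlap in age, which is what lets the short
# panel segments be chained into a ~35-year age window.
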