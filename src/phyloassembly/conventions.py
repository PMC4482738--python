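"""Shared statistical conventions.

Z_CRIT is the two-sided 5% critical value of the standard normal; a
standardized effect size with |SES| > Z_CRIT is flagged significant at
P < 0.05 throughout the package.
"""

Z_CRIT = 1.96

DEFAULT_N_REPS = 999
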