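"""Published benchmark counts for eight colorectal cancer cell line
experiments, used as fixed inputs to worked-example arithmetic checks.

Values are raw counts (never derived statistics): per-line reference
profile sizes and covered-position counts; total reads and total SNVs per
experiment; per-replicate two-site read counts for the HCT116/HKE3 pair;
and pooled match/mismatch characterisation counts by impact and effect.
"""

# cell line -> (unique reference SNVs, covered positions)
COVERAGE_COUNTS = {
    "COLO205": (241, 68),
    "DLD1": (7649, 2239),
    "HCT15": (7649, 3356),
    "HCT116a": (2428, 1122),
    "HCT116b": (2428, 1003),
    "HKE3": (2428, 1379),
    "HT29": (462, 145),
    "RKO": (2676, 1112),
}

# cell line -> printed coverage percentage
COVERAGE_PCT = {
    "COLO205": 28.2, "DLD1": 29.3, "HCT15": 43.9, "HCT116a": 46.2,
    "HCT116b": 41.3, "HKE3": 56.8, "HT29": 31.4, "RKO": 41.6,
}
MEAN_COVERAGE_PCT = 39.8

# cell line -> (total SNVs, total reads, printed SNVs per 10^6 reads)
SNV_YIELD = {
    "COLO205": (38_777, 89_964_067, 431),
    "DLD1": (72_203, 37_087_864, 1947),
    "HCT116a": (177_948, 98_756_403, 1802),
    "HCT116b": (44_231, 96_249_743, 460),
    "HCT15": (55_195, 97_492_596, 566),
    "HKE3": (670_153, 255_394_483, 2624),
    "HT29": (38_456, 87_846_283, 438),
    "RKO": (250_042, 103_479_468, 2416),
}

# replicate -> (12wt/13wt, 12wt/13mut, 12mut/13wt)
HAPLOTYPE_REPLICATES = {
    "HCT116": [(40, 40, 0), (36, 34, 0), (60, 36, 0)],
    "HKE3": [(82, 46, 35), (55, 46, 30), (32, 62, 44), (31, 48, 38)],
}
HAPLOTYPE_POOLED_PCT = {
    "HCT116": (55.3, 44.7, 0.0),
    "HKE3": (36.4, 36.8, 26.8),
}

# impact level -> (matching SNVs, mismatched SNVs); totals 10231 / 193
IMPACT_COUNTS = {
    "HIGH": (280, 2),
    "MODERATE": (7254, 112),
    "LOW": (2651, 45),
    "MODIFIER": (46, 34),
}
# effect class -> (matching, mismatched)
EFFECT_COUNTS = {
    "missense": (7238, 134),
    "nonsense": (255, 5),
    "synonymous": (2738, 54),
}
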