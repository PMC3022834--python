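"""Printed reference values the implementation must reproduce."""

VL_GRID = (500, 1000, 2000, 3000, 4000, 5000, 10000, 20000,
           30000, 40000, 50000, 100000, 150000)

# Estimated CD4 slope (cells/uL/year) by period and viral load, 1 dp.
# Patient 1: male, 30 years, CDC-A, concurrent CD4 200, no hepatitis.
TABLE3_PATIENT1 = {
    "P6_12":   [85.6, 73.4, 61.2, 54.1, 49.0, 45.1, 32.9, 20.7, 13.6, 8.5, 4.6, -7.6, -14.7],
    "P12_18":  [64.1, 51.9, 39.7, 32.6, 27.5, 23.6, 11.4, -0.8, -7.9, -13.0, -16.9, -29.1, -36.2],
    "P18_24":  [59.8, 47.6, 35.4, 28.3, 23.2, 19.3, 7.1, -5.1, -12.2, -17.3, -21.2, -33.4, -40.5],
    "P24PLUS": [26.5, 14.3, 2.1, -5.0, -10.1, -14.0, -26.2, -38.4, -45.5, -50.6, -54.5, -66.7, -73.8],
}
# Patient 2: as patient 1 but hepatitis B/C co-infected.
TABLE3_PATIENT2 = {
    "P6_12":   [67.9, 55.7, 43.5, 36.4, 31.3, 27.4, 15.2, 3.0, -4.1, -9.2, -13.1, -25.3, -32.4],
    "P12_18":  [46.4, 34.2, 22.0, 14.9, 9.8, 5.9, -6.3, -18.5, -25.6, -30.7, -34.6, -46.8, -53.9],
    "P18_24":  [42.1, 29.9, 17.7, 10.6, 5.5, 1.6, -10.6, -22.8, -29.9, -35.0, -38.9, -51.1, -58.2],
    "P24PLUS": [8.8, -3.4, -15.6, -22.7, -27.8, -31.7, -43.9, -56.1, -63.2, -68.3, -72.2, -84.4, -91.5],
}

# Largest grid VL (copies/mL) keeping the predicted slope >= 20 for patient 1.
THRESHOLDS_PATIENT1 = {"P6_12": 20000, "P12_18": 5000, "P18_24": 4000, "P24PLUS": 500}

# Two-phase mean slopes (cells/uL/year) and 6-month suppression fraction.
EARLY_MEAN_SLOPE = 179.0
LATE_MEAN_SLOPE = 44.0
SUPPRESSED_6M = 0.83
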