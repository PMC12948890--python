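"""Printed group-mean T2 triplets (rest, 21k, control; ms) and the PRI
printed alongside them, used as worked-example inputs for the recovery
metrics.  Rows are (label, rest, t21k, control, printed_pri)."""

GLOBAL_ROWS = [
    ("Total", 43.1, 42.2, 43.1, 1.0),
    ("Left", 42.8, 41.9, 42.5, 0.8),
    ("Right", 43.4, 42.5, 43.8, 1.2),
    ("Male", 43.6, 42.7, 43.7, 1.1),
    ("Female", 41.5, 40.6, 41.6, 1.1),
]

COMPARTMENT_ROWS = [
    ("LF", 45.0, 44.4, 45.0, 1.0),
    ("LT", 36.4, 36.9, 36.0, 1.8),
    ("MF", 45.9, 44.2, 45.3, 0.6),
    ("MT", 40.8, 38.5, 41.4, 1.3),
    ("LatC", 42.4, 40.7, 40.5, -0.1),
    ("MedC", 43.7, 41.4, 43.4, 0.9),
    ("LPF", 44.2, 43.8, 44.4, 1.5),
    ("TrPF", 44.0, 42.8, 44.2, 1.2),
]

SUBGROUP_ROWS = [
    ("LF/Left", 44.6, 44.1, 44.4, 0.6),
    ("LF/Right", 45.4, 44.8, 45.6, 1.3),
    ("LF/Male", 46.0, 45.2, 45.7, 0.6),
    ("LF/Female", 42.2, 42.4, 42.8, -2.0),
    ("LT/Left", 36.3, 38.2, 36.4, 0.9),
    ("LT/Right", 36.5, 35.6, 35.5, -0.1),
    ("LT/Male", 35.9, 36.6, 36.0, 0.9),
    ("LT/Female", 37.6, 37.8, 36.0, 9.0),
    ("MF/Left", 46.3, 44.3, 45.5, 0.6),
    ("MF/Right", 45.5, 44.1, 45.0, 0.6),
    ("MF/Male", 46.7, 44.7, 46.0, 0.6),
    ("MF/Female", 43.7, 42.9, 43.3, 0.5),
    ("MT/Left", 40.7, 37.8, 39.7, 0.7),
    ("MT/Right", 40.9, 39.3, 43.4, 2.6),
    ("MT/Male", 42.1, 39.7, 43.1, 1.4),
    ("MT/Female", 37.3, 35.1, 36.7, 0.7),
    ("LatC/Left", 41.7, 41.2, 40.4, -1.6),
    ("LatC/Right", 43.3, 40.2, 40.5, 0.1),
    ("LatC/Male", 42.7, 40.9, 40.8, -0.1),
    ("LatC/Female", 41.7, 40.1, 39.5, -0.4),
    ("MedC/Left", 43.9, 41.1, 42.6, 0.5),
    ("MedC/Right", 43.4, 41.7, 44.2, 1.5),
    ("MedC/Male", 44.5, 42.2, 44.6, 1.0),
    ("MedC/Female", 41.3, 39.0, 40.0, 0.4),
    ("LPF/Left", 42.1, 41.9, 42.5, 3.0),
    ("LPF/Right", 40.6, 40.3, 41.1, 2.7),
    ("LPF/Male", 41.1, 41.4, 41.2, 0.7),
    ("LPF/Female", 42.4, 40.3, 43.7, 1.6),
    ("TrPF/Left", 44.3, 43.0, 44.4, 1.1),
    ("TrPF/Right", 43.6, 42.5, 44.0, 1.4),
    ("TrPF/Male", 44.7, 43.6, 44.6, 0.9),
    ("TrPF/Female", 42.0, 40.4, 43.1, 1.7),
]

ALL_ROWS = GLOBAL_ROWS + COMPARTMENT_ROWS + SUBGROUP_ROWS

# the four worked examples quoted to one decimal in the report tables that
# must reproduce exactly from the rounded triplets
CITED_EXACT = {"Total", "LatC", "LT", "MT/Right"}

# rows whose printed PRI is arithmetically unattainable from their own
# printed one-decimal triplet (interval analysis): the global "Right" row
# prints PRI 1.2 while any triplet consistent with (43.4, 42.5, 43.8)
# yields at least 1.3 — a source-table inconsistency, recorded as such
KNOWN_INCONSISTENT = {"Right"}
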