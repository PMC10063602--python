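"""Published conversion-table values used as fixed inputs in tests.

These are the printed score-to-measure rows (raw score, ability in logits,
2SE, and for the 57-item composite also the 0-100 columns) of the composite
memory metric and the legacy instruments, as released with the study the
crosswalk methodology comes from.  They serve as *inputs* to the transform
and matching routines, not as fitted output.

The legacy RAVLT column carries scores 0..14 only: the published table's
maximum-score row was not recoverable from the source text.
"""

# raw_score, theta (logits), 2SE, 0-100 value, 0-100 2SE
NMM_TABLE = [
    (0, -8.49, 2.86, 0.00, 16.83),
    (1, -7.47, 2.01, 6.01, 11.83),
    (2, -6.72, 1.67, 10.46, 9.84),
    (3, -6.12, 1.51, 13.95, 8.86),
    (4, -5.61, 1.40, 16.96, 8.27),
    (5, -5.16, 1.34, 19.64, 7.86),
    (6, -4.73, 1.29, 22.12, 7.58),
    (7, -4.34, 1.25, 24.46, 7.38),
    (8, -3.96, 1.23, 26.71, 7.22),
    (9, -3.59, 1.20, 28.89, 7.07),
    (10, -3.23, 1.17, 31.00, 6.88),
    (11, -2.89, 1.13, 33.00, 6.66),
    (12, -2.57, 1.09, 34.87, 6.40),
    (13, -2.28, 1.04, 36.57, 6.12),
    (14, -2.02, 0.99, 38.11, 5.85),
    (15, -1.78, 0.95, 39.51, 5.60),
    (16, -1.56, 0.91, 40.79, 5.37),
    (17, -1.36, 0.88, 41.97, 5.18),
    (18, -1.18, 0.85, 43.06, 5.00),
    (19, -1.01, 0.82, 44.08, 4.86),
    (20, -0.84, 0.80, 45.04, 4.73),
    (21, -0.69, 0.78, 45.96, 4.62),
    (22, -0.54, 0.77, 46.83, 4.53),
    (23, -0.39, 0.76, 47.68, 4.45),
    (24, -0.26, 0.74, 48.49, 4.38),
    (25, -0.12, 0.73, 49.28, 4.32),
    (26, 0.01, 0.73, 50.06, 4.27),
    (27, 0.14, 0.72, 50.82, 4.23),
    (28, 0.27, 0.71, 51.56, 4.20),
    (29, 0.39, 0.71, 52.30, 4.18),
    (30, 0.51, 0.71, 53.03, 4.17),
    (31, 0.64, 0.71, 53.75, 4.16),
    (32, 0.76, 0.71, 54.48, 4.16),
    (33, 0.88, 0.71, 55.20, 4.16),
    (34, 1.01, 0.71, 55.93, 4.17),
    (35, 1.13, 0.71, 56.66, 4.19),
    (36, 1.26, 0.72, 57.40, 4.22),
    (37, 1.38, 0.72, 58.15, 4.26),
    (38, 1.51, 0.73, 58.92, 4.30),
    (39, 1.65, 0.74, 59.70, 4.35),
    (40, 1.78, 0.75, 60.51, 4.41),
    (41, 1.92, 0.76, 61.34, 4.49),
    (42, 2.07, 0.78, 62.19, 4.58),
    (43, 2.22, 0.79, 63.09, 4.68),
    (44, 2.38, 0.82, 64.03, 4.80),
    (45, 2.55, 0.84, 65.03, 4.94),
    (46, 2.73, 0.87, 66.09, 5.11),
    (47, 2.93, 0.90, 67.23, 5.31),
    (48, 3.14, 0.94, 68.47, 5.55),
    (49, 3.37, 0.99, 69.83, 5.84),
    (50, 3.63, 1.05, 71.36, 6.18),
    (51, 3.92, 1.12, 73.09, 6.61),
    (52, 4.26, 1.21, 75.09, 7.13),
    (53, 4.66, 1.33, 77.44, 7.80),
    (54, 5.15, 1.48, 80.32, 8.72),
    (55, 5.78, 1.72, 84.01, 10.10),
    (56, 6.66, 2.13, 89.20, 12.56),
    (57, 7.83, 3.05, 100.00, 17.98),
]

# raw_score, theta, 2SE
CBT_TABLE = [
    (0, -7.48, 3.52),
    (1, -6.58, 2.63),
    (2, -4.64, 2.13),
    (3, -3.68, 2.02),
    (4, -2.68, 2.05),
    (5, -1.56, 2.04),
    (6, -0.55, 1.95),
    (7, 0.35, 1.90),
    (8, 1.21, 1.90),
    (9, 2.11, 1.98),
    (10, 3.01, 1.97),
    (11, 4.00, 2.27),
    (12, 5.31, 2.12),
    (13, 6.44, 2.41),
    (14, 7.75, 3.28),
]

# raw_score, theta, 2SE (scores 0..14; the published maximum-score row was
# not recoverable from the source text)
RAVLT_TABLE = [
    (0, -2.59, 2.73),
    (1, -1.63, 1.87),
    (2, -0.98, 1.52),
    (3, -0.50, 1.35),
    (4, -0.10, 1.25),
    (5, 0.25, 1.19),
    (6, 0.57, 1.15),
    (7, 0.88, 1.13),
    (8, 1.19, 1.13),
    (9, 1.50, 1.14),
    (10, 1.82, 1.18),
    (11, 2.16, 1.23),
    (12, 2.54, 1.33),
    (13, 3.00, 1.50),
    (14, 3.63, 1.84),
]

# full 30-item MMSE crosswalk column: raw_score, theta, 2SE
MMSE_TABLE = [
    (0, -7.06, 2.56),
    (1, -6.21, 1.79),
    (2, -5.62, 1.43),
    (3, -5.19, 1.25),
    (4, -4.85, 1.14),
    (5, -4.56, 1.06),
    (6, -4.30, 1.01),
    (7, -4.07, 0.97),
    (8, -3.84, 0.94),
    (9, -3.64, 0.92),
    (10, -3.43, 0.90),
    (11, -3.24, 0.89),
    (12, -3.05, 0.88),
    (13, -2.86, 0.87),
    (14, -2.68, 0.87),
    (15, -2.49, 0.87),
    (16, -2.30, 0.88),
    (17, -2.11, 0.88),
    (18, -1.92, 0.89),
    (19, -1.72, 0.91),
    (20, -1.51, 0.92),
    (21, -1.30, 0.94),
    (22, -1.07, 0.97),
    (23, -0.84, 1.00),
    (24, -0.58, 1.04),
    (25, -0.30, 1.10),
    (26, 0.01, 1.17),
    (27, 0.36, 1.28),
    (28, 0.81, 1.46),
    (29, 1.42, 1.81),
    (30, 2.27, 2.59),
]


def as_table(rows):
    """Build a ScoreToMeasureTable from printed (score, theta, 2SE[, ...]) rows."""
    import pandas as pd

    from nmm import ScoreToMeasureTable

    frame = pd.DataFrame(
        {
            "raw_score": [r[0] for r in rows],
            "theta": [r[1] for r in rows],
            "se": [r[2] / 2.0 for r in rows],
            "two_se": [r[2] for r in rows],
        }
    )
    return ScoreToMeasureTable(frame=frame)
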