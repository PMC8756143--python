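"""Published border-orientation angles and segmentation sizes used as inputs.

These are the printed per-approach results of the connectivity-based EC
segmentation study this package operationalizes, plus two earlier fMRI-based
segmentations (carried under neutral keys ``fmri_study_1`` and
``fmri_study_2``).  They serve as *inputs* for validating the package's
conversion arithmetic — the angle→percentage mapping and the MEC/LEC size
ratio — not as quantities the package claims to recompute from imaging data.

``REFERENCE_ANGLES`` maps approach → ``{"angle_pa", "pct_pa", "angle_ml",
"pct_ml"}``, each a ``(mean, mad)`` pair in degrees / percent (mean of both
hemispheres ± mean absolute deviation).  Two ML cells (the combined DTI
approach and ``fmri_study_2``) disagree with the linear mapping by one unit
in the last printed decimal because the printed angles are themselves
rounded; they are flagged in ``ANGLE_ROWS_CONSISTENT``.

``REFERENCE_SIZES`` maps approach → ``(mec_voxels, lec_voxels,
printed_ratio)`` at 0.5 mm isotropic resolution.
"""

REFERENCE_ANGLES = {
    "presubiculum/dCA1pSub": {
        "angle_pa": (45.1, 3.0), "pct_pa": (49.9, 3.3),
        "angle_ml": (29.8, 1.9), "pct_ml": (66.9, 2.1),
    },
    "RSC/OFC": {
        "angle_pa": (39.7, 15.3), "pct_pa": (55.9, 17.0),
        "angle_ml": (84.5, 11.1), "pct_ml": (6.1, 12.3),
    },
    "presubiculum/OFC": {
        "angle_pa": (41.3, 17.3), "pct_pa": (54.1, 19.3),
        "angle_ml": (81.2, 10.3), "pct_ml": (9.8, 11.5),
    },
    "RSC/dCA1pSub": {
        "angle_pa": (33.9, 1.2), "pct_pa": (62.3, 1.3),
        "angle_ml": (64.9, 18.8), "pct_ml": (27.9, 20.9),
    },
    "combined": {
        "angle_pa": (37.5, 10.6), "pct_pa": (58.3, 11.8),
        "angle_ml": (73.1, 17.4), "pct_ml": (18.7, 19.3),
    },
    "fmri_study_1": {
        "angle_pa": (6.8, 1.8), "pct_pa": (92.4, 2.0),
        "angle_ml": (85.5, 0.7), "pct_ml": (5.0, 0.8),
    },
    "fmri_study_2": {
        "angle_pa": (6.6, 0.5), "pct_pa": (92.7, 0.6),
        "angle_ml": (87.9, 0.9), "pct_ml": (2.4, 1.0),
    },
}

# (approach, axis) cells where the printed percentage matches the linear
# mapping of the printed (rounded) angle at one-decimal precision.
ANGLE_ROWS_CONSISTENT = {
    ("presubiculum/dCA1pSub", "pa"), ("presubiculum/dCA1pSub", "ml"),
    ("RSC/OFC", "pa"), ("RSC/OFC", "ml"),
    ("presubiculum/OFC", "pa"), ("presubiculum/OFC", "ml"),
    ("RSC/dCA1pSub", "pa"), ("RSC/dCA1pSub", "ml"),
    ("combined", "pa"),          # ML cell: 73.1° → 18.8 vs printed 18.7
    ("fmri_study_1", "pa"), ("fmri_study_1", "ml"),
    ("fmri_study_2", "pa"),      # ML cell: 87.9° → 2.3 vs printed 2.4
}

REFERENCE_SIZES = {
    "presubiculum/dCA1pSub": (12_759, 7_763, 1.64),
    "RSC/OFC": (12_971, 8_727, 1.49),
    "presubiculum/OFC": (13_614, 6_979, 1.95),
    "RSC/dCA1pSub": (11_045, 10_282, 1.07),
    "combined": (13_571, 7_379, 1.84),
    "fmri_study_1": (12_802, 16_028, 0.80),
    "fmri_study_2": (3_776, 11_008, 0.34),
}
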