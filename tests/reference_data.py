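"""Published reference values shared by the test modules.

REFERENCE_LADDER: the 21-replica HRE parameter table (index, T/K,
alpha, sigma/nm, epsilon/(kJ/mol)) exactly as printed.

REFERENCE_TABLE3: per-system mean principal radii of the gyration
tensor (nm) and the reported asphericity b, shape anisotropy k2 and
prolateness P.
"""

REFERENCE_LADDER = [
    (0, 300, 0, 0.273239, 0.50208),
    (1, 300.75, -0.05, 0.275077, 0.500581),
    (2, 301.5, -0.1, 0.276915, 0.499083),
    (3, 302.25, -0.15, 0.278753, 0.497584),
    (4, 303, -0.2, 0.280591, 0.496085),
    (5, 303.75, -0.25, 0.282429, 0.494587),
    (6, 304.5, -0.3, 0.284267, 0.493088),
    (7, 305.25, -0.35, 0.286105, 0.491589),
    (8, 306, -0.4, 0.287943, 0.49009),
    (9, 306.75, -0.45, 0.289781, 0.488592),
    (10, 307.5, -0.5, 0.291619, 0.487093),
    (11, 308.25, -0.55, 0.293457, 0.485594),
    (12, 309, -0.6, 0.295295, 0.484096),
    (13, 309.75, -0.65, 0.297134, 0.482597),
    (14, 310.5, -0.7, 0.298972, 0.481098),
    (15, 311.25, -0.75, 0.30081, 0.4796),
    (16, 312, -0.8, 0.302648, 0.478101),
    (17, 312.75, -0.85, 0.304486, 0.476602),
    (18, 313.5, -0.9, 0.306324, 0.475103),
    (19, 314.25, -0.95, 0.308162, 0.473605),
    (20, 315, -1, 0.31, 0.472106),
]

# system -> ((Rx, Ry, Rz), b, k2, P)
REFERENCE_TABLE3 = {
    "PASA-0.07": ((0.866, 0.607, 0.289), 0.481, 0.082, -0.169),
    "PASA-0.29": ((1.391, 0.452, 0.292), 0.731, 0.233, 0.911),
    "PGA-0.07": ((0.912, 0.557, 0.409), 0.466, 0.059, 0.603),
    "PGA-0.29": ((0.845, 0.563, 0.399), 0.430, 0.047, 0.435),
}

# molality (mol/kg) -> (n_ca, n_cl)
REFERENCE_ION_TABLE = {
    0.0: (0, 0),
    0.03: (6, 12),
    0.07: (14, 28),
    0.29: (58, 116),
    0.75: (145, 290),
    1.0: (190, 380),
}
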