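"""Published summary tables from an 82-case / 100-control AVNRT exome study.

These are the printed per-gene summary statistics of a whole-exome
case-control study of atrioventricular nodal reentrant tachycardia — carrier
counts for the gene-based collapsing candidates, per-group node scores of the
dual PPI networks, allele frequencies for association hits, cohort
demographics, and the variant lists used for cross-cohort replication
against a Danish AVNRT sequencing study.  They serve as demonstration
inputs and as ground truth for validating the statistics re-implemented
here; only counts and scores are stored, every derived number (odds ratio,
exact p, combined score) is recomputed at run time.
"""

from __future__ import annotations

STUDY_N_CASES = 82
STUDY_N_CONTROLS = 100
#: of the 82 cases, 25 were male
STUDY_N_MALE_CASES = 25

#: gene -> {stratum: (carrier cases, carrier controls)} for the 37
#: collapsing candidate genes, at both MAF strata.
BURDEN_CARRIERS: dict[str, dict[str, tuple[int, int]]] = {
    "CFTR":    {"MAF<0.01": (68, 51), "MAF<0.001": (6, 4)},
    "EVL":     {"MAF<0.01": (12, 0),  "MAF<0.001": (12, 0)},
    "HIP1R":   {"MAF<0.01": (7, 0),   "MAF<0.001": (2, 0)},
    "ABCC8":   {"MAF<0.01": (6, 0),   "MAF<0.001": (3, 0)},
    "COG4":    {"MAF<0.01": (7, 1),   "MAF<0.001": (3, 0)},
    "LAMC1":   {"MAF<0.01": (7, 1),   "MAF<0.001": (1, 1)},
    "AP1G2":   {"MAF<0.01": (7, 1),   "MAF<0.001": (1, 0)},
    "GAD2":    {"MAF<0.01": (5, 0),   "MAF<0.001": (1, 0)},
    "CSF2RB":  {"MAF<0.01": (5, 0),   "MAF<0.001": (2, 0)},
    "BEGAIN":  {"MAF<0.01": (5, 0),   "MAF<0.001": (3, 0)},
    "SYT10":   {"MAF<0.01": (5, 0),   "MAF<0.001": (1, 0)},
    "LRFN4":   {"MAF<0.01": (5, 0),   "MAF<0.001": (5, 0)},
    "NOS1":    {"MAF<0.01": (42, 35), "MAF<0.001": (39, 32)},
    "SLC12A4": {"MAF<0.01": (8, 2),   "MAF<0.001": (5, 2)},
    "ROBO1":   {"MAF<0.01": (8, 2),   "MAF<0.001": (7, 1)},
    "SFTPA2":  {"MAF<0.01": (12, 5),  "MAF<0.001": (11, 3)},
    "TSPOAP1": {"MAF<0.01": (9, 3),   "MAF<0.001": (4, 3)},
    "KCNV2":   {"MAF<0.01": (6, 1),   "MAF<0.001": (2, 1)},
    "PIK3CB":  {"MAF<0.01": (6, 1),   "MAF<0.001": (2, 1)},
    "CD163":   {"MAF<0.01": (4, 0),   "MAF<0.001": (4, 0)},
    "PRKAG2":  {"MAF<0.01": (4, 0),   "MAF<0.001": (1, 0)},
    "DOK4":    {"MAF<0.01": (4, 0),   "MAF<0.001": (2, 0)},
    "HEPH":    {"MAF<0.01": (4, 0),   "MAF<0.001": (2, 0)},
    "SCN1A":   {"MAF<0.01": (4, 0),   "MAF<0.001": (3, 0)},
    "PPFIA1":  {"MAF<0.01": (4, 0),   "MAF<0.001": (3, 0)},
    "EPHB4":   {"MAF<0.01": (7, 2),   "MAF<0.001": (6, 1)},
    "MMP2":    {"MAF<0.01": (7, 2),   "MAF<0.001": (4, 1)},
    "TCF3":    {"MAF<0.01": (7, 2),   "MAF<0.001": (3, 1)},
    "COL5A1":  {"MAF<0.01": (8, 3),   "MAF<0.001": (7, 2)},
    "ATP2C2":  {"MAF<0.01": (8, 4),   "MAF<0.001": (6, 1)},
    "SLC26A4": {"MAF<0.01": (6, 3),   "MAF<0.001": (4, 0)},
    "ASPH":    {"MAF<0.01": (6, 3),   "MAF<0.001": (4, 0)},
    "PSMB11":  {"MAF<0.01": (7, 4),   "MAF<0.001": (4, 0)},
    "RYR2":    {"MAF<0.01": (10, 8),  "MAF<0.001": (8, 3)},
    "COL4A3":  {"MAF<0.01": (6, 4),   "MAF<0.001": (5, 0)},
    "HIPK2":   {"MAF<0.01": (7, 9),   "MAF<0.001": (5, 0)},
    "SLC9B1":  {"MAF<0.01": (82, 100), "MAF<0.001": (77, 84)},
}

#: per-group PPI node scores for the 29 ranked genes:
#: gene -> ((n_nodes_1, total_1) or None, (n_nodes_2, total_2) or None).
#: None marks a gene absent from that network construction (printed NA).
PPI_GROUP_SCORES: dict[str, tuple[tuple[int, float] | None, tuple[int, float] | None]] = {
    "RYR2":    ((37, 23.226), (10, 6.533)),
    "NOS1":    ((12, 9.121),  (5, 4.469)),
    "SCN1A":   ((18, 10.844), (3, 1.297)),
    "CFTR":    ((8, 5.596),   (5, 3.750)),
    "EPHB4":   ((4, 2.463),   (11, 6.508)),
    "PRKAG2":  ((14, 7.370),  (2, 1.299)),
    "ROBO1":   ((3, 1.958),   (10, 6.524)),
    "ASPH":    ((4, 3.105),   (3, 2.897)),
    "MMP2":    ((4, 2.741),   (4, 2.589)),
    "ABCC8":   ((8, 4.278),   (1, 0.496)),
    "ATP2C2":  ((4, 2.077),   (5, 2.687)),
    "COL5A1":  ((3, 2.280),   (3, 2.280)),
    "CSF2RB":  ((2, 1.819),   (3, 2.340)),
    "PIK3CB":  ((3, 1.977),   (2, 1.361)),
    "COL4A3":  ((3, 1.782),   (2, 1.356)),
    "HIPK2":   ((3, 2.433),   (1, 0.625)),
    "SFTPA2":  ((2, 1.841),   (1, 0.917)),
    "HIP1R":   ((2, 1.800),   (1, 0.900)),
    "EVL":     ((1, 0.925),   (2, 1.503)),
    "SLC26A4": ((2, 1.143),   (2, 1.186)),
    "PPFIA1":  ((1, 0.933),   (1, 0.933)),
    "GAD2":    ((2, 0.929),   (2, 0.929)),
    "PSMB11":  ((1, 0.905),   (1, 0.905)),
    "TCF7L1":  ((1, 0.625),   (1, 0.625)),
    "LAMC1":   ((1, 0.553),   (1, 0.553)),
    "KCNV2":   ((1, 0.926),   None),
    "COG4":    ((1, 0.902),   None),
    "SLC12A4": ((1, 0.591),   None),
    "SYT10":   ((1, 0.400),   None),
}

#: published combined values (combined mean total score, combined mean node
#: count) for the same 29 genes, as printed to 3 / 1 d.p.
PPI_COMBINED_PUBLISHED: dict[str, tuple[float, float]] = {
    "RYR2": (14.880, 23.5), "NOS1": (6.795, 8.5), "SCN1A": (6.071, 10.5),
    "CFTR": (4.673, 6.5), "EPHB4": (4.483, 7.5), "PRKAG2": (4.335, 8.0),
    "ROBO1": (4.241, 6.5), "ASPH": (3.001, 3.5), "MMP2": (2.665, 4.0),
    "ABCC8": (2.387, 4.5), "ATP2C2": (2.382, 4.5), "COL5A1": (2.280, 3.0),
    "CSF2RB": (2.080, 2.5), "PIK3CB": (1.669, 2.5), "COL4A3": (1.569, 2.5),
    "HIPK2": (1.529, 2.0), "SFTPA2": (1.379, 1.5), "HIP1R": (1.350, 1.5),
    "EVL": (1.214, 1.5), "SLC26A4": (1.165, 2.0), "PPFIA1": (0.933, 1.0),
    "GAD2": (0.929, 2.0), "PSMB11": (0.905, 1.0), "TCF7L1": (0.625, 1.0),
    "LAMC1": (0.553, 1.0), "KCNV2": (0.463, 0.5), "COG4": (0.451, 0.5),
    "SLC12A4": (0.296, 0.5), "SYT10": (0.200, 0.5),
}

#: the published EPHB4 combined total (4.483) disagrees with the average of
#: its own printed group totals ((2.463 + 6.508)/2 = 4.486) by 0.003 — a
#: rounding slip in the published table; every other row reproduces exactly.
PPI_COMBINED_INCONSISTENT = frozenset({"EPHB4"})

#: association hits whose printed p reproduces exactly from rounded allele
#: frequencies: gene -> (tested allele, F_A, F_U, other allele)
ASSOC_ROWS: dict[str, tuple[str, float, float, str]] = {
    "SEMA6D": ("G", 0.414, 0.225, "T"),
    "ROBO2": ("G", 0.207, 0.075, "C"),
    "ATP2B2": ("A", 0.000, 0.060, "G"),
}

#: rare variants in the two strongest candidate genes of this cohort
#: (gene, hgvs_c, hgvs_p) — the internal side of the replication comparison
INTERNAL_CANDIDATE_VARIANTS: list[tuple[str, str, str]] = [
    ("RYR2", "c.4652A > G", "p.Asn1551Ser"),
    ("RYR2", "c.4094C > T", "p.Ala1365Val"),
    ("RYR2", "c.7076G > A", "p.Arg2359Gln"),
    ("RYR2", "c.3143A > G", "p.Asp1048Gly"),
    ("RYR2", "c.6040G > T", "p.Asp2014Tyr"),
    ("RYR2", "c.5774T > C", "p.Ile1925Thr"),
    ("RYR2", "c.11352T > G", "p.Ile3784Met"),
    ("RYR2", "c.13050A > C", "p.Leu4350Phe"),
    ("RYR2", "c.5923A > G", "p.Met1975Val"),
    ("RYR2", "c.5570C > T", "p.Pro1857Leu"),
    ("RYR2", "c.6092C > T", "p.Ser2031Phe"),
    ("RYR2", "c.3683C > A", "p.Thr1228Asn"),
    ("RYR2", "c.3721G > A", "p.Val1241Ile"),
    ("SCN1A", "c.3176A > T", "p.Asp1059Val"),
    ("SCN1A", "c.3053G > A", "p.Arg1018Lys"),
    ("SCN1A", "c.2141T > G", "p.Met714Arg"),
    ("SCN1A", "c.135C > G", "p.Asp45Glu"),
]

#: the Danish AVNRT cohort's rare variants in the same genes
#: (gene, hgvs_c, hgvs_p)
DANISH_COHORT_VARIANTS: list[tuple[str, str, str]] = [
    ("RYR2", "c.4652A > G", "p.Asn1551Ser"),
    ("RYR2", "c.1088T > C", "p.Ile363Thr"),
    ("RYR2", "c.1115T > A", "p.Leu372His"),
    ("RYR2", "c.1250G > A", "p.Arg417Gln"),
    ("RYR2", "c.2828T > C", "p.Leu943Ser"),
    ("RYR2", "c.3251G > A", "p.Arg1084Lys"),
    ("RYR2", "c.5186T > C", "p.Met1729Thr"),
    ("RYR2", "c.8162T > C", "p.Ile2721Thr"),
    ("RYR2", "c.10468G > T", "p.Ala3490Ser"),
    ("RYR2", "c.10528C > A", "p.Arg3510Ser"),
    ("RYR2", "c.10846G > T", "p.Ala3616Ser"),
    ("SCN1A", "c.3521C > G", "p.Thr1174Ser"),
    ("SCN1A", "c.1625G > A", "p.Arg542Gln"),
    ("SCN1A", "c.1199T > C", "p.Met400Thr"),
]
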