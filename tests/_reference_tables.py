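"""Published England 2010-2015 neonatal brain-injury surveillance values.

Each cell carries the printed numerator, the printed live-birth denominator
for its stratum-year, the reporting scale, the printed decimal places, and
the printed (rate, ci_low, ci_high) triple. ``exact=False`` marks the
handful of cells whose printed last digit is internally inconsistent with
any Poisson interval around the printed point estimate (rounding-boundary
or typesetting slips in the published tables); those are asserted to
last-digit closeness instead of equality, with the single digit-transposed
lower bound (printed 4.47 where every method gives 4.74) special-cased.
"""

# live births by (stratum, year)
LIVE_BIRTHS = {
    ("all", 2010): 687_007,
    ("all", 2011): 688_120,
    ("all", 2012): 694_241,
    ("all", 2013): 664_517,
    ("all", 2014): 661_496,
    ("all", 2015): 664_399,
    ("term", 2012): 640_787,
    ("term", 2013): 612_816,
    ("term", 2014): 607_972,
    ("term", 2015): 609_076,
    ("preterm", 2012): 49_949,
    ("preterm", 2013): 48_844,
    ("preterm", 2014): 49_379,
    ("preterm", 2015): 50_308,
}

# neonatal-unit admissions by year (complete-coverage years 2012-2015)
ADMISSIONS = {2010: 64_375, 2011: 72_678, 2012: 78_952, 2013: 80_199,
              2014: 84_981, 2015: 88_785}

# composite after-exclusion counts (complete years) and 2010/2011 observed
COMPOSITE_AFTER = {2010: 2_966, 2011: 3_331, 2012: 3_359, 2013: 3_358,
                   2014: 3_528, 2015: 3_418}
COMPOSITE_BEFORE = {2010: 3_011, 2011: 3_377, 2012: 3_404, 2013: 3_393,
                    2014: 3_558, 2015: 3_445}

# published adjusted ranges for the incomplete-coverage year 2010
ADJUSTED_2010_AFTER = (3_113, 3_566)
ADJUSTED_2010_RATE_RANGE = (4.53, 5.19)


def _cell(label, n, stratum, year, scale, dp, printed, exact=True):
    return {
        "label": label,
        "n": n,
        "d": LIVE_BIRTHS[(stratum, year)],
        "scale": scale,
        "dp": dp,
        "printed": printed,
        "exact": exact,
    }


CELLS = [
    # composite, before exclusions, all live births, per 1000
    _cell("composite-before 2012", 3404, "all", 2012, 1000, 2, (4.90, 4.47, 5.07), exact=False),
    _cell("composite-before 2013", 3393, "all", 2013, 1000, 2, (5.11, 4.94, 5.28)),
    _cell("composite-before 2014", 3558, "all", 2014, 1000, 2, (5.38, 5.20, 5.56)),
    _cell("composite-before 2015", 3445, "all", 2015, 1000, 2, (5.19, 5.01, 5.36)),
    # composite, after exclusions, all live births, per 1000
    _cell("composite-after 2012", 3359, "all", 2012, 1000, 2, (4.84, 4.68, 5.00)),
    _cell("composite-after 2013", 3358, "all", 2013, 1000, 2, (5.05, 4.89, 5.23)),
    _cell("composite-after 2014", 3528, "all", 2014, 1000, 2, (5.33, 5.16, 5.51)),
    _cell("composite-after 2015", 3418, "all", 2015, 1000, 2, (5.14, 4.97, 5.32)),
    # composite after exclusions, term births, per 1000
    _cell("composite-term 2012", 2074, "term", 2012, 1000, 2, (3.24, 3.10, 3.38)),
    _cell("composite-term 2013", 2105, "term", 2013, 1000, 2, (3.43, 3.29, 3.58)),
    _cell("composite-term 2014", 2189, "term", 2014, 1000, 2, (3.60, 3.45, 3.75)),
    _cell("composite-term 2015", 2116, "term", 2015, 1000, 2, (3.47, 3.33, 3.62), exact=False),
    # composite after exclusions, preterm births, per 1000
    _cell("composite-preterm 2012", 1285, "preterm", 2012, 1000, 2, (25.73, 24.36, 27.17)),
    _cell("composite-preterm 2013", 1253, "preterm", 2013, 1000, 2, (25.65, 24.27, 27.11)),
    _cell("composite-preterm 2014", 1339, "preterm", 2014, 1000, 2, (27.12, 25.70, 28.61)),
    _cell("composite-preterm 2015", 1302, "preterm", 2015, 1000, 2, (25.88, 24.51, 27.33)),
    # seizures, all live births, per 1000
    _cell("seizures 2012", 1445, "all", 2012, 1000, 1, (2.1, 2.0, 2.1), exact=False),
    _cell("seizures 2013", 1432, "all", 2013, 1000, 1, (2.2, 2.1, 2.3), exact=False),
    _cell("seizures 2014", 1360, "all", 2014, 1000, 1, (2.1, 2.0, 2.2), exact=False),
    _cell("seizures 2015", 1249, "all", 2015, 1000, 1, (1.9, 1.8, 2.0)),
    # intracranial haemorrhage, all live births, per 1000
    _cell("ich 2012", 754, "all", 2012, 1000, 1, (1.1, 1.0, 1.2)),
    _cell("ich 2013", 677, "all", 2013, 1000, 1, (1.0, 0.9, 1.1)),
    _cell("ich 2014", 689, "all", 2014, 1000, 1, (1.0, 1.0, 1.1)),
    _cell("ich 2015", 726, "all", 2015, 1000, 1, (1.1, 1.0, 1.2)),
    # intracranial haemorrhage, term births, per 10 000
    _cell("ich-term 2012", 110, "term", 2012, 10000, 1, (1.7, 1.4, 2.1)),
    _cell("ich-term 2013", 94, "term", 2013, 10000, 1, (1.5, 1.3, 1.9)),
    _cell("ich-term 2014", 104, "term", 2014, 10000, 1, (1.7, 1.4, 2.1)),
    _cell("ich-term 2015", 117, "term", 2015, 10000, 1, (1.9, 1.6, 2.3)),
    # perinatal/neonatal stroke, all live births, per 1000
    _cell("stroke 2012", 77, "all", 2012, 1000, 2, (0.11, 0.09, 0.14)),
    _cell("stroke 2013", 100, "all", 2013, 1000, 2, (0.15, 0.12, 0.18)),
    _cell("stroke 2014", 88, "all", 2014, 1000, 2, (0.13, 0.11, 0.16)),
    _cell("stroke 2015", 90, "all", 2015, 1000, 2, (0.14, 0.11, 0.17)),
    # hypoxic-ischaemic encephalopathy, all live births, per 1000
    _cell("hie 2012", 1674, "all", 2012, 1000, 1, (2.4, 2.3, 2.5)),
    _cell("hie 2013", 1674, "all", 2013, 1000, 1, (2.5, 2.4, 2.6)),
    _cell("hie 2014", 1824, "all", 2014, 1000, 1, (2.8, 2.6, 2.9)),
    _cell("hie 2015", 1742, "all", 2015, 1000, 1, (2.6, 2.5, 2.8), exact=False),
    # CNS infection, all live births, per 1000
    _cell("cns 2012", 353, "all", 2012, 1000, 2, (0.51, 0.46, 0.56)),
    _cell("cns 2013", 422, "all", 2013, 1000, 2, (0.64, 0.58, 0.70)),
    _cell("cns 2014", 504, "all", 2014, 1000, 2, (0.76, 0.70, 0.83)),
    _cell("cns 2015", 465, "all", 2015, 1000, 2, (0.70, 0.64, 0.77)),
    # bilirubin encephalopathy, all live births, per 100 000
    _cell("bilirubin 2012", 8, "all", 2012, 100000, 1, (1.2, 0.6, 2.3)),
    _cell("bilirubin 2013", 7, "all", 2013, 100000, 1, (1.1, 0.5, 2.2)),
    _cell("bilirubin 2014", 2, "all", 2014, 100000, 1, (0.3, 0.1, 1.2)),
    _cell("bilirubin 2015", 4, "all", 2015, 100000, 1, (0.6, 0.2, 1.6)),
    # cystic PVL (preterm cases), all live births, per 1000
    _cell("cpvl 2012", 199, "all", 2012, 1000, 1, (0.3, 0.3, 0.3), exact=False),
    _cell("cpvl 2013", 175, "all", 2013, 1000, 1, (0.3, 0.2, 0.3)),
    _cell("cpvl 2014", 171, "all", 2014, 1000, 1, (0.3, 0.2, 0.3)),
    _cell("cpvl 2015", 184, "all", 2015, 1000, 1, (0.3, 0.2, 0.3)),
]

EXACT_CELLS = [c for c in CELLS if c["exact"]]
ANOMALOUS_CELLS = [c for c in CELLS if not c["exact"]]
#: the one printed bound best explained by a digit transposition (4.47 / 4.74)
TRANSPOSED = {("composite-before 2012", "ci_low"): (4.47, 4.74)}
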