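"""Published summary counts for the carfilzomib cardiovascular analysis.

These are the printed marginals of a published FAERS 2015-2019
disproportionality study of carfilzomib cardiovascular toxicity: the
cleaned database total, the carfilzomib record total, and per-category
case counts with the published reporting odds ratios.  Together with
:func:`faersig.disproportionality.reconstruct_table` they allow the full
2x2 tables — and hence the IC, its bounds and the Woolf interval — to be
recomputed from the published numbers alone.
"""

from __future__ import annotations

#: Cleaned database total after duplicate/aberrant removal.
N_TOTAL = 28_479_963

#: Records extracted before cleaning.
N_EXTRACTED = 35_989_308

#: Records mentioning the target drug (brand or generic name).
N_DRUG = 22_705

#: Target-drug records mapping to >=1 cardiovascular narrow SMQ.
N_CARDIOVASCULAR = 3_370

#: Per-category case count and published corrected reporting odds ratio.
CATEGORY_N_ROR: dict[str, tuple[int, float]] = {
    "cardiac arrhythmias": (618, 1.40),
    "cardiac failure": (765, 2.79),
    "cardiomyopathy": (1_301, 2.29),
    "embolic and thrombotic events": (821, 1.67),
    "hypertension": (254, 1.69),
    "ischemic heart disease": (271, 1.55),
    "pulmonary hypertension": (605, 2.54),
    "torsade de pointes/QT prolongation": (299, 1.44),
}

#: Published total-row ROR (all cardiovascular categories pooled).
TOTAL_ROR = 2.02

#: Outcome block of the published characteristics table:
#: (count, available denominator) pairs used by recomputation checks.
DEATH_TOTAL = (498, 3_046)
DEATH_TDP = (131, 297)
LIFE_THREATENING_ISCHEMIC = (45, 270)

#: Category share examples: (count, denominator).
SHARE_CARDIOVASCULAR = (3_370, 22_705)
SHARE_CARDIOMYOPATHY = (1_301, 3_370)
SHARE_EMBOLIC = (821, 3_370)
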