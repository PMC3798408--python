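"""Worked-example contingency tables from a published Crohn's disease cohort.

Two tables from a cohort of 845 Crohn's disease patients are bundled as
plain counts.  They serve as fixed inputs for worked examples: the raw
genotypes of that study were never deposited, but the printed tables are
sufficient to reproduce its headline association test and the population
summary percentages.
"""

from __future__ import annotations

from .assoc import ContingencyTable

__all__ = ["cohort_population_table", "class_population_table"]

_POPULATIONS = ["East Asia", "Europe", "Sub-Saharan Africa", "Missing"]
_SELF_REPORTED = ["Admixed", "Africa", "Asia", "Europe", "Missing"]

# self-reported continental origin (rows) vs origin inferred from 30 ancestry
# informative markers (columns); 845 patients, 450 of whom were AIM-typed
_COHORT_COUNTS = [
    [1, 3, 1, 1],      # Admixed
    [0, 0, 5, 1],      # Africa
    [0, 3, 1, 1],      # Asia
    [0, 341, 1, 335],  # Europe
    [2, 83, 9, 57],    # Missing
]

_CLASS_POPULATIONS = ["Admixed", "Africa", "Asia", "East Asia", "Europe",
                      "Sub-Saharan Africa", "Missing"]

# nine latent classes (rows) vs combined population information (columns);
# class 8 is the population-enriched class (12 of 17 members African)
_CLASS_COUNTS = [
    [0, 0, 1, 1, 370, 4, 31],   # class 1
    [1, 0, 0, 1, 146, 2, 13],   # class 2
    [0, 0, 0, 0, 134, 0, 2],    # class 3
    [0, 0, 0, 0, 31, 0, 2],     # class 4
    [0, 0, 0, 1, 24, 0, 7],     # class 5
    [0, 0, 0, 0, 24, 0, 0],     # class 6
    [0, 0, 0, 0, 18, 0, 0],     # class 7
    [0, 1, 0, 0, 4, 11, 1],     # class 8
    [0, 0, 0, 0, 14, 0, 1],     # class 9
]


def cohort_population_table() -> ContingencyTable:
    """Self-reported origin vs AIM-derived origin for the 845-patient cohort."""
    return ContingencyTable(_COHORT_COUNTS, list(_SELF_REPORTED),
                            list(_POPULATIONS))


def class_population_table() -> ContingencyTable:
    """Latent class vs combined population information (9 x 7 counts)."""
    return ContingencyTable(_CLASS_COUNTS, [f"class {i}" for i in range(1, 10)],
                            list(_CLASS_POPULATIONS))
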