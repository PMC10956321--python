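"""Published reference values for the pig assembly comparison.

Summary statistics reported for SVs called from the Nanchukmacdon (NCMD)
and Landrace chromosome-level assemblies against the Duroc (Sscrofa11.1)
reference, plus two worked-example NSV deletions. These serve as external
inputs for consistency checks: the package's own summary arithmetic must
reproduce the printed totals, span lengths and percentages.
"""

from __future__ import annotations

import pandas as pd

from .svcalls import StructuralVariant

#: Per-type SV statistics per assembly: count, median length (bp), total
#: length (bp), and the number of Nanchukmacdon-specific SVs (NSVs; only
#: defined for the Nanchukmacdon set).
PUBLISHED_SV_SUMMARY = pd.DataFrame(
    [
        ("nanchukmacdon", "DEL", 15_636, 288.0, 12_662_862, 7_012),
        ("nanchukmacdon", "DUP", 96, 5_297.0, 859_163, 70),
        ("nanchukmacdon", "INS", 14_986, 281.0, 7_038_645, 9_785),
        ("nanchukmacdon", "INV", 66, 1_576.5, 347_275, 31),
        ("landrace", "DEL", 28_573, 151.0, 10_049_685, None),
        ("landrace", "DUP", 343, 752.0, 511_567, None),
        ("landrace", "INS", 33_361, 127.0, 7_912_026, None),
        ("landrace", "INV", 96, 1_161.0, 798_021, None),
    ],
    columns=["breed", "sv_type", "count", "median_length", "total_length", "n_nsv"],
)

#: Reported breed totals and NSV total for the same comparison.
PUBLISHED_TOTALS = {"nanchukmacdon": 30_784, "landrace": 62_373, "nsv": 16_898}

#: Mean number of NSVs genotyped per sample across the 29-sample panel,
#: and the percentage it was reported as.
PUBLISHED_GENOTYPED_PER_SAMPLE = 7_051
PUBLISHED_GENOTYPED_PCT = 41.73

#: Worked-example NSV deletions on Sscrofa11.1 coordinates (1-based
#: inclusive, chrom/pos/end): one in the first intron of AR, one in the
#: last exon of SPAG9. Span lengths are computed, not stored.
PUBLISHED_EXAMPLE_DELETIONS = {
    "AR": ("X", 53_609_703, 53_609_995),
    "SPAG9": ("12", 27_201_206, 27_201_509),
}


def example_deletion(name: str) -> StructuralVariant:
    """Build the worked-example deletion as a variant record (length derived
    from the 1-based inclusive span)."""
    chrom, pos, end = PUBLISHED_EXAMPLE_DELETIONS[name]
    return StructuralVariant.from_interval(f"nsv_{name.lower()}", "DEL", chrom, pos, end,
                                           source_breed="nanchukmacdon",
                                           provenance="file")
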