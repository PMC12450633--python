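"""Peak-category composition, chi-squared contrast and histone match.

Compares the Promoter/Distal/Exonic/Intronic composition of the disease and
normal peak sets with a Pearson chi-squared test, and reports what fraction
of each peak set is covered by each histone mark.
"""

from hepacre.peakstats import (
    category_table,
    chisq_independence,
    histone_match_fraction,
)
from hepacre.synthetic import SyntheticConfig, generate_peaks_and_histone

config = SyntheticConfig(seed=42)
bundles = {cond: generate_peaks_and_histone(config, cond)
           for cond in ("HTN", "normal")}

table = category_table({c: b.peaks for c, b in bundles.items()})
print(table.to_frame())
print((table.proportions * 100).round(1))

result = chisq_independence(table)
print(f"chi-squared: stat={result.statistic:.1f} df={result.df} "
      f"p={result.p_value:.3g}")

for cond, bundle in bundles.items():
    match = histone_match_fraction(bundle.peaks, bundle.tracks["H3K4me1"])
    print(f"{cond}: {100 * match.unmatched_fraction:.1f}% of peaks lack "
          f"H3K4me1 support")
# A tiny p-value says the category composition differs between conditions;
# the unmatched fractions mirror how much of the open chromatin carries no
# enhancer-mark evidence in each state.
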