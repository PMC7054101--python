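"""Profile statistics for the packaged seven-plasmid congener table.

For each heterologously expressed acyltransferase, print the average chain
length (the one-number summary of chain specificity), the main congeners
(>= 10% of the mixture), and the share of novel odd-chain material.
"""

from haams import (
    average_chain_length,
    categorize_novelty,
    fixture_profile,
    main_congeners,
    odd_chain_share,
    profile_report,
    reference_congener_list,
)
from haams.profiles import FIXTURE_COLUMNS

ref = reference_congener_list()
for col in FIXTURE_COLUMNS:
    p = fixture_profile(col)
    mains = ", ".join(sorted(c.name for c in main_congeners(p)))
    print(
        f"{col}: ACL {average_chain_length(p):>4}  "
        f"odd-chain (novel) {odd_chain_share(p, novel_only=True, ref=ref):>4}%  "
        f"main: {mains}"
    )

print("\nnovelty breakdown of the pAMB profile:")
report = profile_report(fixture_profile("pAMB"), ref)
novel = report[~report["known"]]
for row in novel.itertuples():
    print(f"  {row.congener:<12s} {row.fraction_percent:>5}%  {row.novelty_categories}")
# ACL separates the C10-specific enzymes (~10.5) from the C14-specific
# ones (~14); the pAMB column carries the largest novel odd-chain share.
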