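"""Confirm a hydroxy fatty acid chain from its GC-EI spectrum.

After hydrolysis, methylation and trimethylsilylation, the [M-15]+ ion
fixes the chain length and the m/z 175 fragment localizes the hydroxy
group at carbon 3.  Here: the odd-chain C13:0 hydroxy acid.
"""

from haams import (
    ChainSpec,
    assign_chain_from_ei,
    derivatized_formula,
    generate_ei_peaklist,
    m_minus_15,
    position_diagnostic_mz,
)

chain = ChainSpec(13, 0)
print(f"derivatized {chain.label}: {derivatized_formula(chain)}")
print(f"  [M-15]+ at m/z {m_minus_15(chain)}; 3-OH diagnostic at m/z {position_diagnostic_mz(3)}")

peaks = generate_ei_peaklist(chain, seed=7, n_background=5)
print(f"\nsimulated EI peak list ({len(peaks)} peaks, jittered + background)")
for ev in assign_chain_from_ei(peaks):
    status = "hydroxy position confirmed" if ev.position_confirmed else "position unconfirmed"
    print(
        f"assigned {ev.chain.label}: [M-15]+ predicted {ev.m15_mz}, "
        f"observed {ev.m15_peak.mz:.2f} ({status})"
    )
# A unique assignment back to C13:0: the 14-Da homolog spacing of [M-15]+
# keeps neighboring chain lengths well outside the 0.3 Da window.
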