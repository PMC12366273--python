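"""Two-day gradient design run: how far does each growth factor act?

Simulates diffusion + half-life decay of every default factor from its own
end of the chip after a single media loading, then reports the maximum
distance at which each stays above its EC50 and which factor limits each
medium.  (Full-resolution run; takes ~10 s.)
"""

import gradientchip as gc

analysis = gc.run_distribution_analysis()

print(analysis.to_table().to_string(index=False,
                                    float_format=lambda v: f"{v:.2f}"))
print()
for medium, factor in analysis.limiting.items():
    print(f"limiting factor for {medium} media: {factor}")
print()
print("A factor's reach grows while its reservoir is above EC50 and shrinks "
      "once decay wins; the limiting factor bounds where its whole medium "
      "is effective.")
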