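"""Macrobend loss of standard vs. bend-insensitive fiber.

Evaluates the calibrated exponential loss law at the protocol bend radii
(180-degree bends) and prints the one-way loss and the round-trip optical
transmission relative to a straight fiber.  Standard SMF collapses below
10 mm radius while the bend-insensitive fiber keeps >= 95% of its signal
down to 2.5 mm.
"""

import foustrack as ft

model = ft.BendLossModel.calibrated()
print(f"{'radius_mm':>9} {'SMF loss dB':>12} {'SMF roundtrip':>14} {'BI loss dB':>11} {'BI roundtrip':>13}")
for r_mm in (12.5, 10.0, 7.5, 5.0, 2.5):
    row = []
    for ftype in ("standard_smf", "bend_insensitive"):
        fiber = ft.FiberSpec(ftype, ((r_mm * 1e-3, 0.5),))
        row += [ft.bend_loss_db(model, fiber), ft.roundtrip_transmission(model, fiber)]
    print(f"{r_mm:9.1f} {row[0]:12.3g} {row[1]:14.4g} {row[2]:11.3g} {row[3]:13.4g}")

bi_turn = ft.FiberSpec("bend_insensitive", ((5e-3, 1.0),))
print(f"\nBI fiber, one full turn at 5 mm: {ft.bend_loss_db(model, bi_turn):.3g} dB one-way "
      "(the G.657.B3 specification value)")
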