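"""Estimate alpha-helix content from CD spectra and detect peak shifts.

Generates CD spectra for the free protein and two ligand ratios, reads
the 208 nm mean residue ellipticity through the normalisation used for
a 2 uM, 585-residue protein in a 1 cm cell, and reports the helix loss.
Also demonstrates the synchronous-fluorescence blue-shift readout.
"""

from albind import helix_change, peak_shift
from albind.synthetic import gen_cd, gen_sync

spectra = [gen_cd(h, C_p=2e-6, n_res=585, path_length=1.0, label=lab,
                  noise_mdeg=0.5, seed=i)
           for i, (h, lab) in enumerate([(52.08, "1:0"), (49.25, "1:1"),
                                         (47.69, "1:3")])]
for row in helix_change(spectra):
    print(f"ratio {row['label']}: alpha-helix {row['helix_percent']:5.2f}% "
          f"(change {row['delta_vs_reference']:+.2f} points)")

shift, direction = peak_shift(gen_sync(delta_lambda=15),
                              gen_sync(delta_lambda=15, shift_nm=-2.0))
print(f"synchronous (delta-lambda 15 nm) peak shift: {shift:+.2f} nm ({direction})")
# A few points of helix loss with a tyrosine-channel blue shift indicates
# mild local unfolding around the binding pocket, not global denaturation.
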