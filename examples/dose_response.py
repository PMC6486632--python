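"""Estimate an IC50 from a percent-activity dose-response curve.

Simulates enzyme activity at fixed substrates while titrating an RNA
inhibitor over 1 nM-10 uM (log-spaced), then fits
%activity = 100(1 - [I]/([I] + IC50)).
"""

import ribokin as rk

IC50_TRUE = 0.033  # uM = 33 nM, the strongest inhibitor in the forward assay

design = rk.builtin_design("rna-dose-response")
data = rk.generate_inhibition_curve(design, rk.InhibitionCurveParams(ic50=IC50_TRUE), seed=3)

fit = rk.fit_inhibition_curve(data)
print(f"true IC50   : {IC50_TRUE * 1e3:.1f} nM")
print(f"fitted IC50 : {fit.params['ic50'] * 1e3:.1f} +/- {fit.stderr['ic50'] * 1e3:.1f} nM")
print(f"RSS         : {fit.rss:.1f} over {fit.n_points} points")
print("IC50 is the inhibitor concentration leaving 50% residual activity")
print("under these fixed substrate concentrations; it is condition-specific,")
print("unlike the mechanistic constants Ki and alpha.")
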