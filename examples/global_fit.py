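"""Global fit of the hyperbolic-competitive rate law across inhibitor series.

Simulates the full kinetic design - initial velocities over an 8-point THF
grid (10-488 uM) at six tRNA concentrations (0-1.77 uM), 3 replicates, 5%
CV - and estimates all five parameters jointly, comparing the hyperbolic
model against pure competitive inhibition.
"""

import ribokin as rk

truth = rk.KineticParams(vmax=1.0, km=50.0, ki_thf=200.0, ki=0.031, alpha=18.8)
design = rk.builtin_design("thf-inhibitor-grid")
series = rk.generate_velocity_matrix(design, truth, seed=11)

fit = rk.fit_global(series, model="eq4")
fit = rk.bootstrap_ci(fit, series, n_resamples=500, seed=11)
competitive = rk.fit_global(series, model="pure_competitive")
verdict = rk.compare_models([fit, competitive])

print("hyperbolic-competitive global fit (truth in parentheses):")
for name, true in [("vmax", 1.0), ("km", 50.0), ("ki_thf", 200.0),
                   ("ki", 0.031), ("alpha", 18.8)]:
    lo, hi = fit.ci[name]
    print(f"  {name:7s} = {fit.params[name]:8.4f}  ({true})   95% CI [{lo:.4f}, {hi:.4f}]")
print(f"model comparison: preferred = {verdict.preferred} "
      f"(delta-AICc = {verdict.delta_aicc:.1f})")
print("Ki is the RNA dissociation constant from the free enzyme; alpha is")
print("the factor by which folate and RNA mutually weaken each other's")
print("binding. alpha >> 1 but finite means inhibition saturates - the")
print("signature of partial (hyperbolic) competitive inhibition.")
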