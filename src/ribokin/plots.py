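"""Optional static figures for the kinetic diagnostics (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .data import VelocitySeries
from .diagnostics import double_reciprocal, exclude_substrate_inhibition, replot
from .fitting import fit_saturation


def plot_diagnostics(series_set: list[VelocitySeries], path) -> None:
    """Write a four-panel figure: saturation curves, double-reciprocal
    lines after exclusion, and slope/intercept replots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = min(series_set, key=lambda s: s.inhibitor_conc)
    eq3 = fit_saturation(base, model="eq3")
    kept = [exclude_substrate_inhibition(s, eq3) for s in series_set]
    rec = double_reciprocal(kept)
    rep = replot(rec)

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ser in series_set:
        avg = ser.averaged()
        axes[0, 0].plot(avg.substrate_conc, avg.velocity, "o-", ms=4,
                        label=f"I = {ser.inhibitor_conc:g}")
    axes[0, 0].set(xlabel=f"[{series_set[0].substrate_name}] (uM)",
                   ylabel="velocity", title="saturation curves")
    axes[0, 0].legend(fontsize=7)

    for ser, line in zip(kept, rec):
        avg = ser.averaged()
        ok = avg.velocity > 0
        x = 1.0 / avg.substrate_conc[ok]
        axes[0, 1].plot(x, 1.0 / avg.velocity[ok], "o", ms=4)
        xx = np.linspace(0, x.max(), 50)
        axes[0, 1].plot(xx, line.intercept + line.slope * xx, "-", lw=1)
    axes[0, 1].set(xlabel="1/[S]", ylabel="1/v", title="double reciprocal (excluded)")

    axes[1, 0].plot(rep["inhibitor_conc"], rep["slope"], "ko-")
    axes[1, 0].set(xlabel=f"[{series_set[0].inhibitor_name}] (uM)",
                   ylabel="slope (Km_app/Vmax)", title="slope replot")
    axes[1, 1].plot(rep["inhibitor_conc"], rep["intercept"], "ro-")
    axes[1, 1].set(xlabel=f"[{series_set[0].inhibitor_name}] (uM)",
                   ylabel="intercept (1/Vmax)", title="intercept replot")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
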