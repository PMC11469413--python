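"""Fixed-point structure of the 2D circuit (one y neuron, one a neuron).

Enumerates all fixed points for three printed parameter regimes —
contractive recurrence, expansive recurrence with small semisaturation,
and expansive recurrence with large semisaturation — for both the main
and the rectified model, and writes a phase-portrait figure.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from organics import CircuitParams, find_fixed_points_2d, phase_portrait_2d

REGIMES = {
    "contractive (wr=0.5, b0=0.5, sigma=0.1)": dict(wr=0.5, b0=0.5, sigma=0.1),
    "expansive, small sigma (wr=2, b0=0.5, sigma=0.1)": dict(wr=2.0, b0=0.5, sigma=0.1),
    "expansive, large sigma (wr=2, b0=1, sigma=1)": dict(wr=2.0, b0=1.0, sigma=1.0),
}

fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True, sharey=True)
for col, (label, cfg) in enumerate(REGIMES.items()):
    params = CircuitParams(n=1, tau_y=2.0, tau_a=2.0, b=0.5, b0=cfg["b0"],
                           sigma=cfg["sigma"], W_r=[[cfg["wr"]]], W=[[1.0]])
    for row, variant in enumerate(("general", "rectified")):
        fps = find_fixed_points_2d(params, 1.0, variant=variant)
        print(f"{label} [{variant}]:")
        for f in fps:
            print(f"  y_s={f.y_s[0]:+.6f}  a_s={f.a_s[0]:.6f}  stable={f.stable}")
        pp = phase_portrait_2d(params, 1.0, y_range=(-1.05, 1.05),
                               a_range=(-0.2, 1.6), grid_n=25, variant=variant)
        ax = axes[row, col]
        ax.streamplot(pp.Y, pp.A, pp.dY, pp.dA, density=0.8, color="0.7", linewidth=0.7)
        ax.plot(*pp.y_nullcline.T, ".", ms=2, color="tab:blue", label="dy/dt = 0")
        ax.plot(*pp.a_nullcline.T, ".", ms=2, color="tab:orange", label="da/dt = 0")
        for f in fps:
            marker, color = ("*", "red") if f.stable else ("o", "black")
            ax.plot(f.y_s[0], f.a_s[0], marker, color=color, ms=10)
        if row == 0:
            ax.set_title(label, fontsize=8)
        ax.set_xlabel("y")
        ax.set_ylabel("a" if col == 0 else "")
fig.suptitle("2D circuit: red stars stable, black circles unstable; top = main, bottom = rectified")
fig.tight_layout()
fig.savefig("phase_portraits.png", dpi=120)
print("\nwrote phase_portraits.png")
# A stable fixed point with the input's sign always exists; extra
# (unstable) fixed points can appear only for expansive recurrence with
# small semisaturation, and the rectified model never has an unstable one
# for positive input.
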