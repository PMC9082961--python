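"""Scatter-with-identity and Bland-Altman figures for agreement runs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import bland_altman, linear_fit

__all__ = ["agreement_plots"]


def agreement_plots(ola, vla_incl, vla_excl, outdir: str | Path) -> list[Path]:
    """Write the two-panel agreement figures; returns the file paths."""
    outdir = Path(outdir)
    ola = np.asarray(ola, dtype=float)
    paths = []
    for label, vla in (("incl_midrib", np.asarray(vla_incl, dtype=float)),
                       ("excl_midrib", np.asarray(vla_excl, dtype=float))):
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        fit = linear_fit(ola, vla)
        lim = [0, max(ola.max(), vla.max()) * 1.05]
        ax1.scatter(ola, vla, s=18)
        ax1.plot(lim, lim, "k--", lw=0.8, label="1:1")
        ax1.plot(lim, fit.intercept + fit.slope * np.asarray(lim),
                 "r-", lw=1, label=f"fit (slope {fit.slope:.3f})")
        ax1.set_xlabel("optical leaf area (mm$^2$)")
        ax1.set_ylabel("volumetric leaf area (mm$^2$)")
        ax1.legend(frameon=False)

        ba = bland_altman(vla, ola)
        mean_av = (ola + vla) / 2.0
        ax2.scatter(mean_av, vla - ola, s=18)
        for y, style in ((ba.bias, "-"), (ba.loa_low, ":"), (ba.loa_high, ":")):
            ax2.axhline(y, color="r", ls=style, lw=0.9)
        ax2.set_xlabel("mean of methods (mm$^2$)")
        ax2.set_ylabel("VLA $-$ OLA (mm$^2$)")
        fig.tight_layout()
        path = outdir / f"agreement_{label}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
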