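"""Basic diagnostic plots: Patlak plot and bias/variability bars."""

from __future__ import annotations

import numpy as np

from .patlak import PatlakFit

__all__ = ["patlak_plot", "bias_variability_bars"]


def patlak_plot(fit: PatlakFit, ref=None, ax=None):
    """Patlak plot: AC_t/AC_p against AUC_p/AC_p with the fitted line.

    ``ref`` may be a ``KineticParameters`` to overlay the reference line.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(fit.patlak_x)
    xs = np.linspace(0, 1.05 * x.max(), 50)
    ax.plot(x, fit.patlak_y, "o", color="tab:green", label="simulated")
    ax.plot(xs, fit.ki_hat * xs + fit.vt_hat, "-", color="tab:pink",
            label=f"fit: Ki={fit.ki_hat:.2e}/h, VT={fit.vt_hat:.3f}")
    if ref is not None:
        ax.plot(xs, ref.ki * xs + ref.vt, "k--",
                label=f"reference: Ki={ref.ki:.2e}/h, VT={ref.vt:.3f}")
    ax.set_xlabel("AUC$_p$ / AC$_p$ [h]")
    ax.set_ylabel("AC$_t$ / AC$_p$")
    ax.legend()
    return ax


def bias_variability_bars(summary_df, value: str = "vt", ax=None):
    """Grouped bars of percent bias and variability per schedule.

    ``summary_df`` is a ``run_grid`` output restricted to one fixture and
    one (rKi, rVT, noise) cell; ``value`` selects ``"ki"`` or ``"vt"``.
    """
    import matplotlib.pyplot as plt

    if value not in ("ki", "vt"):
        raise ValueError("value must be 'ki' or 'vt'")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    labels = [
        f"{int(r.t1_h)}/{int(r.t2_h)}/{int(r.t3_h)}" for r in summary_df.itertuples()
    ]
    pos = np.arange(len(labels))
    ax.bar(pos - 0.2, summary_df[f"bias_{value}_pct"], width=0.4, label="bias [%]")
    ax.bar(pos + 0.2, summary_df[f"variability_{value}_pct"], width=0.4,
           label="variability [%]")
    ax.set_xticks(pos, labels, rotation=45, ha="right")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel(f"{value.upper()} bias / variability [%]")
    ax.legend()
    return ax
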