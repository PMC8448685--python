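"""Basic figures: synchrony/metastability sweeps and measure-length scatters."""

from __future__ import annotations

def plot_sweep(sweep_estimated, sweep_constant=None, axes=None):
    """Synchrony (top) and metastability (bottom) over the coupling grid.

    Draws mean +/- SD bands per condition; the constant-velocity condition
    is optional.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    conditions = [("estimated", sweep_estimated)]
    if sweep_constant is not None:
        conditions.append(("constant velocity", sweep_constant))
    for label, sw in conditions:
        for ax, mean, sd in (
            (axes[0], sw.synchrony_mean, sw.synchrony_sd),
            (axes[1], sw.metastability_mean, sw.metastability_sd),
        ):
            ax.plot(sw.couplings, mean, label=label)
            ax.fill_between(sw.couplings, mean - sd, mean + sd, alpha=0.2)
    axes[0].set_ylabel("global synchrony")
    axes[1].set_ylabel("metastability")
    axes[1].set_xlabel("coupling factor k")
    axes[0].legend()
    return axes


def plot_measure_length(edges, measure, ax=None, label=None):
    """Scatter of an edge measure against connection length."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(edges["length_m"], edges[measure], s=8, alpha=0.5)
    ax.set_xlabel("connection length (m)")
    ax.set_ylabel(label or measure)
    return ax
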