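"""Minimal plotting helper for concentration trajectories."""

from __future__ import annotations

import numpy as np


def plot_curve(curve, observations=(), ax=None, n_points: int = 400,
               label: str = None):
    """Plot a ConcentrationCurve with optional (t, level) observations.

    Requires matplotlib (the ``plot`` extra).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ts = np.linspace(curve.t_start, curve.t_end, n_points)
    ax.plot(ts, [curve.evaluate(t) for t in ts], label=label)
    if observations:
        obs = np.asarray(list(observations), dtype=float)
        ax.plot(obs[:, 0], obs[:, 1], "o", ms=4, color="k", label="observed")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (mg/L)")
    if label or len(observations):
        ax.legend(frameon=False)
    return ax
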