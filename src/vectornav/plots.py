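"""Circular orientation diagrams (funnel-style plots)."""

from __future__ import annotations

import numpy as np

from .circstats import CircularSample, mean_ci95, mean_vector, rayleigh_p


def plot_group_diagram(sample: CircularSample, ax=None, sun_azimuth=None):
    """Bearing dots on the unit circle, mean vector scaled by r, and the
    95% confidence arc when the sample is significantly directed.

    North is up, angles run clockwise (compass convention).  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_yticklabels([])
    ax.set_ylim(0, 1.15)

    theta = np.radians(sample.bearings)
    ax.plot(theta, np.full_like(theta, 1.05), "o", ms=5, mfc="white", mec="black")

    alpha, r = mean_vector(sample)
    if alpha is not None:
        ax.annotate("", xy=(np.radians(alpha), r), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="-|>", lw=2, color="black"))
        if rayleigh_p(sample.n, r) < 0.05:
            try:
                lo, hi = mean_ci95(sample)
                half = (hi - alpha) % 360.0
                arc = np.radians(np.linspace(alpha - half, alpha + half, 60))
                ax.plot(arc, np.full_like(arc, 1.0), ":", color="black", lw=1)
            except ValueError:
                pass
    if sun_azimuth is not None:
        ax.plot([np.radians(sun_azimuth)], [1.12], marker="*", ms=12,
                color="orange")
    ax.set_title(f"{sample.label}  (n={sample.n})", fontsize=10)
    return ax
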