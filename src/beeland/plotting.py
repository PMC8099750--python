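"""Minimal plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_profile(profile, ax=None):
    """Bin-averaged V(y) and r(y) of one treatment cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    m = profile.mask
    ax.plot(profile.bin_centers[m], profile.mean_V[m], "o-", label="V (m/s)")
    ax.plot(profile.bin_centers[m], profile.mean_r[m] * 0.1, "s-",
            label="r / 10 (1/s)")
    ax.set_xlabel("distance y (m)")
    ax.set_ylabel("bin mean")
    ax.legend(frameon=False)
    return ax


def plot_setpoints(records, fit=None, ax=None):
    """Detected set points r* vs distance y* on log-log axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.loglog(records["y_star"], records["r_star"], ".", alpha=0.4)
    if fit is not None:
        yy = np.geomspace(records["y_star"].min(), records["y_star"].max(), 50)
        inter = float(fit.params.get("Intercept", 0.0))
        ax.loglog(yy, np.exp(inter + fit.slope * np.log(yy)), "k-",
                  label=f"slope {fit.slope:.2f}")
        ax.legend(frameon=False)
    ax.set_xlabel("y* (m)")
    ax.set_ylabel("r* (1/s)")
    return ax
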