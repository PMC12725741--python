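"""Quick-look figures for the standard analyses.

Each function draws on a provided axes (or a fresh one) and returns it, so
figures compose the usual matplotlib way.
"""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_kymograph(kymo: np.ndarray, times=None, ax=None):
    """Monomer-vs-time condensate membership map."""
    ax = _ax(ax)
    extent = None
    if times is not None:
        times = np.asarray(times)
        extent = (times[0], times[-1], 0, kymo.shape[0])
    ax.imshow(kymo, aspect="auto", origin="lower", interpolation="nearest",
              cmap="Greys", extent=extent)
    ax.set_xlabel(r"time ($\tau$)" if times is not None else "frame")
    ax.set_ylabel("monomer")
    return ax


def plot_force_scan(scan, x="re_prime", ax=None):
    """Capillary force with replicate error bars across a scan grid."""
    ax = _ax(ax)
    ax.errorbar(scan[x], scan["F_pN"],
                yerr=scan["F_std"] * scan["F_pN"] / scan["F_kBT_sigma"].where(
                    scan["F_kBT_sigma"] != 0, 1.0).abs(),
                marker="o", capsize=3)
    ax.set_xlabel(r"$R_e'$" if x == "re_prime" else r"$\rho_p$ ($\mu$M)")
    ax.set_ylabel("capillary force (pN)")
    return ax


def plot_kdistance(curve, smoothed=None, epsilon=None, ax=None):
    """Sorted k-NN distance curve with its smoothed version and the knee."""
    ax = _ax(ax)
    ax.plot(curve, lw=0.8, label="sorted k-distance")
    if smoothed is not None:
        ax.plot(smoothed, lw=1.5, label="smoothed")
    if epsilon is not None:
        ax.axhline(epsilon, ls="--", color="k", lw=0.8,
                   label=f"epsilon = {epsilon:.2f}")
    ax.set_xlabel("point rank")
    ax.set_ylabel(r"distance ($\sigma$)")
    ax.legend(frameon=False)
    return ax


def plot_coarsening(result, ax=None):
    """Scaled condensate radii against time on log-log axes."""
    ax = _ax(ax)
    df = result.series
    for tid, grp in (df.groupby("track_id") if "track_id" in df else
                     [(0, df)]):
        ax.loglog(grp["time"], grp["R_scaled"], lw=1.0, label=f"track {tid}")
    if result.exponent is not None:
        t = np.array([df["time"].min(), df["time"].max()])
        ref = result.series["R_scaled"].max() * (t / t[-1]) ** result.exponent
        ax.loglog(t, ref, "k--", lw=0.8,
                  label=f"slope {result.exponent:.2f}")
    ax.set_xlabel(r"time ($\tau$)")
    ax.set_ylabel(r"$R / R_{final}$")
    ax.legend(frameon=False, fontsize=8)
    return ax
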