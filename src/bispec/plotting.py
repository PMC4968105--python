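"""Optional matplotlib figures for experiment reports.

Kept separate so the core package has no plotting dependency; importing
this module requires the ``plots`` extra.
"""

from __future__ import annotations

from pathlib import Path


def plot_binding_curves(report, outpath: str | Path, logx: bool = True):
    """One panel of total-MFI binding curves per cell type (or variant)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for key, curve in report.curves.items():
        label = key if isinstance(key, str) else " / ".join(map(str, key))
        ax.plot(curve.x, curve.mfi("total"), marker="o", ms=3, label=label)
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(next(iter(report.curves.values())).x_kind)
    ax.set_ylabel("bound antibody (MFI units)")
    ax.set_title(report.name)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outpath, dpi=150)
    plt.close(fig)
    return Path(outpath)
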