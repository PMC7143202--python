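"""Optional Manhattan-style plot of window variance percentages."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def manhattan_plot(windows_frame: pd.DataFrame, path, window_size: int | None = None,
                   threshold_pct: float | None = None) -> None:
    """Chromosome-ordered % of genetic variance per window.

    ``windows_frame`` is the TSV layout produced by
    :func:`wssgblup.gwas.windows_to_frame`; pick one ``window_size`` to plot.
    """
    df = windows_frame
    if window_size is not None:
        df = df[df["n_snp"] == window_size]
    df = df.sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(9, 3))
    x0 = 0
    for i, (c, sub) in enumerate(df.groupby("chrom", sort=False)):
        x = x0 + (sub["start_bp"] - sub["start_bp"].min()).to_numpy()
        ax.scatter(x, sub["pct_variance"], s=4, color=f"C{i % 2}", label=None)
        x0 = x.max() + 1e6 if len(x) else x0
    if threshold_pct is not None:
        ax.axhline(threshold_pct, color="red", lw=0.8, ls="--")
    ax.set_xlabel("genome position (chromosomes concatenated)")
    ax.set_ylabel("% additive genetic variance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
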