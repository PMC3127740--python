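"""Optional matplotlib views of the report tables (behind the CLI --plot flag)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_composition", "plot_flanking", "plot_covariation"]


def _axes(n=1, width=7.0, height=3.2):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, n, figsize=(width, height), squeeze=False)
    return fig, axes[0]


def plot_composition(composition_tsv, out_png) -> Path:
    """Observed vs resampled 5'-nt frequencies, one panel per strand class."""
    df = pd.read_csv(composition_tsv, sep="\t")
    df = df[df.stratum == "all"]
    classes = list(df.strand_class.unique())
    fig, axes = _axes(len(classes))
    for ax, cls in zip(axes, classes):
        sub = df[df.strand_class == cls]
        x = range(len(sub))
        ax.bar([i - 0.2 for i in x], sub.observed_freq, 0.4, color="0.3", label="position 1")
        ax.bar(
            [i + 0.2 for i in x], sub.resample_mean, 0.4,
            yerr=sub.resample_sd, color="white", edgecolor="0.3", label="resampled body",
        )
        ax.set_xticks(list(x), sub.nucleotide)
        ax.set_ylim(0, 1)
        ax.set_title(cls)
        ax.set_ylabel("frequency")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    return Path(out_png)


def plot_flanking(flanking_tsv, out_png) -> Path:
    """U frequency around miRNA nt 1 with the resampled background band."""
    df = pd.read_csv(flanking_tsv, sep="\t")
    fig, (ax,) = _axes()
    ax.plot(df.offset, df.u_freq, "o-", color="0.2")
    ax.axhline(df.background_mean.iloc[0], color="0.5")
    ax.axhline(df.ci_low.iloc[0], color="0.5", linestyle="--")
    ax.axhline(df.ci_high.iloc[0], color="0.5", linestyle="--")
    ax.set_xlabel("offset from miRNA nt 1")
    ax.set_ylabel("U frequency")
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    return Path(out_png)


def plot_covariation(covariation_tsv, out_png) -> Path:
    """-log10 p per position: identity in black, pairing status in gray."""
    df = pd.read_csv(covariation_tsv, sep="\t")
    panels = [(s, a) for s in ("miRNA", "miRNA*") for a in ("5p", "3p")]
    fig, axes = _axes(len(panels), width=13.0)
    for ax, (strand, anchor) in zip(axes, panels):
        sub = df[(df.strand == strand) & (df.anchor == anchor)]
        for block, color in (("identity", "black"), ("pairing", "0.6")):
            b = sub[sub.block == block].sort_values("position")
            ax.plot(b.position, b.neg_log10_p, "o-", ms=3, color=color, label=block)
        ax.set_title(f"{strand} from {anchor}", fontsize=9)
        ax.set_xlabel("position")
    axes[0].set_ylabel("-log10 p")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    return Path(out_png)
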