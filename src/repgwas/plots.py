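"""Manhattan and QQ plot helpers for scan results."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["manhattan", "qq"]


def manhattan(scan_result, path, significance: float = None) -> None:
    """Write a Manhattan plot (−log10 p by position, colored per chromosome)."""
    tab = scan_result.table
    ok = tab["p"].notna()
    lp = -np.log10(tab.loc[ok, "p"].to_numpy(dtype=float))
    chroms = tab.loc[ok, "chrom"].astype(str).to_numpy()
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for k, ch in enumerate(dict.fromkeys(chroms)):
        sel = chroms == ch
        x = offset + np.arange(sel.sum())
        ax.scatter(x, lp[sel], s=4, color=f"C{k % 2}", rasterized=True)
        offset += sel.sum()
    if significance is not None:
        ax.axhline(-np.log10(significance), color="red", lw=0.8, ls="--")
    ax.set_xlabel("SNP index")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"lambda = {scan_result.lambda_gc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qq(scan_result, path) -> None:
    """Write a QQ plot of observed vs expected −log10 p."""
    p = scan_result.table["p"].dropna().to_numpy(dtype=float)
    obs = -np.log10(np.sort(p))
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))[::-1]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(exp, obs[::-1], ".", ms=3)
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], "k-", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.set_title(f"lambda = {scan_result.lambda_gc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
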