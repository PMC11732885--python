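"""Pre- vs post-treatment dosimetry agreement: Bland–Altman and Pearson.

The Bland–Altman convention here follows the study design this package
emulates: differences are pre-treatment minus post-treatment dose, plotted
against the *post-treatment* value (``abscissa="post"``); the conventional
mean-of-pair abscissa is available.  Limits of agreement use a fixed 1.96
multiplier on the sample (n-1) standard deviation of the differences — the
bias and limits themselves do not depend on the abscissa choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BAResult", "bland_altman", "pearson_corr"]


@dataclass
class BAResult:
    """Bland–Altman summary of paired pre/post doses (Gy)."""

    bias_Gy: float
    sd_diff_Gy: float
    loa_low_Gy: float
    loa_high_Gy: float
    n: int
    abscissa: str = "post"

    def to_dict(self) -> dict:
        return {
            "bias_Gy": self.bias_Gy,
            "sd_diff_Gy": self.sd_diff_Gy,
            "loa95_Gy": [self.loa_low_Gy, self.loa_high_Gy],
            "n": self.n,
            "abscissa": self.abscissa,
        }


def bland_altman(pre, post, abscissa: str = "post") -> BAResult:
    """Bias and 95% limits of agreement of pre-minus-post differences.

    Parameters
    ----------
    pre, post : array-like, Gy
        Paired dose series of equal length, n >= 2.
    abscissa : {"post", "mean"}
        What the differences are plotted against; statistics are unaffected.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D series")
    if pre.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    if abscissa not in ("post", "mean"):
        raise ValueError("abscissa must be 'post' or 'mean'")
    d = pre - post
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BAResult(
        bias_Gy=bias,
        sd_diff_Gy=sd,
        loa_low_Gy=bias - 1.96 * sd,
        loa_high_Gy=bias + 1.96 * sd,
        n=pre.size,
        abscissa=abscissa,
    )


def pearson_corr(x, y) -> float:
    """Sample product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the series")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman_plot(pre, post, result: BAResult | None = None, path: str | None = None):
    """Optional Bland–Altman scatter (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    res = result or bland_altman(pre, post)
    x = post if res.abscissa == "post" else (pre + post) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, pre - post, s=12, alpha=0.6)
    for yv, style in [(res.bias_Gy, "-"), (res.loa_low_Gy, "--"), (res.loa_high_Gy, "--")]:
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("post-treatment dose (Gy)" if res.abscissa == "post" else "mean dose (Gy)")
    ax.set_ylabel("pre − post (Gy)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
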