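"""QQ-plot rendering for scan diagnostics (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_qq(tables: dict[str, pd.DataFrame], path: str | Path,
            lambda_gc: float | None = None, title: str = "") -> None:
    """Overlay QQ tables from :func:`koassoc.assoc_perm.qq_points` (keys are
    legend labels; the ``all`` table, if present, also draws the 95% band)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    band = tables.get("all")
    if band is not None:
        ax.fill_between(band["expected"], band["lower95"], band["upper95"],
                        color="0.85", label="95% null band")
    for name, t in tables.items():
        ax.plot(t["expected"], t["observed"], ".", ms=4, label=name)
    lim = max(t["observed"].max() for t in tables.values()) * 1.05 + 0.1
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} P$")
    ax.set_ylabel(r"observed $-\log_{10} P$")
    label = title
    if lambda_gc is not None:
        label = f"{title} ($\\lambda_{{GC}}$ = {lambda_gc:.2f})".strip()
    ax.set_title(label)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
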