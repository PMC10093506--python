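"""Forest-plot data export for screening results.

The plot rows and the side table of non-estimable pairs together cover the
whole screening grid — nothing is silently dropped. Rendering is a thin
optional layer; nothing downstream depends on pixels.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .disprop import DisproportionalityResult

__all__ = ["ForestPlotData", "export_forest", "render_forest"]


@dataclass(frozen=True)
class ForestPlotData:
    """Computable pairs only, sorted by event then drug (log-scale plottable)."""

    rows: tuple[tuple[str, str, float, float, float, bool, int], ...]

    @classmethod
    def from_results(
        cls, results: Sequence[DisproportionalityResult]
    ) -> "ForestPlotData":
        rows = sorted(
            (
                (r.event, r.drug_code, r.ror, r.ci_low, r.ci_high, r.sdr, r.table.a)
                for r in results
                if r.computable
            ),
        )
        return cls(
            rows=tuple(
                (drug, event, ror, lo, hi, sdr, a)
                for event, drug, ror, lo, hi, sdr, a in rows
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows),
            columns=["drug", "event", "ror", "ci_low", "ci_high", "sdr", "n_cases"],
        )


def export_forest(
    results: Sequence[DisproportionalityResult], path: str | Path
) -> tuple[Path, Path]:
    """Write plot rows to ``path`` and non-estimable pairs to a side table.

    Returns (plot_path, side_path); the side table lists every pair without
    an estimate together with its case count.
    """
    path = Path(path)
    data = ForestPlotData.from_results(results)
    data.to_frame().to_csv(path, index=False)
    side = pd.DataFrame(
        sorted(
            (r.event, r.drug_code, r.table.a)
            for r in results
            if not r.computable
        ),
        columns=["event", "drug", "n_cases"],
    )[["drug", "event", "n_cases"]]
    side_path = path.with_name(path.stem + "_omitted" + path.suffix)
    side.to_csv(side_path, index=False)
    return path, side_path


def render_forest(data: ForestPlotData, path: str | Path) -> None:
    """Optional SVG rendering (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = data.to_frame()
    fig, ax = plt.subplots(figsize=(7, max(2, 0.3 * len(df) + 1)))
    y = range(len(df))
    for i, row in df.iterrows():
        color = "tab:red" if row.sdr else "tab:gray"
        ax.plot([row.ci_low, row.ci_high], [i, i], color=color, lw=1.5)
        ax.plot(row.ror, i, "o", color=color, ms=4)
    ax.axvline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(list(y))
    ax.set_yticklabels([f"{r.drug} / {r.event}" for r in df.itertuples()], fontsize=6)
    ax.set_xlabel("reporting odds ratio (log scale)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
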