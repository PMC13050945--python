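"""Heat-map rendering and text summaries of relation tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .corpus import ValidationError
from .relation import RelationTable

__all__ = ["HeatMapSpec", "render_heatmap", "summarize"]


@dataclass(frozen=True)
class HeatMapSpec:
    """Layout of the relation-intensity heat map.

    ``split`` panels cut the (sorted) emotion-set rows into contiguous
    blocks; the default 4 mirrors a 2x2 grid presentation.  The colour
    scale is fixed to [0, 1] for intensity.
    """

    value: str = "intensity"
    split: int = 4
    cmap: str = "viridis"

    def __post_init__(self) -> None:
        if self.value not in {"intensity", "prob", "relation", "weight_level"}:
            raise ValidationError(f"unknown statistic {self.value!r}")
        if self.split < 1:
            raise ValidationError("split must be >= 1")


def render_heatmap(
    table: RelationTable,
    path: str | Path,
    spec: HeatMapSpec | None = None,
) -> list[Path]:
    """Render the table as one PNG per panel; returns the written paths.

    Rows are emotion sets (sorted), columns discourse combinations sorted
    by (size, codes).  Written files are byte-stable for a fixed renderer
    version (PNG date metadata is suppressed).
    """
    spec = spec or HeatMapSpec()
    if not table.records:
        raise ValidationError("empty relation table")
    frame = table.to_frame()
    if spec.value == "intensity" and (
        (frame["intensity"] < 0).any() or (frame["intensity"] > 1).any()
    ):
        raise ValidationError("intensity values outside [0, 1]")
    pivot = frame.pivot_table(
        index="emotion_set", columns="discourse_set", values=spec.value,
        aggfunc="first",
    )
    col_order = sorted(pivot.columns, key=lambda c: (c.count(",") + 1, c))
    pivot = pivot.loc[sorted(pivot.index), col_order].fillna(0.0)
    path = Path(path)
    blocks = np.array_split(np.arange(len(pivot.index)), spec.split)
    blocks = [b for b in blocks if b.size]
    written: list[Path] = []
    vmax = 1.0 if spec.value in {"intensity", "prob"} else None
    for i, block in enumerate(blocks, start=1):
        sub = pivot.iloc[block]
        fig, ax = plt.subplots(
            figsize=(1.0 + 0.6 * len(pivot.columns), 1.0 + 0.35 * len(sub))
        )
        im = ax.imshow(
            sub.to_numpy(), aspect="auto", cmap=spec.cmap, vmin=0.0, vmax=vmax
        )
        ax.set_xticks(range(len(sub.columns)), sub.columns, rotation=45,
                      ha="right", fontsize=7)
        ax.set_yticks(range(len(sub.index)), sub.index, fontsize=7)
        ax.set_xlabel("discourse combination")
        fig.colorbar(im, ax=ax, label=spec.value)
        fig.tight_layout()
        out = (
            path if len(blocks) == 1
            else path.with_name(f"{path.stem}_part{i}{path.suffix}")
        )
        fig.savefig(out, dpi=110, metadata={"Date": None, "Software": None})
        plt.close(fig)
        written.append(out)
    return written


def summarize(table: RelationTable, k: int = 5) -> str:
    """Human-readable summary: top-k emotion sets per discourse combination.

    For every discourse combination observed, the k emotion sets with the
    largest relation intensity are listed (RI to 2 decimals, descending),
    followed by a tally of emotion sets associated with more than one
    combination at nonzero intensity.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    by_combo: dict[str, list] = {}
    for r in table.records:
        by_combo.setdefault(r.pair.discourse_key, []).append(r)
    lines = []
    combos = sorted(by_combo, key=lambda c: (c.count(",") + 1, c))
    for combo in combos:
        ranked = sorted(
            by_combo[combo],
            key=lambda r: (-r.intensity, -r.support, r.pair.emotion_key),
        )[:k]
        lines.append(f"Top {min(k, len(ranked))} emotion combinations for {{{combo}}}:")
        for r in ranked:
            lines.append(
                f"  {{{r.pair.emotion_key}}} RI {{{combo}}} = {r.intensity:.2f}"
                f"  (support {r.support})"
            )
        lines.append("")
    multi = sum(
        1
        for eset in table.emotion_sets()
        if sum(
            1 for r in table.records
            if r.pair.emotion_key == eset and r.intensity > 0
        ) > 1
    )
    lines.append(
        f"Emotion sets with more than one nonzero relation intensity: {multi}"
    )
    return "\n".join(lines)
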