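"""Visualization: percent-identity heatmaps and per-motif sequence logos.

Figures default to 300 dpi PNG; ``pdf=True`` writes PDF instead. The logo
renderer draws stacked residue glyphs scaled by frequency × per-position
information content, R_i = log2(20) − H_i, where H_i is the Shannon entropy
(bits) of column i's residue distribution over the 20-letter alphabet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .blast import HitRecord
from .motifs import MotifMatch

MAX_INFORMATION = math.log2(20)

#: Amber/teal/slate grouping by residue chemistry.
_RESIDUE_COLORS = {
    **dict.fromkeys("AVLIMFWPG", "#2d2d2d"),    # hydrophobic
    **dict.fromkeys("STNQYC", "#1b9e77"),       # polar
    **dict.fromkeys("KRH", "#2c7fb8"),          # basic
    **dict.fromkeys("DE", "#d95f02"),           # acidic
}


def build_identity_matrix(
    filtered: Sequence[HitRecord],
    queries: Sequence[str] | None = None,
    databases: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Query × database matrix of maximal percent identity among filtered hits.

    Pairings with no filtered hit are NaN and rendered in a reserved "no hit"
    color. Rows are query identifiers (qseqid), columns database names.
    """
    rows = list(queries) if queries else sorted({h.qseqid for h in filtered})
    cols = list(databases) if databases else sorted({h.database for h in filtered})
    matrix = pd.DataFrame(np.nan, index=rows, columns=cols, dtype=float)
    for hit in filtered:
        if hit.qseqid in matrix.index and hit.database in matrix.columns:
            current = matrix.at[hit.qseqid, hit.database]
            if np.isnan(current) or hit.pident > current:
                matrix.at[hit.qseqid, hit.database] = hit.pident
    return matrix


@dataclass
class MotifProfile:
    """Per-position residue frequencies and information content for one motif."""

    pattern: str
    match_count: int
    frequencies: pd.DataFrame  # positions × residue letters, rows sum to 1
    information: np.ndarray    # bits per position, in [0, log2(20)]


def build_motif_profile(matches: Sequence[MotifMatch]) -> MotifProfile | None:
    """Column frequencies and information content from one pattern's matches.

    Returns None for zero matches (no logo is drawn then).
    """
    if not matches:
        return None
    strings = [m.matched for m in matches]
    width = len(strings[0])
    if any(len(s) != width for s in strings):
        raise ValueError("all matched strings for one pattern must share its length")
    letters = sorted({c for s in strings for c in s})
    counts = pd.DataFrame(0.0, index=range(1, width + 1), columns=letters)
    for s in strings:
        for pos, ch in enumerate(s, start=1):
            counts.at[pos, ch] += 1
    freqs = counts.div(counts.sum(axis=1), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs.values > 0, freqs.values * np.log2(freqs.values), 0.0)
    entropy = -plogp.sum(axis=1)
    information = np.clip(MAX_INFORMATION - entropy, 0.0, MAX_INFORMATION)
    return MotifProfile(
        pattern=matches[0].pattern.raw,
        match_count=len(strings),
        frequencies=freqs,
        information=information,
    )


def _save(fig, out_path: str | Path, pdf: bool) -> Path:
    out_path = Path(out_path)
    if pdf:
        out_path = out_path.with_suffix(".pdf")
    elif out_path.suffix.lower() != ".png":
        out_path = out_path.with_suffix(".png")
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=300, bbox_inches="tight")
    plt.close(fig)
    return out_path


def render_heatmap(matrix: pd.DataFrame, out_path: str | Path, pdf: bool = False) -> Path | None:
    """Percent-identity heatmap; skipped (None) for fewer than two databases."""
    if matrix.shape[1] < 2:
        return None
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * matrix.shape[1] + 2), max(3.0, 0.4 * matrix.shape[0] + 2))
    )
    ax.set_facecolor("#d9d9d9")  # reserved "no hit" color under masked cells
    sns.heatmap(
        matrix, ax=ax, vmin=0, vmax=100, cmap="viridis",
        mask=matrix.isna(), linewidths=0.5, linecolor="white",
        cbar_kws={"label": "percent identity"},
    )
    ax.set_xlabel("database")
    ax.set_ylabel("query")
    return _save(fig, out_path, pdf)


def render_logo(profile: MotifProfile, out_path: str | Path, pdf: bool = False) -> Path:
    """Stacked-letter sequence logo; glyph height = frequency × information (bits)."""
    fig, ax = plt.subplots(figsize=(max(3.0, 0.55 * len(profile.information)), 2.8))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for i, (pos, row) in enumerate(profile.frequencies.iterrows()):
        bottom = 0.0
        total = profile.information[i]
        for letter, freq in sorted(row.items(), key=lambda kv: kv[1]):
            height = freq * total
            if height <= 0:
                continue
            tp = TextPath((0, 0), letter, size=1.0, prop=font)
            bbox = tp.get_extents()
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(0.9 / bbox.width, height / bbox.height)
                .translate(i + 0.05, bottom)
            )
            ax.add_patch(
                PathPatch(transform.transform_path(tp),
                          facecolor=_RESIDUE_COLORS.get(letter, "#888888"),
                          edgecolor="none")
            )
            bottom += height
    ax.set_xlim(0, len(profile.information))
    ax.set_ylim(0, MAX_INFORMATION)
    ax.set_xticks(np.arange(len(profile.information)) + 0.5)
    ax.set_xticklabels(profile.frequencies.index)
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_title(f"{profile.pattern}  (n={profile.match_count})")
    return _save(fig, out_path, pdf)


def render_logos(
    matches: Sequence[MotifMatch], out_dir: str | Path, pdf: bool = False
) -> list[Path]:
    """One logo per distinct pattern that returned at least one match."""
    out_dir = Path(out_dir)
    by_pattern: dict[str, list[MotifMatch]] = {}
    for m in matches:
        by_pattern.setdefault(m.pattern.motif, []).append(m)
    outputs: list[Path] = []
    for motif, group in sorted(by_pattern.items()):
        profile = build_motif_profile(group)
        if profile is not None:
            outputs.append(render_logo(profile, out_dir / f"logo_{motif}.png", pdf=pdf))
    return outputs
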