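"""Deterministic matplotlib figures for the sex-linkage report.

Two figure types: a pairwise-distance heatmap with individuals grouped by
sex, and the per-individual locus index tile plot (individuals × selected
loci) in the classic three-state scheme — orange for fragment presence,
green for absence, white for missing calls.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, ListedColormap

from .matrices import MISSING, PaMatrix, Sex, SexRegistry, SnpGenotypeMatrix

#: presence / absence / missing tile colors
TILE_COLORS = {"present": "#ff7f0e", "absent": "#2ca02c", "missing": "#ffffff"}


def _sex_sorted(individuals: Sequence[str], registry: SexRegistry) -> list[str]:
    males = [i for i in individuals if registry[i] is Sex.MALE]
    females = [i for i in individuals if registry[i] is Sex.FEMALE]
    return males + females


def distance_heatmap(
    dist: pd.DataFrame,
    registry: SexRegistry,
    out: Union[str, Path],
    title: str = "",
) -> Path:
    """Save a symmetric pairwise-distance heatmap, males before females."""
    registry.check_covers(list(dist.index))
    order = _sex_sorted(list(dist.index), registry)
    d = dist.loc[order, order]
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(d.to_numpy(), cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    n_m = len([i for i in order if registry[i] is Sex.MALE])
    for pos in (n_m - 0.5,):
        ax.axhline(pos, color="white", lw=1.5)
        ax.axvline(pos, color="white", lw=1.5)
    fig.colorbar(im, ax=ax, label="Hamming distance")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return out


def locus_index_plot(
    matrix: Union[PaMatrix, SnpGenotypeMatrix],
    loci: Sequence[str],
    registry: SexRegistry,
    out: Union[str, Path],
    title: str = "",
) -> Path:
    """Tile plot of selected loci across individuals, grouped by sex.

    For PA markers the tiles are presence (orange) / absence (green) /
    missing (white); SNP matrices are shown on the same scheme with any
    SNP-allele carrier (het or hom) coloured as "present".  Rendering is
    deterministic given the inputs.
    """
    if len(loci) == 0:
        raise ValueError("empty locus selection")
    sub = matrix.subset_loci(list(loci))
    registry.check_covers(sub.individual_ids)
    order = _sex_sorted(sub.individual_ids, registry)
    calls = sub.calls[order].to_numpy().T  # individuals × loci
    shown = np.where(calls == MISSING, -1, np.where(calls == 0, 0, 1))
    cmap = ListedColormap(
        [TILE_COLORS["missing"], TILE_COLORS["absent"], TILE_COLORS["present"]]
    )
    norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5], cmap.N)
    fig, ax = plt.subplots(figsize=(max(4.0, 0.14 * len(loci)), 5.0))
    ax.imshow(shown, cmap=cmap, norm=norm, aspect="auto", interpolation="nearest")
    ax.set_yticks(range(len(order)), order, fontsize=6)
    ax.set_xlabel(f"{sub.marker_type} locus index ({len(loci)} loci)")
    n_m = len([i for i in order if registry[i] is Sex.MALE])
    ax.axhline(n_m - 0.5, color="black", lw=1.0)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return out
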