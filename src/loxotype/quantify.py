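"""Internal-standard normalization and the strain x oxylipin matrix.

Quantification here is deliberately semi-quantitative: each compound's peak
area is divided by the peak area of the spiked internal standard of the same
run, and the resulting ratios are assembled into a compounds-by-strains
matrix suitable for heat-map display. No response factors, no absolute
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NormalizationError, ValidationError

__all__ = ["StrainProfile", "normalize", "build_matrix", "matrix_to_tsv",
           "read_matrix_tsv", "plot_heatmap"]


@dataclass
class StrainProfile:
    """Identified oxylipins and (after normalization) their ratios for one strain."""

    strain_id: str
    species_label: str | None = None
    replicate: int | None = None
    identifications: list = field(default_factory=list)  # IdentificationResult
    compound_areas: dict[str, float] = field(default_factory=dict)
    is_area: float | None = None
    missing_internal_standard: bool = False
    lox_positions: set[int] = field(default_factory=set)
    marker_groups: set[str] = field(default_factory=set)
    oxo_present: bool = False
    normalized: dict[str, float] | None = None

    @property
    def column_label(self) -> str:
        """Matrix column label; replicates carry the '/r<n>' suffix."""
        if self.replicate is None:
            return self.strain_id
        return f"{self.strain_id}/r{self.replicate}"

    @property
    def quantified(self) -> bool:
        return self.normalized is not None


def normalize(profile: StrainProfile) -> StrainProfile:
    """Divide each identified compound's area by the internal-standard area.

    Raises :class:`NormalizationError` (and leaves the profile non-quantified)
    when the internal standard is missing or has non-positive area.
    """
    if profile.is_area is None or profile.missing_internal_standard:
        raise NormalizationError(
            f"{profile.strain_id}: internal standard not found; profile left non-quantified")
    if profile.is_area <= 0:
        raise NormalizationError(
            f"{profile.strain_id}: internal-standard area {profile.is_area} must be > 0")
    profile.normalized = {name: area / profile.is_area
                          for name, area in profile.compound_areas.items()}
    return profile


def build_matrix(profiles: list[StrainProfile],
                 missing_as_na: bool = False) -> pd.DataFrame:
    """Assemble the compounds-by-strains ratio matrix.

    Rows are the union of observed compounds in first-seen order; columns
    preserve the input profile order; absent cells are 0 (or NA on request).
    """
    quantified = [p for p in profiles if p.quantified]
    if not quantified:
        raise ValidationError("no quantified profiles to assemble")
    labels = [p.column_label for p in quantified]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValidationError(f"duplicate strain/replicate columns: {sorted(dupes)}")
    rows: list[str] = []
    for p in quantified:
        for name in p.normalized:
            if name not in rows:
                rows.append(name)
    fill = np.nan if missing_as_na else 0.0
    data = {p.column_label: [p.normalized.get(r, fill) for r in rows] for p in quantified}
    return pd.DataFrame(data, index=pd.Index(rows, name="compound"), columns=labels)


def matrix_to_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def plot_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Render the matrix as a heat map (log1p-scaled viridis, linear colorbar ticks)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.45 * matrix.shape[1] + 2), max(3.0, 0.4 * matrix.shape[0] + 1)))
    im = ax.imshow(np.log1p(matrix.fillna(0.0).to_numpy()), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log(1 + area / IS area)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
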