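"""The per-frame interaction-energy container.

An :class:`EnergySeries` holds the ordered protein–ligand interaction
energies ΔE_IE = ΔE_el + ΔE_vdW sampled along a molecular-dynamics
trajectory, together with the temperature at which entropies should be
evaluated and, optionally, the spacing between frames and per-frame
annotations (frame index, ligand rmsd, ...). It is the object every
entropy estimator and diagnostic in this package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE

__all__ = ["EnergySeries", "interaction_energy"]


@dataclass
class EnergySeries:
    """Ordered per-frame interaction energies with metadata.

    Parameters
    ----------
    values : array-like of float
        ΔE_IE per frame, in kJ/mol. Order defines time.
    temperature : float, default 300.0
        Absolute temperature T in K used for RT in the estimators.
    frame_spacing : float, optional
        Time between successive frames in ps; ``None`` when unknown.
    labels : pandas.DataFrame, optional
        Per-frame annotations (e.g. ``frame``, ``rmsd``). Must have one
        row per energy value when present.
    """

    values: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    frame_spacing: Optional[float] = None
    labels: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size < 1:
            raise ValueError("an EnergySeries needs at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all energies must be finite")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.frame_spacing is not None and self.frame_spacing <= 0:
            raise ValueError("frame_spacing, when given, must be > 0 ps")
        if self.labels is not None:
            self.labels = pd.DataFrame(self.labels).reset_index(drop=True)
            if len(self.labels) != self.values.size:
                raise ValueError(
                    f"labels have {len(self.labels)} rows for "
                    f"{self.values.size} frames"
                )

    def __len__(self) -> int:
        return self.values.size

    def subset(self, mask_or_indices) -> "EnergySeries":
        """Order-preserving subset of frames; metadata carried through."""
        idx = np.asarray(mask_or_indices)
        values = self.values[idx]
        labels = self.labels.loc[idx].reset_index(drop=True) if self.labels is not None else None
        return EnergySeries(values, self.temperature, self.frame_spacing, labels)

    def with_values(self, values: np.ndarray) -> "EnergySeries":
        """New series with replaced energies, metadata except labels kept."""
        return EnergySeries(np.asarray(values, dtype=float), self.temperature, self.frame_spacing)


def interaction_energy(
    elec: Sequence[float],
    vdw: Sequence[float],
    temperature: float = DEFAULT_TEMPERATURE,
    frame_spacing: Optional[float] = None,
    labels: Optional[pd.DataFrame] = None,
) -> EnergySeries:
    """Combine per-frame electrostatic and van-der-Waals terms.

    ΔE_IE = ΔE_el + ΔE_vdW, element-wise over frames, both in kJ/mol.
    """
    elec = np.asarray(elec, dtype=float)
    vdw = np.asarray(vdw, dtype=float)
    if elec.shape != vdw.shape or elec.ndim != 1:
        raise ValueError(
            f"elec and vdw must be 1-d sequences of equal length, "
            f"got shapes {elec.shape} and {vdw.shape}"
        )
    if elec.size < 1:
        raise ValueError("need at least one frame")
    return EnergySeries(elec + vdw, temperature, frame_spacing, labels)
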