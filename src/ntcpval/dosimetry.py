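"""Dose-volume histogram handling and EQD2 conversion.

A cumulative DVH gives, for each dose level, the fraction of a structure's
volume receiving at least that dose. The NTCP model consumes one summary
per salivary gland: the (volume-weighted) mean dose, optionally after
converting every dose bin to the equivalent dose in 2-Gy fractions (EQD2)
under the linear-quadratic model with alpha/beta = 3 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, InvalidDVHError

#: Controlled vocabulary for salivary-gland structure labels.
STRUCTURE_LABELS = ("parotid_ipsi", "parotid_contra", "smg_ipsi", "smg_contra")


@dataclass
class DoseVolumeHistogram:
    """Cumulative dose/volume curve for one structure.

    Parameters
    ----------
    structure_label:
        One of :data:`STRUCTURE_LABELS`, or any other free label.
    bin_edges:
        Strictly increasing dose values in Gy, starting at 0.
    cumulative_volume:
        Fraction of the structure volume receiving at least each bin dose;
        non-increasing, first entry 1.0, all entries in [0, 1].
    absolute_volume:
        Structure volume in cm3; required only for volume-weighted
        combination of several structures.
    """

    structure_label: str
    bin_edges: np.ndarray
    cumulative_volume: np.ndarray
    absolute_volume: float | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cumulative_volume = np.asarray(self.cumulative_volume, dtype=float)
        self.validate()

    def validate(self) -> None:
        lab = self.structure_label
        e, v = self.bin_edges, self.cumulative_volume
        if e.ndim != 1 or v.ndim != 1 or e.size != v.size or e.size < 2:
            raise InvalidDVHError(f"{lab}: need matching 1-d dose and volume arrays with >= 2 bins")
        if np.any(np.diff(e) <= 0) or e[0] < 0:
            raise InvalidDVHError(f"{lab}: bin edges must be strictly increasing and >= 0")
        if np.any(np.diff(v) > 1e-12):
            raise InvalidDVHError(f"{lab}: cumulative volume must be non-increasing")
        if abs(v[0] - 1.0) > 1e-9 or np.any(v < -1e-12) or np.any(v > 1 + 1e-9):
            raise InvalidDVHError(f"{lab}: cumulative volume must start at 1.0 and stay in [0, 1]")


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription used to derive the per-bin fraction dose.

    The per-bin dose per fraction is ``bin_dose / n_fractions``, i.e. uniform
    fractionation of each dose level across the whole course (the convention
    matching simultaneous-integrated-boost delivery).
    """

    prescribed_dose: float
    n_fractions: int
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if self.prescribed_dose <= 0:
            raise ConfigError("prescribed_dose must be > 0")
        if self.n_fractions < 1:
            raise ConfigError("n_fractions must be >= 1")
        if self.alpha_beta <= 0:
            raise ConfigError("alpha_beta must be > 0")


def cumulative_to_differential(dvh: DoseVolumeHistogram) -> list[tuple[float, float]]:
    """Convert a cumulative DVH to (bin center, volume fraction) pairs.

    The fraction in each bin is the drop of the cumulative curve across the
    bin; the representative dose is the midpoint of the adjacent edges. Any
    residual volume above the last edge is ignored (a well-formed cumulative
    DVH ends at 0).
    """
    dvh.validate()
    centers = 0.5 * (dvh.bin_edges[:-1] + dvh.bin_edges[1:])
    fractions = -np.diff(dvh.cumulative_volume)
    return list(zip(centers.tolist(), fractions.tolist()))


def eqd2_bin(dose: float, scheme: FractionationScheme) -> float:
    """EQD2 of a single dose level under the linear-quadratic model.

    ``EQD2 = D * (d + ab) / (2 + ab)`` with per-fraction dose
    ``d = D / n_fractions`` and ``ab`` the alpha/beta ratio in Gy. The map is
    the identity exactly at 2 Gy per fraction.
    """
    if dose < 0:
        raise DataError(f"negative dose {dose} Gy")
    d = dose / scheme.n_fractions
    return dose * (d + scheme.alpha_beta) / (2.0 + scheme.alpha_beta)


def eqd2_transform(dvh: DoseVolumeHistogram, scheme: FractionationScheme) -> DoseVolumeHistogram:
    """Replace every bin dose by its EQD2; the volume axis is unchanged.

    The LQ map is strictly increasing for dose >= 0, so the output satisfies
    the DVH invariants whenever the input does.
    """
    dvh.validate()
    edges = np.array([eqd2_bin(float(d), scheme) for d in dvh.bin_edges])
    return DoseVolumeHistogram(
        structure_label=dvh.structure_label,
        bin_edges=edges,
        cumulative_volume=dvh.cumulative_volume.copy(),
        absolute_volume=dvh.absolute_volume,
    )


def mean_dose(dvh: DoseVolumeHistogram) -> float:
    """Volume-weighted mean dose of the differential DVH, in Gy."""
    diff = cumulative_to_differential(dvh)
    if not diff:
        raise DataError(f"{dvh.structure_label}: empty DVH")
    centers, fractions = np.array(diff).T
    total = fractions.sum()
    if total <= 0:
        raise DataError(f"{dvh.structure_label}: DVH carries no volume")
    return float(np.dot(centers, fractions) / total)


def combined_mean_dose(
    dvhs: list[DoseVolumeHistogram], equal_volume_fallback: bool = False
) -> float:
    """Mean dose over several structures treated as one.

    Weighted by absolute structure volume; with ``equal_volume_fallback``
    every structure gets equal weight when volumes are missing. With a single
    structure this reduces to :func:`mean_dose`.
    """
    if not dvhs:
        raise DataError("no DVHs supplied")
    means = np.array([mean_dose(d) for d in dvhs])
    volumes = [d.absolute_volume for d in dvhs]
    if any(v is None for v in volumes):
        if not equal_volume_fallback:
            raise ConfigError(
                "absolute volumes missing for combined mean; "
                "request the equal-volume fallback explicitly"
            )
        weights = np.ones(len(dvhs))
    else:
        weights = np.asarray(volumes, dtype=float)
    return float(np.dot(means, weights) / weights.sum())


def read_dvh_file(path: str | Path) -> dict[str, DoseVolumeHistogram]:
    """Read one patient's per-structure cumulative DVHs from CSV.

    Expected columns: ``structure,dose_gy,cum_volume_fraction[,volume_cc]``.
    Returns a mapping from structure label to DVH.
    """
    df = pd.read_csv(path)
    required = {"structure", "dose_gy", "cum_volume_fraction"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: DVH file must have columns {sorted(required)}")
    out: dict[str, DoseVolumeHistogram] = {}
    for label, grp in df.groupby("structure", sort=False):
        grp = grp.sort_values("dose_gy")
        vol = None
        if "volume_cc" in grp.columns and grp["volume_cc"].notna().any():
            vol = float(grp["volume_cc"].dropna().iloc[0])
        out[str(label)] = DoseVolumeHistogram(
            structure_label=str(label),
            bin_edges=grp["dose_gy"].to_numpy(),
            cumulative_volume=grp["cum_volume_fraction"].to_numpy(),
            absolute_volume=vol,
        )
    return out


def write_dvh_file(path: str | Path, dvhs: dict[str, DoseVolumeHistogram]) -> None:
    """Write per-structure cumulative DVHs to the CSV layout of :func:`read_dvh_file`."""
    frames = []
    for label, dvh in dvhs.items():
        frames.append(
            pd.DataFrame(
                {
                    "structure": label,
                    "dose_gy": dvh.bin_edges,
                    "cum_volume_fraction": dvh.cumulative_volume,
                    "volume_cc": dvh.absolute_volume,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
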